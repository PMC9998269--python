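"""Ground-truth genome evolution simulator.

A root genome of ``n_genes`` signed genes on ``n_chromosomes`` chromosomes
evolves along the dated species tree.  On each branch, event counts per type
are drawn as Poisson(rate x branch length in My) and applied in random order
at uniformly chosen positions:

* inversion — reverse a segment (geometric length, default mean 5 genes) and
  flip its strands;
* reciprocal translocation — exchange terminal segments of two chromosomes;
* fusion / fission — join two chromosomes (random orientations) / split one;
* duplication — copy a segment (geometric length) to a uniform position,
  creating a duplication node in each affected gene lineage;
* loss — delete one uniformly chosen gene;
* gain — insert a new single-gene family at a uniform position;
* WGD — scheduled per branch: every chromosome is doubled, then each
  duplicate pair is fractionated back to one copy with probability
  ``1 - wgd_retention``.

The simulator records the true genome at every tree node, an event log, and
a gene forest congruent with the duplication/loss history — the ground truth
against which reconstructions are benchmarked.  Everything is reproducible
from the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    FORWARD,
    REVERSE,
    DUPLICATION,
    SPECIATION,
    LEAF,
    Genome,
    GeneTree,
    GeneTreeNode,
    SpeciesTree,
    write_gene_forest,
    write_genome,
)
from .linearize import CARSet
from .reconcile import AncestralGeneSet

__all__ = [
    "SimParams",
    "SimEvent",
    "EvolutionTrace",
    "simulate",
    "make_benchmark",
    "apply_inversion",
    "apply_translocation",
    "apply_fusion",
    "apply_fission",
]

Chromosomes = list  # list of chromosomes; each chromosome: list[(item, strand)]


@dataclass
class SimParams:
    """Simulation parameters: genome size and per-branch per-My event rates."""

    n_genes: int = 5000
    n_chromosomes: int = 20
    inversion_rate: float = 0.0
    translocation_rate: float = 0.0
    fusion_rate: float = 0.0
    fission_rate: float = 0.0
    duplication_rate: float = 0.0
    loss_rate: float = 0.0
    gain_rate: float = 0.0
    inversion_mean_len: float = 5.0
    duplication_mean_len: float = 5.0
    wgd_branches: frozenset[str] = frozenset()
    wgd_retention: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.n_chromosomes or self.n_chromosomes < 1:
            raise ValueError("need n_genes >= n_chromosomes >= 1")
        for name in (
            "inversion_rate", "translocation_rate", "fusion_rate", "fission_rate",
            "duplication_rate", "loss_rate", "gain_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimEvent:
    branch: str  # label of the child node of the branch
    kind: str    # inversion|translocation|fusion|fission|duplication|loss|gain|wgd
    genes: tuple  # affected lineage ids (simulator-internal)
    delta_genes: int = 0  # change in gene count caused by the event
    feasible: bool = True


# ---------------------------------------------------------------------------
# Pure rearrangement operators (no lineage bookkeeping; used by tests too)
# ---------------------------------------------------------------------------

def _flip_seg(seg: Sequence[tuple]) -> list[tuple]:
    return [(g, FORWARD if s == REVERSE else REVERSE) for g, s in reversed(seg)]


def apply_inversion(chroms: Chromosomes, ci: int, pos: int, length: int) -> None:
    chrom = chroms[ci]
    end = min(pos + length, len(chrom))
    chrom[pos:end] = _flip_seg(chrom[pos:end])


def apply_translocation(chroms: Chromosomes, i: int, j: int, a: int, b: int) -> None:
    """Reciprocal exchange of the tails of chromosomes *i* and *j*."""
    ci, cj = chroms[i], chroms[j]
    chroms[i], chroms[j] = ci[:a] + cj[b:], cj[:b] + ci[a:]


def apply_fusion(chroms: Chromosomes, i: int, j: int, flip_i: bool, flip_j: bool) -> None:
    ci = _flip_seg(chroms[i]) if flip_i else chroms[i]
    cj = _flip_seg(chroms[j]) if flip_j else chroms[j]
    keep = [c for k, c in enumerate(chroms) if k not in (i, j)]
    chroms[:] = keep + [ci + cj]


def apply_fission(chroms: Chromosomes, ci: int, pos: int) -> None:
    chrom = chroms.pop(ci)
    chroms.append(chrom[:pos])
    chroms.append(chrom[pos:])


# ---------------------------------------------------------------------------
# Trace
# ---------------------------------------------------------------------------

@dataclass
class EvolutionTrace:
    """Truth container: genomes at every node, forest, event log, lineages."""

    genomes: dict[str, Genome]          # node label -> truth-space Genome
    extant_genomes: dict[str, Genome]   # leaf label -> Genome with extant ids
    forest: list[GeneTree]
    events: list[SimEvent]
    params: SimParams
    # internals for truth mapping
    _inst_at_node: dict[str, dict[int, str]]  # node -> instance -> truth gene id
    _extant_inst: dict[str, int]              # extant gene id -> instance
    _parent: dict[int, int | None]
    #: per forest tree: internal gene-tree node id -> (event, species node
    #: or branch child label where the split truly happened)
    truth_node_info: list[dict[int, tuple[str, str]]] = field(default_factory=list)
    _ancestor_maps: dict[str, dict[str, str | None]] = field(default_factory=dict)

    def ancestor_map(self, node: str) -> dict[str, str | None]:
        """Map extant gene id -> truth gene id at *node* (None if the gene
        arose below the node)."""
        if node in self._ancestor_maps:
            return self._ancestor_maps[node]
        at_node = self._inst_at_node[node]
        cache: dict[int, str | None] = {}

        def climb(inst: int) -> str | None:
            chain = []
            cur: int | None = inst
            while cur is not None and cur not in cache:
                if cur in at_node:
                    cache[cur] = at_node[cur]
                    break
                chain.append(cur)
                cur = self._parent[cur]
            resolved = cache.get(cur) if cur is not None else None
            for c in chain:
                cache[c] = resolved
            return cache[inst] if inst in cache else resolved

        out = {gid: climb(inst) for gid, inst in self._extant_inst.items()}
        self._ancestor_maps[node] = out
        return out

    def branch_orthology(self, parent_node: str, child_node: str) -> dict[str, list[str]]:
        """Truth orthology across one branch: parent gene -> descendant genes."""
        at_parent = self._inst_at_node[parent_node]
        out: dict[str, list[str]] = {}
        for inst, gid in self._inst_at_node[child_node].items():
            cur: int | None = inst
            while cur is not None and cur not in at_parent:
                cur = self._parent[cur]
            if cur is not None:
                out.setdefault(at_parent[cur], []).append(gid)
        return out

    def relabel_carset(self, node: str, ancset: AncestralGeneSet, carset: CARSet) -> CARSet:
        """Express a reconstruction in the truth gene-id space of *node*.

        Each reconstructed ancestral gene is renamed to the truth gene its
        extant descendants point back to (majority vote); ambiguous or
        conflicting genes get unmatchable placeholder names so downstream
        comparison excludes them.
        """
        amap = self.ancestor_map(node)
        votes: dict[str, dict[str, int]] = {}
        for gene in carset.genes():
            tally: dict[str, int] = {}
            for extants in ancset.descendants.get(gene, {}).values():
                for extant in extants:
                    target = amap.get(extant)
                    if target is not None:
                        tally[target] = tally.get(target, 0) + 1
            votes[gene] = tally

        claimed: dict[str, tuple[int, str]] = {}  # truth gene -> (votes, recon gene)
        rename: dict[str, str] = {}
        for gene in sorted(votes):
            tally = votes[gene]
            if not tally:
                continue
            best = max(sorted(tally), key=lambda t: tally[t])
            prev = claimed.get(best)
            if prev is None or tally[best] > prev[0]:
                if prev is not None:
                    rename.pop(prev[1], None)
                claimed[best] = (tally[best], gene)
                rename[gene] = best
        cars = [
            [(rename.get(g, f"__unmatched__{g}"), s) for g, s in car]
            for car in carset.cars
        ]
        return CARSet(ancestor=carset.ancestor, cars=cars, source_mode=carset.source_mode)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

class _Evolver:
    def __init__(self, stree: SpeciesTree, params: SimParams):
        self.stree = stree
        self.params = params
        self.rng = np.random.default_rng(params.seed)
        self._inst = itertools.count()
        self._fam = itertools.count()
        self.fam_of: dict[int, int] = {}
        self.parent: dict[int, int | None] = {}
        self.split_kind: dict[int, str] = {}
        self.split_at: dict[int, str] = {}  # species node (speciation) or branch child (duplication)
        self.events: list[SimEvent] = []
        self.snapshots: dict[str, Chromosomes] = {}

    # -- lineage bookkeeping --------------------------------------------

    def new_instance(self, fam: int, parent: int | None) -> int:
        inst = next(self._inst)
        self.fam_of[inst] = fam
        self.parent[inst] = parent
        return inst

    def root_genome(self) -> Chromosomes:
        p = self.params
        sizes = [p.n_genes // p.n_chromosomes] * p.n_chromosomes
        for k in range(p.n_genes % p.n_chromosomes):
            sizes[k] += 1
        chroms: Chromosomes = []
        for size in sizes:
            chrom = []
            for _ in range(size):
                inst = self.new_instance(next(self._fam), None)
                strand = FORWARD if self.rng.random() < 0.5 else REVERSE
                chrom.append((inst, strand))
            chroms.append(chrom)
        return chroms

    # -- random coordinates ---------------------------------------------

    def _locus(self, chroms: Chromosomes) -> tuple[int, int]:
        total = sum(len(c) for c in chroms)
        k = int(self.rng.integers(total))
        for ci, chrom in enumerate(chroms):
            if k < len(chrom):
                return ci, k
            k -= len(chrom)
        raise AssertionError("unreachable")

    def _geom(self, mean: float) -> int:
        return int(self.rng.geometric(1.0 / max(mean, 1.0)))

    # -- events ----------------------------------------------------------

    def _do_inversion(self, chroms: Chromosomes, branch: str) -> SimEvent:
        ci, pos = self._locus(chroms)
        length = self._geom(self.params.inversion_mean_len)
        affected = tuple(g for g, _ in chroms[ci][pos : pos + length])
        apply_inversion(chroms, ci, pos, length)
        return SimEvent(branch, "inversion", affected)

    def _do_translocation(self, chroms: Chromosomes, branch: str) -> SimEvent:
        if len(chroms) < 2:
            return SimEvent(branch, "translocation", (), feasible=False)
        for _ in range(20):
            i, j = self.rng.choice(len(chroms), size=2, replace=False)
            i, j = int(i), int(j)
            a = int(self.rng.integers(0, len(chroms[i]) + 1))
            b = int(self.rng.integers(0, len(chroms[j]) + 1))
            new_i = len(chroms[i][:a]) + len(chroms[j][b:])
            new_j = len(chroms[j][:b]) + len(chroms[i][a:])
            moved = (len(chroms[i]) - a) + (len(chroms[j]) - b)
            if new_i and new_j and 0 < moved < len(chroms[i]) + len(chroms[j]):
                affected = tuple(g for g, _ in chroms[i][a:] + chroms[j][b:])
                apply_translocation(chroms, i, j, a, b)
                return SimEvent(branch, "translocation", affected)
        return SimEvent(branch, "translocation", (), feasible=False)

    def _do_fusion(self, chroms: Chromosomes, branch: str) -> SimEvent:
        if len(chroms) < 2:
            return SimEvent(branch, "fusion", (), feasible=False)
        i, j = self.rng.choice(len(chroms), size=2, replace=False)
        i, j = int(i), int(j)
        affected = (chroms[i][-1][0], chroms[j][0][0])
        apply_fusion(
            chroms, i, j,
            bool(self.rng.random() < 0.5), bool(self.rng.random() < 0.5),
        )
        return SimEvent(branch, "fusion", affected)

    def _do_fission(self, chroms: Chromosomes, branch: str) -> SimEvent:
        eligible = [ci for ci, c in enumerate(chroms) if len(c) >= 2]
        if not eligible:
            return SimEvent(branch, "fission", (), feasible=False)
        weights = np.array([len(chroms[ci]) - 1 for ci in eligible], dtype=float)
        ci = int(self.rng.choice(eligible, p=weights / weights.sum()))
        pos = int(self.rng.integers(1, len(chroms[ci])))
        affected = (chroms[ci][pos - 1][0], chroms[ci][pos][0])
        apply_fission(chroms, ci, pos)
        return SimEvent(branch, "fission", affected)

    def _do_duplication(self, chroms: Chromosomes, branch: str) -> SimEvent:
        ci, pos = self._locus(chroms)
        length = self._geom(self.params.duplication_mean_len)
        segment = chroms[ci][pos : pos + length]
        continuation, copy = [], []
        for inst, strand in segment:
            fam = self.fam_of[inst]
            self.split_kind[inst] = DUPLICATION
            self.split_at[inst] = branch
            continuation.append((self.new_instance(fam, inst), strand))
            copy.append((self.new_instance(fam, inst), strand))
        chroms[ci][pos : pos + len(segment)] = continuation
        if self.rng.random() < 0.5:
            copy = _flip_seg(copy)
        tj = int(self.rng.integers(len(chroms)))
        tpos = int(self.rng.integers(0, len(chroms[tj]) + 1))
        chroms[tj][tpos:tpos] = copy
        return SimEvent(
            branch, "duplication", tuple(g for g, _ in segment),
            delta_genes=len(segment),
        )

    def _do_loss(self, chroms: Chromosomes, branch: str) -> SimEvent:
        if sum(len(c) for c in chroms) < 2:
            return SimEvent(branch, "loss", (), feasible=False)
        ci, pos = self._locus(chroms)
        inst, _ = chroms[ci].pop(pos)
        if not chroms[ci]:
            del chroms[ci]
        return SimEvent(branch, "loss", (inst,), delta_genes=-1)

    def _do_gain(self, chroms: Chromosomes, branch: str) -> SimEvent:
        inst = self.new_instance(next(self._fam), None)
        strand = FORWARD if self.rng.random() < 0.5 else REVERSE
        ci = int(self.rng.integers(len(chroms)))
        pos = int(self.rng.integers(0, len(chroms[ci]) + 1))
        chroms[ci].insert(pos, (inst, strand))
        return SimEvent(branch, "gain", (inst,), delta_genes=1)

    def _do_wgd(self, chroms: Chromosomes, branch: str) -> SimEvent:
        retention = self.params.wgd_retention
        doubled: Chromosomes = []
        retained = 0
        affected = []
        for chrom in chroms:
            original, duplicate = [], []
            for inst, strand in chrom:
                fam = self.fam_of[inst]
                self.split_kind[inst] = DUPLICATION
                self.split_at[inst] = branch
                a = (self.new_instance(fam, inst), strand)
                b = (self.new_instance(fam, inst), strand)
                if self.rng.random() < retention:
                    original.append(a)
                    duplicate.append(b)
                    retained += 1
                elif self.rng.random() < 0.5:
                    original.append(a)
                else:
                    duplicate.append(b)
                affected.append(inst)
            for part in (original, duplicate):
                if part:
                    doubled.append(part)
        chroms[:] = doubled
        return SimEvent(branch, "wgd", tuple(affected), delta_genes=retained)

    _DISPATCH = {
        "inversion": _do_inversion,
        "translocation": _do_translocation,
        "fusion": _do_fusion,
        "fission": _do_fission,
        "duplication": _do_duplication,
        "loss": _do_loss,
        "gain": _do_gain,
    }

    # -- branch / tree traversal ----------------------------------------

    def evolve_branch(self, chroms: Chromosomes, child: str, length: float) -> Chromosomes:
        chroms = [list(c) for c in chroms]
        if child in self.params.wgd_branches:
            self.events.append(self._do_wgd(chroms, child))
        p = self.params
        kinds: list[str] = []
        for kind, rate in (
            ("inversion", p.inversion_rate),
            ("translocation", p.translocation_rate),
            ("fusion", p.fusion_rate),
            ("fission", p.fission_rate),
            ("duplication", p.duplication_rate),
            ("loss", p.loss_rate),
            ("gain", p.gain_rate),
        ):
            kinds += [kind] * int(self.rng.poisson(rate * length))
        order = self.rng.permutation(len(kinds))
        for k in order:
            self.events.append(self._DISPATCH[kinds[int(k)]](self, chroms, child))
        return chroms

    def run(self) -> None:
        def recurse(node: str, chroms: Chromosomes) -> None:
            self.snapshots[node] = [list(c) for c in chroms]
            for child in self.stree.children(node):
                speciated: Chromosomes = []
                for chrom in chroms:
                    copies = []
                    for inst, strand in chrom:
                        self.split_kind[inst] = SPECIATION
                        self.split_at[inst] = node
                        copies.append((self.new_instance(self.fam_of[inst], inst), strand))
                    speciated.append(copies)
                evolved = self.evolve_branch(
                    speciated, child, self.stree.branch_length(child)
                )
                recurse(child, evolved)

        recurse(self.stree.root, self.root_genome())


def _truth_ids(evolver: _Evolver, node: str) -> dict[int, str]:
    """Stable truth gene ids at a node: f<fam> when single-copy, f<fam>.<k>
    (k by lineage id order) when the family has several copies there."""
    instances = [g for chrom in evolver.snapshots[node] for g, _ in chrom]
    per_fam: dict[int, list[int]] = {}
    for inst in instances:
        per_fam.setdefault(evolver.fam_of[inst], []).append(inst)
    out: dict[int, str] = {}
    for fam, insts in per_fam.items():
        if len(insts) == 1:
            out[insts[0]] = f"f{fam}"
        else:
            for k, inst in enumerate(sorted(insts)):
                out[inst] = f"f{fam}.{k}"
    return out


def _build_forest(
    evolver: _Evolver, extant_label: dict[int, tuple[str, str]]
) -> tuple[list[GeneTree], list[dict[int, tuple[str, str]]]]:
    children_of: dict[int, list[int]] = {}
    for inst, par in evolver.parent.items():
        if par is not None:
            children_of.setdefault(par, []).append(inst)
    roots_by_fam: dict[int, int] = {
        inst: fam
        for inst, fam in evolver.fam_of.items()
        if evolver.parent[inst] is None
    }

    forest: list[GeneTree] = []
    info: list[dict[int, tuple[str, str]]] = []
    for root_inst in sorted(roots_by_fam):
        nodes: dict[int, GeneTreeNode] = {}
        node_info: dict[int, tuple[str, str]] = {}
        counter = itertools.count()

        def build(inst: int) -> int | None:
            if inst in extant_label:
                species, gene_id = extant_label[inst]
                nid = next(counter)
                nodes[nid] = GeneTreeNode(
                    nid, (), species=species, gene_id=gene_id, event=LEAF
                )
                return nid
            kids = [build(c) for c in sorted(children_of.get(inst, ()))]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            nid = next(counter)
            event = evolver.split_kind.get(inst, SPECIATION)
            nodes[nid] = GeneTreeNode(nid, tuple(kids), event=event)
            node_info[nid] = (event, evolver.split_at.get(inst, ""))
            return nid

        root_nid = build(root_inst)
        if root_nid is None:
            continue  # family went extinct
        forest.append(GeneTree(nodes, root_nid))
        info.append(node_info)
    return forest, info


def simulate(stree: SpeciesTree, params: SimParams) -> EvolutionTrace:
    """Evolve a genome along *stree* and return the full ground truth."""
    evolver = _Evolver(stree, params)
    evolver.run()

    # truth genomes (all nodes) -----------------------------------------
    genomes: dict[str, Genome] = {}
    inst_at_node: dict[str, dict[int, str]] = {}
    for node in stree.postorder():
        ids = _truth_ids(evolver, node)
        inst_at_node[node] = ids
        genomes[node] = Genome(
            name=node,
            chromosomes={
                f"c{ci + 1}": [(ids[g], s) for g, s in chrom]
                for ci, chrom in enumerate(evolver.snapshots[node])
            },
            is_ancestral=not stree.is_leaf(node),
        )

    # extant genomes with globally unique extant gene ids ----------------
    extant_label: dict[int, tuple[str, str]] = {}
    extant_genomes: dict[str, Genome] = {}
    extant_inst: dict[str, int] = {}
    for leaf in stree.leaves:
        per_fam_counter: dict[int, int] = {}
        chroms: dict[str, list[tuple[str, str]]] = {}
        for ci, chrom in enumerate(evolver.snapshots[leaf]):
            placements = []
            for inst, strand in chrom:
                fam = evolver.fam_of[inst]
                k = per_fam_counter.get(fam, 0)
                per_fam_counter[fam] = k + 1
                gene_id = f"{leaf}_f{fam}_{k}"
                extant_label[inst] = (leaf, gene_id)
                extant_inst[gene_id] = inst
                placements.append((gene_id, strand))
            chroms[f"c{ci + 1}"] = placements
        extant_genomes[leaf] = Genome(name=leaf, chromosomes=chroms)

    forest, truth_node_info = _build_forest(evolver, extant_label)
    return EvolutionTrace(
        genomes=genomes,
        extant_genomes=extant_genomes,
        forest=forest,
        events=evolver.events,
        params=params,
        truth_node_info=truth_node_info,
        _inst_at_node=inst_at_node,
        _extant_inst=extant_inst,
        _parent=evolver.parent,
    )


# ---------------------------------------------------------------------------
# Benchmark plumbing
# ---------------------------------------------------------------------------

@dataclass
class Benchmark:
    trace: EvolutionTrace
    extant_genomes: dict[str, Genome]
    forest: list[GeneTree]

    def truth(self, node: str) -> Genome:
        return self.trace.genomes[node]


def make_benchmark(
    stree: SpeciesTree, params: SimParams, outdir: str | Path | None = None
) -> Benchmark:
    """Simulate and package reconstruction inputs plus the truth genomes.

    With *outdir*, writes ``genomes/<leaf>.tsv``, ``forest.nhx``,
    ``truth/<node>.tsv`` and ``events.tsv`` in the package dialects.
    """
    trace = simulate(stree, params)
    bench = Benchmark(
        trace=trace, extant_genomes=trace.extant_genomes, forest=trace.forest
    )
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "genomes").mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(parents=True, exist_ok=True)
        for leaf, genome in trace.extant_genomes.items():
            (outdir / "genomes" / f"{leaf}.tsv").write_text(write_genome(genome))
        for node, genome in trace.genomes.items():
            if genome.is_ancestral:
                (outdir / "truth" / f"{node}.tsv").write_text(write_genome(genome))
        (outdir / "forest.nhx").write_text(write_gene_forest(trace.forest))
        lines = ["# branch\tkind\tfeasible\tdelta_genes\tn_affected"]
        for ev in trace.events:
            lines.append(
                f"{ev.branch}\t{ev.kind}\t{int(ev.feasible)}\t{ev.delta_genes}\t{len(ev.genes)}"
            )
        (outdir / "events.tsv").write_text("\n".join(lines) + "\n")
    return bench
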