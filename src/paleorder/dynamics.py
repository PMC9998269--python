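"""Rearrangement dynamics between genomes at successive tree nodes.

Successive genomes are first projected onto their one-to-one orthologues
(genes with several descendants are ambiguous to place and dropped).
Synteny blocks are maximal runs of orthologues consecutive in both genomes
with consistent relative orientation — a deliberately strict, gap-free
stand-in for chained-homology block detectors.  A breakpoint is a block end
that is interior to a chromosome in at least one of the two genomes; each
junction involves two block ends, so the count halves.  Under this
convention an inversion or reciprocal translocation leaves 2 breakpoints and
a fusion or fission leaves 1.

Interchromosomal events are called from groups of at least 20 orthologues
changing chromosome assignment, examining only chromosomes larger than 200
genes; a reciprocal exchange seen from both the fission view and the fusion
view is counted once and classified as a translocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import Genome

__all__ = [
    "SyntenyBlock",
    "BranchDynamics",
    "InterchromosomalEvent",
    "one_to_one",
    "synteny_blocks",
    "breakpoints",
    "breakpoint_flanks",
    "interchromosomal_events",
    "branch_rates",
    "breakpoint_map",
]

SHORT_BRANCH_MY = 5.0
MIN_GROUP = 20
MIN_CHROM = 200


def one_to_one(orth: Mapping[str, Sequence[str]]) -> dict[str, str]:
    """Restrict an orthology map to one-to-one pairs (others are ambiguous)."""
    counts: dict[str, int] = {}
    for targets in orth.values():
        for t in targets:
            counts[t] = counts.get(t, 0) + 1
    return {
        g: targets[0]
        for g, targets in orth.items()
        if len(targets) == 1 and counts[targets[0]] == 1
    }


def _positions(genome: Genome, keep: set[str]) -> dict[str, tuple[str, int, str]]:
    """gene -> (chromosome, projected index, strand), keeping *keep* genes."""
    out: dict[str, tuple[str, int, str]] = {}
    for chrom, placements in genome.chromosomes.items():
        idx = 0
        for gene, strand in placements:
            if gene in keep:
                out[gene] = (chrom, idx, strand)
                idx += 1
    return out


@dataclass
class SyntenyBlock:
    genes: list[str]            # parent-genome gene ids, in parent order
    parent_chrom: str
    child_chrom: str
    orientation: int            # +1 collinear, -1 reversed


def synteny_blocks(
    parent: Genome, child: Genome, orth: Mapping[str, Sequence[str]]
) -> list[SyntenyBlock]:
    """Maximal collinear runs of one-to-one orthologues (strict, gap 0)."""
    o2o = one_to_one(orth)
    if not o2o:
        raise ValueError("no shared one-to-one orthologues between genomes")
    child_genes = set(o2o.values())
    parent_pos = _positions(parent, set(o2o))
    child_pos = _positions(child, child_genes)

    blocks: list[SyntenyBlock] = []
    for pchrom, placements in parent.chromosomes.items():
        run: list[str] = []

        def close_run() -> None:
            if run:
                g0 = run[0]
                cchrom, _, _ = child_pos[o2o[g0]]
                rel = _rel(g0)
                blocks.append(
                    SyntenyBlock(list(run), pchrom, cchrom, rel)
                )
                run.clear()

        def _rel(g: str) -> int:
            return 1 if parent_pos[g][2] == child_pos[o2o[g]][2] else -1

        projected = [g for g, _ in placements if g in parent_pos]
        for g in projected:
            if not run:
                run.append(g)
                continue
            prev = run[-1]
            c_prev, c_cur = child_pos[o2o[prev]], child_pos[o2o[g]]
            same_chrom = c_prev[0] == c_cur[0]
            rel_prev, rel_cur = _rel(prev), _rel(g)
            step = c_cur[1] - c_prev[1]
            if same_chrom and rel_prev == rel_cur and step == rel_cur:
                run.append(g)
            else:
                close_run()
                run.append(g)
        close_run()
    return blocks


def breakpoints(
    parent: Genome, child: Genome, orth: Mapping[str, Sequence[str]]
) -> int:
    """Number of synteny-block boundaries that are not chromosome ends."""
    blocks = synteny_blocks(parent, child, orth)
    o2o = one_to_one(orth)
    parent_pos = _positions(parent, set(o2o))
    child_pos = _positions(child, set(o2o.values()))
    parent_len: dict[str, int] = {}
    for chrom, idx, _ in parent_pos.values():
        parent_len[chrom] = max(parent_len.get(chrom, 0), idx + 1)
    child_len: dict[str, int] = {}
    for chrom, idx, _ in child_pos.values():
        child_len[chrom] = max(child_len.get(chrom, 0), idx + 1)

    loose_ends = 0
    for block in blocks:
        p_first, p_last = parent_pos[block.genes[0]], parent_pos[block.genes[-1]]
        c_first = child_pos[o2o[block.genes[0]]][1]
        c_last = child_pos[o2o[block.genes[-1]]][1]
        c_lo, c_hi = min(c_first, c_last), max(c_first, c_last)
        ends_parent = (
            p_first[1] > 0,
            p_last[1] < parent_len[p_first[0]] - 1,
        )
        # pair each parent-side block end with the child-side end of the same
        # physical junction: for reversed blocks the parent-left end sits at
        # the child-high coordinate
        ends_child = (
            c_lo > 0,
            c_hi < child_len[block.child_chrom] - 1,
        )
        if block.orientation == -1:
            ends_child = (ends_child[1], ends_child[0])
        for p_int, c_int in zip(ends_parent, ends_child):
            if p_int or c_int:
                loose_ends += 1
    # Interior rearrangements leave an even count (two ends per junction);
    # events at chromosome extremities can leave an unpaired end, in which
    # case the half-count is floored.  Documented convention, exact for
    # spaced interior events.
    return loose_ends // 2


def breakpoint_flanks(
    parent: Genome, child: Genome, orth: Mapping[str, Sequence[str]]
) -> list[str]:
    """Parent-genome genes immediately left of an interior block junction."""
    blocks = synteny_blocks(parent, child, orth)
    o2o = one_to_one(orth)
    parent_pos = _positions(parent, set(o2o))
    parent_len: dict[str, int] = {}
    for chrom, idx, _ in parent_pos.values():
        parent_len[chrom] = max(parent_len.get(chrom, 0), idx + 1)
    flanks = []
    for block in blocks:
        last = block.genes[-1]
        chrom, idx, _ = parent_pos[last]
        if idx < parent_len[chrom] - 1:
            flanks.append(last)
    return flanks


# ---------------------------------------------------------------------------
# Interchromosomal events
# ---------------------------------------------------------------------------

@dataclass
class InterchromosomalEvent:
    kind: str  # fission | fusion | translocation
    parent_chroms: tuple[str, ...]
    child_chroms: tuple[str, ...]


def interchromosomal_events(
    parent: Genome,
    child: Genome,
    orth: Mapping[str, Sequence[str]],
    min_group: int = MIN_GROUP,
    min_chrom: int = MIN_CHROM,
) -> tuple[int, list[InterchromosomalEvent]]:
    """Call fusions, fissions and translocations from chromosome assignment.

    Only source chromosomes larger than *min_chrom* genes are examined; a
    destination group must hold at least *min_group* orthologues.  Candidate
    links are grouped into connected components so a reciprocal exchange is
    one event, classified translocation.
    """
    o2o = one_to_one(orth)
    parent_sizes = {c: len(p) for c, p in parent.chromosomes.items()}
    child_sizes = {c: len(p) for c, p in child.chromosomes.items()}
    parent_chrom = {g: c for c, p in parent.chromosomes.items() for g, _ in p}
    child_chrom = {g: c for c, p in child.chromosomes.items() for g, _ in p}

    # shared-orthologue counts per (parent chrom, child chrom)
    link_counts: dict[tuple[str, str], int] = {}
    for pg, cg in o2o.items():
        key = (parent_chrom[pg], child_chrom[cg])
        link_counts[key] = link_counts.get(key, 0) + 1
    links = {k for k, n in link_counts.items() if n >= min_group}

    def candidates(view: str) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        if view == "fission":
            groups: dict[str, list[tuple[str, str]]] = {}
            for pch, cch in links:
                if parent_sizes[pch] > min_chrom:
                    groups.setdefault(pch, []).append((pch, cch))
        else:
            groups = {}
            for pch, cch in links:
                if child_sizes[cch] > min_chrom:
                    groups.setdefault(cch, []).append((pch, cch))
        for _src, members in groups.items():
            if len(members) < 2:
                continue
            members.sort(key=lambda lk: (-link_counts[lk], lk))
            out.update(members[1:])  # all but the dominant assignment
        return out

    fission_view = candidates("fission")
    fusion_view = candidates("fusion")
    all_candidates = fission_view | fusion_view
    if not all_candidates:
        return 0, []

    # connected components over the >=min_group link graph
    adjacency: dict[str, set[str]] = {}
    for pch, cch in links:
        adjacency.setdefault(f"p:{pch}", set()).add(f"c:{cch}")
        adjacency.setdefault(f"c:{cch}", set()).add(f"p:{pch}")
    component_of: dict[str, int] = {}
    comp = 0
    for start in sorted(adjacency):
        if start in component_of:
            continue
        stack = [start]
        component_of[start] = comp
        while stack:
            cur = stack.pop()
            for nxt in adjacency[cur]:
                if nxt not in component_of:
                    component_of[nxt] = comp
                    stack.append(nxt)
        comp += 1

    by_comp: dict[int, dict[str, set[tuple[str, str]]]] = {}
    for cand in all_candidates:
        cid = component_of[f"p:{cand[0]}"]
        entry = by_comp.setdefault(cid, {"fission": set(), "fusion": set()})
        if cand in fission_view:
            entry["fission"].add(cand)
        if cand in fusion_view:
            entry["fusion"].add(cand)

    events: list[InterchromosomalEvent] = []
    for cid in sorted(by_comp):
        entry = by_comp[cid]
        involved = entry["fission"] | entry["fusion"]
        pchroms = tuple(sorted({p for p, _ in involved}))
        cchroms = tuple(sorted({c for _, c in involved}))
        if entry["fission"] and entry["fusion"]:
            kind = "translocation"
        elif entry["fission"]:
            kind = "fission"
        else:
            kind = "fusion"
        events.append(InterchromosomalEvent(kind, pchroms, cchroms))
    return len(events), events


# ---------------------------------------------------------------------------
# Rates and maps
# ---------------------------------------------------------------------------

@dataclass
class BranchDynamics:
    branch: tuple[str, str]  # (parent label, child label)
    n_breakpoints: int
    n_interchromosomal: int
    branch_length: float  # My
    breakpoint_rate: float = field(init=False)
    rearrangement_rate: float = field(init=False)
    short_branch: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.branch_length <= 0:
            raise ValueError("branch length must be positive to compute rates")
        self.breakpoint_rate = self.n_breakpoints / self.branch_length
        self.rearrangement_rate = self.n_interchromosomal / self.branch_length
        self.short_branch = self.branch_length < SHORT_BRANCH_MY


def branch_rates(
    n_breakpoints: int,
    n_interchromosomal: int,
    branch_length: float,
    branch: tuple[str, str] = ("", ""),
) -> BranchDynamics:
    """Per-My breakpoint and rearrangement rates for one branch; branches
    shorter than 5 My are flagged to avoid small-sample distortions."""
    return BranchDynamics(
        branch=branch,
        n_breakpoints=n_breakpoints,
        n_interchromosomal=n_interchromosomal,
        branch_length=branch_length,
    )


def breakpoint_map(
    flank_genes: Iterable[Iterable[str]],
    reference: Genome,
    window: int,
) -> list[int]:
    """Cumulative per-window breakpoint counts on a reference genome.

    *flank_genes* holds, per branch, the reference-space genes immediately
    left of each breakpoint; windows are consecutive non-overlapping blocks
    of *window* genes in reference reading order (chromosomes concatenated).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rank: dict[str, int] = {}
    pos = 0
    for placements in reference.chromosomes.values():
        for gene, _ in placements:
            rank[gene] = pos
            pos += 1
    n_windows = (pos + window - 1) // window
    counts = [0] * max(n_windows, 1)
    for per_branch in flank_genes:
        for gene in per_branch:
            if gene in rank:
                counts[rank[gene] // window] += 1
    return counts
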