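"""End-to-end drivers: reconstruction runs, simulation benchmarks, dynamics.

These functions orchestrate the library modules for batch use and back the
command-line interface.  All randomness flows from explicit seeds and all
outputs are canonicalized text, so a run is byte-reproducible from its
config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .adjacency import informative_pairs
from .dynamics import branch_rates, breakpoints, interchromosomal_events
from .io import (
    Genome,
    SpeciesTree,
    parse_gene_forest,
    parse_species_tree,
    read_genome,
    write_ancestral_genome,
)
from .linearize import CARSet, ConstraintParams, carset_to_genome, reconstruct
from .metrics import assembly_stats, compare_to_truth, quality_filter
from .reconcile import ancestral_gene_content, reconcile_forest
from .simulate import SimParams, make_benchmark

__all__ = [
    "RunConfig",
    "load_config",
    "run_reconstruction",
    "run_benchmark",
    "run_dynamics",
    "family_orthology",
    "deepest_ancestors",
]

logger = logging.getLogger("paleorder")


@dataclass
class RunConfig:
    """Paths and knobs of a reconstruction run (one YAML file)."""

    tree: Path
    forest: Path
    genome_dir: Path
    out_dir: Path
    mode: str = "basic"
    tree_parameter: float = 0.35
    passes: int = 2
    scaffold_rounds: int = 2
    min_weight: int = 1
    clade: str = "vertebrate"
    seed: int = 0
    log_level: str = "INFO"

    def params(self) -> ConstraintParams:
        return ConstraintParams(
            tree_parameter=self.tree_parameter,
            passes=self.passes,
            scaffold_rounds=self.scaffold_rounds,
            min_weight=self.min_weight,
        )

    def validate(self) -> None:
        for attr in ("tree", "forest", "genome_dir"):
            path = Path(getattr(self, attr))
            if not path.exists():
                raise FileNotFoundError(f"{attr} path does not exist: {path}")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("tree", "forest", "genome_dir", "out_dir"):
        if key in raw:
            raw[key] = Path(raw[key])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_reconstruction(config: RunConfig) -> Path:
    """Reconstruct every ancestor; write CAR files, stats and a manifest.

    Per-ancestor failures are logged and the run continues; a RuntimeError
    summarizing them is raised at the end (nonzero exit in the CLI).
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    stree = parse_species_tree(Path(config.tree).read_text())
    forest = parse_gene_forest(Path(config.forest).read_text(), stree)
    genomes = {
        leaf: read_genome(Path(config.genome_dir) / f"{leaf}.tsv", name=leaf)
        for leaf in stree.leaves
    }
    out = Path(config.out_dir)
    (out / "cars").mkdir(parents=True, exist_ok=True)

    reconciliations = reconcile_forest(forest, stree)
    stats_rows = ["# ancestor\tn_cars\tn_genes\tL70\tG50\tn_informative"]
    failures: dict[str, str] = {}
    # leaf-ward to root-ward: postorder lists shallow ancestors first
    for ancestor in stree.internal_nodes:
        try:
            carsets = reconstruct(
                stree,
                forest,
                genomes,
                mode=config.mode,
                params=config.params(),
                ancestors=[ancestor],
                reconciliations=reconciliations,
            )
            carset = carsets[ancestor]
            genome = carset_to_genome(carset)
            (out / "cars" / f"{ancestor}.tsv").write_text(
                write_ancestral_genome(genome)
            )
            stats = assembly_stats(carset, clade=config.clade)
            n_informative = len(informative_pairs(stree, ancestor))
            stats_rows.append(
                f"{ancestor}\t{stats.n_cars}\t{stats.total_genes}\t"
                f"{stats.l70}\t{stats.g50}\t{n_informative}"
            )
            logger.info(
                "%s: %d CARs, %d genes, L70=%d G50=%d",
                ancestor, stats.n_cars, stats.total_genes, stats.l70, stats.g50,
            )
        except Exception as exc:  # per-ancestor failure policy
            logger.error("ancestor %s failed: %s", ancestor, exc)
            failures[ancestor] = str(exc)

    (out / "stats.tsv").write_text("\n".join(stats_rows) + "\n")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "tree_parameter": config.tree_parameter,
        "passes": config.passes,
        "scaffold_rounds": config.scaffold_rounds,
        "inputs": {
            "tree": _sha256(Path(config.tree)),
            "forest": _sha256(Path(config.forest)),
            "genomes": {
                leaf: _sha256(Path(config.genome_dir) / f"{leaf}.tsv")
                for leaf in stree.leaves
            },
        },
        "failures": failures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if failures:
        raise RuntimeError(
            f"{len(failures)} ancestor(s) failed: {sorted(failures)}"
        )
    return out


def deepest_ancestors(stree: SpeciesTree, n: int = 2) -> list[str]:
    """The *n* oldest non-root ancestors (the root has no outgroup evidence)."""
    candidates = [a for a in stree.internal_nodes if a != stree.root]
    candidates.sort(key=lambda a: (-stree.age(a), a))
    return candidates[:n]


def run_benchmark(
    stree: SpeciesTree,
    sim_params: SimParams,
    seeds: Sequence[int],
    mode: str = "basic",
    params: ConstraintParams | None = None,
    ancestors: Sequence[str] | None = None,
) -> list[dict]:
    """simulate -> reconstruct -> compare_to_truth, one row per (seed, ancestor)."""
    rows: list[dict] = []
    for seed in seeds:
        run_params = dataclasses.replace(sim_params, seed=seed)
        bench = make_benchmark(stree, run_params)
        forest = bench.forest
        reconciliations = reconcile_forest(forest, stree)
        targets = (
            list(ancestors) if ancestors is not None else list(stree.internal_nodes)
        )
        carsets = reconstruct(
            stree,
            forest,
            bench.extant_genomes,
            mode=mode,
            params=params,
            ancestors=targets,
            reconciliations=reconciliations,
        )
        for ancestor in targets:
            ancset = ancestral_gene_content(
                forest, stree, ancestor, reconciliations
            )
            relabeled = bench.trace.relabel_carset(
                ancestor, ancset, carsets[ancestor]
            )
            cmp = compare_to_truth(relabeled, bench.truth(ancestor))
            rows.append(
                {
                    "seed": seed,
                    "ancestor": ancestor,
                    "tp": cmp.tp,
                    "fp": cmp.fp,
                    "fn": cmp.fn,
                    "sensitivity": cmp.sensitivity,
                    "precision": cmp.precision,
                    "agreement": cmp.agreement,
                }
            )
    return rows


def family_orthology(parent: Genome, child: Genome) -> dict[str, list[str]]:
    """Orthology between truth-dialect genomes whose gene ids are
    ``f<family>`` or ``f<family>.<copy>`` (the simulator's convention)."""
    def fam(gene: str) -> str:
        return gene.split(".", 1)[0]

    child_by_fam: dict[str, list[str]] = {}
    for gene in sorted(child.genes()):
        child_by_fam.setdefault(fam(gene), []).append(gene)
    out: dict[str, list[str]] = {}
    for gene in sorted(parent.genes()):
        targets = child_by_fam.get(fam(gene))
        if targets:
            out[gene] = list(targets)
    return out


def run_dynamics(
    stree: SpeciesTree,
    genomes: Mapping[str, Genome],
    orthologies: Mapping[tuple[str, str], Mapping[str, Sequence[str]]] | None = None,
    apply_quality_filter: bool = False,
    min_group: int = 20,
    min_chrom: int = 200,
) -> list[dict]:
    """Breakpoints, interchromosomal events and per-My rates per tree branch.

    *genomes* maps node labels to genomes at those nodes (ancestral genomes
    may be reconstructions or simulator truth).  Without explicit
    *orthologies*, gene ids are matched by the simulator's family convention.
    With the quality filter on, branches whose ancestral endpoint fails
    G50 > 230 / L70 < 40 are skipped.
    """
    if not genomes:
        raise ValueError("no genomes supplied")
    rows: list[dict] = []
    for node in stree.postorder():
        parent = stree.parent(node)
        if parent is None or parent not in genomes or node not in genomes:
            continue
        pg, cg = genomes[parent], genomes[node]
        if apply_quality_filter:
            as_cars = CARSet(
                ancestor=parent,
                cars=[list(p) for p in pg.chromosomes.values()],
            )
            if not quality_filter(as_cars):
                logger.info("skipping branch to %s: %s fails quality filter", node, parent)
                continue
        orth = (
            orthologies[(parent, node)]
            if orthologies is not None
            else family_orthology(pg, cg)
        )
        n_bp = breakpoints(pg, cg, orth)
        n_inter, _events = interchromosomal_events(
            pg, cg, orth, min_group=min_group, min_chrom=min_chrom
        )
        length = stree.branch_length(node)
        if length <= 0:
            logger.warning("branch to %s has zero length; rates omitted", node)
            continue
        dyn = branch_rates(n_bp, n_inter, length, branch=(parent, node))
        rows.append(
            {
                "parent": parent,
                "child": node,
                "n_breakpoints": dyn.n_breakpoints,
                "n_interchromosomal": dyn.n_interchromosomal,
                "branch_My": dyn.branch_length,
                "breakpoint_rate": dyn.breakpoint_rate,
                "rearrangement_rate": dyn.rearrangement_rate,
                "short_branch": dyn.short_branch,
            }
        )
    return rows
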