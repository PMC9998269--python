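"""Stated-world benchmark configurations used for validation.

The desk-scale benchmark evolves 5,000 genes on 20 chromosomes along a dated
8-leaf tree (total branch length 450 My, mean branch 32.1 My).  Rearrangement
rates are split realistically across event types (inversions dominate) and
sum to ~0.62 events/My, i.e. about 20 rearrangements per branch on average.
The duplication/loss variant adds segmental duplications at a rate putting
~5% of gene families in multi-copy state (50 expected events of mean length
5 over the tree) and single-gene losses removing ~5% of genes (250 expected
events).  These settings are fixed a priori; benchmark quality is always
measured at the two oldest non-root ancestors, the best-sampled nodes that
still have outgroup evidence.
"""

from __future__ import annotations

from .io import SpeciesTree, parse_species_tree
from .simulate import SimParams

__all__ = [
    "BENCHMARK_TREE_NEWICK",
    "benchmark_tree",
    "single_copy_params",
    "duplication_loss_params",
]

#: 8 extant species, root age 100 My, 14 branches totalling 450 My.
BENCHMARK_TREE_NEWICK = (
    "(((A:30,B:30)AB:30,(C:35,D:35)CD:25)ABCD:40,"
    "((E:25,F:25)EF:35,(G:40,H:40)GH:20)EFGH:40)R;"
)

_TOTAL_TREE_MY = 450.0

# events/My; together ~0.622/My -> ~20 events per mean 32.1-My branch
_INVERSION_RATE = 0.45
_TRANSLOCATION_RATE = 0.10
_FUSION_RATE = 0.035
_FISSION_RATE = 0.035

# ~5% duplicated families: 50 expected segmental duplications of mean
# length 5 genes over the whole tree; ~5% losses: 250 expected single-gene
# losses over 5,000 genes
_DUPLICATION_RATE = 50.0 / _TOTAL_TREE_MY
_LOSS_RATE = 250.0 / _TOTAL_TREE_MY


def benchmark_tree() -> SpeciesTree:
    return parse_species_tree(BENCHMARK_TREE_NEWICK)


def single_copy_params(seed: int = 1) -> SimParams:
    """Rearrangement-only benchmark: duplication/loss/gain rates all zero."""
    return SimParams(
        n_genes=5000,
        n_chromosomes=20,
        inversion_rate=_INVERSION_RATE,
        translocation_rate=_TRANSLOCATION_RATE,
        fusion_rate=_FUSION_RATE,
        fission_rate=_FISSION_RATE,
        seed=seed,
    )


def duplication_loss_params(seed: int = 1) -> SimParams:
    """Benchmark not restricted to single-copy genes (~5% duplicated
    families, ~5% losses) on top of the same rearrangement rates."""
    return SimParams(
        n_genes=5000,
        n_chromosomes=20,
        inversion_rate=_INVERSION_RATE,
        translocation_rate=_TRANSLOCATION_RATE,
        fusion_rate=_FUSION_RATE,
        fission_rate=_FISSION_RATE,
        duplication_rate=_DUPLICATION_RATE,
        loss_rate=_LOSS_RATE,
        seed=seed,
    )
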