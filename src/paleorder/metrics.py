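"""Contiguity statistics and truth-comparison statistics.

Contiguity is measured in gene units: L70 is the smallest number of CARs
adding up to 70% of the total genome length, G50 the length of the CAR at
which cumulative descending length first reaches 50%.  Chromosomal-scale
classification uses strict thresholds (vertebrates: L70 < 100 and G50 > 450;
plants: L70 < 20 and G50 > 450).

Reconstruction accuracy against a known truth is computed on oriented
adjacency sets (unordered extremity pairs): sensitivity TP/(TP+FN),
precision TP/(TP+FP) and agreement TP/(TP+FP+FN) — the Jaccard index of the
two adjacency sets, which satisfies agreement = 1/(1/sens + 1/prec - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .adjacency import Edge, adjacency_set, left_extremity, right_extremity
from .io import Genome
from .linearize import CARSet

__all__ = [
    "AssemblyStats",
    "TruthComparison",
    "l70",
    "g50",
    "assembly_stats",
    "classify",
    "compare_to_truth",
    "quality_filter",
    "jaccard_from_rates",
    "carset_adjacencies",
]

CLADE_THRESHOLDS = {
    # clade -> (max exclusive L70, min exclusive G50) for "chromosomal"
    "vertebrate": (100, 450),
    "plant": (20, 450),
}

CHROMOSOMAL = "chromosomal"
SUBCHROMOSOMAL = "subchromosomal"


def _lengths(cars: CARSet | Sequence[int]) -> list[int]:
    if isinstance(cars, CARSet):
        lengths = cars.lengths
    else:
        lengths = list(cars)
    if not lengths:
        raise ValueError("empty CAR set")
    return sorted(lengths, reverse=True)


def l70(cars: CARSet | Sequence[int]) -> int:
    """Smallest number of CARs adding up to 70% of total length (gene units)."""
    lengths = _lengths(cars)
    target = 0.70 * sum(lengths)
    cumulative = 0
    for k, length in enumerate(lengths, start=1):
        cumulative += length
        if cumulative >= target:
            return k
    return len(lengths)


def g50(cars: CARSet | Sequence[int]) -> int:
    """Length of the CAR at which cumulative descending length reaches 50%."""
    lengths = _lengths(cars)
    target = 0.50 * sum(lengths)
    cumulative = 0
    for length in lengths:
        cumulative += length
        if cumulative >= target:
            return length
    return lengths[-1]


@dataclass
class AssemblyStats:
    n_cars: int
    total_genes: int
    l70: int
    g50: int
    clade_class: str | None = None


def classify(stats: "AssemblyStats | tuple[int, int]", clade: str) -> str:
    """Chromosomal vs subchromosomal classification at clade thresholds."""
    if clade not in CLADE_THRESHOLDS:
        raise ValueError(f"unknown clade {clade!r}; expected {sorted(CLADE_THRESHOLDS)}")
    if isinstance(stats, AssemblyStats):
        value_l70, value_g50 = stats.l70, stats.g50
    else:
        value_l70, value_g50 = stats
    max_l70, min_g50 = CLADE_THRESHOLDS[clade]
    if value_l70 < max_l70 and value_g50 > min_g50:
        return CHROMOSOMAL
    return SUBCHROMOSOMAL


def assembly_stats(cars: CARSet, clade: str | None = None) -> AssemblyStats:
    stats = AssemblyStats(
        n_cars=len(cars.cars),
        total_genes=cars.n_genes,
        l70=l70(cars),
        g50=g50(cars),
    )
    if clade is not None:
        stats.clade_class = classify(stats, clade)
    return stats


def quality_filter(cars: CARSet, min_g50: int = 230, max_l70: int = 40) -> bool:
    """Reconstruction-quality filter used to select ancestors for dynamics
    analyses (default G50 > 230 and L70 < 40, strict)."""
    return g50(cars) > min_g50 and l70(cars) < max_l70


# ---------------------------------------------------------------------------
# Truth comparison
# ---------------------------------------------------------------------------

@dataclass
class TruthComparison:
    tp: int
    fp: int
    fn: int
    n_only_recon: int = 0  # genes absent from the truth genome
    n_only_truth: int = 0  # genes absent from the reconstruction

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 1.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 1.0

    @property
    def agreement(self) -> float:
        denom = self.tp + self.fp + self.fn
        return self.tp / denom if denom else 1.0


def jaccard_from_rates(sensitivity: float, precision: float) -> float:
    """Agreement implied by sensitivity and precision when TP > 0:
    TP/(TP+FP+FN) = 1/(1/sens + 1/prec - 1)."""
    if sensitivity <= 0 or precision <= 0:
        raise ValueError("rates must be positive")
    return 1.0 / (1.0 / sensitivity + 1.0 / precision - 1.0)


def carset_adjacencies(cars: CARSet) -> set[Edge]:
    """Oriented adjacency set of a CAR set."""
    out: set[Edge] = set()
    for car in cars.cars:
        for (g1, s1), (g2, s2) in zip(car, car[1:]):
            out.add(frozenset((right_extremity(g1, s1), left_extremity(g2, s2))))
    return out


def _restrict(adjacencies: set[Edge], universe: set[str]) -> set[Edge]:
    return {
        edge for edge in adjacencies if all(gene in universe for gene, _ in edge)
    }


def compare_to_truth(recon: CARSet, truth: Genome) -> TruthComparison:
    """Adjacency-level accuracy of a reconstruction against a truth genome.

    Both sides must be expressed in the same gene-id space; genes present on
    only one side are excluded from the adjacency sets and counted
    separately.
    """
    recon_genes = recon.genes()
    truth_genes = truth.genes()
    shared = recon_genes & truth_genes
    if not shared:
        raise ValueError("disjoint gene universes: cannot compare")
    recon_adj = _restrict(carset_adjacencies(recon), shared)
    truth_adj = _restrict(adjacency_set(truth), shared)
    tp = len(recon_adj & truth_adj)
    fp = len(recon_adj - truth_adj)
    fn = len(truth_adj - recon_adj)
    return TruthComparison(
        tp=tp,
        fp=fp,
        fn=fn,
        n_only_recon=len(recon_genes - truth_genes),
        n_only_truth=len(truth_genes - recon_genes),
    )
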