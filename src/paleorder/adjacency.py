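"""Conserved-adjacency extraction and the per-ancestor weighted graph.

An adjacency is an unordered pair of gene *extremities*.  Each gene has a
``tail`` (5') and a ``head`` (3') in its own reading frame: a ``+`` placement
exposes its tail on the chromosome-left side and its head on the right, a
``-`` placement the reverse.  Encoding adjacencies as extremity pairs makes
them invariant under reading a chromosome in either direction, which is what
"adjacent and in the same orientation" requires.

For a target ancestor, every pair of extant genomes whose tree path crosses
the ancestor is informative; adjacencies conserved in such a pair are
parsimony evidence for the ancestral gene order, and pairwise votes
accumulate as integer edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import FORWARD, Genome, SpeciesTree

__all__ = [
    "HEAD",
    "TAIL",
    "Extremity",
    "Edge",
    "AdjacencyGraph",
    "informative_pairs",
    "conserved_adjacencies",
    "adjacency_set",
    "build_graph",
    "export_graph",
]

HEAD = "h"
TAIL = "t"

Extremity = tuple[str, str]  # (ancestral gene id, HEAD|TAIL)
Edge = frozenset  # frozenset of two Extremities


def right_extremity(gene: str, strand: str) -> Extremity:
    return (gene, HEAD if strand == FORWARD else TAIL)


def left_extremity(gene: str, strand: str) -> Extremity:
    return (gene, TAIL if strand == FORWARD else HEAD)


@dataclass
class AdjacencyGraph:
    """Weighted graph over ancestral gene extremities for one ancestor."""

    ancestor: str
    weights: dict[Edge, int] = field(default_factory=dict)
    n_informative: int = 0

    def genes(self) -> set[str]:
        return {gene for edge in self.weights for gene, _ in edge}

    @property
    def n_edges(self) -> int:
        return len(self.weights)


def informative_pairs(stree: SpeciesTree, ancestor: str) -> list[tuple[str, str]]:
    """Unordered extant-species pairs whose tree path crosses *ancestor*.

    Either the two species sit in different child clades of the ancestor
    (their LCA is the ancestor), or one is below it and the other outside it
    (ingroup-outgroup).
    """
    if stree.is_leaf(ancestor):
        raise ValueError(f"{ancestor!r} is a leaf")
    children = stree.children(ancestor)
    left = stree.leaves_below(children[0])
    right = stree.leaves_below(children[1])
    below = set(left) | set(right)
    outside = [s for s in stree.leaves if s not in below]
    pairs = [tuple(sorted((a, b))) for a in left for b in right]
    pairs += [tuple(sorted((a, b))) for a in below for b in outside]
    return sorted(set(pairs))


def _extant_to_ancestral(
    orth: Mapping[str, tuple[list[str], list[str]]], side: int
) -> dict[str, tuple[str, ...]]:
    """Invert one side of an orthology map; an extant gene may stand for
    several co-orthologous ancestral genes (duplications near the ancestor)."""
    out: dict[str, list[str]] = {}
    for anc_gene, lists in orth.items():
        for extant in lists[side]:
            out.setdefault(extant, []).append(anc_gene)
    return {g: tuple(sorted(a)) for g, a in out.items()}


def _genome_adjacencies(
    genome: Genome, to_anc: Mapping[str, tuple[str, ...]]
) -> set[Edge]:
    adjacencies: set[Edge] = set()
    for placements in genome.chromosomes.values():
        projected = [(g, s) for g, s in placements if g in to_anc]
        for (g1, s1), (g2, s2) in zip(projected, projected[1:]):
            for a1 in to_anc[g1]:
                for a2 in to_anc[g2]:
                    if a1 == a2:
                        continue  # tandem copies of one ancestral gene
                    adjacencies.add(
                        frozenset((right_extremity(a1, s1), left_extremity(a2, s2)))
                    )
    return adjacencies


def adjacency_set(genome: Genome) -> set[Edge]:
    """Oriented adjacency set of a genome in its own gene-id space."""
    return _genome_adjacencies(genome, {g: (g,) for g in genome.genes()})


def conserved_adjacencies(
    genome_a: Genome,
    genome_b: Genome,
    orth: Mapping[str, tuple[list[str], list[str]]],
) -> set[Edge]:
    """Ancestral extremity pairs adjacent (and co-oriented) in both genomes.

    Each genome is first projected onto genes with an orthologue in the
    comparison, so lineage-specific insertions are transparent.  Every copy
    pair may support an adjacency but the comparison contributes at most one
    vote per extremity pair.
    """
    adj_a = _genome_adjacencies(genome_a, _extant_to_ancestral(orth, 0))
    adj_b = _genome_adjacencies(genome_b, _extant_to_ancestral(orth, 1))
    return adj_a & adj_b


def build_graph(ancestor: str, comparisons: Sequence[Iterable[Edge]]) -> AdjacencyGraph:
    """Accumulate per-comparison adjacency votes into the weighted graph."""
    weights: dict[Edge, int] = {}
    for comparison in comparisons:
        for edge in set(comparison):
            weights[edge] = weights.get(edge, 0) + 1
    return AdjacencyGraph(
        ancestor=ancestor, weights=weights, n_informative=len(comparisons)
    )


def export_graph(graph: AdjacencyGraph) -> str:
    """TSV export: ancestor, geneA, endA, geneB, endB, weight."""
    lines = ["# ancestor\tgeneA\tendA\tgeneB\tendB\tweight"]
    for edge in sorted(graph.weights, key=lambda e: tuple(sorted(e))):
        (ga, ea), (gb, eb) = sorted(edge)
        lines.append(
            f"{graph.ancestor}\t{ga}\t{ea}\t{gb}\t{eb}\t{graph.weights[edge]}"
        )
    return "\n".join(lines) + "\n"
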