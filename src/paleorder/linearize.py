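"""Linearization of the weighted adjacency graph into CARs.

The graph is reduced to vertex-disjoint oriented paths by a greedy
maximum-weight rule: edges are visited by decreasing weight (deterministic
lexicographic tie-break) and accepted when both extremities are still free
and acceptance closes no cycle (Kruskal-style union-find over genes).
Accepted edges chain genes into contiguous ancestral regions (CARs); genes
left without an accepted edge become singleton CARs.

Two robustness extensions deal with noisy gene trees: a *constrained* first
pass restricted to genes close to single-copy across informative species
(tree parameter ``t``, default 0.35, with a second pass inserting the
remaining genes), and *multi-integration* scaffolding that contracts CARs to
meta-markers and re-linearizes inter-CAR edges over several rounds
(default 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .adjacency import (
    HEAD,
    TAIL,
    AdjacencyGraph,
    Edge,
    Extremity,
    build_graph,
    conserved_adjacencies,
    informative_pairs,
    left_extremity,
    right_extremity,
)
from .io import FORWARD, REVERSE, Genome, GeneTree, SpeciesTree
from .reconcile import (
    AncestralGeneSet,
    Reconciliation,
    ancestral_gene_content,
    orthologues_at,
    reconcile_forest,
)

__all__ = [
    "CARSet",
    "ConstraintParams",
    "linearize",
    "select_constrained",
    "insert_unconstrained",
    "scaffold_pass",
    "reconstruct",
    "carset_to_genome",
]

MODES = ("basic", "constrained_2pass", "multi_integration")


@dataclass
class ConstraintParams:
    """Tunables of the reconstruction modes.

    ``tree_parameter`` is the fraction of informative species allowed to
    deviate from single-copy for a gene to count as constrained; ``passes=2``
    means the constrained pass is followed by the insertion pass.
    """

    tree_parameter: float = 0.35
    passes: int = 2
    scaffold_rounds: int = 2
    min_weight: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.tree_parameter <= 1.0:
            raise ValueError("tree_parameter must be in [0, 1]")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")


@dataclass
class CARSet:
    """Oriented CARs of one ancestor; a partition of its ancestral genes."""

    ancestor: str
    cars: list[list[tuple[str, str]]]
    source_mode: str = "basic"

    def genes(self) -> set[str]:
        return {g for car in self.cars for g, _ in car}

    @property
    def n_genes(self) -> int:
        return sum(len(car) for car in self.cars)

    @property
    def lengths(self) -> list[int]:
        return [len(car) for car in self.cars]


# ---------------------------------------------------------------------------
# Greedy path cover
# ---------------------------------------------------------------------------

def _edge_sort_key(item: tuple[Edge, int]):
    edge, weight = item
    (g1, e1), (g2, e2) = sorted(edge)
    return (-weight, g1, e1, g2, e2)


class _UnionFind:
    def __init__(self) -> None:
        self._parent: dict = {}

    def find(self, x):
        parent = self._parent
        root = x
        while parent.get(root, root) != root:
            root = parent[root]
        while parent.get(x, x) != x:
            parent[x], x = root, parent[x]
        return root

    def union(self, a, b) -> None:
        self._parent[self.find(a)] = self.find(b)


def _greedy_links(
    weights: Mapping[Edge, int], min_weight: int = 1
) -> dict[Extremity, Extremity]:
    """Greedy max-weight path cover; returns the symmetric link map."""
    links: dict[Extremity, Extremity] = {}
    uf = _UnionFind()
    for edge, weight in sorted(weights.items(), key=_edge_sort_key):
        if weight < min_weight:
            continue
        (g1, e1), (g2, e2) = sorted(edge)
        if g1 == g2:
            continue  # never join the two extremities of one gene
        if (g1, e1) in links or (g2, e2) in links:
            continue
        if uf.find(g1) == uf.find(g2):
            continue  # would close a cycle
        links[(g1, e1)] = (g2, e2)
        links[(g2, e2)] = (g1, e1)
        uf.union(g1, g2)
    return links


def _other_end(end: str) -> str:
    return HEAD if end == TAIL else TAIL


def _links_to_cars(
    links: Mapping[Extremity, Extremity], genes: Iterable
) -> list[list[tuple[str, str]]]:
    """Read the link map out as oriented gene paths (deterministic)."""
    genes = sorted(set(genes))
    degree = {g: 0 for g in genes}
    for (g, _e) in links:
        degree[g] = degree.get(g, 0) + 1
    cars: list[list[tuple[str, str]]] = []
    visited: set = set()
    for g in genes:
        if g in visited:
            continue
        if degree.get(g, 0) == 0:
            visited.add(g)
            cars.append([(g, FORWARD)])
            continue
        if degree[g] != 1:
            continue  # interior gene; reached from a terminal
        # free end is the left end of the walk
        free = TAIL if (g, TAIL) not in links else HEAD
        car = [(g, FORWARD if free == TAIL else REVERSE)]
        visited.add(g)
        current, end = g, _other_end(free)
        while (current, end) in links:
            nxt, entry = links[(current, end)]
            car.append((nxt, FORWARD if entry == TAIL else REVERSE))
            visited.add(nxt)
            current, end = nxt, _other_end(entry)
        cars.append(car)
    return cars


def _flip_car(car: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    return [(g, FORWARD if s == REVERSE else REVERSE) for g, s in reversed(car)]


def canonicalize_cars(
    cars: Iterable[Sequence[tuple[str, str]]]
) -> list[list[tuple[str, str]]]:
    """Flip each CAR so its smallest terminal gene id is leftmost; order CARs
    by descending length then leading gene id."""
    out = []
    for car in cars:
        car = list(car)
        if car[-1][0] < car[0][0]:
            car = _flip_car(car)
        out.append(car)
    out.sort(key=lambda c: (-len(c), c[0][0]))
    return out


def linearize(
    graph: AdjacencyGraph,
    genes: Iterable[str] | None = None,
    min_weight: int = 1,
    source_mode: str = "basic",
) -> CARSet:
    """Greedy maximum-weight linearization of the adjacency graph."""
    universe = set(graph.genes())
    if genes is not None:
        universe |= set(genes)
    links = _greedy_links(graph.weights, min_weight=min_weight)
    cars = canonicalize_cars(_links_to_cars(links, universe))
    return CARSet(ancestor=graph.ancestor, cars=cars, source_mode=source_mode)


# ---------------------------------------------------------------------------
# Constrained two-pass mode
# ---------------------------------------------------------------------------

def select_constrained(
    forest: Sequence[GeneTree],
    stree: SpeciesTree,
    ancestor: str,
    params: ConstraintParams | None = None,
    ancset: AncestralGeneSet | None = None,
) -> set[str]:
    """Ancestral genes close to single-copy across informative species.

    A gene is constrained iff the fraction of informative species (species in
    at least one informative pair) carrying a descendant copy number != 1 is
    at most the tree parameter ``t``.
    """
    params = params or ConstraintParams()
    if ancset is None:
        ancset = ancestral_gene_content(forest, stree, ancestor)
    informative_species = sorted(
        {s for pair in informative_pairs(stree, ancestor) for s in pair}
    )
    n = len(informative_species)
    constrained: set[str] = set()
    for gene in ancset.genes:
        deviating = sum(
            1 for sp in informative_species if ancset.copies_in(gene, sp) != 1
        )
        if deviating <= params.tree_parameter * n:
            constrained.add(gene)
    return constrained


def _component(links: Mapping[Extremity, Extremity], gene: str) -> set[str]:
    seen = {gene}
    stack = [gene]
    while stack:
        g = stack.pop()
        for end in (HEAD, TAIL):
            partner = links.get((g, end))
            if partner is not None and partner[0] not in seen:
                seen.add(partner[0])
                stack.append(partner[0])
    return seen


def insert_unconstrained(
    cars_constrained: CARSet,
    graph_full: AdjacencyGraph,
    all_genes: Iterable[str] | None = None,
    min_weight: int = 1,
) -> CARSet:
    """Second stage: place non-constrained genes into CAR gaps or at CAR ends.

    Adjacencies between consecutive constrained genes are kept as breakable
    *provisional* links: an unconstrained gene (or run) may open a gap and
    chain itself between the two constrained neighbours.  Candidate edges of
    the full graph touching at least one unconstrained gene are accepted in
    decreasing weight order under the usual degree and acyclicity rules;
    provisional links whose gap attracted no insertion are restored, so
    placed constrained genes are never reordered.
    """
    constrained = cars_constrained.genes()
    universe = set(constrained) | set(graph_full.genes())
    if all_genes is not None:
        universe |= set(all_genes)

    links: dict[Extremity, Extremity] = {}
    provisional: set[Edge] = set()
    for car in cars_constrained.cars:
        for (g1, s1), (g2, s2) in zip(car, car[1:]):
            e1 = right_extremity(g1, s1)
            e2 = left_extremity(g2, s2)
            links[e1] = e2
            links[e2] = e1
            provisional.add(frozenset((e1, e2)))

    candidates = [
        (edge, w)
        for edge, w in graph_full.weights.items()
        if w >= min_weight
        and any(gene not in constrained for gene, _ in edge)
    ]
    candidates.sort(key=_edge_sort_key)

    broken: list[Edge] = []
    for edge, _w in candidates:
        (g1, e1), (g2, e2) = sorted(edge)
        if g1 == g2:
            continue
        x, y = (g1, e1), (g2, e2)

        to_break: list[Edge] = []
        usable = True
        for ext in (x, y):
            partner = links.get(ext)
            if partner is None:
                continue
            pair = frozenset((ext, partner))
            if pair in provisional:
                to_break.append(pair)
            else:
                usable = False
                break
        if not usable:
            continue

        # tentatively open the gap(s), then test acyclicity by walking
        removed: list[tuple[Extremity, Extremity]] = []
        for pair in to_break:
            a, b = tuple(pair)
            del links[a]
            del links[b]
            provisional.discard(pair)
            removed.append((a, b))
        if g2 in _component(links, g1):
            for a, b in removed:  # would close a cycle: restore
                links[a] = b
                links[b] = a
                provisional.add(frozenset((a, b)))
            continue
        broken.extend(frozenset((a, b)) for a, b in removed)
        links[x] = y
        links[y] = x

    # Restore gaps that did not close.  If an inserted chain connected the
    # two sides the gap is filled; otherwise dangling chains are detached
    # (they stay CARs of their own) and the original join is reinstated, so
    # a constrained CAR is never split by a failed insertion.
    for pair in broken:
        a, b = tuple(pair)
        if b[0] in _component(links, a[0]):
            continue  # gap closed (or reconnected elsewhere): keep as is
        for ext in (a, b):
            partner = links.pop(ext, None)
            if partner is not None:
                del links[partner]
        links[a] = b
        links[b] = a

    cars = canonicalize_cars(_links_to_cars(links, universe))
    return CARSet(
        ancestor=cars_constrained.ancestor, cars=cars, source_mode="constrained_2pass"
    )


# ---------------------------------------------------------------------------
# Multi-round scaffolding
# ---------------------------------------------------------------------------

def scaffold_pass(cars: CARSet, graph: AdjacencyGraph) -> CARSet:
    """Contract CARs to meta-markers and re-linearize inter-CAR edges.

    A CAR's two free terminal extremities become the tail (left) and head
    (right) of its meta-marker; graph edges joining terminal extremities of
    different CARs are re-aggregated onto the meta-markers and linearized by
    the same greedy rule.  Idempotent when no inter-CAR edge exists.
    """
    terminal: dict[Extremity, tuple[int, str]] = {}
    for idx, car in enumerate(cars.cars):
        g_first, s_first = car[0]
        g_last, s_last = car[-1]
        terminal[left_extremity(g_first, s_first)] = (idx, TAIL)
        terminal[right_extremity(g_last, s_last)] = (idx, HEAD)

    meta_weights: dict[Edge, int] = {}
    for edge, weight in graph.weights.items():
        exts = tuple(edge)
        if exts[0] not in terminal or exts[1] not in terminal:
            continue
        (i, end_i), (j, end_j) = terminal[exts[0]], terminal[exts[1]]
        if i == j:
            continue  # would circularize one CAR
        meta_edge = frozenset(((i, end_i), (j, end_j)))
        meta_weights[meta_edge] = max(meta_weights.get(meta_edge, 0), weight)

    links = _greedy_links(meta_weights)
    meta_cars = _links_to_cars(links, range(len(cars.cars)))
    merged: list[list[tuple[str, str]]] = []
    for meta in meta_cars:
        seq: list[tuple[str, str]] = []
        for idx, orient in meta:
            block = cars.cars[idx]
            seq.extend(block if orient == FORWARD else _flip_car(block))
        merged.append(seq)
    return CARSet(
        ancestor=cars.ancestor,
        cars=canonicalize_cars(merged),
        source_mode="multi_integration",
    )


# ---------------------------------------------------------------------------
# End-to-end reconstruction driver
# ---------------------------------------------------------------------------

def reconstruct(
    stree: SpeciesTree,
    forest: Sequence[GeneTree],
    genomes: Mapping[str, Genome],
    mode: str = "basic",
    params: ConstraintParams | None = None,
    ancestors: Sequence[str] | None = None,
    reconciliations: Sequence[Reconciliation] | None = None,
) -> dict[str, CARSet]:
    """Reconstruct CAR sets for every (or selected) ancestors of the tree."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    params = params or ConstraintParams()
    if reconciliations is None:
        reconciliations = reconcile_forest(forest, stree)
    targets = list(ancestors) if ancestors is not None else list(stree.internal_nodes)

    result: dict[str, CARSet] = {}
    for ancestor in targets:
        ancset = ancestral_gene_content(forest, stree, ancestor, reconciliations)
        pairs = informative_pairs(stree, ancestor)
        comparisons = [
            conserved_adjacencies(
                genomes[a], genomes[b], orthologues_at(ancset, a, b)
            )
            for a, b in pairs
        ]
        graph = build_graph(ancestor, comparisons)

        if mode == "basic":
            carset = linearize(
                graph, genes=ancset.genes, min_weight=params.min_weight
            )
        elif mode == "constrained_2pass":
            constrained = select_constrained(
                forest, stree, ancestor, params, ancset=ancset
            )
            sub_weights = {
                e: w
                for e, w in graph.weights.items()
                if all(g in constrained for g, _ in e)
            }
            subgraph = AdjacencyGraph(
                ancestor=ancestor,
                weights=sub_weights,
                n_informative=graph.n_informative,
            )
            carset = linearize(
                subgraph,
                genes=constrained,
                min_weight=params.min_weight,
                source_mode="constrained_2pass",
            )
            if params.passes >= 2:
                carset = insert_unconstrained(
                    carset, graph, all_genes=ancset.genes, min_weight=params.min_weight
                )
            else:
                leftover = set(ancset.genes) - carset.genes()
                cars = carset.cars + [[(g, FORWARD)] for g in sorted(leftover)]
                carset = CARSet(ancestor, canonicalize_cars(cars), "constrained_2pass")
        else:  # multi_integration
            carset = linearize(
                graph,
                genes=ancset.genes,
                min_weight=params.min_weight,
                source_mode="multi_integration",
            )
            for _ in range(params.scaffold_rounds):
                carset = scaffold_pass(carset, graph)
        result[ancestor] = carset
    return result


def carset_to_genome(carset: CARSet) -> Genome:
    """Express a CAR set as an ancestral Genome (CAR ids by size rank)."""
    cars = canonicalize_cars(carset.cars)
    width = max(4, len(str(len(cars))))
    chromosomes = {
        f"car{str(i + 1).zfill(width)}": list(car) for i, car in enumerate(cars)
    }
    return Genome(name=carset.ancestor, chromosomes=chromosomes, is_ancestral=True)
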