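"""LCA reconciliation of gene trees against the species tree and inference of
ancestral gene content.

Every gene-tree node is mapped to the most recent species-tree node containing
all its leaf species (LCA mapping).  A node is a duplication when the leaf
species sets of its two children overlap (species-overlap rule) or when the
input tree carries an NHX ``D=Y`` tag; tags are never downgraded to
speciation.  An ancestral gene at species node ``A`` is a reconciled gene
lineage present at ``A``: either a speciation node mapped exactly to ``A``, a
gene-tree edge whose species path crosses ``A``, or a post-duplication copy
whose duplication node is mapped to ``A`` itself.  Lineages are asserted
parsimoniously — only on paths connecting observed descendants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import DUPLICATION, LEAF, SPECIATION, GeneTree, SpeciesTree

__all__ = [
    "Reconciliation",
    "AncestralGeneSet",
    "reconcile",
    "reconcile_forest",
    "ancestral_gene_content",
    "orthologues_at",
    "export_gene_set",
]


@dataclass
class Reconciliation:
    """Per-node species mapping and event labels for one gene tree."""

    mapping: dict[int, str]  # gene-tree node id -> species-tree label
    events: dict[int, str]   # gene-tree node id -> speciation|duplication|leaf


def reconcile(tree: GeneTree, stree: SpeciesTree) -> Reconciliation:
    mapping: dict[int, str] = {}
    events: dict[int, str] = {}
    species_sets: dict[int, frozenset[str]] = {}

    for node in tree.postorder():
        if node.is_leaf:
            assert node.species is not None
            mapping[node.id] = node.species
            events[node.id] = LEAF
            species_sets[node.id] = frozenset((node.species,))
            continue
        children = node.children
        mapped = stree.lca_of([mapping[c] for c in children])
        mapping[node.id] = mapped
        sets = [species_sets[c] for c in children]
        merged = frozenset().union(*sets)
        species_sets[node.id] = merged
        overlap = len(merged) < sum(len(s) for s in sets)
        if node.event == DUPLICATION or overlap:
            events[node.id] = DUPLICATION
        else:
            events[node.id] = SPECIATION
    return Reconciliation(mapping=mapping, events=events)


def reconcile_forest(
    forest: Sequence[GeneTree], stree: SpeciesTree
) -> list[Reconciliation]:
    return [reconcile(tree, stree) for tree in forest]


@dataclass
class AncestralGeneSet:
    """Gene content of one ancestor, with per-gene extant descendants."""

    ancestor: str
    genes: list[str]
    # ancestral gene id -> species -> extant gene ids
    descendants: dict[str, dict[str, list[str]]]

    def copies_in(self, gene: str, species: str) -> int:
        return len(self.descendants.get(gene, {}).get(species, ()))


def _lineage_anchors(
    tree: GeneTree, rec: Reconciliation, stree: SpeciesTree, ancestor: str
) -> list[int]:
    """Gene-tree nodes anchoring one gene lineage each at *ancestor*.

    A node ``n`` (with parent ``p``) anchors a lineage when either:

    * ``mapped(n) == ancestor`` and ``n`` is a speciation node; or
    * the species path of the edge ``p -> n`` crosses the ancestor strictly
      (``mapped(p)`` strictly above, ``mapped(n)`` strictly below); or
    * ``mapped(p) == ancestor`` and ``p`` is a duplication with ``mapped(n)``
      strictly below (the duplication has already happened at the ancestor,
      so each emerging copy is a distinct ancestral gene).

    The three cases are mutually exclusive, so extant genes below the
    ancestor are partitioned across lineages.
    """
    anchors: list[int] = []
    parent_of: dict[int, int] = {}
    for node in tree.postorder():
        for c in node.children:
            parent_of[c] = node.id
    for node in tree.postorder():  # deterministic post-order enumeration
        nid = node.id
        mapped = rec.mapping[nid]
        if mapped == ancestor and rec.events[nid] == SPECIATION:
            anchors.append(nid)
            continue
        pid = parent_of.get(nid)
        if pid is None:
            continue
        pm = rec.mapping[pid]
        if not stree.is_strict_ancestor(ancestor, mapped) and mapped != ancestor:
            continue
        if mapped == ancestor:
            continue  # handled above or by the duplication clause on children
        if stree.is_strict_ancestor(pm, ancestor):
            anchors.append(nid)
        elif pm == ancestor and rec.events[pid] == DUPLICATION:
            anchors.append(nid)
    return anchors


def _leaves_by_species(tree: GeneTree) -> dict[int, dict[str, list[str]]]:
    """Per gene-tree node: species -> extant gene ids below it (postorder merge)."""
    out: dict[int, dict[str, list[str]]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            assert node.species is not None and node.gene_id is not None
            out[node.id] = {node.species: [node.gene_id]}
        else:
            merged: dict[str, list[str]] = {}
            for c in node.children:
                for sp, genes in out[c].items():
                    merged.setdefault(sp, []).extend(genes)
            out[node.id] = merged
    return out


def _lineage_descendants(
    tree: GeneTree,
    nid: int,
    parent_of: Mapping[int, int],
    by_species: Mapping[int, dict[str, list[str]]],
) -> dict[str, list[str]]:
    """Extant descendants of the lineage anchored at *nid*, per species.

    Species below the anchor come from its own subtree.  For any other
    species the orthologues are the extant genes under the nearest gene-tree
    ancestor of the anchor whose subtree reaches that species — the point
    where the two lineages diverged.  Minimality keeps the assignment as
    tight as the tree allows.
    """
    out = {sp: list(genes) for sp, genes in by_species[nid].items()}
    seen = set(out)
    cur = parent_of.get(nid)
    while cur is not None:
        for sp, genes in by_species[cur].items():
            if sp not in seen:
                seen.add(sp)
                out[sp] = list(genes)
        cur = parent_of.get(cur)
    return out


def ancestral_gene_content(
    forest: Sequence[GeneTree],
    stree: SpeciesTree,
    ancestor: str,
    reconciliations: Sequence[Reconciliation] | None = None,
) -> AncestralGeneSet:
    """Infer the gene content of *ancestor* from the reconciled forest.

    Ancestral gene ids are ``<treeIndex>.<k>`` with ``k`` enumerating the
    tree's lineages at the ancestor in post-order — stable and collision-free.
    """
    if ancestor not in stree:
        raise KeyError(f"unknown species-tree node {ancestor!r}")
    if stree.is_leaf(ancestor):
        raise ValueError(f"{ancestor!r} is a leaf, not an ancestor")
    if reconciliations is None:
        reconciliations = reconcile_forest(forest, stree)
    genes: list[str] = []
    descendants: dict[str, dict[str, list[str]]] = {}
    for ti, (tree, rec) in enumerate(zip(forest, reconciliations)):
        anchors = _lineage_anchors(tree, rec, stree, ancestor)
        if not anchors:
            continue
        parent_of: dict[int, int] = {}
        for node in tree.postorder():
            for c in node.children:
                parent_of[c] = node.id
        by_species = _leaves_by_species(tree)
        for k, nid in enumerate(anchors):
            gid = f"{ti}.{k}"
            genes.append(gid)
            descendants[gid] = _lineage_descendants(tree, nid, parent_of, by_species)
    return AncestralGeneSet(ancestor=ancestor, genes=genes, descendants=descendants)


def orthologues_at(
    ancset: AncestralGeneSet, species_a: str, species_b: str
) -> dict[str, tuple[list[str], list[str]]]:
    """Per-ancestral-gene descendant lists restricted to two extant species.

    Only ancestral genes with at least one descendant in each species are
    returned; lists exceed length 1 when duplications occurred below the
    ancestor.
    """
    out: dict[str, tuple[list[str], list[str]]] = {}
    for gene, per_species in ancset.descendants.items():
        in_a = per_species.get(species_a)
        in_b = per_species.get(species_b)
        if in_a and in_b:
            out[gene] = (list(in_a), list(in_b))
    return out


def export_gene_set(ancset: AncestralGeneSet) -> str:
    """TSV export: ancestor, ancestral_gene_id, species, extant_gene_id."""
    lines = ["# ancestor\tancestral_gene_id\tspecies\textant_gene_id"]
    for gene in ancset.genes:
        for species in sorted(ancset.descendants[gene]):
            for extant in ancset.descendants[gene][species]:
                lines.append(f"{ancset.ancestor}\t{gene}\t{species}\t{extant}")
    return "\n".join(lines) + "\n"
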