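"""Readers and writers for species trees, gene-tree forests and gene-order tables.

The on-disk dialects are deliberately minimal and text-only:

* species tree: newick with named internal nodes and branch lengths in
  million years (My);
* gene forest: one rooted newick/NHX tree per line, leaves labelled
  ``<gene_id><sep><species>`` (default separator ``|``), duplication nodes
  tagged ``[&&NHX:D=Y]``;
* genome: 4-column tab-separated table ``chromosome  rank  strand  gene_id``
  with dense 1-based ranks per chromosome and ``#`` comment lines.

All writers are deterministic and bit-exact given canonicalized input, so
outputs can be diffed across runs.
"""

from __future__ import annotations

import io as _stdio
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "SpeciesNode",
    "SpeciesTree",
    "GeneTreeNode",
    "GeneTree",
    "Genome",
    "PhyloIOError",
    "parse_species_tree",
    "parse_gene_forest",
    "write_gene_forest",
    "read_genome",
    "parse_genome",
    "write_ancestral_genome",
    "write_genome",
    "canonicalize_genome",
]

FORWARD = "+"
REVERSE = "-"
_STRANDS = {FORWARD, REVERSE}


class PhyloIOError(ValueError):
    """Raised for malformed trees or gene-order tables."""


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesNode:
    name: str
    parent: str | None
    children: tuple[str, ...]
    branch_length: float  # My, length of the branch above this node

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """Rooted, binary, dated species phylogeny.

    Internal nodes are the reconstruction targets.  Node lookup is by unique
    label; ancestry queries are O(depth), which is ample for the tree sizes
    this package targets (tens to hundreds of species).
    """

    def __init__(self, nodes: Mapping[str, SpeciesNode], root: str):
        self.nodes: dict[str, SpeciesNode] = dict(nodes)
        self.root = root
        self._depth: dict[str, int] = {}
        self._leaves_below: dict[str, tuple[str, ...]] = {}
        self._index()

    def _index(self) -> None:
        def depth(name: str) -> int:
            if name not in self._depth:
                parent = self.nodes[name].parent
                self._depth[name] = 0 if parent is None else depth(parent) + 1
            return self._depth[name]

        for name in self.nodes:
            depth(name)

        def collect(name: str) -> tuple[str, ...]:
            node = self.nodes[name]
            if node.is_leaf:
                res: tuple[str, ...] = (name,)
            else:
                res = tuple(
                    leaf for child in node.children for leaf in collect(child)
                )
            self._leaves_below[name] = res
            return res

        collect(self.root)

    # -- queries ---------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def is_leaf(self, name: str) -> bool:
        return self.nodes[name].is_leaf

    @property
    def leaves(self) -> tuple[str, ...]:
        return self._leaves_below[self.root]

    @property
    def internal_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.postorder() if not self.nodes[n].is_leaf)

    def leaves_below(self, name: str) -> tuple[str, ...]:
        return self._leaves_below[name]

    def children(self, name: str) -> tuple[str, ...]:
        return self.nodes[name].children

    def parent(self, name: str) -> str | None:
        return self.nodes[name].parent

    def branch_length(self, name: str) -> float:
        return self.nodes[name].branch_length

    def postorder(self) -> Iterator[str]:
        def walk(name: str) -> Iterator[str]:
            for child in self.nodes[name].children:
                yield from walk(child)
            yield name

        return walk(self.root)

    def lca(self, a: str, b: str) -> str:
        da, db = self._depth[a], self._depth[b]
        while da > db:
            a = self.nodes[a].parent  # type: ignore[assignment]
            da -= 1
        while db > da:
            b = self.nodes[b].parent  # type: ignore[assignment]
            db -= 1
        while a != b:
            a = self.nodes[a].parent  # type: ignore[assignment]
            b = self.nodes[b].parent  # type: ignore[assignment]
        return a

    def lca_of(self, names: Iterable[str]) -> str:
        names = list(names)
        if not names:
            raise ValueError("lca_of() of empty set")
        acc = names[0]
        for other in names[1:]:
            acc = self.lca(acc, other)
        return acc

    def is_strict_ancestor(self, anc: str, desc: str) -> bool:
        """True iff *anc* is a proper ancestor of *desc*."""
        if anc == desc:
            return False
        node = self.nodes[desc].parent
        while node is not None:
            if node == anc:
                return True
            node = self.nodes[node].parent
        return False

    def age(self, name: str) -> float:
        """Max summed branch length from *name* down to any leaf (reporting only)."""
        node = self.nodes[name]
        if node.is_leaf:
            return 0.0
        return max(
            self.age(c) + self.nodes[c].branch_length for c in node.children
        )


def _auto_name(dnode: "dendropy.Node", existing: set[str]) -> str:
    # Alphabetically first leaf of each child clade, joined by "-".
    parts = []
    for child in dnode.child_nodes():
        leaves = sorted(
            lf.taxon.label for lf in child.leaf_iter() if lf.taxon is not None
        )
        parts.append(leaves[0])
    name = "-".join(sorted(parts))
    if name in existing:
        raise PhyloIOError(f"auto-generated label {name!r} collides with an existing label")
    return name


def parse_species_tree(text: str) -> SpeciesTree:
    """Parse a rooted binary species tree from newick text.

    Unnamed internal nodes are auto-named deterministically; missing branch
    lengths default to 0 My with a warning.  Multifurcations and duplicate
    labels are rejected.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise PhyloIOError(f"malformed newick: {exc}") from exc

    seen: set[str] = set()
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon is None:
            raise PhyloIOError("unnamed leaf in species tree")
        if leaf.taxon.label in seen:
            raise PhyloIOError(f"duplicate label {leaf.taxon.label!r}")
        seen.add(leaf.taxon.label)

    nodes: dict[str, SpeciesNode] = {}
    missing_bl = False

    def name_of(dnode: "dendropy.Node") -> str:
        if dnode.is_leaf():
            return dnode.taxon.label
        return dnode.label if dnode.label else ""

    # First pass: assign names (auto-name where absent), check arity/duplicates.
    labels: dict[int, str] = {}
    for dnode in dtree.preorder_node_iter():
        nchildren = len(dnode.child_nodes())
        if nchildren not in (0, 2):
            leaves = sorted(
                lf.taxon.label for lf in dnode.leaf_iter() if lf.taxon is not None
            )
            raise PhyloIOError(
                f"multifurcation ({nchildren} children) at node above leaves "
                f"{{{', '.join(leaves)}}}: species tree must be binary"
            )
        name = name_of(dnode)
        if not name:
            name = _auto_name(dnode, seen)
        elif not dnode.is_leaf():
            if name in seen:
                raise PhyloIOError(f"duplicate label {name!r}")
            seen.add(name)
        labels[id(dnode)] = name

    for dnode in dtree.preorder_node_iter():
        name = labels[id(dnode)]
        parent = labels[id(dnode.parent_node)] if dnode.parent_node else None
        children = tuple(labels[id(c)] for c in dnode.child_nodes())
        bl = dnode.edge.length
        if bl is None:
            if parent is not None:
                missing_bl = True
            bl = 0.0
        if bl < 0:
            raise PhyloIOError(f"negative branch length at {name!r}")
        nodes[name] = SpeciesNode(name, parent, children, float(bl))

    if missing_bl:
        warnings.warn(
            "species tree has branches without lengths; defaulting to 0 My",
            stacklevel=2,
        )
    root = labels[id(dtree.seed_node)]
    return SpeciesTree(nodes, root)


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------

SPECIATION = "speciation"
DUPLICATION = "duplication"
LEAF = "leaf"
UNSET = "unset"


@dataclass
class GeneTreeNode:
    id: int
    children: tuple[int, ...]
    species: str | None = None  # leaves only
    gene_id: str | None = None  # leaves only
    event: str = UNSET

    @property
    def is_leaf(self) -> bool:
        return not self.children


class GeneTree:
    """Rooted gene family tree; leaves carry (species, extant gene id)."""

    def __init__(self, nodes: Mapping[int, GeneTreeNode], root: int):
        self.nodes: dict[int, GeneTreeNode] = dict(nodes)
        self.root = root

    def postorder(self) -> Iterator[GeneTreeNode]:
        def walk(nid: int) -> Iterator[GeneTreeNode]:
            node = self.nodes[nid]
            for child in node.children:
                yield from walk(child)
            yield node

        return walk(self.root)

    def leaves(self) -> list[GeneTreeNode]:
        return [n for n in self.postorder() if n.is_leaf]


def parse_gene_forest(
    text: str, stree: SpeciesTree, sep: str = "|"
) -> list[GeneTree]:
    """Parse a forest of rooted gene trees, one newick/NHX tree per line.

    Leaf labels are ``<gene_id><sep><species>``; NHX ``D=Y`` marks a
    duplication, other internal nodes stay ``unset`` for reconciliation to
    decide.  Gene ids must be unique across the whole forest and leaf
    species must exist in *stree*.
    """
    forest: list[GeneTree] = []
    seen_genes: set[str] = set()
    leaf_species = set(stree.leaves)
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            dtree = dendropy.Tree.get(
                data=line,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
                extract_comment_metadata=True,
            )
        except Exception as exc:
            raise PhyloIOError(f"line {lineno}: malformed gene tree: {exc}") from exc

        nodes: dict[int, GeneTreeNode] = {}
        counter = 0

        def build(dnode: "dendropy.Node") -> int:
            nonlocal counter
            nid = counter
            counter += 1
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
                if sep not in label:
                    raise PhyloIOError(
                        f"line {lineno}: leaf label {label!r} lacks separator {sep!r}"
                    )
                gene_id, species = label.rsplit(sep, 1)
                if species not in leaf_species:
                    raise PhyloIOError(
                        f"line {lineno}: gene {gene_id!r} references species "
                        f"{species!r} absent from the species tree"
                    )
                if gene_id in seen_genes:
                    raise PhyloIOError(
                        f"line {lineno}: duplicate gene id {gene_id!r} in forest"
                    )
                seen_genes.add(gene_id)
                nodes[nid] = GeneTreeNode(
                    nid, (), species=species, gene_id=gene_id, event=LEAF
                )
                return nid
            children = tuple(build(c) for c in dnode.child_nodes())
            event = UNSET
            dtag = dnode.annotations.get_value("D")
            if dtag is not None and str(dtag).upper() == "Y":
                event = DUPLICATION
            nodes[nid] = GeneTreeNode(nid, children, event=event)
            return nid

        root = build(dtree.seed_node)
        forest.append(GeneTree(nodes, root))
    return forest


def write_gene_forest(forest: Sequence[GeneTree], sep: str = "|") -> str:
    """Serialize a forest back to one NHX newick per line (D=Y on duplications)."""
    lines = []
    for tree in forest:
        def fmt(nid: int) -> str:
            node = tree.nodes[nid]
            if node.is_leaf:
                return f"{node.gene_id}{sep}{node.species}"
            inner = ",".join(fmt(c) for c in node.children)
            tag = "[&&NHX:D=Y]" if node.event == DUPLICATION else ""
            return f"({inner}){tag}"

        lines.append(fmt(tree.root) + ";")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """Ordered, signed gene placements per chromosome (extant or ancestral)."""

    name: str
    chromosomes: dict[str, list[tuple[str, str]]]  # chrom -> [(gene, strand)]
    is_ancestral: bool = False

    def genes(self) -> set[str]:
        return {g for placements in self.chromosomes.values() for g, _ in placements}

    @property
    def n_genes(self) -> int:
        return sum(len(p) for p in self.chromosomes.values())


def parse_genome(text: str, name: str = "", is_ancestral: bool = False) -> Genome:
    """Parse a gene-order table (chromosome, rank, strand, gene_id)."""
    rows: dict[str, dict[int, tuple[str, str]]] = {}
    seen_genes: set[str] = set()
    n_rows = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split("\t")
        if len(fields) != 4:
            raise PhyloIOError(
                f"line {lineno}: expected 4 tab-separated columns, got {len(fields)}"
            )
        chrom, rank_s, strand, gene = fields
        try:
            rank = int(rank_s)
        except ValueError:
            raise PhyloIOError(f"line {lineno}: rank {rank_s!r} is not an integer")
        if rank < 1:
            raise PhyloIOError(f"line {lineno}: rank must be >= 1, got {rank}")
        if strand not in _STRANDS:
            raise PhyloIOError(f"line {lineno}: strand must be + or -, got {strand!r}")
        if gene in seen_genes:
            raise PhyloIOError(f"line {lineno}: duplicate gene id {gene!r}")
        seen_genes.add(gene)
        per_chrom = rows.setdefault(chrom, {})
        if rank in per_chrom:
            raise PhyloIOError(f"line {lineno}: duplicate rank {rank} on {chrom!r}")
        per_chrom[rank] = (gene, strand)
        n_rows += 1
    if n_rows == 0:
        raise PhyloIOError("no placements: genome table is empty")

    chromosomes: dict[str, list[tuple[str, str]]] = {}
    for chrom, by_rank in rows.items():
        expected = set(range(1, len(by_rank) + 1))
        if set(by_rank) != expected:
            missing = sorted(expected - set(by_rank))
            raise PhyloIOError(
                f"rank gap on {chrom!r}: missing rank(s) {missing[:5]}"
            )
        chromosomes[chrom] = [by_rank[r] for r in sorted(by_rank)]
    return Genome(name=name, chromosomes=chromosomes, is_ancestral=is_ancestral)


def read_genome(path: str | Path, name: str | None = None, is_ancestral: bool = False) -> Genome:
    path = Path(path)
    return parse_genome(
        path.read_text(),
        name=name if name is not None else path.stem,
        is_ancestral=is_ancestral,
    )


def _flip(placements: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    return [(g, FORWARD if s == REVERSE else REVERSE) for g, s in reversed(placements)]


def canonicalize_genome(genome: Genome) -> Genome:
    """Deterministic form: each chromosome oriented so its lexicographically
    smallest terminal gene is leftmost; chromosomes ordered by descending gene
    count, then id."""
    chroms: dict[str, list[tuple[str, str]]] = {}
    for chrom, placements in genome.chromosomes.items():
        if not placements:
            raise PhyloIOError(f"empty chromosome {chrom!r}")
        if placements[-1][0] < placements[0][0]:
            placements = _flip(placements)
        chroms[chrom] = list(placements)
    ordered = dict(
        sorted(chroms.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    )
    return Genome(name=genome.name, chromosomes=ordered, is_ancestral=genome.is_ancestral)


def write_genome(genome: Genome) -> str:
    """Serialize a genome in the 4-column dialect after canonicalization."""
    canon = canonicalize_genome(genome)
    out = _stdio.StringIO()
    out.write("# chromosome\trank\tstrand\tgene_id\n")
    for chrom, placements in canon.chromosomes.items():
        for rank, (gene, strand) in enumerate(placements, start=1):
            out.write(f"{chrom}\t{rank}\t{strand}\t{gene}\n")
    return out.getvalue()


def write_ancestral_genome(genome: Genome) -> str:
    """Serialize an ancestral genome (CAR set); alias of :func:`write_genome`
    kept separate because ancestral output is the primary product."""
    if not genome.is_ancestral:
        genome = replace(genome, is_ancestral=True)
    return write_genome(genome)
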