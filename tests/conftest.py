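import pytest

from paleorder.io import parse_gene_forest, parse_species_tree


THREE_TAXON = "((A:10,B:10)X:5,C:15)R;"


@pytest.fixture(scope="session")
def stree3():
    """((A,B)X,C)R with branch lengths in My."""
    return parse_species_tree(THREE_TAXON)


@pytest.fixture(scope="session")
def stree8():
    """The dated 8-leaf benchmark tree (450 My total branch length)."""
    from paleorder.benchmarks import benchmark_tree

    return benchmark_tree()


def make_forest(stree, lines):
    return parse_gene_forest("\n".join(lines), stree)


@pytest.fixture
def forest3(stree3):
    """Small forest on ((A,B)X,C)R mixing clean and duplicated families."""
    return make_forest(
        stree3,
        [
            "(g1|A,g2|B);",
            "((g3|A,g4|B),(g5|A,g6|B))[&&NHX:D=Y];",
            "((g7|A,g8|B),g9|C);",
        ],
    )
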