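"""Graph linearization, constrained mode, insertion and scaffolding."""

import pytest

from paleorder.adjacency import HEAD, TAIL, AdjacencyGraph
from paleorder.io import parse_gene_forest
from paleorder.linearize import (
    CARSet,
    ConstraintParams,
    canonicalize_cars,
    insert_unconstrained,
    linearize,
    reconstruct,
    scaffold_pass,
    select_constrained,
)
from paleorder.simulate import SimParams, make_benchmark


def edge(g1, e1, g2, e2):
    return frozenset({(g1, e1), (g2, e2)})


def graph_of(weights, ancestor="anc"):
    return AdjacencyGraph(ancestor=ancestor, weights=weights, n_informative=10)


class TestLinearize:
    def test_path_shaped_graph(self):
        g = graph_of({edge("a1", HEAD, "a2", TAIL): 2, edge("a2", HEAD, "a3", TAIL): 2})
        cars = linearize(g)
        assert cars.cars == [[("a1", "+"), ("a2", "+"), ("a3", "+")]]

    def test_conflict_resolved_by_weight(self):
        g = graph_of({edge("a2", TAIL, "a1", HEAD): 3, edge("a2", TAIL, "a3", HEAD): 1})
        cars = linearize(g)
        assert [len(c) for c in cars.cars] == [2, 1]
        joined = next(c for c in cars.cars if len(c) == 2)
        assert {g for g, _ in joined} == {"a1", "a2"}

    def test_three_cycle_broken_into_one_car(self):
        g = graph_of(
            {
                edge("a1", HEAD, "a2", TAIL): 2,
                edge("a2", HEAD, "a3", TAIL): 2,
                edge("a3", HEAD, "a1", TAIL): 2,
            }
        )
        cars = linearize(g)
        assert len(cars.cars) == 1 and len(cars.cars[0]) == 3

    def test_isolated_genes_become_singletons(self):
        g = graph_of({edge("a1", HEAD, "a2", TAIL): 1})
        cars = linearize(g, genes=["a1", "a2", "a9"])
        assert [("a9", "+")] in cars.cars

    def test_min_weight_floor(self):
        g = graph_of({edge("a1", HEAD, "a2", TAIL): 1})
        cars = linearize(g, min_weight=2)
        assert all(len(c) == 1 for c in cars.cars)


class TestSelectConstrained:
    def test_single_copy_everywhere_always_constrained(self, stree3):
        forest = parse_gene_forest("((g1|A,g2|B),g3|C);", stree3)
        for t in (0.0, 0.35, 1.0):
            got = select_constrained(
                forest, stree3, "X", ConstraintParams(tree_parameter=t)
            )
            assert got == {"0.0"}

    def test_deviation_above_threshold_excluded(self, stree3):
        # duplicated in A: 1 of 3 informative species deviates (33% <= 35%)
        # missing in C as well: 2 of 3 deviate (67% > 35%)
        dup_a = parse_gene_forest("((g1|A,g4|A)[&&NHX:D=Y],g2|B);", stree3)
        got = select_constrained(dup_a, stree3, "X", ConstraintParams())
        assert got == set()  # deviates in A (2 copies) and C (0 copies)

    def test_t_one_constrains_everything(self, stree3, forest3):
        got = select_constrained(
            forest3, stree3, "X", ConstraintParams(tree_parameter=1.0)
        )
        assert len(got) == 4  # every ancestral gene of the forest


class TestInsertUnconstrained:
    def test_gap_insertion(self):
        constrained = CARSet("anc", [[("a1", "+"), ("a3", "+")]])
        full = graph_of(
            {
                edge("a1", HEAD, "a3", TAIL): 6,
                edge("a1", HEAD, "a2", TAIL): 5,
                edge("a2", HEAD, "a3", TAIL): 5,
            }
        )
        cars = insert_unconstrained(constrained, full)
        assert cars.cars == [[("a1", "+"), ("a2", "+"), ("a3", "+")]]

    def test_gene_without_edges_stays_singleton(self):
        constrained = CARSet("anc", [[("a1", "+"), ("a3", "+")]])
        full = graph_of({edge("a1", HEAD, "a3", TAIL): 6})
        cars = insert_unconstrained(constrained, full, all_genes=["a1", "a3", "a7"])
        assert [("a7", "+")] in cars.cars
        assert [("a1", "+"), ("a3", "+")] in cars.cars

    def test_competing_candidates_resolved_by_weight(self):
        constrained = CARSet("anc", [[("a1", "+")]])
        full = graph_of(
            {
                edge("a1", HEAD, "b1", TAIL): 4,
                edge("a1", HEAD, "b2", TAIL): 2,
            }
        )
        cars = insert_unconstrained(constrained, full)
        assert [("a1", "+"), ("b1", "+")] in cars.cars
        assert [("b2", "+")] in cars.cars

    def test_failed_insertion_restores_the_gap(self):
        # b1 attaches inside the gap but cannot reach a3; the a1-a3 join must
        # not be lost, so b1 ends up at the CAR end or singleton
        constrained = CARSet("anc", [[("a1", "+"), ("a3", "+")]])
        full = graph_of(
            {
                edge("a1", HEAD, "a3", TAIL): 6,
                edge("a1", HEAD, "b1", TAIL): 5,
            }
        )
        cars = insert_unconstrained(constrained, full, all_genes=["a1", "a3", "b1"])
        big = next(c for c in cars.cars if len(c) > 1)
        genes = [g for g, _ in big]
        assert genes.index("a3") == genes.index("a1") + 1


class TestScaffoldPass:
    def test_terminal_edge_merges_two_cars(self):
        cars = CARSet("anc", [[("a1", "+"), ("a2", "+")], [("a3", "+"), ("a4", "+")]])
        g = graph_of({edge("a2", HEAD, "a3", TAIL): 3})
        merged = scaffold_pass(cars, g)
        assert merged.cars == [[("a1", "+"), ("a2", "+"), ("a3", "+"), ("a4", "+")]]

    def test_no_inter_car_edges_is_identity(self):
        cars = CARSet(
            "anc", canonicalize_cars([[("a1", "+"), ("a2", "+")], [("a3", "+")]])
        )
        g = graph_of({edge("a1", HEAD, "a2", TAIL): 3})
        assert scaffold_pass(cars, g).cars == cars.cars

    def test_fixpoint_without_new_evidence(self):
        cars = CARSet("anc", [[("a1", "+"), ("a2", "+")], [("a3", "+"), ("a4", "+")]])
        g = graph_of({edge("a2", HEAD, "a3", TAIL): 3})
        once = scaffold_pass(cars, g)
        twice = scaffold_pass(once, g)
        assert once.cars == twice.cars

    def test_interior_edges_do_not_merge(self):
        cars = CARSet("anc", [[("a1", "+"), ("a2", "+")], [("a3", "+"), ("a4", "+")]])
        g = graph_of({edge("a1", HEAD, "a3", HEAD): 3})  # interior extremity of car 1
        assert scaffold_pass(cars, g).cars == canonicalize_cars(cars.cars)


@pytest.fixture(scope="module")
def zero_rate_bench(stree8):
    params = SimParams(n_genes=80, n_chromosomes=4, seed=5)
    return make_benchmark(stree8, params)


class TestReconstruct:
    @pytest.mark.parametrize("mode", ["basic", "constrained_2pass", "multi_integration"])
    def test_zero_rate_recovers_root_everywhere(self, stree8, zero_rate_bench, mode):
        bench = zero_rate_bench
        carsets = reconstruct(stree8, bench.forest, bench.extant_genomes, mode=mode)
        from paleorder.metrics import compare_to_truth
        from paleorder.reconcile import ancestral_gene_content

        for ancestor in stree8.internal_nodes:
            ancset = ancestral_gene_content(bench.forest, stree8, ancestor)
            relabeled = bench.trace.relabel_carset(
                ancestor, ancset, carsets[ancestor]
            )
            cmp = compare_to_truth(relabeled, bench.truth(ancestor))
            assert cmp.agreement == 1.0

    def test_partition_invariant_every_mode(self, stree8, zero_rate_bench):
        bench = zero_rate_bench
        from paleorder.reconcile import ancestral_gene_content

        for mode in ("basic", "constrained_2pass", "multi_integration"):
            carsets = reconstruct(
                stree8, bench.forest, bench.extant_genomes, mode=mode
            )
            for ancestor, carset in carsets.items():
                ancset = ancestral_gene_content(bench.forest, stree8, ancestor)
                genes = [g for car in carset.cars for g, _ in car]
                assert sorted(genes) == sorted(ancset.genes)

    def test_single_lineage_inversion_does_not_leak_upward(self, stree3):
        """Parsimony: rearrangement on one terminal branch leaves the
        ancestor matching the unrearranged sister."""
        from paleorder.io import Genome
        from paleorder.metrics import carset_adjacencies
        from paleorder.adjacency import adjacency_set

        n = 10
        forest = parse_gene_forest(
            "\n".join(f"((a{i:02d}|A,b{i:02d}|B),c{i:02d}|C);" for i in range(n)),
            stree3,
        )
        ordered = [f"{i:02d}" for i in range(n)]
        genome_b = Genome("B", {"c1": [(f"b{k}", "+") for k in ordered]})
        genome_c = Genome("C", {"c1": [(f"c{k}", "+") for k in ordered]})
        # A carries an inversion of genes 4..6
        a_order = ordered[:4] + ordered[4:7][::-1] + ordered[7:]
        a_strand = ["+"] * 4 + ["-"] * 3 + ["+"] * 3
        genome_a = Genome(
            "A", {"c1": [(f"a{k}", s) for k, s in zip(a_order, a_strand)]}
        )
        carsets = reconstruct(
            stree3, forest, {"A": genome_a, "B": genome_b, "C": genome_c}
        )
        x = carsets["X"]
        assert len(x.cars) == 1
        # ancestral order matches the sister (collinear, no inversion)
        genes = [g for g, _ in x.cars[0]]
        idx = [int(g.split(".")[0]) for g in genes]
        assert idx == sorted(idx) or idx == sorted(idx)[::-1]

    def test_modes_agree_on_clean_input(self, stree8, zero_rate_bench):
        bench = zero_rate_bench
        results = {
            mode: reconstruct(stree8, bench.forest, bench.extant_genomes, mode=mode)
            for mode in ("basic", "constrained_2pass", "multi_integration")
        }
        for ancestor in stree8.internal_nodes:
            basic = results["basic"][ancestor].cars
            assert results["constrained_2pass"][ancestor].cars == basic
            assert results["multi_integration"][ancestor].cars == basic

    def test_unknown_mode_rejected(self, stree8, zero_rate_bench):
        with pytest.raises(ValueError, match="unknown mode"):
            reconstruct(
                stree8,
                zero_rate_bench.forest,
                zero_rate_bench.extant_genomes,
                mode="fancy",
            )
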