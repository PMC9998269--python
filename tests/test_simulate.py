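"""Genome-evolution simulator: determinism, accounting, truth consistency."""

import dataclasses

import pytest

from paleorder.io import DUPLICATION, write_genome
from paleorder.reconcile import reconcile
from paleorder.simulate import (
    SimParams,
    apply_fission,
    apply_fusion,
    apply_inversion,
    apply_translocation,
    make_benchmark,
    simulate,
)


@pytest.fixture(scope="module")
def busy_trace(stree8):
    params = SimParams(
        n_genes=200,
        n_chromosomes=5,
        inversion_rate=0.02,
        translocation_rate=0.005,
        fusion_rate=0.002,
        fission_rate=0.002,
        duplication_rate=0.004,
        loss_rate=0.01,
        gain_rate=0.004,
        seed=42,
    )
    return simulate(stree8, params)


class TestZeroRates:
    def test_every_genome_identical_to_root(self, stree8):
        trace = simulate(stree8, SimParams(n_genes=60, n_chromosomes=3, seed=2))
        root_text = write_genome(trace.genomes[stree8.root])
        for node in stree8.postorder():
            assert write_genome(trace.genomes[node]) == root_text

    def test_forest_is_single_copy(self, stree8):
        trace = simulate(stree8, SimParams(n_genes=60, n_chromosomes=3, seed=2))
        assert len(trace.forest) == 60
        for tree in trace.forest:
            leaves = tree.leaves()
            assert len(leaves) == len(stree8.leaves)
            assert not any(
                n.event == DUPLICATION for n in tree.postorder() if not n.is_leaf
            )


class TestDeterminism:
    def test_same_seed_same_trace(self, stree8):
        params = SimParams(
            n_genes=100, n_chromosomes=4, inversion_rate=0.05,
            duplication_rate=0.01, loss_rate=0.01, gain_rate=0.01, seed=9,
        )
        t1, t2 = simulate(stree8, params), simulate(stree8, params)
        for node in stree8.postorder():
            assert write_genome(t1.genomes[node]) == write_genome(t2.genomes[node])
        assert [(e.branch, e.kind, e.genes) for e in t1.events] == [
            (e.branch, e.kind, e.genes) for e in t2.events
        ]

    def test_different_seed_differs(self, stree8):
        base = SimParams(n_genes=100, n_chromosomes=4, inversion_rate=0.05, seed=9)
        other = dataclasses.replace(base, seed=10)
        t1, t2 = simulate(stree8, base), simulate(stree8, other)
        texts1 = [write_genome(t1.extant_genomes[s]) for s in stree8.leaves]
        texts2 = [write_genome(t2.extant_genomes[s]) for s in stree8.leaves]
        assert texts1 != texts2


class TestRearrangementOperators:
    def test_forced_internal_inversion_makes_two_breakpoints(self):
        from paleorder.dynamics import breakpoints
        from paleorder.io import Genome

        genes = [f"g{i}" for i in range(8)]
        parent = Genome("P", {"c1": [(g, "+") for g in genes]})
        chroms = [list(parent.chromosomes["c1"])]
        apply_inversion(chroms, 0, 3, 2)
        child = Genome("C", {"c1": chroms[0]})
        orth = {g: [g] for g in genes}
        assert breakpoints(parent, child, orth) == 2

    def test_operators_preserve_gene_content(self):
        chroms = [[(f"a{i}", "+") for i in range(6)], [(f"b{i}", "+") for i in range(6)]]
        before = {g for c in chroms for g, _ in c}
        apply_inversion(chroms, 0, 1, 3)
        apply_translocation(chroms, 0, 1, 2, 4)
        apply_fission(chroms, 0, 1)
        apply_fusion(chroms, 0, 1, False, True)
        assert {g for c in chroms for g, _ in c} == before


class TestAccounting:
    def test_gene_counts_match_event_log_per_branch(self, stree8, busy_trace):
        trace = busy_trace
        deltas = {}
        for ev in trace.events:
            deltas[ev.branch] = deltas.get(ev.branch, 0) + ev.delta_genes
        for node in stree8.postorder():
            parent = stree8.parent(node)
            if parent is None:
                continue
            expected = trace.genomes[parent].n_genes + deltas.get(node, 0)
            assert trace.genomes[node].n_genes == expected

    def test_every_extant_gene_traces_to_a_source(self, stree8, busy_trace):
        amap = busy_trace.ancestor_map(stree8.root)
        gained = {
            gid for ev in busy_trace.events if ev.kind == "gain" for gid in ev.genes
        }
        for extant, root_gene in amap.items():
            inst = busy_trace._extant_inst[extant]
            if root_gene is None:
                # must descend from a gained gene
                cur = inst
                while busy_trace._parent[cur] is not None:
                    cur = busy_trace._parent[cur]
                assert cur in gained

    def test_forest_leaves_match_extant_genomes(self, stree8, busy_trace):
        forest_leaves = {
            leaf.gene_id for tree in busy_trace.forest for leaf in tree.leaves()
        }
        genome_genes = set()
        for leaf in stree8.leaves:
            genome_genes |= busy_trace.extant_genomes[leaf].genes()
        assert forest_leaves == genome_genes


class TestReconciliationRoundTrip:
    def test_duplication_nodes_and_mappings_recovered(self, stree8):
        """With no losses, LCA reconciliation of the emitted forest recovers
        the simulator's duplication nodes and branch assignments exactly."""
        params = SimParams(
            n_genes=120, n_chromosomes=4, duplication_rate=0.01, seed=7
        )
        trace = simulate(stree8, params)
        n_dup_nodes = 0
        for tree, node_info in zip(trace.forest, trace.truth_node_info):
            rec = reconcile(tree, stree8)
            for node in tree.postorder():
                if node.is_leaf:
                    continue
                true_event, true_place = node_info[node.id]
                assert rec.events[node.id] == true_event
                # speciations map to the species node where they happened;
                # duplications map to the child node of their branch (all
                # descendants survive when the loss rate is zero)
                assert rec.mapping[node.id] == true_place
                n_dup_nodes += rec.events[node.id] == DUPLICATION
        n_dup_events_with_survivors = sum(
            1 for ev in trace.events if ev.kind == "duplication" for _ in ev.genes
        )
        assert n_dup_nodes > 0
        assert n_dup_nodes <= n_dup_events_with_survivors


class TestWGD:
    def test_wgd_doubles_then_fractionates(self, stree8):
        params = SimParams(
            n_genes=100,
            n_chromosomes=4,
            wgd_branches=frozenset({"ABCD"}),
            wgd_retention=1.0,
            seed=3,
        )
        trace = simulate(stree8, params)
        assert trace.genomes["ABCD"].n_genes == 200
        assert len(trace.genomes["ABCD"].chromosomes) == 8
        assert trace.genomes["EFGH"].n_genes == 100
        half = simulate(
            stree8, dataclasses.replace(params, wgd_retention=0.5, seed=3)
        )
        assert 100 < half.genomes["ABCD"].n_genes < 200


class TestBenchmarkPlumbing:
    def test_zero_rate_benchmark_perfect_agreement(self, stree8):
        from paleorder.linearize import reconstruct
        from paleorder.metrics import compare_to_truth
        from paleorder.reconcile import ancestral_gene_content

        bench = make_benchmark(stree8, SimParams(n_genes=60, n_chromosomes=3, seed=4))
        carsets = reconstruct(stree8, bench.forest, bench.extant_genomes)
        for ancestor in ("ABCD", "EFGH"):
            ancset = ancestral_gene_content(bench.forest, stree8, ancestor)
            relabeled = bench.trace.relabel_carset(ancestor, ancset, carsets[ancestor])
            assert compare_to_truth(relabeled, bench.truth(ancestor)).agreement == 1.0

    def test_single_copy_benchmark_constrains_everything(self, stree8):
        from paleorder.linearize import select_constrained
        from paleorder.reconcile import ancestral_gene_content

        bench = make_benchmark(stree8, SimParams(n_genes=40, n_chromosomes=2, seed=6))
        ancset = ancestral_gene_content(bench.forest, stree8, "ABCD")
        constrained = select_constrained(bench.forest, stree8, "ABCD", ancset=ancset)
        assert constrained == set(ancset.genes)

    def test_files_written(self, stree8, tmp_path):
        make_benchmark(
            stree8, SimParams(n_genes=30, n_chromosomes=2, seed=1), outdir=tmp_path
        )
        assert (tmp_path / "forest.nhx").exists()
        assert (tmp_path / "events.tsv").exists()
        assert sorted(p.stem for p in (tmp_path / "genomes").glob("*.tsv")) == sorted(
            stree8.leaves
        )
        assert (tmp_path / "truth" / "ABCD.tsv").exists()
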