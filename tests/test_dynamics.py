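"""Synteny blocks, breakpoints, interchromosomal events and rates."""

import pytest

from paleorder.dynamics import (
    branch_rates,
    breakpoint_map,
    breakpoints,
    interchromosomal_events,
    one_to_one,
    synteny_blocks,
)
from paleorder.io import Genome
from paleorder.simulate import (
    apply_fission,
    apply_fusion,
    apply_inversion,
    apply_translocation,
)


def genome(name, *chroms):
    return Genome(name, {f"c{i+1}": list(c) for i, c in enumerate(chroms)})


def identity_orth(g):
    return {gene: [gene] for gene in g.genes()}


class TestSyntenyBlocks:
    def test_identical_chromosomes_single_block(self):
        g = genome("P", [(f"g{i}", "+") for i in range(5)])
        h = genome("C", [(f"g{i}", "+") for i in range(5)])
        blocks = synteny_blocks(g, h, identity_orth(g))
        assert len(blocks) == 1
        assert breakpoints(g, h, identity_orth(g)) == 0

    def test_internal_inversion_blocks_and_breakpoints(self):
        p = genome("P", [(g, "+") for g in "abcde"])
        c = genome("C", [("a", "+"), ("b", "+"), ("d", "-"), ("c", "-"), ("e", "+")])
        blocks = synteny_blocks(p, c, identity_orth(p))
        assert [b.genes for b in blocks] == [["a", "b"], ["c", "d"], ["e"]]
        assert [b.orientation for b in blocks] == [1, -1, 1]
        assert breakpoints(p, c, identity_orth(p)) == 2

    def test_fission_boundary_counts_once(self):
        genes = [f"g{i:02d}" for i in range(40)]
        p = genome("P", [(g, "+") for g in genes])
        c = genome("C", [(g, "+") for g in genes[:20]], [(g, "+") for g in genes[20:]])
        assert breakpoints(p, c, identity_orth(p)) == 1

    def test_fusion_counts_once(self):
        genes = [f"g{i:02d}" for i in range(40)]
        p = genome("P", [(g, "+") for g in genes[:20]], [(g, "+") for g in genes[20:]])
        c = genome("C", [(g, "+") for g in genes])
        assert breakpoints(p, c, identity_orth(p)) == 1

    def test_multi_copy_genes_dropped_before_comparison(self):
        p = genome("P", [("a", "+"), ("b", "+"), ("c", "+")])
        c = genome("C", [("a1", "+"), ("b1", "+"), ("c1", "+"), ("a2", "+")])
        orth = {"a": ["a1", "a2"], "b": ["b1"], "c": ["c1"]}
        assert one_to_one(orth) == {"b": "b1", "c": "c1"}
        assert breakpoints(p, c, orth) == 0

    def test_no_shared_genes_rejected(self):
        p = genome("P", [("a", "+")])
        c = genome("C", [("z", "+")])
        with pytest.raises(ValueError):
            synteny_blocks(p, c, {})

    def test_self_comparison_one_block_per_chromosome(self):
        g = genome(
            "G", [(f"a{i}", "+") for i in range(4)], [(f"b{i}", "-") for i in range(3)]
        )
        blocks = synteny_blocks(g, g, identity_orth(g))
        assert len(blocks) == len(g.chromosomes)
        assert breakpoints(g, g, identity_orth(g)) == 0


class TestEventAccounting:
    """Breakpoint counts match 2*inversions + 2*translocations + fissions +
    fusions when events are spaced (no shared breakpoint positions)."""

    def test_spaced_events_formula(self):
        genes = [f"g{i:03d}" for i in range(120)]
        parent_chroms = [
            [(g, "+") for g in genes[:60]],
            [(g, "+") for g in genes[60:]],
        ]
        p = Genome("P", {f"c{i}": list(c) for i, c in enumerate(parent_chroms)})
        child = [list(c) for c in parent_chroms]
        apply_inversion(child, 0, 10, 5)       # 2 breakpoints
        apply_inversion(child, 0, 30, 4)       # 2 breakpoints
        apply_translocation(child, 0, 1, 50, 40)  # 2 breakpoints
        apply_fission(child, 1, 20)            # 1 breakpoint
        apply_fusion(child, 0, 1, False, False)   # 1 breakpoint
        c = Genome("C", {f"k{i}": list(ch) for i, ch in enumerate(child)})
        orth = {g: [g] for g in genes}
        assert breakpoints(p, c, orth) == 2 * 2 + 2 + 1 + 1


class TestInterchromosomal:
    def test_large_fission_called_once(self):
        genes = [f"g{i:03d}" for i in range(250)]
        p = genome("P", [(g, "+") for g in genes])
        c = genome("C", [(g, "+") for g in genes[:130]], [(g, "+") for g in genes[130:]])
        n, events = interchromosomal_events(p, c, identity_orth(p))
        assert n == 1 and events[0].kind == "fission"

    def test_large_fusion_called_once(self):
        genes = [f"g{i:03d}" for i in range(500)]
        p = genome("P", [(g, "+") for g in genes[:250]], [(g, "+") for g in genes[250:]])
        c = genome("C", [(g, "+") for g in genes])
        n, events = interchromosomal_events(p, c, identity_orth(p))
        assert n == 1 and events[0].kind == "fusion"

    def test_reciprocal_translocation_counted_once(self):
        a = [f"a{i:03d}" for i in range(250)]
        b = [f"b{i:03d}" for i in range(250)]
        p = genome("P", [(g, "+") for g in a], [(g, "+") for g in b])
        c = genome(
            "C",
            [(g, "+") for g in a[:200] + b[200:]],
            [(g, "+") for g in b[:200] + a[200:]],
        )
        n, events = interchromosomal_events(p, c, identity_orth(p))
        assert n == 1 and events[0].kind == "translocation"

    def test_small_group_below_floor_ignored(self):
        genes = [f"g{i:03d}" for i in range(250)]
        p = genome("P", [(g, "+") for g in genes])
        # only 10 genes move to another chromosome
        c = genome("C", [(g, "+") for g in genes[:240]], [(g, "+") for g in genes[240:]])
        n, _ = interchromosomal_events(p, c, identity_orth(p))
        assert n == 0

    def test_small_chromosomes_excluded(self):
        genes = [f"g{i:03d}" for i in range(100)]
        p = genome("P", [(g, "+") for g in genes])
        c = genome("C", [(g, "+") for g in genes[:50]], [(g, "+") for g in genes[50:]])
        n, _ = interchromosomal_events(p, c, identity_orth(p))
        assert n == 0  # 100-gene chromosome is below the 200-gene floor


class TestBranchRates:
    def test_gibbon_style_rate(self):
        dyn = branch_rates(0, 60, 25.0)
        assert dyn.rearrangement_rate == pytest.approx(2.4)

    def test_breakpoint_rate(self):
        dyn = branch_rates(5, 0, 10.0)
        assert dyn.breakpoint_rate == pytest.approx(0.5)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            branch_rates(1, 1, 0.0)

    def test_short_branch_flag(self):
        assert branch_rates(1, 1, 4.9).short_branch
        assert not branch_rates(1, 1, 5.0).short_branch


class TestBreakpointMap:
    def test_single_breakpoint_in_first_window(self):
        reference = genome("R", [(f"g{i:02d}", "+") for i in range(60)])
        counts = breakpoint_map([["g09"]], reference, window=20)
        assert counts == [1, 0, 0]

    def test_no_breakpoints(self):
        reference = genome("R", [(f"g{i}", "+") for i in range(10)])
        assert breakpoint_map([], reference, window=5) == [0, 0]

    def test_counts_accumulate_across_branches(self):
        reference = genome("R", [(f"g{i:02d}", "+") for i in range(40)])
        counts = breakpoint_map([["g05"], ["g07", "g30"]], reference, window=20)
        assert counts == [2, 1]
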