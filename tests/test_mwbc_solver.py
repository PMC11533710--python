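"""The exact-cover ILP, its costs, and the exhaustive oracles."""

import pytest

from blockgraph import (
    Block,
    ObjectiveSpec,
    block_cost,
    make_block,
    overlaps,
    solve_exhaustive,
    solve_gmwbc_oracle,
    solve_ilp,
)
from blockgraph.mwbc_solver import OBJECTIVES, SolverError, verify_exact_cover
from blockgraph.synthetic_fixtures import random_msa

from conftest import msa_from_rows, single_window_instance


class TestBlockCost:
    def test_blocks_is_unit(self, example):
        obj = ObjectiveSpec("blocks")
        assert block_cost(example, Block(2, 9, (2, 3, 4)), obj) == 1.0

    def test_weighted_penalises_short_labels(self, example):
        obj = ObjectiveSpec("weighted", q=20, delta=1000.0)
        # gap-free label GA has length 2 <= q
        assert block_cost(example, Block(7, 8, (1, 2, 3, 4, 5)), obj) == 1000.0

    def test_weighted_long_label_unit(self):
        msa = msa_from_rows("A" * 25, "A" * 25)
        obj = ObjectiveSpec("weighted", q=20, delta=1000.0)
        assert block_cost(msa, Block(1, 25, (1, 2)), obj) == 1.0

    def test_weighted_boundary_is_penalised(self):
        # the formula penalises labels with length exactly q too
        msa = msa_from_rows("A" * 20, "A" * 20)
        obj = ObjectiveSpec("weighted", q=20, delta=1000.0)
        assert block_cost(msa, Block(1, 20, (1, 2)), obj) == 1000.0

    def test_depth_fractional_threshold(self, example):
        obj = ObjectiveSpec("depth", p=0.11, delta=1000.0)
        # floor(0.11 * 5) = 0: nothing penalised
        assert block_cost(example, Block(1, 1, (3,)), obj) == 1.0
        obj = ObjectiveSpec("depth", p=0.5, delta=1000.0)
        # floor(0.5 * 5) = 2: 1- and 2-row blocks penalised
        assert block_cost(example, Block(1, 1, (3,)), obj) == 1000.0
        assert block_cost(example, Block(2, 9, (2, 3, 4)), obj) == 1.0

    def test_depth_literal_count_mode(self, example):
        obj = ObjectiveSpec("depth", delta=1000.0, depth_min_count=3)
        assert block_cost(example, Block(2, 9, (2, 3, 4)), obj) == 1000.0
        assert block_cost(example, Block(7, 8, (1, 2, 3, 4, 5)), obj) == 1.0

    def test_strings_counts_gap_free_length(self, example):
        obj = ObjectiveSpec("strings")
        assert block_cost(example, Block(2, 9, (2, 3, 4)), obj) == 6.0

    def test_penalized_strings(self, example):
        obj = ObjectiveSpec("penalized-strings")
        assert block_cost(example, Block(2, 9, (2, 3, 4)), obj) == pytest.approx(2.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ObjectiveSpec("nonsense")
        with pytest.raises(ValueError):
            ObjectiveSpec("depth", p=0.0)
        with pytest.raises(ValueError):
            ObjectiveSpec("weighted", delta=0.5)


class TestSolveILP:
    def test_identical_pair_single_block(self):
        inst = single_window_instance(msa_from_rows("AC", "AC"))
        cover = solve_ilp(inst, ObjectiveSpec("blocks"))
        assert cover.objective_value == 1.0
        assert cover.blocks == (Block(1, 2, (1, 2)),)

    def test_mismatched_pair_needs_three(self):
        inst = single_window_instance(msa_from_rows("AC", "AG"))
        cover = solve_ilp(inst, ObjectiveSpec("blocks"))
        assert cover.objective_value == 3.0

    def test_delta_one_reduces_weighted_to_blocks(self):
        for seed in range(5):
            inst = single_window_instance(random_msa(seed, 4, 6, "ACG-"))
            v_blocks = solve_ilp(inst, ObjectiveSpec("blocks")).objective_value
            v_w = solve_ilp(inst, ObjectiveSpec("weighted", delta=1.0)).objective_value
            assert v_w == pytest.approx(v_blocks)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("obj_name", OBJECTIVES)
    def test_cover_is_exact_and_value_consistent(self, seed, obj_name):
        msa = random_msa(seed, 4, 8, "ACGT-")
        inst = single_window_instance(msa)
        obj = ObjectiveSpec(obj_name)
        cover = solve_ilp(inst, obj)
        verify_exact_cover(msa, cover.blocks)
        for i, a in enumerate(cover.blocks):
            for b in cover.blocks[i + 1:]:
                assert not overlaps(a, b)
        recomputed = sum(block_cost(msa, b, obj) for b in cover.blocks)
        assert cover.objective_value == pytest.approx(recomputed, abs=1e-6)

    def test_empty_candidates_rejected(self, example):
        from blockgraph.instance_builder import MWBCInstance

        inst = MWBCInstance(example, 0, ())
        with pytest.raises(SolverError):
            solve_ilp(inst, ObjectiveSpec())


class TestOracles:
    def test_exhaustive_identical_pair(self):
        inst = single_window_instance(msa_from_rows("AC", "AC"))
        assert solve_exhaustive(inst, ObjectiveSpec("blocks")).objective_value == 1.0

    def test_exhaustive_strings_mismatched_pair(self):
        inst = single_window_instance(msa_from_rows("AC", "AG"))
        cover = solve_exhaustive(inst, ObjectiveSpec("strings"))
        assert cover.objective_value == 3.0

    def test_exhaustive_guard(self):
        inst = single_window_instance(msa_from_rows("ACGTACGTAC", "ACGTACGTAC",
                                                    "ACGTACGTAC", "ACGTACGTAC"))
        with pytest.raises(ValueError, match="too large"):
            solve_exhaustive(inst, ObjectiveSpec())

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("obj_name", OBJECTIVES)
    def test_ilp_matches_exhaustive(self, seed, obj_name):
        msa = random_msa(seed, 3, 4, "AC-")
        inst = single_window_instance(msa)
        obj = ObjectiveSpec(obj_name)
        assert solve_ilp(inst, obj).objective_value == pytest.approx(
            solve_exhaustive(inst, obj).objective_value
        )

    def test_gmwbc_trivial_cases(self):
        obj = ObjectiveSpec("blocks")
        assert solve_gmwbc_oracle(msa_from_rows("AC", "AC"), obj).objective_value == 1.0
        assert solve_gmwbc_oracle(msa_from_rows("ACGT"), obj).objective_value == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_gmwbc_lower_bounds_restricted_optimum(self, seed):
        """The unrestricted optimum never exceeds the pipeline-candidate one."""
        msa = random_msa(seed, 3, 4, "AC-")
        inst = single_window_instance(msa)
        for obj_name in OBJECTIVES:
            obj = ObjectiveSpec(obj_name)
            lower = solve_gmwbc_oracle(msa, obj).objective_value
            assert lower <= solve_ilp(inst, obj).objective_value + 1e-9

    def test_gmwbc_guard(self):
        with pytest.raises(ValueError, match="too large"):
            solve_gmwbc_oracle(
                msa_from_rows("ACGTACGT", "ACGTACGT", "ACGTACGT"), ObjectiveSpec()
            )


@pytest.mark.parametrize("seed", range(6))
def test_more_candidates_never_hurt(seed):
    """Adding candidates (complete vs row-maximal) cannot raise the optimum."""
    msa = random_msa(seed, 4, 7, "AC-")
    rm = single_window_instance(msa, "row-maximal")
    co = single_window_instance(msa, "complete")
    assert set(rm.candidates) <= set(co.candidates)
    for obj_name in OBJECTIVES:
        obj = ObjectiveSpec(obj_name)
        assert (
            solve_ilp(co, obj).objective_value
            <= solve_ilp(rm, obj).objective_value + 1e-9
        )
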