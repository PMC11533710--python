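"""Vertical-block forcing, window splitting and candidate completion."""

import pytest

from blockgraph import (
    Block,
    add_short_blocks,
    breakpoints,
    build_instance,
    enumerate_maximal_blocks,
    find_vertical_blocks,
    longest_free_window,
    split_by_vertical,
)
from blockgraph.instance_builder import one_character_blocks, one_row_blocks
from blockgraph.mwbc_solver import verify_exact_cover
from blockgraph.synthetic_fixtures import random_msa

from conftest import msa_from_rows

ALL5 = (1, 2, 3, 4, 5)


class TestVerticalBlocks:
    def test_example_alpha2(self, example):
        assert find_vertical_blocks(example, 2) == [Block(7, 8, ALL5)]

    def test_example_alpha1_includes_singleton_runs(self, example):
        # columns 2 and 5 are uniform across all rows; 7-8 is the only run >= 2
        assert find_vertical_blocks(example, 1) == [
            Block(2, 2, ALL5),
            Block(5, 5, ALL5),
            Block(7, 8, ALL5),
        ]

    def test_example_alpha3_empty(self, example):
        assert find_vertical_blocks(example, 3) == []

    def test_identical_rows(self):
        msa = msa_from_rows("ACGT", "ACGT", "ACGT")
        assert find_vertical_blocks(msa, 1) == [Block(1, 4, (1, 2, 3))]

    def test_disabled(self, example):
        assert find_vertical_blocks(example, None) == []


class TestSplit:
    def test_example_split(self, example):
        wins = split_by_vertical(example, [Block(7, 8, ALL5)])
        assert [(w.start, w.end, w.role) for w in wins] == [
            (1, 6, "free"),
            (7, 8, "forced-vertical"),
            (9, 9, "free"),
        ]

    def test_no_forced(self, example):
        wins = split_by_vertical(example, [])
        assert [(w.start, w.end, w.role) for w in wins] == [(1, 9, "free")]

    def test_fully_forced(self):
        msa = msa_from_rows("AC", "AC")
        wins = split_by_vertical(msa, [Block(1, 2, (1, 2))])
        assert [(w.start, w.end, w.role) for w in wins] == [
            (1, 2, "forced-vertical")
        ]

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("alpha", [1, 2, 3])
    def test_windows_tile_the_columns(self, seed, alpha):
        msa = random_msa(seed, max_rows=6, max_cols=12, alphabet="ACG-")
        wins = split_by_vertical(msa, find_vertical_blocks(msa, alpha))
        cols = [c for w in wins for c in range(w.start, w.end + 1)]
        assert cols == list(range(1, msa.n + 1))


class TestAlphaCurve:
    def test_example_values(self, example):
        assert longest_free_window(example, 2) == 6
        assert longest_free_window(example, 3) == 9
        assert longest_free_window(example, 1) == 2

    def test_example_breakpoints(self, example):
        assert breakpoints(example) == [(1, 2), (2, 6), (3, 9)]

    def test_no_vertical_column(self):
        msa = msa_from_rows("AAAA", "CCCC")
        assert breakpoints(msa) == [(1, 4)]

    def test_identical_rows(self):
        msa = msa_from_rows("ACGT", "ACGT")
        assert breakpoints(msa) == [(1, 0), (5, 4)]

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_and_matches_sweep(self, seed):
        msa = random_msa(seed, max_rows=5, max_cols=12, alphabet="AC-")
        sweep = [longest_free_window(msa, a) for a in range(1, msa.n + 2)]
        assert sweep == sorted(sweep)
        bps = breakpoints(msa)
        # reconstruct the step function from the breakpoints
        recon = []
        for a in range(1, msa.n + 2):
            vals = [v for aa, v in bps if aa <= a]
            recon.append(vals[-1])
        assert recon == sweep


class TestShortBlocks:
    def test_one_character_blocks_column1(self, example):
        col1 = [b for b in one_character_blocks(example) if b.b == 1]
        assert set(col1) == {
            Block(1, 1, (1, 2, 5)),
            Block(1, 1, (3,)),
            Block(1, 1, (4,)),
        }

    def test_uniform_column_single_block(self):
        msa = msa_from_rows("AG", "AC")
        col1 = [b for b in one_character_blocks(msa) if b.b == 1]
        assert col1 == [Block(1, 1, (1, 2))]

    def test_at_most_six_per_column(self, example):
        for b in range(1, example.n + 1):
            assert len([x for x in one_character_blocks(example) if x.b == b]) <= 6

    @pytest.mark.parametrize("seed", range(10))
    def test_one_character_blocks_are_exact_cover(self, seed):
        msa = random_msa(seed, alphabet="ACGT-")
        verify_exact_cover(msa, one_character_blocks(msa))

    def test_one_row_blocks_fill_uncovered_stretches(self, example):
        maximal = enumerate_maximal_blocks(example, 2)
        for blk in one_row_blocks(example, maximal):
            assert len(blk.rows) == 1
            r = blk.rows[0]
            for c in range(blk.b, blk.e + 1):
                assert not any(
                    r in mb.K and mb.b <= c <= mb.e for mb in maximal
                )

    def test_add_short_blocks_keeps_candidates(self, example):
        maximal = enumerate_maximal_blocks(example, 2)
        out = add_short_blocks(example, maximal, coverage=maximal)
        assert set(maximal) <= set(out)
        assert len(out) == len(set(out))


class TestBuildInstance:
    def test_example_alpha2(self, example):
        res = build_instance(example, alpha=2)
        assert len(res.instances) == 2
        assert res.forced == [Block(7, 8, ALL5)]
        assert [(i.offset + 1, i.offset + i.msa.n) for i in res.instances] == [
            (1, 6),
            (9, 9),
        ]

    def test_disabled_single_window(self, example):
        res = build_instance(example, alpha=None)
        assert len(res.instances) == 1 and res.forced == []
        assert res.instances[0].msa.n == example.n

    @pytest.mark.parametrize("alpha", [1, 2, None])
    def test_every_instance_feasible(self, example, alpha):
        """The window's one-character blocks are all candidates and alone form
        an exact cover of the window."""
        res = build_instance(example, alpha=alpha)
        for inst in res.instances:
            ones = one_character_blocks(inst.msa)
            assert set(ones) <= set(inst.candidates)
            verify_exact_cover(inst.msa, ones)

    def test_candidates_stay_inside_window(self, example):
        res = build_instance(example, alpha=2)
        for inst in res.instances:
            for blk in inst.candidates:
                assert 1 <= blk.b <= blk.e <= inst.msa.n
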