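"""Fisher test, BH adjustment and the hypo-DMR selection/merge pipeline."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import gbmscape as gb
from conftest import make_records
from gbmscape.dmr import DmrParams, TileTestResult, merge_selected_tiles
from gbmscape.errors import ValidationError
from oracles import bh_adjust_naive, fisher_two_sided_exact


class TestFisherExact:
    def test_all_zero_table_is_degenerate(self):
        assert gb.fisher_exact_2x2(0, 0, 0, 0) == 1.0

    def test_perfect_split_matches_enumeration(self):
        # margins (5,5,5,5): only the two extreme tables are as extreme
        expected = float(fisher_two_sided_exact(5, 0, 0, 5))
        assert expected == pytest.approx(2 / 252)
        assert gb.fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(expected, rel=1e-12)

    def test_balanced_table_has_p_one(self):
        # the observed table is the distribution mode: every table qualifies
        assert gb.fisher_exact_2x2(10, 10, 10, 10) == pytest.approx(1.0)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValidationError):
            gb.fisher_exact_2x2(-1, 2, 3, 4)

    @settings(max_examples=150)
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    def test_agrees_with_scipy(self, a, b, c, d):
        ours = gb.fisher_exact_2x2(a, b, c, d)
        ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


class TestBHAdjust:
    def test_step_up_collapses_linear_p(self):
        out = gb.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert gb.bh_adjust([1.0]) == pytest.approx([1.0])

    def test_missing_excluded_from_m(self):
        out = gb.bh_adjust([0.5, np.nan, 0.5])
        assert out[0] == pytest.approx(0.5)  # m = 2: q = 0.5 * 2 / 2
        assert np.isnan(out[1])
        assert out[2] == pytest.approx(0.5)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            gb.bh_adjust([0.5, 1.5])

    @settings(max_examples=100)
    @given(st.lists(st.one_of(st.none(), st.floats(0, 1)), max_size=25))
    def test_matches_naive_definition(self, ps):
        got = gb.bh_adjust([np.nan if p is None else p for p in ps])
        ref = bh_adjust_naive(ps)
        for g, r in zip(got, ref):
            if r is None:
                assert np.isnan(g)
            else:
                assert g == pytest.approx(r, rel=1e-12)

    @settings(max_examples=60)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25),
           st.randoms(use_true_random=False))
    def test_monotone_in_rank_and_permutation_invariant(self, ps, rnd):
        q = gb.bh_adjust(ps)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        q_perm = gb.bh_adjust([ps[i] for i in perm])
        assert np.allclose([q[i] for i in perm], q_perm)

    def test_statsmodels_cross_check(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        ps = rng.random(50)
        ours = gb.bh_adjust(ps)
        theirs = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, rtol=1e-12)


def _counts(tiles, pairs, label="s"):
    cs = gb.TileCountSet(tiles=tiles, context="CG")
    m = np.array([p[0] for p in pairs])
    u = np.array([p[1] for p in pairs])
    cs.add_sample(label, m, u)
    return cs


class TestTestTiles:
    def setup_method(self):
        self.tiles = gb.tile_genome({"c": 300}, 100)

    def test_19_calls_untested_regardless_of_other_sample(self):
        wt = _counts(self.tiles, [(10, 9), (20, 0), (10, 10)], "WT")
        kd = _counts(self.tiles, [(100, 100), (0, 20), (10, 10)], "kd")
        res = gb.test_tiles(wt, kd)
        assert not res.tested[0] and np.isnan(res.p[0]) and np.isnan(res.q[0])

    def test_extreme_difference(self):
        wt = _counts(self.tiles, [(10, 9), (20, 0), (10, 10)], "WT")
        kd = _counts(self.tiles, [(100, 100), (0, 20), (10, 10)], "kd")
        res = gb.test_tiles(wt, kd)
        assert res.tested[1]
        assert res.delta[1] == pytest.approx(1.0)
        assert res.p[1] < 1e-9

    def test_identical_counts_not_selectable(self):
        wt = _counts(self.tiles, [(10, 9), (20, 0), (10, 10)], "WT")
        kd = _counts(self.tiles, [(100, 100), (0, 20), (10, 10)], "kd")
        res = gb.test_tiles(wt, kd)
        assert res.delta[2] == 0.0
        assert res.q[2] >= res.p[2]

    def test_tile_list_mismatch_rejected(self):
        other = gb.tile_genome({"c": 200}, 100)
        wt = _counts(self.tiles, [(10, 10)] * 3, "WT")
        kd = _counts(other, [(10, 10)] * 2, "kd")
        with pytest.raises(ValidationError, match="tile lists"):
            gb.test_tiles(wt, kd)


class TestSelectHypoTiles:
    def _result(self, qs, deltas, tested=None):
        n = len(qs)
        tiles = gb.tile_genome({"c": n * 100}, 100)
        tested = np.ones(n, bool) if tested is None else np.asarray(tested)
        return TileTestResult(tiles=tiles, context="CG", p=np.asarray(qs, float),
                              q=np.asarray(qs, float),
                              delta=np.asarray(deltas, float), tested=tested)

    def test_intersection_requires_every_replicate(self):
        r1 = self._result([0.001], [0.35])
        r2 = self._result([0.001], [0.10])
        assert list(gb.select_hypo_tiles([r1, r2])) == []

    def test_tile_passing_both_replicates_selected(self):
        r1 = self._result([0.001], [0.35])
        r2 = self._result([0.005], [0.21])
        assert list(gb.select_hypo_tiles([r1, r2])) == [0]

    def test_hypermethylation_never_selected(self):
        r = self._result([0.0001], [-0.4])
        assert list(gb.select_hypo_tiles([r, r])) == []

    def test_too_few_replicates_rejected(self):
        r = self._result([0.001], [0.35])
        with pytest.raises(ValidationError, match="replicate"):
            gb.select_hypo_tiles([r], DmrParams(n_required_reps=2))


class TestMergeSelectedTiles:
    def test_gap_150_merges(self):
        tiles = [gb.GenomicInterval("c", 0, 100, kind="tile"),
                 gb.GenomicInterval("c", 250, 350, kind="tile")]
        merged = merge_selected_tiles(tiles, 200)
        assert [(m[0], m[1], m[2]) for m in merged] == [("c", 0, 350)]

    def test_gap_201_does_not_merge(self):
        tiles = [gb.GenomicInterval("c", 0, 100, kind="tile"),
                 gb.GenomicInterval("c", 301, 401, kind="tile")]
        merged = merge_selected_tiles(tiles, 200)
        assert len(merged) == 2

    def test_gap_exactly_200_merges(self):
        tiles = [gb.GenomicInterval("c", 0, 100, kind="tile"),
                 gb.GenomicInterval("c", 300, 400, kind="tile")]
        assert len(merge_selected_tiles(tiles, 200)) == 1

    def test_adjacent_tiles_merge(self):
        tiles = [gb.GenomicInterval("c", 0, 100, kind="tile"),
                 gb.GenomicInterval("c", 100, 200, kind="tile")]
        merged = merge_selected_tiles(tiles, 200)
        assert merged[0][1:3] == (0, 200) and len(merged[0][3]) == 2


def _null_records(rng, size=3_000, n_cyt=120, coverage=30, level=0.6):
    pos = np.sort(rng.choice(size, n_cyt, replace=False)) + 1
    total = rng.poisson(coverage, n_cyt)
    meth = rng.binomial(total, level)
    return make_records([
        ("c", int(p), "+", "CG", int(m), int(t - m))
        for p, m, t in zip(pos, meth, total)
    ])


class TestCallDmrs:
    def test_identical_methylomes_give_no_dmrs(self):
        rng = np.random.default_rng(5)
        wt = _null_records(rng)
        dmrs = gb.call_dmrs(wt, [wt.copy(), wt.copy()], {"c": 3_000}, "CG")
        assert dmrs == []

    def test_planted_region_recovered(self):
        """A 500-bp region with WT level 0.8 vs kd 0.2 at coverage 30 is
        recovered within one tile of its edges."""
        rng = np.random.default_rng(11)
        size = 5_000
        pos = np.sort(rng.choice(size, 250, replace=False))
        planted = (pos >= 2_000) & (pos < 2_500)

        def sample(levels, seed):
            r = np.random.default_rng(seed)
            total = r.poisson(30, len(pos))
            meth = r.binomial(total, levels)
            return make_records([
                ("c", int(p) + 1, "+", "CG", int(m), int(t - m))
                for p, m, t in zip(pos, meth, total)
            ])

        wt_levels = np.where(planted, 0.8, 0.3)
        kd_levels = np.where(planted, 0.2, 0.3)
        wt = sample(wt_levels, 1)
        kds = [sample(kd_levels, 2), sample(kd_levels, 3)]
        dmrs = gb.call_dmrs(wt, kds, {"c": size}, "CG")
        assert len(dmrs) == 1
        d = dmrs[0]
        assert abs(d.interval.start - 2_000) <= 100
        assert abs(d.interval.end - 2_500) <= 100
        assert d.delta > 0.4 and d.min_q < 0.01

    def test_unsatisfiable_delta_threshold(self):
        rng = np.random.default_rng(5)
        wt = _null_records(rng, level=0.9)
        kd = _null_records(rng, level=0.1)
        params = DmrParams(min_delta=1.0)
        strict = gb.call_dmrs(wt, [kd, kd.copy()], {"c": 3_000}, "CG", params)
        loose = gb.call_dmrs(wt, [kd, kd.copy()], {"c": 3_000}, "CG",
                             DmrParams(min_delta=0.2))
        # a per-tile reduction of 1.0 needs fully methylated WT and fully
        # unmethylated kd counts at >= 20 calls; these levels cannot do that
        assert strict == []
        assert len(loose) > 0

    def test_too_few_replicates_rejected(self):
        rng = np.random.default_rng(5)
        wt = _null_records(rng)
        with pytest.raises(ValidationError, match="replicates"):
            gb.call_dmrs(wt, [wt.copy()], {"c": 3_000}, "CG")

    def test_monotone_in_thresholds(self):
        """Raising min_delta or lowering fdr never adds selected tiles."""
        rng = np.random.default_rng(23)
        size = 8_000
        pos = np.sort(rng.choice(size, 400, replace=False))
        wt_levels = rng.uniform(0.2, 0.9, len(pos))
        kd_levels = np.clip(wt_levels - rng.uniform(0, 0.5, len(pos)), 0, 1)

        def sample(levels, seed):
            r = np.random.default_rng(seed)
            total = r.poisson(25, len(pos))
            meth = r.binomial(total, levels)
            return make_records([
                ("c", int(p) + 1, "+", "CG", int(m), int(t - m))
                for p, m, t in zip(pos, meth, total)
            ])

        wt = sample(wt_levels, 1)
        kds = [sample(kd_levels, 2), sample(kd_levels, 3)]
        tiles = gb.tile_genome({"c": size}, 100)
        wt_c = gb.aggregate_to_tiles(wt, tiles, "CG", "WT")
        kd_cs = [gb.aggregate_to_tiles(k, tiles, "CG", "kd") for k in kds]
        results = [gb.test_tiles(wt_c, kc) for kc in kd_cs]
        n_prev = None
        for min_delta in (0.1, 0.2, 0.3, 0.5):
            n = len(gb.select_hypo_tiles(results, DmrParams(min_delta=min_delta)))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n
        n_prev = None
        for fdr in (0.1, 0.05, 0.01, 0.001):
            n = len(gb.select_hypo_tiles(results, DmrParams(fdr=fdr)))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n
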