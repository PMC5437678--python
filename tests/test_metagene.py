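"""Quintile assignment and scaled metagene profiling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gbmscape as gb
from conftest import make_records
from gbmscape.errors import ValidationError
from gbmscape.metagene import MethylationSource, TrackSource, QUINTILE_LABELS


class TestAssignQuintiles:
    def test_even_split_by_expression(self):
        expr = {f"g{i}": float(i) for i in range(1, 11)}
        q = gb.assign_quintiles(expr, list(expr))
        assert {g for g, v in q.items() if v == "Q1"} == {"g1", "g2"}
        assert {g for g, v in q.items() if v == "Q5"} == {"g9", "g10"}

    def test_all_ties_broken_by_id(self):
        expr = {g: 0.0 for g in ("e", "d", "c", "b", "a")}
        q = gb.assign_quintiles(expr, list(expr))
        assert q == {"a": "Q1", "b": "Q2", "c": "Q3", "d": "Q4", "e": "Q5"}

    def test_fewer_genes_than_groups_fill_from_q1(self):
        expr = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        q = gb.assign_quintiles(expr, list(expr))
        assert q == {"a": "Q1", "b": "Q2", "c": "Q3", "d": "Q4"}
        assert "Q5" not in q.values()

    def test_missing_gene_listed(self):
        with pytest.raises(ValidationError, match="ghost"):
            gb.assign_quintiles({"a": 1.0}, ["a", "ghost"])

    def test_group_sizes_differ_by_at_most_one(self):
        expr = {f"g{i:03d}": float(i % 7) for i in range(23)}
        q = gb.assign_quintiles(expr, list(expr))
        sizes = [sum(1 for v in q.values() if v == lab) for lab in QUINTILE_LABELS]
        assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 23

    def test_expressed_filter_drops_low_fpkm_genes(self):
        genes = [gb.GenomicInterval("c", i * 200, i * 200 + 100, "+", f"g{i}", "gene")
                 for i in range(6)]
        expr = {g.id: float(i) for i, g in enumerate(genes)}  # g0 has FPKM 0
        grouping = gb.expression_quintile_grouping(expr, genes)
        assert "g0" not in grouping and len(grouping) == 5


def _const_track(value, size=10_000, chrom="c"):
    return gb.SignalTrack(data={chrom: np.full(size, float(value))})


class TestGeneProfile:
    def test_constant_track_gives_constant_bins(self):
        src = TrackSource(_const_track(2.0))
        gene = gb.GenomicInterval("c", 2_000, 3_000, "+", "g", "gene")
        vec = gb.gene_profile(src, gene, 40, 20, chrom_size=10_000)
        assert vec.shape == (80,)
        assert np.allclose(vec, 2.0, rtol=1e-12)

    def test_body_halves_and_minus_strand_reversal(self):
        track = _const_track(0.0)
        track.data["c"][2_000:2_500] = 1.0  # first half of the body
        src = TrackSource(track)
        plus = gb.GenomicInterval("c", 2_000, 3_000, "+", "g", "gene")
        vec = gb.gene_profile(src, plus, 2, 1, chrom_size=10_000)
        assert np.allclose(vec[1:3], [1.0, 0.0])
        # same signal mirrored onto a minus-strand gene
        mirrored = gb.SignalTrack(data={"c": track.data["c"][::-1].copy()})
        minus = gb.GenomicInterval("c", 10_000 - 3_000, 10_000 - 2_000, "-", "g", "gene")
        vec_m = gb.gene_profile(TrackSource(mirrored), minus, 2, 1, chrom_size=10_000)
        assert np.allclose(vec_m, vec)

    def test_flank_past_chromosome_start_is_missing(self):
        src = TrackSource(_const_track(1.0))
        gene = gb.GenomicInterval("c", 100, 1_100, "+", "g", "gene")
        vec = gb.gene_profile(src, gene, 4, 2, chrom_size=10_000)
        assert np.isnan(vec[0])  # upstream flank would start at -900
        assert np.allclose(vec[2:], 1.0)

    def test_short_gene_rejected(self):
        src = TrackSource(_const_track(1.0))
        gene = gb.GenomicInterval("c", 0, 10, "+", "tiny", "gene")
        with pytest.raises(ValidationError, match="tiny"):
            gb.gene_profile(src, gene, 40, 20)

    def test_methylation_bins_pool_counts(self):
        records = make_records([
            ("c", 2_001, "+", "CG", 9, 1),   # first body half
            ("c", 2_100, "-", "CG", 1, 9),
            ("c", 2_900, "+", "CG", 5, 5),   # second body half
        ])
        src = MethylationSource(records, "CG")
        gene = gb.GenomicInterval("c", 2_000, 3_000, "+", "g", "gene")
        vec = gb.gene_profile(src, gene, 2, 1, chrom_size=10_000)
        assert vec[1] == pytest.approx(10 / 20)  # pooled, not (0.9 + 0.1) / 2
        assert vec[2] == pytest.approx(0.5)
        assert np.isnan(vec[0]) and np.isnan(vec[3])  # empty flanks


class TestMetagene:
    def _genes(self):
        return [gb.GenomicInterval("c", 2_000, 3_000, "+", "g1", "gene"),
                gb.GenomicInterval("c", 5_000, 6_000, "+", "g2", "gene")]

    def test_identical_genes_average_to_single_profile(self):
        src = TrackSource(_const_track(3.0))
        genes = self._genes()
        grouping = {"g1": "all", "g2": "all"}
        prof = gb.metagene(src, genes, grouping, 10, 5, {"c": 10_000})
        single = gb.gene_profile(src, genes[0], 10, 5, chrom_size=10_000)
        assert np.allclose(prof.values[0], single)
        assert prof.n_genes[0] == 2

    def test_all_zero_signal(self):
        src = TrackSource(_const_track(0.0))
        prof = gb.metagene(src, self._genes(), {"g1": "all", "g2": "all"},
                           10, 5, {"c": 10_000})
        assert np.allclose(prof.values, 0.0)

    def test_empty_group_warns_and_is_missing(self):
        src = TrackSource(_const_track(1.0))
        with pytest.warns(UserWarning, match="no profiled genes"):
            prof = gb.metagene(src, self._genes(), {"g1": "A", "g2": "A"},
                               10, 5, {"c": 10_000}, group_order=["A", "B"])
        assert np.isnan(prof.values[1]).all()

    def test_all_profile_is_gene_count_weighted_mean_of_groups(self):
        rng = np.random.default_rng(3)
        track = gb.SignalTrack(data={"c": rng.random(40_000)})
        src = TrackSource(track)
        genes = [gb.GenomicInterval("c", 3_000 + i * 3_500, 3_000 + i * 3_500 + 1_000,
                                    "+", f"g{i}", "gene") for i in range(9)]
        groups = {g.id: ("A" if i < 4 else "B") for i, g in enumerate(genes)}
        prof_split = gb.metagene(src, genes, groups, 10, 5, {"c": 40_000},
                                 group_order=["A", "B"])
        prof_all = gb.metagene(src, genes, {g.id: "all" for g in genes},
                               10, 5, {"c": 40_000})
        weighted = (prof_split.values[0] * 4 + prof_split.values[1] * 5) / 9
        assert np.allclose(prof_all.values[0], weighted, rtol=1e-10)

    @settings(max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_strand_flip_equivariance(self, seed):
        """Mirroring all coordinates and flipping strands leaves every
        profile unchanged."""
        rng = np.random.default_rng(seed)
        size = 5_000
        vec = rng.random(size)
        genes, mirrored = [], []
        pos = 1_000
        for i in range(3):
            length = int(rng.integers(60, 400))
            start = pos + int(rng.integers(0, 300))
            pos = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            flip = "-" if strand == "+" else "+"
            genes.append(gb.GenomicInterval("c", start, start + length, strand,
                                            f"g{i}", "gene"))
            mirrored.append(gb.GenomicInterval("c", size - (start + length),
                                               size - start, flip, f"g{i}", "gene"))
        grouping = {f"g{i}": "all" for i in range(3)}
        src = TrackSource(gb.SignalTrack(data={"c": vec}))
        src_m = TrackSource(gb.SignalTrack(data={"c": vec[::-1].copy()}))
        prof = gb.metagene(src, genes, grouping, 12, 6, {"c": size})
        prof_m = gb.metagene(src_m, mirrored, grouping, 12, 6, {"c": size})
        assert np.allclose(prof.values, prof_m.values, rtol=1e-9, equal_nan=True)


class TestNormalizeTrack:
    def test_counts_per_million(self):
        track = gb.SignalTrack(data={"c": np.full(10, 10.0)}, total_reads=1_000_000)
        assert np.allclose(gb.normalize_track(track).data["c"], 10.0)
        track2 = gb.SignalTrack(data={"c": np.full(10, 10.0)}, total_reads=2_000_000)
        assert np.allclose(gb.normalize_track(track2).data["c"], 5.0)

    def test_missing_total_rejected(self):
        track = gb.SignalTrack(data={"c": np.zeros(5)})
        with pytest.raises(ValidationError):
            gb.normalize_track(track)


class TestDifferentialProfile:
    def _profile(self, values, groups=("all",)):
        values = np.atleast_2d(np.asarray(values, float))
        return gb.MetageneProfile(n_bins_body=values.shape[1] - 2, n_bins_flank=1,
                                  groups=list(groups), values=values,
                                  n_genes=np.array([1] * len(groups)))

    def test_self_difference_is_zero(self):
        p = self._profile([1.0, 2.0, 3.0, 4.0])
        diff = gb.differential_profile(p, p, mode="difference")
        assert np.all(diff.values == 0.0)

    def test_self_ratio_is_zero(self):
        p = self._profile([1.0, 2.0, 3.0, 4.0])
        diff = gb.differential_profile(p, p, mode="log2_ratio")
        assert np.allclose(diff.values, 0.0)

    def test_structure_mismatch_rejected(self):
        p = self._profile([1.0, 2.0, 3.0, 4.0])
        q = self._profile([[1.0, 2.0, 3.0, 4.0]] * 2, groups=("a", "b"))
        with pytest.raises(ValidationError, match="structure"):
            gb.differential_profile(p, q)

    def test_missing_propagates(self):
        p = self._profile([1.0, np.nan, 3.0, 4.0])
        diff = gb.differential_profile(p, p)
        assert np.isnan(diff.values[0, 1])


@pytest.fixture(scope="module")
def tracks(small_sim):
    cfg, ann = small_sim["config"], small_sim["annotation"]
    # raw counts: simulated conditions are depth-matched by construction,
    # so no per-million rescaling is applied before differencing
    out = {}
    for factor in ("H1", "H2A.Z"):
        for cond in ("WT", "kd"):
            out[(factor, cond)] = gb.simulate_track(ann, cfg, factor, cond)
    return out


class TestChromatinDifferentials:
    """Knockdown chromatin changes concentrate over expressed gene bodies."""

    @pytest.mark.parametrize("factor", ["H1", "H2A.Z"])
    def test_kd_gain_over_bodies_grows_with_expression(self, small_sim, tracks, factor):
        ann = small_sim["annotation"]
        grouping = dict(ann.quintile)
        profs = {
            cond: gb.metagene(TrackSource(tracks[(factor, cond)]), ann.genes,
                              grouping, 20, 10, ann.chrom_sizes,
                              group_order=list(QUINTILE_LABELS))
            for cond in ("WT", "kd")
        }
        diff = gb.differential_profile(profs["kd"], profs["WT"])
        body = slice(10, 30)
        q1 = np.nanmean(diff.values[0, body])
        q5 = np.nanmean(diff.values[4, body])
        assert q5 > q1 > 0
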