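"""Oligo-track densities, region building, statistics, and burden arithmetic."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tymap.catalog import TyElement
from tymap.dsb import (AnalysisRegion, DsbCalibration, DsbError, OligoTrack,
                       SubtelomereRule, build_analysis_regions, burden_metrics,
                       classify_intergenic, flanking_density, internal_density,
                       normalize_to_hpm, oligo_fraction_to_dsb_percent,
                       one_way_anova, rank_sum_test, select_control_sites)


def _elem(chrom, start, end=None, family="Ty1", name=None):
    return TyElement(chrom=chrom, name=name or f"e_{chrom}_{start}",
                     insert_start=start, insert_end=end or start + 1,
                     family=family, strand="+")


def _hpm_track(values: dict[str, np.ndarray]) -> OligoTrack:
    """A track whose values are already hpM (for direct density checks)."""
    return OligoTrack(counts={c: np.asarray(v, float)
                              for c, v in values.items()},
                      total_mapped=1e6, normalized=True)


class TestNormalization:
    def test_hpm_scaling(self):
        t = OligoTrack(counts={"c": np.array([5.0])}, total_mapped=1e6)
        assert normalize_to_hpm(t).counts["c"][0] == 5.0
        t2 = OligoTrack(counts={"c": np.array([5.0])}, total_mapped=2e6)
        assert normalize_to_hpm(t2).counts["c"][0] == 2.5

    def test_idempotent(self):
        t = normalize_to_hpm(OligoTrack(counts={"c": np.arange(5.0)},
                                        total_mapped=1e4))
        again = normalize_to_hpm(t)
        assert np.array_equal(again.counts["c"], t.counts["c"])

    def test_all_zero_track_with_external_total_stays_zero(self):
        t = OligoTrack(counts={"c": np.zeros(10)}, total_mapped=1e6)
        assert normalize_to_hpm(t).counts["c"].sum() == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(DsbError):
            normalize_to_hpm(OligoTrack.from_arrays({"c": np.zeros(3)}))

    def test_normalized_sum_is_one_million(self):
        rng = np.random.default_rng(0)
        t = normalize_to_hpm(OligoTrack.from_arrays(
            {"a": rng.poisson(2.0, 5000), "b": rng.poisson(1.0, 5000)}))
        total = sum(a.sum() for a in t.counts.values())
        assert total == pytest.approx(1e6, abs=1e-3)

    def test_density_invariant_under_library_rescaling(self):
        rng = np.random.default_rng(1)
        raw = rng.poisson(3.0, 4000).astype(float)
        t1 = normalize_to_hpm(OligoTrack.from_arrays({"c": raw}))
        t2 = normalize_to_hpm(OligoTrack.from_arrays({"c": raw * 7}))
        region = AnalysisRegion("r", "c", 2000, 2001, [])
        for side in ("left", "right"):
            d1 = flanking_density(t1, region, 500, side).density
            d2 = flanking_density(t2, region, 500, side).density
            assert d1 == pytest.approx(d2)


class TestRegions:
    def test_table1_gives_27_regions(self, sk1_catalog):
        regions = build_analysis_regions(sk1_catalog)
        assert len(regions) == 27
        merged = [r for r in regions if len(r.members) > 1]
        assert len(merged) == 2      # the Chr IV and Chr XIV neighbor pairs
        assert not any(m.family == "Ty5" for r in regions for m in r.members)

    def test_no_neighbors_no_exclusions_one_region_each(self):
        elems = [_elem("c1", 10_000 + 50_000 * i) for i in range(4)]
        assert len(build_analysis_regions(elems, exclusions=None)) == 4

    def test_zero_distance_elements_merge(self):
        elems = [_elem("c1", 50_000, name="a"), _elem("c1", 50_000, name="b")]
        regions = build_analysis_regions(elems, exclusions=None)
        assert len(regions) == 1 and len(regions[0].members) == 2

    def test_all_family_distance_rule(self):
        elems = [_elem("c1", 5_000), _elem("c1", 100_000)]
        rule = SubtelomereRule(dist=20_000, families=None)
        assert len(build_analysis_regions(elems, exclusions=rule)) == 1


class TestControls:
    def test_distance_filter_drops_near_case_controls(self):
        cases = build_analysis_regions([_elem("c1", 100_000)], exclusions=None)
        controls = [_elem("c1", 101_500, name="near")] + \
            [_elem("c1", 150_000 + 30_000 * i, name=f"far{i}") for i in range(4)]
        kept = select_control_sites(controls, cases, exclusions=None)
        assert len(kept) == 4
        assert all("near" not in m.name for r in kept for m in r.members)

    def test_empty_reference_list(self):
        cases = build_analysis_regions([_elem("c1", 100_000)], exclusions=None)
        assert select_control_sites([], cases, exclusions=None) == []

    def test_neighboring_controls_merge(self):
        cases = build_analysis_regions([_elem("c1", 500_000)], exclusions=None)
        controls = [_elem("c1", 100_000, name="a"),
                    _elem("c1", 100_500, name="b")]
        kept = select_control_sites(controls, cases, exclusions=None)
        assert len(kept) == 1 and len(kept[0].members) == 2


class TestDensities:
    def test_uniform_track_gives_100_per_kb(self):
        t = _hpm_track({"c": np.full(10_000, 0.1)})
        region = AnalysisRegion("r", "c", 5000, 5001, [])
        for width in (500, 1000, 2000):
            for side in ("left", "right"):
                w = flanking_density(t, region, width, side)
                assert w.density == pytest.approx(100.0)
                assert not w.truncated

    def test_half_kb_window_with_50_hits(self):
        vals = np.zeros(10_000)
        vals[5001:5501] = 0.1            # 50 hpM in the right 0.5-kb window
        t = _hpm_track({"c": vals})
        region = AnalysisRegion("r", "c", 5000, 5001, [])
        assert flanking_density(t, region, 500, "right").density == \
            pytest.approx(100.0)

    def test_zero_count_window(self):
        t = _hpm_track({"c": np.zeros(5000)})
        region = AnalysisRegion("r", "c", 2500, 2501, [])
        assert flanking_density(t, region, 500, "left").density == 0.0

    def test_adjacent_half_kb_windows_average_to_1kb(self):
        rng = np.random.default_rng(2)
        t = _hpm_track({"c": rng.random(20_000)})
        region = AnalysisRegion("r", "c", 10_000, 10_001, [])
        d1000 = flanking_density(t, region, 1000, "right").density
        inner = flanking_density(t, region, 500, "right").density
        shifted = AnalysisRegion("r2", "c", 10_000, 10_501, [])
        outer = flanking_density(t, shifted, 500, "right").density
        assert (inner + outer) / 2 == pytest.approx(d1000)

    def test_off_chromosome_window_errors(self):
        t = _hpm_track({"c": np.zeros(1000)})
        region = AnalysisRegion("edge", "c", 2000, 2001, [])
        with pytest.raises(DsbError, match="edge"):
            flanking_density(t, region, 500, "right")

    def test_truncated_window_flagged(self):
        t = _hpm_track({"c": np.full(1000, 0.1)})
        region = AnalysisRegion("r", "c", 300, 301, [])
        w = flanking_density(t, region, 500, "left")
        assert w.truncated and w.density == pytest.approx(100.0)

    def test_internal_density_scale(self):
        t = _hpm_track({"c": np.full(10_000, 0.0067)})
        assert internal_density(t, "c", 2001, 8000) == pytest.approx(6.7)

    def test_internal_density_zero_counts(self):
        t = _hpm_track({"c": np.zeros(1000)})
        assert internal_density(t, "c", 100, 200) == 0.0

    def test_ltr_side_annotation_follows_strand(self):
        t = _hpm_track({"c": np.zeros(10_000)})
        minus = AnalysisRegion("m", "c", 5000, 5001,
                               [_elem("c", 5000, family="Ty1")])
        minus.members[0].strand = "-"
        w = flanking_density(t, minus, 500, "left")
        assert w.ltr_side == "3prime"


def brute_force_rank_sum_p(a, b):
    """Independent enumeration oracle: two-sided rank-sum p by listing
    every assignment of the pooled observations to the two groups."""
    pooled = sorted(a + b)
    ranks = {}
    i = 0
    rank_list = []
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        mid = (i + 1 + j) / 2.0
        rank_list.extend([mid] * (j - i))
        i = j
    # observed rank sum of sample a (midranks)
    pool = list(pooled)
    obs = 0.0
    used = [False] * len(pool)
    for x in a:
        for idx, v in enumerate(pool):
            if not used[idx] and v == x:
                used[idx] = True
                obs += rank_list[idx]
                break
    sums = [sum(c) for c in itertools.combinations(rank_list, len(a))]
    p_le = sum(s <= obs + 1e-9 for s in sums) / len(sums)
    p_ge = sum(s >= obs - 1e-9 for s in sums) / len(sums)
    return min(1.0, 2 * min(p_le, p_ge))


class TestRankSum:
    def test_disjoint_triples_exact_p(self):
        r = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert r.method == "exact"
        assert r.p_two_sided == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        r = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert r.p_two_sided == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 6), rng.integers(2, 7)
        a = rng.integers(0, 8, size=na).tolist()   # integer data forces ties
        b = rng.integers(0, 8, size=nb).tolist()
        r = rank_sum_test(a, b)
        assert r.method == "exact"
        assert r.p_two_sided == pytest.approx(brute_force_rank_sum_p(a, b))

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_branch_matches_scipy_on_tie_free_data(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(size=5).tolist()
        b = rng.normal(size=6).tolist()
        r = rank_sum_test(a, b)
        expected = stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="exact").pvalue
        assert r.p_two_sided == pytest.approx(expected)

    def test_normal_branch_matches_scipy_tie_correction(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 10, size=20).tolist()
        b = rng.integers(0, 10, size=25).tolist()
        r = rank_sum_test(a, b)
        assert r.method == "normal"
        expected = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=False).pvalue
        assert r.p_two_sided == pytest.approx(expected, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(DsbError):
            rank_sum_test([], [1.0])


class TestAnova:
    def test_hand_computed_example(self):
        # groups {1,2,3},{2,3,4},{3,4,5}: SSB=6 (df 2), SSW=6 (df 6) -> F=3
        r = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert r.F == pytest.approx(3.0)
        assert (r.df_between, r.df_within) == (2, 6)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(loc=m, size=8).tolist() for m in (0, 0.5, 1.0)]
        r = one_way_anova(groups)
        expected = stats.f_oneway(*groups)
        assert r.F == pytest.approx(expected.statistic)
        assert r.p == pytest.approx(expected.pvalue)

    def test_two_groups_equal_squared_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=10).tolist(), rng.normal(1, 1, size=12).tolist()
        r = one_way_anova([a, b])
        t = stats.ttest_ind(a, b).statistic
        assert r.F == pytest.approx(t**2)

    def test_identical_constants_give_zero_f(self):
        r = one_way_anova([[2, 2], [2, 2, 2]])
        assert r.F == 0.0 and r.p == 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DsbError):
            one_way_anova([[1.0]])
        with pytest.raises(DsbError):
            one_way_anova([[1.0], []])


def _annotation(rows):
    return pd.DataFrame([
        {"seqid": c, "source": ".", "type": t, "start": s, "end": e,
         "score": ".", "strand": st_, "phase": ".", "attributes": f"ID=g{i}"}
        for i, (c, t, s, e, st_) in enumerate(rows)])


class TestIntergenicContext:
    region = AnalysisRegion("r", "c", 5000, 5001, [])

    @pytest.mark.parametrize("left,right,expected", [
        ("-", "+", "divergent"),
        ("+", "+", "tandem"),
        ("-", "-", "tandem"),
        ("+", "-", "convergent"),
    ])
    def test_flanking_strand_classes(self, left, right, expected):
        ann = _annotation([("c", "gene", 1000, 3000, left),
                           ("c", "gene", 7000, 9000, right)])
        assert classify_intergenic(self.region, ann).cls == expected

    def test_focal_point_inside_gene_is_intragenic(self):
        ann = _annotation([("c", "gene", 4000, 6000, "+")])
        assert classify_intergenic(self.region, ann).cls == "intragenic"

    def test_chromosome_end_is_undetermined(self):
        ann = _annotation([("c", "gene", 7000, 9000, "+")])
        assert classify_intergenic(self.region, ann).cls == "undetermined"

    def test_trna_flag(self):
        ann = _annotation([("c", "gene", 1000, 3000, "-"),
                           ("c", "tRNA", 4000, 4080, "+"),
                           ("c", "gene", 7000, 9000, "+")])
        ctx = classify_intergenic(self.region, ann)
        assert ctx.cls == "divergent" and ctx.contains_trna


class TestDsbConversions:
    def test_efficiency_correction_published_values(self):
        calib = DsbCalibration(slope=1.0, intercept=0.0, efficiency=0.8)
        assert oligo_fraction_to_dsb_percent(2.0, calib)["corrected"] == 2.5
        assert oligo_fraction_to_dsb_percent(0.85, calib)["corrected"] == 1.1

    def test_unit_efficiency_is_identity(self):
        calib = DsbCalibration(slope=1.0, intercept=0.0, efficiency=1.0)
        out = oligo_fraction_to_dsb_percent(2.0, calib)
        assert out["corrected"] == out["uncorrected"] == 2.0

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(DsbError):
            DsbCalibration(slope=1.0, intercept=0.0, efficiency=0.0)


class TestBurden:
    def test_fold_suppression(self):
        out = burden_metrics(ty_genome_frac=1.5, ty_oligo_frac=0.1)
        assert out["fold_suppression"] == pytest.approx(15.0)

    def test_orf_relative_fold(self):
        out = burden_metrics(ty_genome_frac=1.5, ty_oligo_frac=0.1,
                             orf_oligo_frac=11.5, orf_genome_frac=69.4)
        assert out["orf_relative_fold"] == pytest.approx(2.49, abs=0.005)
        assert out["orf_relative_fold"] <= 3.0

    def test_cell_fraction_from_dna_fraction(self):
        out = burden_metrics(per_dna_frac=0.3)
        assert out["cell_frac"] == pytest.approx(1.2)

    def test_expected_dsbs_per_cell_uses_ltr_inclusive_fraction(self):
        out = burden_metrics(ty_oligo_frac=0.1, ty_genome_frac=1.5,
                             ty_ltr_oligo_frac=0.28)
        assert out["expected_dsbs_per_cell"] == pytest.approx(0.448)
        assert 2.0 < out["one_in_n_cells"] < 3.0

    def test_linearity_in_each_argument(self):
        base = burden_metrics(ty_genome_frac=1.5, ty_oligo_frac=0.1,
                              per_dna_frac=0.2)
        doubled = burden_metrics(ty_genome_frac=3.0, ty_oligo_frac=0.1,
                                 per_dna_frac=0.4)
        assert doubled["fold_suppression"] == pytest.approx(
            2 * base["fold_suppression"])
        assert doubled["cell_frac"] == pytest.approx(2 * base["cell_frac"])

    def test_zero_denominator_rejected(self):
        with pytest.raises(DsbError):
            burden_metrics(ty_genome_frac=1.5, ty_oligo_frac=0.0)

    def test_overfull_dna_fraction_rejected(self):
        with pytest.raises(DsbError):
            burden_metrics(per_dna_frac=30.0)
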