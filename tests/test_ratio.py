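"""The distal-ratio statistic and its comparative uses."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apa3utr import (
    CoverageTrack,
    GenomicInterval,
    RegionSpec,
    compare_cohorts,
    compute_distal_ratio,
    fraction_compare,
    single_cell_ratios,
    stratified_compare,
    trend_test,
)


def small_spec(lp=10, ld=20):
    return RegionSpec(
        "toy", "+",
        GenomicInterval("chr1", 0, lp, "+"),
        GenomicInterval("chr1", lp, lp + ld, "+"),
    )


def track_for(spec, prox_depth, dist_depth):
    depth = np.concatenate([
        np.full(len(spec.proximal), prox_depth),
        np.full(len(spec.distal), dist_depth),
    ])
    return CoverageTrack(spec.span, depth)


class TestComputeDistalRatio:
    def test_zero_distal_gives_zero(self):
        spec = small_spec()
        assert compute_distal_ratio(track_for(spec, 5, 0), spec).ratio == 0.0

    def test_equal_per_base_depth_gives_half(self):
        spec = small_spec()
        assert compute_distal_ratio(track_for(spec, 8, 8), spec).ratio == 0.5

    def test_hand_computed_value(self):
        # proximal mean 100 reads/base, distal mean 5 -> 5/105
        spec = small_spec()
        sr = compute_distal_ratio(track_for(spec, 100, 5), spec)
        assert sr.ratio == pytest.approx(5 / 105, abs=1e-12)
        assert sr.ratio == pytest.approx(0.047619, abs=1e-6)

    def test_no_coverage_is_missing(self):
        spec = small_spec()
        assert compute_distal_ratio(track_for(spec, 0, 0), spec).missing

    @given(c=st.integers(min_value=1, max_value=1000))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance_exact(self, c):
        spec = small_spec()
        depth = np.arange(len(spec.span)) % 7
        base = compute_distal_ratio(CoverageTrack(spec.span, depth), spec).ratio
        scaled = compute_distal_ratio(CoverageTrack(spec.span, c * depth), spec).ratio
        assert scaled == base

    def test_ratio_bounded(self, rng):
        spec = small_spec()
        for _ in range(100):
            depth = rng.integers(0, 50, size=len(spec.span))
            r = compute_distal_ratio(CoverageTrack(spec.span, depth), spec).ratio
            assert math.isnan(r) or 0.0 <= r <= 1.0


class TestCompareCohorts:
    def test_identical_groups(self):
        c = compare_cohorts([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert c.fold_change == 1.0
        assert c.p_value == 1.0

    def test_exact_small_sample_enumeration(self):
        # all case > all control at n=3/3: the most extreme of the C(6,3)=20
        # equally likely rank orderings, exact two-sided p = 2/20
        c = compare_cohorts([0.05, 0.06, 0.08], [0.02, 0.03, 0.04])
        assert c.fold_change == pytest.approx(2.0)
        assert c.p_value == pytest.approx(0.1)

    def test_antisymmetry(self, rng):
        a = rng.beta(2, 10, size=12)
        b = rng.beta(2, 8, size=9)
        ab = compare_cohorts(a, b)
        ba = compare_cohorts(b, a)
        assert ab.fold_change == pytest.approx(1 / ba.fold_change)
        assert ab.p_value == ba.p_value

    def test_missing_dropped_and_empty_group_errors(self):
        c = compare_cohorts([0.1, float("nan"), 0.3], [0.2, 0.2])
        assert c.n_case == 2
        with pytest.raises(ValueError, match="empty"):
            compare_cohorts([float("nan")], [0.2])

    def test_zero_control_median_reports_difference(self):
        c = compare_cohorts([0.2, 0.3, 0.4], [0.0, 0.0, 0.0])
        assert math.isnan(c.fold_change)
        assert c.median_diff == pytest.approx(0.3)


class TestStratified:
    def test_single_stratum_reduces_to_cohort_comparison(self, rng):
        case = rng.beta(4, 40, size=20)
        control = rng.beta(4, 40, size=15)
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(35)],
            "ratio": np.concatenate([case, control]),
            "group": ["case"] * 20 + ["control"] * 15,
            "genotype": "MM",
        })
        per, within = stratified_compare(df, "genotype")
        assert set(per) == {"MM"}
        ref = compare_cohorts(case, control)
        assert per["MM"].p_value == ref.p_value
        assert per["MM"].fold_change == ref.fold_change
        assert within.empty

    def test_planted_shift_detected_only_in_shifted_stratum(self, rng):
        n = 60
        base = rng.beta(4, 76, size=4 * n)
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(4 * n)],
            "ratio": base,
            "group": (["case"] * n + ["control"] * n) * 2,
            "genotype": ["MM"] * 2 * n + ["MS"] * 2 * n,
        })
        # plant a 2.5x shift in MS cases only
        shifted = df["genotype"].eq("MS") & df["group"].eq("case")
        df.loc[shifted, "ratio"] *= 2.5
        per, within = stratified_compare(df, "genotype")
        assert per["MS"].p_value < 0.01
        assert per["MM"].p_value > 0.05
        ms_row = within[within["stratum"] == "MS"].iloc[0]
        assert ms_row["p_value"] < 0.01

    def test_cohort_sized_strata_run_and_flag_low_power(self, rng):
        """Genotype strata at the replication-cohort sizes (MM 210/284,
        MS 14/20, MZ 8/16, ZZ 1/7) run without error; ZZ is low-power."""
        sizes = {"MM": (284, 210), "MS": (20, 14), "MZ": (16, 8), "ZZ": (7, 1)}
        rows = []
        for gt, (n_case, n_control) in sizes.items():
            for g, n in (("case", n_case), ("control", n_control)):
                for i in range(n):
                    rows.append({
                        "sample_id": f"{gt}_{g}_{i}",
                        "ratio": float(rng.beta(4, 76)),
                        "group": g,
                        "genotype": gt,
                    })
        per, within = stratified_compare(
            pd.DataFrame(rows), "genotype", known_levels=["MM", "MS", "MZ", "ZZ"]
        )
        assert set(per) == {"MM", "MS", "MZ", "ZZ"}
        assert per["ZZ"].low_power
        assert not per["MM"].low_power
        assert set(within["stratum"]) == {"MS", "MZ", "ZZ"}

    def test_unknown_level_pooled_under_other(self, rng):
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(8)],
            "ratio": rng.beta(4, 40, size=8),
            "group": ["case", "control"] * 4,
            "genotype": ["MM"] * 6 + ["XX", "XX"],
        })
        with pytest.warns(UserWarning, match="other"):
            per, _ = stratified_compare(df, "genotype",
                                        known_levels=["MM", "MS", "MZ", "ZZ"])
        assert "other" in per


class TestTrend:
    def test_monotone_increase_gives_perfect_correlation(self):
        rho, p, flag = trend_test([0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4])
        assert rho == pytest.approx(1.0)
        assert not flag

    def test_shuffled_stages_rarely_significant(self, rng):
        """Permuting stages against ratios keeps the trend test null."""
        ratios = rng.beta(4, 40, size=40)
        stages = np.repeat([0, 1, 2, 3], 10)
        reject = 0
        n_perm = 300
        for _ in range(n_perm):
            _, p, _ = trend_test(ratios, rng.permutation(stages))
            reject += p < 0.05
        assert reject / n_perm < 0.10

    def test_constant_ratios_flagged_degenerate(self):
        rho, p, flag = trend_test([0.2, 0.2, 0.2, 0.2], [0, 1, 2, 3])
        assert (rho, p, flag) == (0.0, 1.0, True)

    def test_too_few_stages_rejected(self):
        with pytest.raises(ValueError, match="stages"):
            trend_test([0.1, 0.2, 0.3], [1, 1, 2])


class TestFractions:
    def test_nuclear_cytoplasmic_fold(self):
        df = pd.DataFrame({
            "ratio": [0.4, 0.5, 0.1, 0.1],
            "fraction": ["nuclear", "nuclear", "cytoplasmic", "cytoplasmic"],
        })
        out = fraction_compare(df)
        med = dict(zip(out["fraction"], out["median_ratio"]))
        assert med["nuclear"] == pytest.approx(0.45)
        assert out.attrs["nuclear_cytoplasmic_fold"] == pytest.approx(4.5)

    def test_single_fraction_fold_undefined(self):
        df = pd.DataFrame({"ratio": [0.2, 0.3], "fraction": ["nuclear"] * 2})
        out = fraction_compare(df)
        assert len(out) == 1
        assert math.isnan(out.attrs["nuclear_cytoplasmic_fold"])

    def test_equal_fractions_fold_one(self):
        df = pd.DataFrame({
            "ratio": [0.2, 0.2],
            "fraction": ["nuclear", "cytoplasmic"],
        })
        assert fraction_compare(df).attrs["nuclear_cytoplasmic_fold"] == 1.0

    def test_missing_labels_excluded(self):
        df = pd.DataFrame({
            "ratio": [0.2, 0.3, 0.4],
            "fraction": ["nuclear", None, "cytoplasmic"],
        })
        assert fraction_compare(df)["n"].sum() == 2


class TestSingleCell:
    def spec(self):
        # proximal 79 nt / distal 1622 nt toy geometry
        return RegionSpec(
            "toy", "+",
            GenomicInterval("chr1", 0, 79, "+"),
            GenomicInterval("chr1", 79, 79 + 1622, "+"),
        )

    def test_zero_distal_cell(self):
        counts = pd.DataFrame({"cell": ["c1"], "proximal": [5], "distal": [0]})
        per_cell, _ = single_cell_ratios(counts, {"c1": "hep"}, self.spec(),
                                         min_total_reads=1)
        assert per_cell["ratio"].iloc[0] == 0.0

    def test_hand_computed_cell_ratio(self):
        # (2/1622) / ((2/1622) + (5/79)) = 0.01911
        counts = pd.DataFrame({"cell": ["c1"], "proximal": [5], "distal": [2]})
        per_cell, _ = single_cell_ratios(counts, {"c1": "hep"}, self.spec(),
                                         min_total_reads=1)
        assert per_cell["ratio"].iloc[0] == pytest.approx(0.01911, abs=5e-5)

    def test_min_reads_boundaries(self):
        counts = pd.DataFrame({
            "cell": ["c1", "c2"],
            "proximal": [1, 4],
            "distal": [0, 2],
        })
        clusters = {"c1": "a", "c2": "a"}
        per_cell, _ = single_cell_ratios(counts, clusters, self.spec(),
                                         min_total_reads=1)
        assert len(per_cell) == 2
        with pytest.warns(UserWarning, match="no cells"):
            per_cell, per_cluster = single_cell_ratios(
                counts, clusters, self.spec(), min_total_reads=100
            )
        assert per_cell.empty and per_cluster == {}

    def test_pooled_mode_sums_counts_before_ratio(self):
        counts = pd.DataFrame({
            "cell": ["c1", "c2"],
            "proximal": [10, 0],
            "distal": [0, 10],
        })
        clusters = {"c1": "a", "c2": "a"}
        _, per_cluster = single_cell_ratios(counts, clusters, self.spec(),
                                            min_total_reads=1, pooled=True)
        lp, ld = 79, 1622
        expected = (10 / ld) / ((10 / ld) + (10 / lp))
        assert per_cluster["a"]["median"] == pytest.approx(expected)
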