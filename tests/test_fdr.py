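"""Depth normalization, mock comparisons, FDR/sensitivity/downsampling curves."""

import numpy as np
import pandas as pd
import pytest

from recimprint.calls import CallCriteria
from recimprint.errors import ValidationError
from recimprint.fdr import (
    ComparisonScheme,
    DownsampleConfig,
    default_scheme,
    downsample_curve,
    fdr_curve,
    fp_proportion_curve,
    normalize_depth,
    pair_table,
    run_comparison,
    sensitivity_curve,
    significant_units,
    thin_counts,
)


@pytest.fixture
def four_samples():
    return pd.DataFrame(
        {
            "sample_id": ["BxC_M1", "BxC_F1", "CxB_M1", "CxB_F1"],
            "cross": ["BxC", "BxC", "CxB", "CxB"],
            "sex": ["M", "F", "M", "F"],
            "tissue": ["brain"] * 4,
            "replicate": [1, 1, 1, 1],
        }
    )


def _counts(spec):
    """spec: {sample: {snp: (b, c)}}"""
    rows = [
        {"snp_id": snp, "sample_id": sample, "count_B": b, "count_C": c}
        for sample, snps in spec.items()
        for snp, (b, c) in snps.items()
    ]
    return pd.DataFrame(rows)


class TestDefaultScheme:
    def test_four_animal_design(self, four_samples):
        scheme = default_scheme(four_samples)
        recip = scheme.labelled("reciprocal")
        mock = scheme.labelled("mock")
        assert ("BxC_M1", "CxB_M1") in recip and ("BxC_F1", "CxB_F1") in recip
        assert ("BxC_M1", "BxC_F1") in mock and ("CxB_M1", "CxB_F1") in mock

    def test_validation_rejects_mislabeled_pairs(self, four_samples):
        bad = ComparisonScheme("bad", ((("BxC_M1"), ("BxC_F1"), "reciprocal"),))
        with pytest.raises(ValidationError):
            bad.validate(four_samples)
        bad2 = ComparisonScheme("bad2", ((("BxC_M1"), ("CxB_F1"), "mock"),))
        with pytest.raises(ValidationError):
            bad2.validate(four_samples)


class TestNormalizeDepth:
    def _snps(self, chroms):
        return pd.DataFrame(
            {
                "chrom": chroms,
                "pos": range(len(chroms)),
                "snp_id": [f"s{i}" for i in range(len(chroms))],
                "allele_B": "A",
                "allele_C": "G",
            }
        )

    def test_totals_equal_minimum(self, rng):
        counts = _counts(
            {
                "a": {"s0": (60, 40), "s1": (30, 20)},  # 150
                "b": {"s0": (50, 30), "s1": (10, 10)},  # 100
                "c": {"s0": (70, 30), "s1": (15, 5)},  # 120
            }
        )
        snps = self._snps(["chr1", "chr2"])
        out = normalize_depth(counts, snps, rng=rng)
        totals = out.groupby("sample_id")[["count_B", "count_C"]].sum().sum(axis=1)
        assert (totals == 100).all()

    def test_excluded_chromosomes_dropped_before_normalization(self, rng):
        counts = _counts(
            {
                "a": {"s0": (60, 40), "s1": (1000, 0)},
                "b": {"s0": (50, 50), "s1": (5, 5)},
            }
        )
        snps = self._snps(["chr1", "chrX"])
        out = normalize_depth(counts, snps, rng=rng)
        assert "s1" not in set(out["snp_id"])
        totals = out.groupby("sample_id")[["count_B", "count_C"]].sum().sum(axis=1)
        assert (totals == 100).all()

    def test_hypergeometric_expectation(self):
        """Thinned per-cell means match the without-replacement expectation
        n_i * target / total over repeated seeds."""
        counts = _counts({"big": {"s0": (300, 100), "s1": (50, 150)}, "small": {"s0": (100, 100)}})
        snps = self._snps(["chr1", "chr2"])
        target, total = 200, 600
        sums = np.zeros(4)
        n_seeds = 300
        for seed in range(n_seeds):
            out = normalize_depth(counts, snps, rng=seed)
            big = out[out["sample_id"] == "big"].sort_values("snp_id")
            sums += big[["count_B", "count_C"]].to_numpy().ravel()
        means = sums / n_seeds
        expected = np.array([300, 100, 50, 150]) * target / total
        # SE of the mean of a hypergeometric cell over 300 draws is < 0.5
        assert np.allclose(means, expected, atol=1.5)

    def test_empty_after_exclusion_is_error(self, rng):
        counts = _counts({"a": {"s0": (5, 5)}})
        snps = self._snps(["chrX"])
        with pytest.raises(ValidationError):
            normalize_depth(counts, snps, rng=rng)


class TestThinning:
    def test_fraction_one_is_identity(self, count_table, rng):
        out = thin_counts(count_table, 1.0, rng)
        pd.testing.assert_frame_equal(out, count_table)

    def test_fraction_totals(self, count_table, rng):
        out = thin_counts(count_table, 0.5, rng)
        for sid, group in out.groupby("sample_id"):
            orig = count_table[count_table["sample_id"] == sid]
            assert group[["count_B", "count_C"]].to_numpy().sum() == round(
                orig[["count_B", "count_C"]].to_numpy().sum() * 0.5
            )


class TestRunComparison:
    def test_identical_sample_against_itself(self):
        counts = _counts(
            {"a": {"s0": (100, 0), "s1": (30, 70)}, "a2": {"s0": (100, 0), "s1": (30, 70)}}
        )
        # identical counts can never be reciprocally biased
        n, units = run_comparison(counts, ("a", "a2"), CallCriteria(alpha=0.05), unit="snp")
        assert n == 0 and units == []

    def test_engineered_reciprocal_hit(self):
        counts = _counts({"bxc": {"s0": (90, 10)}, "cxb": {"s0": (10, 90)}})
        n, units = run_comparison(counts, ("bxc", "cxb"), CallCriteria(alpha=1e-4), unit="snp")
        assert n == 1 and units == ["s0"]


class TestFdrCurve:
    def _scheme(self):
        return ComparisonScheme(
            "s",
            (
                ("bxc1", "cxb1", "reciprocal"),
                ("bxc1", "bxc2", "mock"),
            ),
        )

    def test_arithmetic_and_zero_mock(self):
        counts = _counts(
            {
                "bxc1": {"s0": (90, 10), "s1": (50, 50)},
                "cxb1": {"s0": (10, 90), "s1": (50, 50)},
                "bxc2": {"s0": (90, 10), "s1": (50, 50)},
            }
        )
        curve = fdr_curve(counts, self._scheme(), [1e-4], unit="snp")
        row = curve.iloc[0]
        assert row["n_reciprocal"] == 1 and row["n_mock"] == 0 and row["fdr"] == 0.0

    def test_absent_when_no_reciprocal_hits(self):
        counts = _counts(
            {
                "bxc1": {"s0": (50, 50)},
                "cxb1": {"s0": (50, 50)},
                "bxc2": {"s0": (50, 50)},
            }
        )
        curve = fdr_curve(counts, self._scheme(), [1e-4], unit="snp")
        assert np.isnan(curve.iloc[0]["fdr"])

    def test_sum_vs_union_pooling(self):
        scheme = ComparisonScheme(
            "s",
            (
                ("bxc1", "cxb1", "reciprocal"),
                ("bxc2", "cxb2", "reciprocal"),
                ("bxc1", "bxc2", "mock"),
            ),
        )
        counts = _counts(
            {
                "bxc1": {"s0": (90, 10)},
                "cxb1": {"s0": (10, 90)},
                "bxc2": {"s0": (90, 10)},
                "cxb2": {"s0": (10, 90)},
            }
        )
        by_sum = fdr_curve(counts, scheme, [1e-4], unit="snp", pooling="sum")
        by_union = fdr_curve(counts, scheme, [1e-4], unit="snp", pooling="union")
        assert by_sum.iloc[0]["n_reciprocal"] == 2  # same unit counted per pair
        assert by_union.iloc[0]["n_reciprocal"] == 1


class TestSensitivityCurve:
    def test_detected_over_powered(self):
        counts = _counts(
            {
                "bxc": {"k1": (90, 10), "k2": (60, 40), "k3": (3, 2), "other": (95, 5)},
                "cxb": {"k1": (10, 90), "k2": (40, 60), "k3": (2, 3), "other": (5, 95)},
            }
        )
        table = pair_table(counts, ("bxc", "cxb"), unit="snp")
        curve = sensitivity_curve(table, ["k1", "k2", "k3"], [1e-4, 0.05])
        strict, lax = curve.iloc[0], curve.iloc[1]
        # k3 is underpowered; k1 passes at both thresholds, k2 only at 0.05
        assert strict["n_powered"] == 2 and strict["n_detected"] == 1
        assert lax["n_detected"] == 2
        assert lax["sensitivity"] == pytest.approx(1.0)

    def test_disjoint_catalog_absent(self):
        counts = _counts({"bxc": {"s0": (90, 10)}, "cxb": {"s0": (10, 90)}})
        table = pair_table(counts, ("bxc", "cxb"), unit="snp")
        curve = sensitivity_curve(table, ["nope"], [0.05])
        assert curve.iloc[0]["n_powered"] == 0 and np.isnan(curve.iloc[0]["sensitivity"])


class TestDownsampleCurve:
    def test_full_fraction_reproduces_exact_count(self):
        counts = _counts(
            {
                "bxc": {"s0": (90, 10), "s1": (80, 20)},
                "cxb": {"s0": (10, 90), "s1": (70, 30)},
            }
        )
        cfg = DownsampleConfig(fractions=(1.0,), iterations=5, seed=1)
        curve = downsample_curve(counts, [("bxc", "cxb")], cfg, CallCriteria(alpha=1e-4), unit="snp")
        full, _ = run_comparison(counts, ("bxc", "cxb"), CallCriteria(alpha=1e-4), unit="snp")
        assert curve.iloc[0]["mean_significant"] == full
        assert curve.iloc[0]["se"] == 0.0

    def test_unsorted_fractions_rejected(self):
        with pytest.raises(ValidationError):
            DownsampleConfig(fractions=(0.5, 0.25))

    def test_mean_count_nondecreasing_in_fraction(self, small_dataset):
        """More reads never lose detections on average (within 3 SE)."""
        counts = small_dataset["counts"]
        assignment = small_dataset["snps"]
        cfg = DownsampleConfig(fractions=(0.2, 0.6, 1.0), iterations=25, seed=7)
        curve = downsample_curve(
            counts,
            [("BxC_M1", "CxB_M1")],
            cfg,
            CallCriteria(alpha=1e-4),
            unit="gene",
            assignment=assignment,
        )
        means, ses = curve["mean_significant"].to_numpy(), curve["se"].to_numpy()
        for i in range(len(means) - 1):
            slack = 3 * np.hypot(ses[i], ses[i + 1])
            assert means[i] <= means[i + 1] + slack


def test_fp_proportion_excludes_known_units():
    scheme = ComparisonScheme("s", (("bxc1", "cxb1", "reciprocal"), ("bxc1", "bxc2", "mock")))
    counts = _counts(
        {
            "bxc1": {"known": (90, 10), "novel": (95, 5)},
            "cxb1": {"known": (10, 90), "novel": (5, 95)},
            "bxc2": {"known": (90, 10), "novel": (95, 5)},
        }
    )
    cfg = DownsampleConfig(fractions=(1.0,), iterations=1, seed=0)
    curve = fp_proportion_curve(counts, scheme, cfg, 1e-4, known_ids=["known"], unit="snp")
    # only "novel" counts: 1 reciprocal hit, 0 mock hits
    assert curve.iloc[0]["mean_n_reciprocal"] == 1
    assert curve.iloc[0]["mean_fdr"] == 0.0
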