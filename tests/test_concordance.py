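"""Same-exon SNP-pair enumeration, discordance curves, and the sampling null."""

import itertools

import numpy as np
import pandas as pd
import pytest

from recimprint.concordance import (
    annotate_pairs,
    build_pairs,
    discordance_curve,
    enumerate_pairs,
    expected_counts_from_partner,
    select_nonredundant_exons,
    simulate_null_pairs,
    solve_pearson_counts,
)
from recimprint.errors import ValidationError
from recimprint.io import GeneModel


def _snp_frame(positions, counts, exon="e1"):
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(len(positions))],
            "pos": positions,
            "count_B": [b for b, _ in counts],
            "count_C": [c for _, c in counts],
            "exon_id": exon,
        }
    )


class TestSelectNonredundantExons:
    def test_longest_wins_on_overlap(self):
        models = [
            GeneModel("g1", "chr1", "+", ((0, 100),), coding=True),
            GeneModel("g2", "chr1", "+", ((50, 120),), coding=True),
        ]
        out = select_nonredundant_exons(models)
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (0, 100)

    def test_equal_length_tie_lower_start(self):
        models = [
            GeneModel("g1", "chr1", "+", ((50, 150),), coding=True),
            GeneModel("g2", "chr1", "+", ((0, 100),), coding=True),
        ]
        out = select_nonredundant_exons(models)
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (0, 100)

    def test_disjoint_both_kept_and_noncoding_excluded(self):
        models = [
            GeneModel("g1", "chr1", "+", ((0, 100),), coding=True),
            GeneModel("g2", "chr1", "+", ((200, 300),), coding=True),
            GeneModel("nc", "chr1", "+", ((400, 500),), coding=False),
        ]
        out = select_nonredundant_exons(models)
        assert set(out["gene_id"]) == {"g1", "g2"}


class TestEnumeratePairs:
    def test_three_snps_three_pairs(self):
        snps = _snp_frame([0, 100, 200], [(30, 70), (40, 60), (20, 80)])
        pairs = enumerate_pairs(snps)
        assert len(pairs) == 3

    def test_boundary_separation_excluded(self):
        snps = _snp_frame([0, 40], [(30, 70), (40, 60)])
        assert len(enumerate_pairs(snps)) == 0
        snps = _snp_frame([0, 41], [(30, 70), (40, 60)])
        assert len(enumerate_pairs(snps)) == 1

    def test_matches_brute_force_filter(self, rng):
        positions = sorted(int(p) for p in rng.choice(500, size=6, replace=False))
        counts = [(int(rng.integers(1, 50)), int(rng.integers(1, 50))) for _ in positions]
        pairs = enumerate_pairs(_snp_frame(positions, counts))
        expected = sum(
            1 for a, b in itertools.combinations(positions, 2) if abs(b - a) > 40
        )
        assert len(pairs) == expected

    def test_tied_snp_yields_nan_concordance(self):
        snps = _snp_frame([0, 100], [(50, 50), (20, 80)])
        pairs = enumerate_pairs(snps)
        assert len(pairs) == 1 and np.isnan(pairs.iloc[0]["concordant"])


class TestDiscordanceCurve:
    def _pairs(self, spec):
        rows = []
        for i, (c1, c2) in enumerate(spec):
            rows.append(
                {
                    "exon_id": "e",
                    "snp_1": f"a{i}",
                    "snp_2": f"b{i}",
                    "pos_1": 0,
                    "pos_2": 100,
                    "separation": 100,
                    "count_B_1": c1[0],
                    "count_C_1": c1[1],
                    "count_B_2": c2[0],
                    "count_C_2": c2[1],
                }
            )
        return annotate_pairs(pd.DataFrame(rows))

    def test_fraction(self):
        pairs = self._pairs(
            [((90, 10), (80, 20))] * 4 + [((90, 10), (10, 90))]  # 1 of 5 discordant
        )
        curve = discordance_curve(pairs, [0.05])
        assert curve.iloc[0]["n_pairs"] == 5
        assert curve.iloc[0]["fraction"] == pytest.approx(0.2)

    def test_all_concordant_and_empty_threshold(self):
        pairs = self._pairs([((90, 10), (80, 20))] * 3)
        curve = discordance_curve(pairs, [0.05, 1e-30])
        assert curve.iloc[0]["fraction"] == 0.0
        assert np.isnan(curve.iloc[1]["fraction"])

    def test_matches_brute_force_recount(self, rng):
        spec = [
            ((int(rng.integers(1, 100)), int(rng.integers(1, 100))),
             (int(rng.integers(1, 100)), int(rng.integers(1, 100))))
            for _ in range(50)
        ]
        pairs = self._pairs(spec)
        t = 0.1
        curve = discordance_curve(pairs, [t])
        n = n_disc = 0
        from recimprint.stats import chi_square_ase

        for (b1, c1), (b2, c2) in spec:
            t1, t2 = chi_square_ase(b1, c1), chi_square_ase(b2, c2)
            if t1.direction == "none" or t2.direction == "none":
                continue
            if max(t1.p, t2.p) < t:
                n += 1
                n_disc += t1.direction != t2.direction
        assert curve.iloc[0]["n_pairs"] == n
        assert curve.iloc[0]["n_discordant"] == n_disc


class TestExpectedCounts:
    @pytest.mark.parametrize(
        "partner, total, expected",
        [((30, 20), 100, (60.0, 40.0)), ((25, 25), 80, (40.0, 40.0)), ((10, 30), 60, (15.0, 45.0))],
    )
    def test_ratio_scaling(self, partner, total, expected):
        assert expected_counts_from_partner(partner, total) == pytest.approx(expected)

    def test_zero_partner_rejected(self):
        with pytest.raises(ValidationError):
            expected_counts_from_partner((0, 0), 10)


class TestSolvePearson:
    def test_worked_example_rounds_to_65_55(self):
        (hi, hi_c), (lo, lo_c) = solve_pearson_counts((60, 40), 1.0)
        assert round(hi) == 65 and round(hi_c) == 35
        assert round(lo) == 55 and round(lo_c) == 45

    def test_zero_deviate_returns_expected(self):
        (hi, _), (lo, _) = solve_pearson_counts((60, 40), 0.0)
        assert hi == lo == 60

    def test_balanced_expected_chi2_four(self):
        (hi, hi_c), (lo, lo_c) = solve_pearson_counts((50, 50), 4.0)
        assert (hi, hi_c) == pytest.approx((60.0, 40.0))
        assert (lo, lo_c) == pytest.approx((40.0, 60.0))

    def test_roots_satisfy_pearson_formula(self, rng):
        for _ in range(20):
            e_b = float(rng.uniform(5, 200))
            e_c = float(rng.uniform(5, 200))
            chi2 = float(rng.chisquare(1))
            for x, y in solve_pearson_counts((e_b, e_c), chi2):
                assert (x - e_b) ** 2 * (1 / e_b + 1 / e_c) == pytest.approx(chi2, abs=1e-9)
                assert x + y == pytest.approx(e_b + e_c)


def _shared_ratio_pairs(rng, n_pairs, ratio_range=(0.5, 0.9), depth_range=(30, 400)):
    """Pairs of binomial SNPs sharing a true B-allele ratio."""
    rows = []
    for i in range(n_pairs):
        ratio = rng.uniform(*ratio_range)
        rows.append(
            {
                "exon_id": f"e{i}",
                "snp_1": f"a{i}",
                "snp_2": f"b{i}",
                "pos_1": 0,
                "pos_2": 100,
                "separation": 100,
            }
        )
        for k in (1, 2):
            n = int(rng.integers(*depth_range))
            b = int(rng.binomial(n, ratio))
            rows[-1][f"count_B_{k}"] = b
            rows[-1][f"count_C_{k}"] = n - b
    return annotate_pairs(pd.DataFrame(rows))


class TestSimulateNull:
    def test_self_consistency_on_binomial_pairs(self, rng):
        """When pairs really are random samples of a shared ratio, the
        simulated discordance matches the observed one."""
        pairs = _shared_ratio_pairs(rng, 3000)
        thresholds = [0.5, 0.05]
        observed = discordance_curve(pairs, thresholds)
        simulated = simulate_null_pairs(pairs, thresholds, rng=rng, iterations=20)
        for k in range(len(thresholds)):
            obs = observed.iloc[k]["fraction"]
            sim, sd = simulated.iloc[k]["mean_fraction"], simulated.iloc[k]["sd_fraction"]
            band = 3 * sd + 3 * np.sqrt(obs * (1 - obs) / max(observed.iloc[k]["n_pairs"], 1))
            assert abs(obs - sim) <= band + 0.01

    def test_replacing_less_significant_lowers_discordance(self, rng):
        pairs = _shared_ratio_pairs(rng, 2000, ratio_range=(0.5, 0.6))
        t = [0.5]
        more = simulate_null_pairs(pairs, t, rng=1, iterations=20, replace="more_significant")
        less = simulate_null_pairs(pairs, t, rng=1, iterations=20, replace="less_significant")
        assert less.iloc[0]["mean_fraction"] <= more.iloc[0]["mean_fraction"] + 0.005

    def test_iteration_counts_agree(self, rng):
        pairs = _shared_ratio_pairs(rng, 1500)
        one = simulate_null_pairs(pairs, [0.5], rng=3, iterations=1)
        many = simulate_null_pairs(pairs, [0.5], rng=4, iterations=30)
        sd = many.iloc[0]["sd_fraction"]
        assert abs(one.iloc[0]["mean_fraction"] - many.iloc[0]["mean_fraction"]) <= 4 * sd + 0.01


def test_build_pairs_respects_exon_selection(small_dataset):
    exons = select_nonredundant_exons(small_dataset["models"])
    pairs = build_pairs(
        small_dataset["snps"], small_dataset["counts"], "BxC_M1", exons=exons
    )
    assert (pairs["separation"] > 40).all()
    assert set(pairs["exon_id"]) <= set(exons["exon_id"])
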