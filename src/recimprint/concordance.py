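"""Within-exon SNP-pair ASE concordance and its random-sampling null.

True allele-specific expression is a property of the transcript, so two
SNPs inside the same coding exon must agree on the *direction* of allelic
bias; disagreement ("discordance") at stringent significance diagnoses
systematic, sequence-dependent error that pure counting statistics do not
model.  The observed discordance curve is compared against a simulated null
in which one SNP of each pair is regenerated under pure random sampling:

1. identify the more significant SNP of the pair;
2. replace its counts with the partner's allelic ratio scaled to its own
   total depth (e.g. partner 30/20 at total 100 -> expected 60/40);
3. perturb by a chi-square(1) deviate: solve Pearson's formula
   ``(x - e_B)^2 * (1/e_B + 1/e_C) = chi2`` for the two roots, pick one at
   random, round to integer counts, clamp to [0, n];
4. re-test the regenerated SNP and rebuild the discordance curve.

If counting noise alone explained the data, observed and simulated curves
would coincide; excess observed discordance measures everything else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .io import GeneModel
from .stats import chi2_components, direction_codes

DEFAULT_MIN_SEPARATION = 40  # bp; the longest sequencing read length

PAIR_COLUMNS = [
    "exon_id",
    "snp_1",
    "snp_2",
    "pos_1",
    "pos_2",
    "separation",
    "count_B_1",
    "count_C_1",
    "count_B_2",
    "count_C_2",
    "chi2_1",
    "p_1",
    "dir_1",
    "chi2_2",
    "p_2",
    "dir_2",
    "p_pair",
    "concordant",
]


def select_nonredundant_exons(models: Sequence[GeneModel]) -> pd.DataFrame:
    """Resolve overlapping coding exons to the longest one.

    Only exons of coding gene models are considered (UTR-bearing / non-coding
    models are excluded by their ``coding`` flag).  Where exons overlap in
    genomic space the longest wins; length ties go to the lower start
    coordinate.  Returns a table (gene_id, exon_id, chrom, start, end).
    """
    exons = [
        {"gene_id": m.gene_id, "exon_id": f"{m.gene_id}:exon{i}", "chrom": m.chrom, "start": s, "end": e}
        for m in models
        if m.coding
        for i, (s, e) in enumerate(m.exons)
    ]
    if not exons:
        return pd.DataFrame(columns=["gene_id", "exon_id", "chrom", "start", "end"])
    df = pd.DataFrame(exons)
    df["length"] = df["end"] - df["start"]
    kept_rows = []
    for _, group in df.groupby("chrom", sort=False):
        group = group.sort_values(["length", "start"], ascending=[False, True], kind="stable")
        kept: list[tuple[int, int]] = []
        for row in group.itertuples(index=False):
            if all(row.start >= e or row.end <= s for s, e in kept):
                kept.append((row.start, row.end))
                kept_rows.append(row)
    out = pd.DataFrame(kept_rows).drop(columns=["length"]).sort_values(["chrom", "start"], kind="stable")
    return out.reset_index(drop=True)


def enumerate_pairs(
    snps: pd.DataFrame,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> pd.DataFrame:
    """All unordered SNP pairs within one exon, separated by more than
    ``min_separation`` bp.

    ``snps`` carries one row per SNP of a single exon for a single sample:
    columns ``snp_id``, ``pos``, ``count_B``, ``count_C`` and optionally
    ``exon_id``.  ``p_pair`` is the less significant of the two p-values;
    ``concordant`` is NaN when either SNP has no direction (exact tie) —
    such pairs are excluded from the discordance fraction but remain in the
    table so the drop tally is visible.
    """
    exon_id = str(snps["exon_id"].iloc[0]) if "exon_id" in snps.columns and len(snps) else ""
    rec = snps.sort_values("pos", kind="stable").reset_index(drop=True)
    rows = []
    for i in range(len(rec)):
        for j in range(i + 1, len(rec)):
            a, b = rec.iloc[i], rec.iloc[j]
            sep = abs(int(b["pos"]) - int(a["pos"]))
            if sep <= min_separation:
                continue
            rows.append(
                {
                    "exon_id": exon_id,
                    "snp_1": a["snp_id"],
                    "snp_2": b["snp_id"],
                    "pos_1": int(a["pos"]),
                    "pos_2": int(b["pos"]),
                    "separation": sep,
                    "count_B_1": int(a["count_B"]),
                    "count_C_1": int(a["count_C"]),
                    "count_B_2": int(b["count_B"]),
                    "count_C_2": int(b["count_C"]),
                }
            )
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS[:10])
    return annotate_pairs(pairs)


def annotate_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Fill per-SNP tests and the pair-level p/concordance columns."""
    pairs = pairs.copy()
    chi2_1, p_1 = chi2_components(pairs["count_B_1"], pairs["count_C_1"])
    chi2_2, p_2 = chi2_components(pairs["count_B_2"], pairs["count_C_2"])
    d1 = direction_codes(pairs["count_B_1"], pairs["count_C_1"])
    d2 = direction_codes(pairs["count_B_2"], pairs["count_C_2"])
    pairs["chi2_1"], pairs["p_1"], pairs["dir_1"] = chi2_1, p_1, d1
    pairs["chi2_2"], pairs["p_2"], pairs["dir_2"] = chi2_2, p_2, d2
    pairs["p_pair"] = np.fmax(p_1, p_2)
    both_called = (d1 != 0) & (d2 != 0)
    pairs["concordant"] = np.where(both_called, (d1 == d2).astype(float), np.nan)
    return pairs


def build_pairs(
    snps_assigned: pd.DataFrame,
    counts: pd.DataFrame,
    sample_id: str,
    exons: pd.DataFrame | None = None,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> pd.DataFrame:
    """Enumerate same-exon pairs genome-wide for one sample.

    ``snps_assigned`` is the output of :func:`recimprint.io.assign_snps`;
    when ``exons`` (from :func:`select_nonredundant_exons`) is given, only
    SNPs in those exons participate.
    """
    sub = counts[counts["sample_id"] == sample_id]
    merged = snps_assigned[snps_assigned["exon_id"] != ""].merge(sub, on="snp_id", how="inner")
    if exons is not None:
        merged = merged[merged["exon_id"].isin(set(exons["exon_id"]))]
    frames = [
        enumerate_pairs(group, min_separation=min_separation)
        for _, group in merged.groupby("exon_id", sort=False)
        if len(group) >= 2
    ]
    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def sample_shared_ratio_pairs(
    n_pairs: int,
    rng: np.random.Generator | int | None = None,
    ratio_range: tuple[float, float] = (0.5, 0.9),
    depth_median: float = 150.0,
    depth_log_sd: float = 0.8,
    depth_bounds: tuple[int, int] = (20, 1000),
) -> pd.DataFrame:
    """Synthetic same-exon SNP pairs under pure random sampling.

    Each pair shares a true B-allele ratio (uniform over ``ratio_range``);
    both members draw binomial counts at independent log-normal depths
    clipped to ``depth_bounds``. This is the regime in which observed and
    simulated discordance must coincide.
    """
    rng = np.random.default_rng(rng)
    ratios = rng.uniform(*ratio_range, n_pairs)
    pairs = pd.DataFrame(
        {
            "exon_id": [f"e{i}" for i in range(n_pairs)],
            "snp_1": [f"e{i}_a" for i in range(n_pairs)],
            "snp_2": [f"e{i}_b" for i in range(n_pairs)],
            "pos_1": 0,
            "pos_2": 100,
            "separation": 100,
        }
    )
    for k in (1, 2):
        depth = np.clip(
            np.round(rng.lognormal(np.log(depth_median), depth_log_sd, n_pairs)), *depth_bounds
        ).astype(np.int64)
        b = rng.binomial(depth, ratios)
        pairs[f"count_B_{k}"] = b
        pairs[f"count_C_{k}"] = depth - b
    return annotate_pairs(pairs)


def discordance_curve(pairs: pd.DataFrame, thresholds: Sequence[float]) -> pd.DataFrame:
    """Fraction of direction-discordant pairs below each p-value threshold.

    A pair enters at threshold ``t`` when its less significant p-value is
    below ``t`` and both SNPs have a defined direction. Thresholds with zero
    qualifying pairs report a NaN fraction.
    """
    usable = pairs["concordant"].notna().to_numpy()
    p_pair = pairs["p_pair"].to_numpy()
    discordant = (pairs["concordant"] == 0).to_numpy()
    rows = []
    for t in thresholds:
        mask = usable & (p_pair < t)
        n = int(mask.sum())
        n_disc = int((mask & discordant).sum())
        rows.append(
            {
                "threshold": t,
                "n_pairs": n,
                "n_discordant": n_disc,
                "fraction": n_disc / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def expected_counts_from_partner(partner: tuple[int, int], total: int) -> tuple[float, float]:
    """Partner's allelic ratio scaled to ``total`` reads.

    >>> expected_counts_from_partner((30, 20), 100)
    (60.0, 40.0)
    """
    pb, pc = partner
    n = pb + pc
    if n < 1:
        raise ValidationError("partner SNP must have at least one read")
    if total < 1:
        raise ValidationError("total must be >= 1")
    e_b = pb / n * total
    return (e_b, total - e_b)


def solve_pearson_counts(expected: tuple[float, float], chi2_draw: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Invert Pearson's chi-square for the two count pairs at a given deviate.

    Solves ``(x - e_B)^2 * (1/e_B + 1/e_C) = chi2`` with the total fixed at
    ``n = e_B + e_C``; returns both real roots as ``(x, n - x)`` pairs
    (identical when ``chi2_draw`` is 0). Callers round to integers and clamp
    to ``[0, n]``.
    """
    e_b, e_c = expected
    if e_b <= 0 or e_c <= 0:
        raise ValidationError("expected counts must both be positive")
    if chi2_draw < 0:
        raise ValidationError("chi2_draw must be non-negative")
    n = e_b + e_c
    delta = np.sqrt(chi2_draw * e_b * e_c / n)
    hi, lo = e_b + delta, e_b - delta
    return ((hi, n - hi), (lo, n - lo))


def simulate_null_pairs(
    pairs: pd.DataFrame,
    thresholds: Sequence[float],
    rng: np.random.Generator | int | None = None,
    iterations: int = 100,
    replace: Literal["more_significant", "less_significant"] = "more_significant",
    round_counts: bool = True,
) -> pd.DataFrame:
    """Discordance curve expected under pure random sampling.

    Per iteration, the more significant SNP of every pair (or the less
    significant, in the alternate mode) is regenerated from the partner's
    ratio perturbed by a chi-square(1) deviate through the Pearson quadratic
    (random root, rounded, clamped), its test recomputed, and the curve
    rebuilt.  Returns, per threshold, the mean simulated discordant fraction
    with its spread over iterations and the mean number of qualifying pairs.
    Pairs whose regenerated SNP lands on an exact tie contribute to
    ``mean_dropped`` instead.
    """
    rng = np.random.default_rng(rng)
    frac = np.full((iterations, len(thresholds)), np.nan)
    npairs = np.zeros((iterations, len(thresholds)))
    ndisc = np.zeros((iterations, len(thresholds)))
    dropped = np.zeros(iterations)
    for it in range(iterations):
        p_pair, concord, valid = regenerate_pairs_once(pairs, rng, replace, round_counts)
        dropped[it] = (~valid).sum()
        for k, t in enumerate(thresholds):
            mask = valid & (p_pair < t)
            n = mask.sum()
            npairs[it, k] = n
            ndisc[it, k] = (mask & ~concord).sum()
            if n:
                frac[it, k] = ndisc[it, k] / n
    rows = []
    for k, t in enumerate(thresholds):
        col = frac[:, k]
        have = col[~np.isnan(col)]
        rows.append(
            {
                "threshold": t,
                "mean_fraction": have.mean() if len(have) else float("nan"),
                "sd_fraction": have.std(ddof=1) if len(have) > 1 else 0.0,
                "mean_n_pairs": npairs[:, k].mean(),
                "mean_n_discordant": ndisc[:, k].mean(),
                "mean_dropped": dropped.mean(),
            }
        )
    return pd.DataFrame(rows)


def regenerate_pairs_once(
    pairs: pd.DataFrame,
    rng: np.random.Generator,
    replace: str,
    round_counts: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One regeneration pass over all pairs (vectorised).

    Returns ``(p_pair, concordant, valid)`` arrays; ``valid`` is False where
    the regenerated SNP has no direction (tie) or the partner ratio is
    degenerate (0 or 1) leaving nothing to perturb.
    """
    b1 = pairs["count_B_1"].to_numpy(float)
    c1 = pairs["count_C_1"].to_numpy(float)
    b2 = pairs["count_B_2"].to_numpy(float)
    c2 = pairs["count_C_2"].to_numpy(float)
    _, p1 = chi2_components(b1, c1)
    _, p2 = chi2_components(b2, c2)

    if replace == "more_significant":
        replace_first = p1 <= p2
    elif replace == "less_significant":
        replace_first = p1 > p2
    else:
        raise ValidationError(f"unknown replace mode {replace!r}")

    rb = np.where(replace_first, b2, b1)  # partner counts
    rc = np.where(replace_first, c2, c1)
    tot = np.where(replace_first, b1 + c1, b2 + c2)  # replaced SNP's own depth
    ratio = rb / (rb + rc)
    e_b = ratio * tot
    e_c = tot - e_b

    perturbable = (e_b > 0) & (e_c > 0)
    chi2_draw = rng.chisquare(df=1, size=len(pairs))
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.sqrt(np.where(perturbable, chi2_draw * e_b * e_c / tot, 0.0))
    sign = rng.choice([-1.0, 1.0], size=len(pairs))
    x = e_b + sign * delta
    if round_counts:
        x = np.round(x)
    new_b = np.clip(x, 0, tot)
    new_c = tot - new_b

    _, p_new = chi2_components(new_b, new_c)
    d_new = np.sign(new_b - new_c).astype(np.int8)
    d_partner = np.sign(rb - rc).astype(np.int8)
    p_partner = np.where(replace_first, p2, p1)

    valid = (d_new != 0) & (d_partner != 0) & perturbable
    p_pair = np.fmax(p_partner, p_new)
    concordant = d_new == d_partner
    return p_pair, concordant, valid
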