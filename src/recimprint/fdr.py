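"""Mock-cross negative controls, empirical FDR, and downsampling curves.

Because an imprinting call demands *reciprocal* bias, comparing two samples
of the *same* cross direction as though they were reciprocal ("mock cross")
can never detect true imprinting — every significant unit there is a false
discovery driven by technical/biological variation.  The empirical FDR at a
p-value threshold is therefore

    FDR(t) = (# significant units, mock pairs) / (# significant units, reciprocal pairs)

with both arms computed at identical, depth-normalized input.  Sensitivity
is tracked as the fraction of known imprinted genes, powered for detection,
that meet significance in the reciprocal arm.  Downsampling curves thin the
counts without replacement (multivariate hypergeometric, i.e. removing
reads at the count level) and re-run the caller to relate depth to yield.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .calls import CallCriteria, aggregate_gene_counts, comparison_table
from .errors import ValidationError

DEFAULT_EXCLUDE_CHROMS = frozenset({"chrX", "chrM"})

PairLabel = Literal["reciprocal", "mock"]


@dataclass(frozen=True)
class ComparisonScheme:
    """Named sample pairings, each labelled reciprocal or mock."""

    name: str
    pairs: tuple[tuple[str, str, PairLabel], ...]

    def validate(self, samples: pd.DataFrame) -> None:
        """Check pair labels against sample cross directions."""
        cross = samples.set_index("sample_id")["cross"]
        for a, b, label in self.pairs:
            for sid in (a, b):
                if sid not in cross.index:
                    raise ValidationError(f"scheme {self.name!r}: unknown sample {sid!r}")
            same = cross[a] == cross[b]
            if label == "mock" and not same:
                raise ValidationError(f"scheme {self.name!r}: mock pair ({a}, {b}) crosses differ")
            if label == "reciprocal" and same:
                raise ValidationError(f"scheme {self.name!r}: reciprocal pair ({a}, {b}) crosses match")

    def labelled(self, label: PairLabel) -> list[tuple[str, str]]:
        return [(a, b) for a, b, lab in self.pairs if lab == label]


def default_scheme(samples: pd.DataFrame, name: str = "default") -> ComparisonScheme:
    """Build the standard 4-animal scheme: sex-matched reciprocal pairs where
    possible, within-cross mock pairs (same sex preferred)."""
    pairs: list[tuple[str, str, PairLabel]] = []
    by_cross = {c: g.reset_index(drop=True) for c, g in samples.groupby("cross")}
    bxc = by_cross.get("BxC", pd.DataFrame(columns=samples.columns))
    cxb = by_cross.get("CxB", pd.DataFrame(columns=samples.columns))

    used_b, used_c = set(), set()
    for _, row in bxc.iterrows():  # sex-matched reciprocal pairs first
        match = cxb[(~cxb["sample_id"].isin(used_c)) & (cxb["sex"] == row["sex"])]
        if len(match):
            other = match.iloc[0]["sample_id"]
            pairs.append((row["sample_id"], other, "reciprocal"))
            used_b.add(row["sample_id"])
            used_c.add(other)
    for _, row in bxc[~bxc["sample_id"].isin(used_b)].iterrows():
        match = cxb[~cxb["sample_id"].isin(used_c)]
        if len(match):
            other = match.iloc[0]["sample_id"]
            pairs.append((row["sample_id"], other, "reciprocal"))
            used_b.add(row["sample_id"])
            used_c.add(other)

    for cross_df in (bxc, cxb):  # within-cross mock pairs, same sex first
        ids = list(cross_df["sample_id"])
        sexes = dict(zip(cross_df["sample_id"], cross_df["sex"]))
        remaining = ids[:]
        while len(remaining) >= 2:
            a = remaining.pop(0)
            same_sex = [s for s in remaining if sexes[s] == sexes[a]]
            b = same_sex[0] if same_sex else remaining[0]
            remaining.remove(b)
            pairs.append((a, b, "mock"))
    scheme = ComparisonScheme(name=name, pairs=tuple(pairs))
    scheme.validate(samples)
    return scheme


# ---------------------------------------------------------------------------
# Depth normalization and thinning


def _thin_vector(values: np.ndarray, target: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``target`` reads without replacement from a count vector."""
    total = int(values.sum())
    if target >= total:
        return values.copy()
    return rng.multivariate_hypergeometric(values, target, method="marginals")


def normalize_depth(
    counts: pd.DataFrame,
    snps: pd.DataFrame,
    exclude_chroms: Iterable[str] = DEFAULT_EXCLUDE_CHROMS,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Equalize aligned-read totals across samples after chromosome exclusion.

    SNPs on ``exclude_chroms`` (default chrX and chrM, whose dosage differs
    between sexes / is uniparental) are dropped; every other sample is then
    randomly thinned — reads removed without replacement across its allelic
    counts — until its total equals the smallest sample total.
    """
    rng = np.random.default_rng(rng)
    excluded_snps = set(snps.loc[snps["chrom"].isin(set(exclude_chroms)), "snp_id"])
    kept = counts[~counts["snp_id"].isin(excluded_snps)].reset_index(drop=True)
    if kept.empty:
        raise ValidationError("no counts remain after chromosome exclusion")
    totals = kept.groupby("sample_id")[["count_B", "count_C"]].sum().sum(axis=1)
    if (totals == 0).any():
        empty = totals.index[totals == 0][0]
        raise ValidationError(f"sample {empty!r} has zero reads after chromosome exclusion")
    target = int(totals.min())
    out = []
    for sid, group in kept.groupby("sample_id", sort=False):
        vec = group[["count_B", "count_C"]].to_numpy().ravel()
        thinned = _thin_vector(vec, target, rng).reshape(-1, 2)
        g = group.copy()
        g["count_B"] = thinned[:, 0]
        g["count_C"] = thinned[:, 1]
        out.append(g)
    return pd.concat(out, ignore_index=True)


def thin_counts(counts: pd.DataFrame, fraction: float, rng: np.random.Generator) -> pd.DataFrame:
    """Thin every sample to ``fraction`` of its reads (without replacement)."""
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return counts
    out = []
    for _, group in counts.groupby("sample_id", sort=False):
        vec = group[["count_B", "count_C"]].to_numpy().ravel()
        target = int(round(vec.sum() * fraction))
        thinned = _thin_vector(vec, target, rng).reshape(-1, 2)
        g = group.copy()
        g["count_B"] = thinned[:, 0]
        g["count_C"] = thinned[:, 1]
        out.append(g)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Comparisons


def _sample_unit_counts(
    counts: pd.DataFrame,
    sample_id: str,
    unit: Literal["gene", "snp"],
    assignment: pd.DataFrame | None,
) -> pd.DataFrame:
    sub = counts[counts["sample_id"] == sample_id]
    if unit == "snp":
        return sub.rename(columns={"snp_id": "unit_id"})[["unit_id", "count_B", "count_C"]]
    if assignment is None:
        raise ValidationError("gene-level comparison requires a SNP->gene assignment")
    agg = aggregate_gene_counts(sub, assignment)
    return agg.rename(columns={"gene_id": "unit_id"})[["unit_id", "count_B", "count_C"]]


def pair_table(
    counts: pd.DataFrame,
    pair: tuple[str, str],
    unit: Literal["gene", "snp"] = "gene",
    assignment: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Comparison table for one sample pair, first sample treated as cross 1.

    For mock pairs this applies the pretend cross labels; the significant
    count is invariant to which member is called "cross 1".
    """
    c1 = _sample_unit_counts(counts, pair[0], unit, assignment)
    c2 = _sample_unit_counts(counts, pair[1], unit, assignment)
    return comparison_table(c1, c2, cross_1="BxC", cross_2="CxB", unit_col="unit_id")


def significant_units(table: pd.DataFrame, alpha: float, min_reads: int = 10) -> pd.Index:
    """Units imprinted at threshold ``alpha``: powered, significant in both
    samples, reciprocally biased."""
    mask = (
        (table["n_1"] >= min_reads)
        & (table["n_2"] >= min_reads)
        & (table["p_1"] < alpha)
        & (table["p_2"] < alpha)
        & table["reciprocal"]
    )
    return table.index[mask]


def run_comparison(
    counts: pd.DataFrame,
    pair: tuple[str, str],
    criteria: CallCriteria,
    unit: Literal["gene", "snp"] = "gene",
    assignment: pd.DataFrame | None = None,
) -> tuple[int, list[str]]:
    """Significant-unit count and identities for one sample pair."""
    table = pair_table(counts, pair, unit, assignment)
    units = significant_units(table, criteria.alpha, criteria.min_reads)
    return len(units), list(units)


@dataclass(frozen=True)
class FdrEstimate:
    threshold: float
    n_mock: int
    n_reciprocal: int

    @property
    def fdr(self) -> float:
        return self.n_mock / self.n_reciprocal if self.n_reciprocal > 0 else float("nan")


def fdr_curve(
    counts: pd.DataFrame,
    scheme: ComparisonScheme,
    thresholds: Sequence[float],
    min_reads: int = 10,
    unit: Literal["gene", "snp"] = "gene",
    assignment: pd.DataFrame | None = None,
    pooling: Literal["sum", "union"] = "sum",
    restrict_to: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Empirical FDR per threshold from pooled mock vs reciprocal counts.

    ``counts`` must already be depth-normalized — both arms see the same
    input by construction, since one table feeds every pair.  ``pooling``
    sums significant counts over pairs (default) or takes the union of the
    significant unit sets.  ``restrict_to`` limits both arms to the given
    unit ids (e.g. novel genes only).
    """
    tables = {label: [pair_table(counts, p, unit, assignment) for p in scheme.labelled(label)] for label in ("mock", "reciprocal")}
    keep = set(restrict_to) if restrict_to is not None else None
    rows = []
    for t in thresholds:
        pooled = {}
        for label, tabs in tables.items():
            sets = [set(significant_units(tab, t, min_reads)) for tab in tabs]
            if keep is not None:
                sets = [s & keep for s in sets]
            pooled[label] = len(set().union(*sets)) if pooling == "union" else sum(len(s) for s in sets)
        est = FdrEstimate(threshold=t, n_mock=pooled["mock"], n_reciprocal=pooled["reciprocal"])
        rows.append({"threshold": t, "n_mock": est.n_mock, "n_reciprocal": est.n_reciprocal, "fdr": est.fdr})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SensitivityEstimate:
    n_detected: int
    n_powered: int

    @property
    def sensitivity(self) -> float:
        return self.n_detected / self.n_powered if self.n_powered > 0 else float("nan")


def sensitivity_curve(
    reciprocal_tables: Sequence[pd.DataFrame] | pd.DataFrame,
    known_ids: Iterable[str],
    thresholds: Sequence[float],
    min_reads: int = 10,
) -> pd.DataFrame:
    """Detected / powered known imprinted genes per p-value threshold.

    A known gene is *powered* when some reciprocal comparison has
    ``min_reads`` in both samples, and *detected* at threshold ``t`` when it
    is significant (reciprocal, both p < t) in some comparison.
    """
    if isinstance(reciprocal_tables, pd.DataFrame):
        reciprocal_tables = [reciprocal_tables]
    known = set(known_ids)
    powered: set[str] = set()
    for tab in reciprocal_tables:
        mask = (tab["n_1"] >= min_reads) & (tab["n_2"] >= min_reads)
        powered |= set(tab.index[mask]) & known
    rows = []
    for t in thresholds:
        detected: set[str] = set()
        for tab in reciprocal_tables:
            detected |= set(significant_units(tab, t, min_reads)) & known
        est = SensitivityEstimate(n_detected=len(detected & powered), n_powered=len(powered))
        rows.append(
            {
                "threshold": t,
                "n_detected": est.n_detected,
                "n_powered": est.n_powered,
                "sensitivity": est.sensitivity,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DownsampleConfig:
    fractions: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    iterations: int = 100
    seed: int | None = None

    def __post_init__(self):
        if list(self.fractions) != sorted(self.fractions):
            raise ValidationError("fractions must be sorted ascending")
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ValidationError("fractions must lie in (0, 1]")


def downsample_curve(
    counts: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    config: DownsampleConfig,
    criteria: CallCriteria,
    unit: Literal["gene", "snp"] = "gene",
    assignment: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean +/- SE of the pooled significant-unit count vs read fraction.

    Per iteration, every sample is thinned to the fraction (reads removed
    without replacement) and the caller re-run on the pooled pairs. At
    fraction 1.0 thinning is a no-op, so the SE is exactly 0.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for f in config.fractions:
        iters = 1 if f == 1.0 else config.iterations
        vals = np.empty(iters)
        for i in range(iters):
            thinned = thin_counts(counts, f, rng)
            vals[i] = sum(
                run_comparison(thinned, p, criteria, unit, assignment)[0] for p in pairs
            )
        mean = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(iters) if iters > 1 else 0.0
        rows.append({"fraction": f, "mean_significant": mean, "se": se, "iterations": iters})
    return pd.DataFrame(rows)


def fp_proportion_curve(
    counts: pd.DataFrame,
    scheme: ComparisonScheme,
    config: DownsampleConfig,
    threshold: float,
    known_ids: Iterable[str],
    min_reads: int = 10,
    unit: Literal["gene", "snp"] = "gene",
    assignment: pd.DataFrame | None = None,
    pooling: Literal["sum", "union"] = "sum",
) -> pd.DataFrame:
    """Estimated false-positive proportion among *novel* units vs read fraction.

    Per fraction, counts are thinned and the empirical FDR at ``threshold``
    recomputed with both arms restricted to units absent from the known
    catalog; mean and SE are over iterations (fraction 1.0 is deterministic).
    """
    rng = np.random.default_rng(config.seed)
    known = set(known_ids)
    rows = []
    for f in config.fractions:
        iters = 1 if f == 1.0 else config.iterations
        fdrs, mocks, recips = [], [], []
        for _ in range(iters):
            thinned = thin_counts(counts, f, rng)
            # novel-only recount: drop known units from both arms
            novel_curve = _fdr_excluding(
                thinned, scheme, threshold, known, min_reads, unit, assignment, pooling
            )
            fdrs.append(novel_curve["fdr"])
            mocks.append(novel_curve["n_mock"])
            recips.append(novel_curve["n_reciprocal"])
        arr = np.array(fdrs, dtype=float)
        valid = arr[~np.isnan(arr)]
        rows.append(
            {
                "fraction": f,
                "mean_fdr": valid.mean() if len(valid) else float("nan"),
                "se": valid.std(ddof=1) / np.sqrt(len(valid)) if len(valid) > 1 else 0.0,
                "mean_n_mock": float(np.mean(mocks)),
                "mean_n_reciprocal": float(np.mean(recips)),
                "iterations": iters,
            }
        )
    return pd.DataFrame(rows)


def _fdr_excluding(counts, scheme, threshold, excluded, min_reads, unit, assignment, pooling):
    pooled = {}
    for label in ("mock", "reciprocal"):
        sets = []
        for p in scheme.labelled(label):
            tab = pair_table(counts, p, unit, assignment)
            sets.append(set(significant_units(tab, threshold, min_reads)) - excluded)
        pooled[label] = len(set().union(*sets)) if pooling == "union" else sum(len(s) for s in sets)
    est = FdrEstimate(threshold, pooled["mock"], pooled["reciprocal"])
    return {"n_mock": est.n_mock, "n_reciprocal": est.n_reciprocal, "fdr": est.fdr}
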