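"""SNP-level and gene-level imprinting calls under the reciprocal criterion.

A unit (SNP or per-gene aggregate) is called imprinted from one pair of
samples — one from each reciprocal cross — when

* both samples have at least ``min_reads`` allelic reads at the unit,
* the chi-square ASE p-value is below ``alpha`` in both samples, and
* more than 50% of reads come from the allele of the same parental sex in
  both samples (reciprocity: maternal in both or paternal in both).

The depth rule alone decides *powered* status: a unit failing it in either
sample is ``underpowered`` and never counts against sensitivity.  Two
operating points mirror common usage: SNP-level replication at
``alpha = 0.05`` and gene-aggregate discovery at ``alpha = 1e-4``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .stats import (
    ImprintScore,
    chi2_components,
    chi_square_ase,
    imprinting_score,
    maternal_fraction_arrays,
)

Status = Literal["imprinted", "not_imprinted", "underpowered"]


@dataclass(frozen=True)
class CallCriteria:
    """Thresholds for an imprinting call."""

    min_reads: int = 10
    alpha: float = 0.05

    def __post_init__(self):
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


#: SNP-level replication criteria (p < 0.05, >= 10 reads in each sample).
SNP_CRITERIA = CallCriteria(min_reads=10, alpha=0.05)
#: Gene-aggregate discovery criteria (p < 1e-4, empirical FDR < 0.05).
GENE_CRITERIA = CallCriteria(min_reads=10, alpha=1e-4)


@dataclass(frozen=True)
class ImprintCall:
    unit: Literal["SNP", "gene"]
    id: str
    status: Status
    parental_direction: Literal["maternal", "paternal", "none"]
    p_bxc: float
    p_cxb: float
    score: ImprintScore | None
    depth_bxc: int
    depth_cxb: int


def comparison_table(
    counts_1: pd.DataFrame,
    counts_2: pd.DataFrame,
    cross_1: str = "BxC",
    cross_2: str = "CxB",
    unit_col: str = "snp_id",
) -> pd.DataFrame:
    """Join per-unit counts from two samples and compute both ASE tests.

    ``counts_1``/``counts_2`` need columns ``[unit_col, count_B, count_C]``.
    Units absent from one sample get zero depth there. For mock comparisons
    pass the pretend cross labels; reciprocity is evaluated under them.

    Returns one row per unit with depths, per-sample chi-square p-values,
    maternal fractions, the reciprocity flag, the less-significant ``p_used``
    and the signed score (nan when not reciprocal).
    """
    left = counts_1[[unit_col, "count_B", "count_C"]].set_index(unit_col)
    right = counts_2[[unit_col, "count_B", "count_C"]].set_index(unit_col)
    joined = left.join(right, how="outer", lsuffix="_1", rsuffix="_2").fillna(0).astype(np.int64)

    b1, c1 = joined["count_B_1"].to_numpy(), joined["count_C_1"].to_numpy()
    b2, c2 = joined["count_B_2"].to_numpy(), joined["count_C_2"].to_numpy()
    chi2_1, p1 = chi2_components(b1, c1)
    chi2_2, p2 = chi2_components(b2, c2)
    mf1 = maternal_fraction_arrays(b1, c1, cross_1)
    mf2 = maternal_fraction_arrays(b2, c2, cross_2)

    maternal = (mf1 > 0.5) & (mf2 > 0.5)
    paternal = (mf1 < 0.5) & (mf2 < 0.5)
    reciprocal = maternal | paternal
    p_used = np.fmax(p1, p2)
    with np.errstate(divide="ignore"):
        magnitude = -np.log10(p_used)
    score = np.where(reciprocal, np.where(maternal, magnitude, -magnitude), np.nan)

    out = pd.DataFrame(
        {
            "count_B_1": b1,
            "count_C_1": c1,
            "count_B_2": b2,
            "count_C_2": c2,
            "n_1": b1 + c1,
            "n_2": b2 + c2,
            "chi2_1": chi2_1,
            "p_1": p1,
            "chi2_2": chi2_2,
            "p_2": p2,
            "maternal_frac_1": mf1,
            "maternal_frac_2": mf2,
            "reciprocal": reciprocal,
            "direction": np.where(maternal, "maternal", np.where(paternal, "paternal", "none")),
            "p_used": p_used,
            "score": score,
        },
        index=joined.index,
    )
    out.index.name = unit_col
    return out


def classify(table: pd.DataFrame, criteria: CallCriteria) -> pd.Series:
    """Status per unit of a :func:`comparison_table` under ``criteria``."""
    powered = (table["n_1"] >= criteria.min_reads) & (table["n_2"] >= criteria.min_reads)
    significant = (table["p_1"] < criteria.alpha) & (table["p_2"] < criteria.alpha)
    imprinted = powered & significant & table["reciprocal"]
    return pd.Series(
        np.where(~powered, "underpowered", np.where(imprinted, "imprinted", "not_imprinted")),
        index=table.index,
        name="status",
    )


def call_table(
    counts_1: pd.DataFrame,
    counts_2: pd.DataFrame,
    criteria: CallCriteria,
    cross_1: str = "BxC",
    cross_2: str = "CxB",
    unit_col: str = "snp_id",
) -> pd.DataFrame:
    """Comparison table plus a ``status`` column."""
    table = comparison_table(counts_1, counts_2, cross_1, cross_2, unit_col)
    table["status"] = classify(table, criteria)
    return table


def _call_from_counts(
    unit: str,
    uid: str,
    bxc: tuple[int, int],
    cxb: tuple[int, int],
    criteria: CallCriteria,
) -> ImprintCall:
    n1, n2 = sum(bxc), sum(cxb)
    if n1 < criteria.min_reads or n2 < criteria.min_reads:
        p1 = chi_square_ase(*bxc).p if n1 > 0 else float("nan")
        p2 = chi_square_ase(*cxb).p if n2 > 0 else float("nan")
        return ImprintCall(unit, uid, "underpowered", "none", p1, p2, None, n1, n2)
    t1, t2 = chi_square_ase(*bxc), chi_square_ase(*cxb)
    score = imprinting_score(t1, t2)
    if score.reciprocal and t1.p < criteria.alpha and t2.p < criteria.alpha:
        return ImprintCall(unit, uid, "imprinted", score.direction, t1.p, t2.p, score, n1, n2)
    return ImprintCall(unit, uid, "not_imprinted", score.direction, t1.p, t2.p, score, n1, n2)


def call_snp(
    counts_bxc: tuple[int, int],
    counts_cxb: tuple[int, int],
    criteria: CallCriteria = SNP_CRITERIA,
    snp_id: str = "",
) -> ImprintCall:
    """Call one SNP from its allelic counts in the two reciprocal samples."""
    return _call_from_counts("SNP", snp_id, counts_bxc, counts_cxb, criteria)


def call_gene(
    aggregate_bxc: tuple[int, int],
    aggregate_cxb: tuple[int, int],
    criteria: CallCriteria = GENE_CRITERIA,
    gene_id: str = "",
) -> ImprintCall:
    """Call one gene from SNP-summed allelic counts in the two samples."""
    return _call_from_counts("gene", gene_id, aggregate_bxc, aggregate_cxb, criteria)


def aggregate_gene_counts(counts: pd.DataFrame, assignment: pd.DataFrame) -> pd.DataFrame:
    """Sum allelic counts over each gene's SNPs, per sample.

    ``assignment`` is the (snp, gene) table from :func:`recimprint.io.assign_snps`;
    unassigned SNPs (empty gene_id) are dropped. A SNP in two overlapping
    genes contributes to both aggregates. Reads spanning two SNPs are
    double-counted at the count-table level; this matches aggregation on
    counts alone and is a documented limitation.
    """
    assigned = assignment.loc[assignment["gene_id"] != "", ["snp_id", "gene_id"]].drop_duplicates()
    merged = counts.merge(assigned, on="snp_id", how="inner")
    agg = (
        merged.groupby(["gene_id", "sample_id"], as_index=False)[["count_B", "count_C"]]
        .sum()
        .sort_values(["gene_id", "sample_id"], kind="stable")
        .reset_index(drop=True)
    )
    return agg


def call_gene_via_snps(snp_calls: pd.DataFrame) -> ImprintCall:
    """Gene call from per-SNP replication calls: imprinted iff >= 1 imprinted SNP.

    ``snp_calls`` carries one row per SNP with columns ``status``,
    ``direction``, ``p_used``, ``pos`` and optionally ``gene_id``. Direction
    is taken from the most significant imprinted SNP (smallest ``p_used``),
    ties broken by lowest genomic coordinate. A gene whose SNPs are all
    underpowered is underpowered.
    """
    gid = str(snp_calls["gene_id"].iloc[0]) if "gene_id" in snp_calls.columns else ""
    imprinted = snp_calls[snp_calls["status"] == "imprinted"]
    if len(imprinted):
        best = imprinted.sort_values(["p_used", "pos"], kind="stable").iloc[0]
        return ImprintCall(
            "gene", gid, "imprinted", best["direction"], float("nan"), float("nan"), None, -1, -1
        )
    if (snp_calls["status"] == "not_imprinted").any():
        return ImprintCall("gene", gid, "not_imprinted", "none", float("nan"), float("nan"), None, -1, -1)
    return ImprintCall("gene", gid, "underpowered", "none", float("nan"), float("nan"), None, -1, -1)


def call_sex_specific(calls_a: pd.DataFrame, calls_b: pd.DataFrame, labels=("sexA", "sexB")) -> pd.Series:
    """Classify units by sex-specificity of the imprinting call.

    ``calls_a``/``calls_b`` are call tables (with ``status``) from the
    reciprocal comparison within each sex, indexed by unit.  A unit is
    sex-specific only when it is imprinted in one sex and *powered but not
    imprinted* in the other; if the other sex lacks coverage the verdict is
    ``underpowered`` — absence of evidence is never claimed as specificity.
    """
    idx = calls_a.index.union(calls_b.index)
    a = calls_a["status"].reindex(idx, fill_value="underpowered")
    b = calls_b["status"].reindex(idx, fill_value="underpowered")
    out = pd.Series("neither", index=idx, name="sex_specificity")
    out[(a == "imprinted") & (b == "imprinted")] = "both"
    out[(a == "imprinted") & (b == "not_imprinted")] = f"{labels[0]}_specific"
    out[(b == "imprinted") & (a == "not_imprinted")] = f"{labels[1]}_specific"
    out[((a == "imprinted") & (b == "underpowered")) | ((b == "imprinted") & (a == "underpowered"))] = (
        "underpowered"
    )
    return out


def extrapolate_total(
    confirmed: int, untested: int, confirmation_rate: float, sensitivity: float
) -> float:
    """Generic extrapolation of the total imprinted-gene count.

    ``(confirmed + confirmation_rate * untested) / sensitivity``: validated
    discoveries plus the expected yield of untested candidates, scaled up by
    the detection sensitivity of the screen. A coarse estimator — the
    confirmation rate itself is usually measured on few genes.
    """
    if sensitivity <= 0 or sensitivity > 1:
        raise ValueError("sensitivity must lie in (0, 1]")
    if not 0 <= confirmation_rate <= 1:
        raise ValueError("confirmation_rate must lie in [0, 1]")
    return (confirmed + confirmation_rate * untested) / sensitivity
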