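"""Candidate ranking by the features that predict true imprinting.

Three properties separate validated imprinted genes from false positives:
a strong imprinting score (reciprocal bias at depth), agreement among the
gene's individual SNPs, and recurrence of the signal across independent
datasets/tissues.  Proximity to known imprinted clusters adds further
prior weight, since imprinted genes cluster and share regulatory elements.
"""

from __future__ import annotations

from typing import Literal, Mapping

import numpy as np
import pandas as pd

#: |score| above which a dataset counts toward recurrence (p < 1e-4).
RECURRENCE_SCORE = 4.0
#: window (bp) for association with a known imprinted cluster.
CLUSTER_WINDOW = 1_000_000


def nearest_known_distance(
    gene: tuple[str, int, int], catalog: pd.DataFrame
) -> float:
    """Distance (bp) to the nearest known imprinted gene on the same
    chromosome; 0 when intervals overlap or touch; NaN when none exists."""
    chrom, start, end = gene
    same = catalog[catalog["chrom"] == chrom]
    if same.empty:
        return float("nan")
    gaps = np.maximum(same["start"].to_numpy() - end, start - same["end"].to_numpy())
    return float(max(gaps.min(), 0))


def proximity_flag(
    distance: float, window: int = CLUSTER_WINDOW
) -> Literal["extension_candidate", "cluster_associated", "novel"]:
    """Positional relationship of a candidate to the known catalog.

    Overlap/adjacency (distance 0) suggests the candidate extends a known
    imprinted transcript; within ``window`` it shares a cluster; beyond it
    is positionally novel. NaN distances (no known gene on the chromosome)
    are novel.
    """
    if np.isnan(distance):
        return "novel"
    if distance == 0:
        return "extension_candidate"
    if distance < window:
        return "cluster_associated"
    return "novel"


def rank_candidates(
    gene_tables: Mapping[str, pd.DataFrame],
    gene_positions: pd.DataFrame,
    catalog: pd.DataFrame,
    snp_calls: Mapping[str, pd.DataFrame] | None = None,
    recurrence_score: float = RECURRENCE_SCORE,
) -> pd.DataFrame:
    """Rank candidate genes across one or more datasets.

    ``gene_tables`` maps dataset name -> gene-level comparison table
    (indexed by gene, with a ``score`` column); ``gene_positions`` supplies
    (gene_id, chrom, start, end); ``snp_calls`` optionally maps dataset ->
    SNP-level call table (columns gene_id, status) from which the count of
    individually reciprocal SNPs is taken (maximum over datasets).

    Sorted by recurrence (datasets with |score| > ``recurrence_score``),
    then |best score|, then supporting-SNP count, then gene_id for a total
    order.
    """
    gene_ids = sorted(set().union(*[set(t.index) for t in gene_tables.values()]))
    pos = gene_positions.set_index("gene_id")

    support: dict[str, int] = {g: 0 for g in gene_ids}
    if snp_calls:
        for table in snp_calls.values():
            counts = (
                table[table["status"] == "imprinted"].groupby("gene_id").size()
                if len(table)
                else pd.Series(dtype=int)
            )
            for g, n in counts.items():
                if g in support:
                    support[g] = max(support[g], int(n))

    rows = []
    for g in gene_ids:
        scores = np.array(
            [t.loc[g, "score"] if g in t.index else np.nan for t in gene_tables.values()], dtype=float
        )
        finite = scores[~np.isnan(scores)]
        best = finite[np.argmax(np.abs(finite))] if len(finite) else float("nan")
        recurrent = int((np.abs(finite) > recurrence_score).sum())
        if g in pos.index:
            dist = nearest_known_distance((pos.loc[g, "chrom"], pos.loc[g, "start"], pos.loc[g, "end"]), catalog)
        else:
            dist = float("nan")
        rows.append(
            {
                "gene_id": g,
                "imprinting_score": best,
                "n_supporting_snps": support[g],
                "n_samples_recurrent": recurrent,
                "distance_to_known": dist,
                "proximity": proximity_flag(dist),
            }
        )
    out = pd.DataFrame(rows)
    out["_abs_score"] = out["imprinting_score"].abs().fillna(-1.0)
    out = out.sort_values(
        ["n_samples_recurrent", "_abs_score", "n_supporting_snps", "gene_id"],
        ascending=[False, False, False, True],
        kind="stable",
    ).drop(columns="_abs_score")
    return out.reset_index(drop=True)
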