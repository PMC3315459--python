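"""Model/results facade over the calling machinery.

`ReciprocalCrossModel` bundles a dataset (counts, sample metadata, SNPs,
gene models); `fit` runs the reciprocal chi-square caller on one pair of
samples and returns an `ImprintingResults` carrying the per-unit tests,
statuses and scores, with `summary()`, empirical-FDR and sensitivity
methods hanging off it.

    >>> model = ReciprocalCrossModel(counts, samples, snps=snps, gene_models=models)
    >>> res = model.fit()                 # gene-level, p < 1e-4, >= 10 reads
    >>> print(res.summary())
    >>> res.fdr_curve(thresholds=[1e-2, 1e-3, 1e-4])
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import io as rio
from .calls import GENE_CRITERIA, CallCriteria, call_sex_specific, classify
from .errors import ValidationError
from .fdr import (
    ComparisonScheme,
    default_scheme,
    fdr_curve,
    pair_table,
    sensitivity_curve,
    significant_units,
)


class ReciprocalCrossModel:
    """A reciprocal-cross allele-specific expression dataset, ready to call.

    Parameters
    ----------
    counts : DataFrame
        Long table (snp_id, sample_id, count_B, count_C).
    samples : DataFrame
        Metadata (sample_id, cross, sex, tissue, replicate).
    snps : DataFrame, optional
        SNP records; required for gene-level calling unless ``assignment``
        is given or ``snps`` already carries ``gene_id``.
    gene_models : sequence of GeneModel, optional
        Collapsed models used to assign SNPs to genes.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        snps: pd.DataFrame | None = None,
        gene_models: Sequence[rio.GeneModel] | None = None,
        assignment: pd.DataFrame | None = None,
    ):
        self.samples = rio.validate_samples(samples)
        self.counts = rio.validate_counts(counts, self.samples)
        self.snps = snps
        self.gene_models = list(gene_models) if gene_models is not None else None
        if assignment is not None:
            self.assignment = assignment
        elif snps is not None and gene_models is not None:
            self.assignment = rio.assign_snps(snps, self.gene_models)
        elif snps is not None and "gene_id" in snps.columns:
            self.assignment = snps
        else:
            self.assignment = None

    @classmethod
    def from_files(
        cls,
        counts_path,
        samples_path,
        snps_path=None,
        bed12_path=None,
    ) -> "ReciprocalCrossModel":
        samples = rio.read_samples(samples_path)
        counts = rio.read_counts(counts_path, samples)
        snps = rio.read_snps(snps_path) if snps_path else None
        models = rio.read_gene_models_bed12(bed12_path) if bed12_path else None
        return cls(counts, samples, snps=snps, gene_models=models)

    def default_scheme(self) -> ComparisonScheme:
        return default_scheme(self.samples)

    def _default_pair(self) -> tuple[str, str]:
        recip = self.default_scheme().labelled("reciprocal")
        if not recip:
            raise ValidationError("no reciprocal sample pair available")
        return recip[0]

    def fit(
        self,
        pair: tuple[str, str] | None = None,
        criteria: CallCriteria = GENE_CRITERIA,
        unit: Literal["gene", "snp"] = "gene",
    ) -> "ImprintingResults":
        """Run the reciprocal caller on one (BxC, CxB) sample pair.

        The pair defaults to the first sex-matched reciprocal pair in the
        metadata. The first sample must be the BxC member (it is reordered
        if not).
        """
        if pair is None:
            pair = self._default_pair()
        cross = self.samples.set_index("sample_id")["cross"]
        if cross[pair[0]] == "CxB" and cross[pair[1]] == "BxC":
            pair = (pair[1], pair[0])
        if cross[pair[0]] != "BxC" or cross[pair[1]] != "CxB":
            raise ValidationError(f"pair {pair} is not reciprocal (crosses {cross[pair[0]]}, {cross[pair[1]]})")
        if unit == "gene" and self.assignment is None:
            raise ValidationError("gene-level fit requires SNPs and gene models (or an assignment)")
        table = pair_table(self.counts, pair, unit=unit, assignment=self.assignment)
        table["status"] = classify(
            table.rename(columns={"n_1": "n_1", "n_2": "n_2"}), criteria
        )
        return ImprintingResults(self, table, pair, criteria, unit)


@dataclass
class ImprintingResults:
    """Per-unit reciprocal test results plus the decision at the fitted
    criteria; produced by :meth:`ReciprocalCrossModel.fit`."""

    model: ReciprocalCrossModel
    table: pd.DataFrame
    pair: tuple[str, str]
    criteria: CallCriteria
    unit: str

    @property
    def imprinted(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "imprinted"]

    @property
    def n_imprinted(self) -> int:
        return int((self.table["status"] == "imprinted").sum())

    @property
    def n_powered(self) -> int:
        powered = (self.table["n_1"] >= self.criteria.min_reads) & (
            self.table["n_2"] >= self.criteria.min_reads
        )
        return int(powered.sum())

    def scores(self) -> pd.Series:
        """Signed imprinting scores (NaN where not reciprocal)."""
        return self.table["score"]

    def significant_at(self, alpha: float) -> pd.Index:
        return significant_units(self.table, alpha, self.criteria.min_reads)

    def fdr_curve(
        self,
        thresholds: Sequence[float],
        scheme: ComparisonScheme | None = None,
        pooling: Literal["sum", "union"] = "sum",
    ) -> pd.DataFrame:
        """Empirical mock/reciprocal FDR on this model's counts.

        Counts are assumed depth-normalized (use
        :func:`recimprint.fdr.normalize_depth` upstream); both arms of the
        ratio see the same table.
        """
        scheme = scheme or self.model.default_scheme()
        scheme.validate(self.model.samples)
        return fdr_curve(
            self.model.counts,
            scheme,
            thresholds,
            min_reads=self.criteria.min_reads,
            unit=self.unit,  # type: ignore[arg-type]
            assignment=self.model.assignment,
            pooling=pooling,
        )

    def sensitivity(self, known_ids: Iterable[str], thresholds: Sequence[float]) -> pd.DataFrame:
        return sensitivity_curve(self.table, known_ids, thresholds, self.criteria.min_reads)

    def sex_specific(self, other: "ImprintingResults", labels=("A", "B")) -> pd.Series:
        """Compare against the reciprocal fit of the other sex."""
        return call_sex_specific(self.table, other.table, labels=labels)

    def summary(self) -> str:
        t = self.table
        maternal = int(((t["status"] == "imprinted") & (t["direction"] == "maternal")).sum())
        paternal = int(((t["status"] == "imprinted") & (t["direction"] == "paternal")).sum())
        lines = [
            "Reciprocal-cross imprinting call summary",
            "=" * 44,
            f"unit:                {self.unit}",
            f"samples (BxC, CxB):  {self.pair[0]}, {self.pair[1]}",
            f"criteria:            p < {self.criteria.alpha:g}, depth >= {self.criteria.min_reads} in both",
            "-" * 44,
            f"units tested:        {len(t)}",
            f"powered:             {self.n_powered}",
            f"imprinted:           {self.n_imprinted}"
            f"   (maternal {maternal}, paternal {paternal})",
            f"not imprinted:       {int((t['status'] == 'not_imprinted').sum())}",
            f"underpowered:        {int((t['status'] == 'underpowered').sum())}",
        ]
        if self.n_imprinted:
            top = self.imprinted.reindex(
                self.imprinted["score"].abs().sort_values(ascending=False).index
            ).head(10)
            lines += ["-" * 44, "top imprinted units (signed score = -log10 p, + maternal):"]
            for uid, row in top.iterrows():
                lines.append(f"  {uid:<20} score {row['score']:+8.2f}  p_used {row['p_used']:.3g}")
        return "\n".join(lines)
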