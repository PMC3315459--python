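"""Pyrosequencing-style validation calls for candidate imprinted transcripts.

Pyrosequencing quantifies the percent contribution of each allele at a SNP
directly from RNA, independently of RNA-seq.  Two corrections make the call
robust:

* **DNA calibration** — the same assay run on F1 hybrid genomic DNA (a true
  50:50 template) measures the assay's intrinsic bias; RNA percentages are
  expressed relative to the mean DNA percentage, so a transcript whose RNA
  reads 57% B against a DNA baseline of 57% shows no allelic bias at all.
* **Replicate-derived threshold** — the detection threshold is k = 2
  standard deviations of the difference in allelic ratio between biological
  replicates, i.e. the assay's own reproducibility.

A transcript is called imprinted when, in *every* replicate pairing, the
DNA-corrected biases of the two reciprocal crosses point in opposite
directions and differ by more than the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Default threshold in percentage points: 2 SD of replicate-to-replicate
#: variation in allelic ratio, as calibrated on biological replicates.
DEFAULT_THRESHOLD_PCT = 5.02


@dataclass(frozen=True)
class PyroAssay:
    """All measurements for one validation assay.

    ``rna_bias`` maps (cross, replicate) to the percent B-allele measured in
    RNA; ``dna_bias`` lists percent B-allele in hybrid genomic DNA, one per
    DNA replicate.
    """

    assay_id: str
    rna_bias: Mapping[tuple[str, int], float]
    dna_bias: tuple[float, ...]
    threshold_pct: float = DEFAULT_THRESHOLD_PCT

    def __post_init__(self):
        vals = list(self.rna_bias.values()) + list(self.dna_bias)
        if any(not 0 <= v <= 100 for v in vals):
            raise ValidationError(f"assay {self.assay_id!r}: percentages must lie in [0, 100]")
        if not self.dna_bias:
            raise ValidationError(f"assay {self.assay_id!r}: at least one DNA measurement required")
        crosses = {c for c, _ in self.rna_bias}
        if not {"BxC", "CxB"} <= crosses:
            raise ValidationError(f"assay {self.assay_id!r}: both crosses must be measured")


@dataclass(frozen=True)
class PyroCall:
    assay_id: str
    status: Literal["imprinted", "not_imprinted"]
    delta_pct: float  # smallest |corrected BxC - corrected CxB| over replicate pairings
    z_units: float  # delta in units of the replicate SD (threshold / 2 per SD)
    direction: Literal["maternal", "paternal", "none"]


def replicate_threshold(paired_biases: Sequence[tuple[float, float]], k: float = 2.0) -> float:
    """Detection threshold as ``k`` SD of replicate-difference variation.

    ``paired_biases`` are (replicate 1, replicate 2) allelic percentages for
    the same assays on independent biological replicates.
    """
    if len(paired_biases) < 2:
        raise ValidationError("at least two replicate pairs required to estimate variance")
    diffs = np.array([a - b for a, b in paired_biases], dtype=float)
    return float(k * diffs.std(ddof=1))


def dna_correct(rna_pct: float, dna_pcts: Sequence[float]) -> float:
    """Allelic bias relative to the DNA-defined null, in percentage points.

    Positive values mean excess of the B allele over the assay's 50:50
    baseline; DNA replicate percentages are averaged before subtraction.
    """
    if len(dna_pcts) == 0:
        raise ValidationError("at least one DNA measurement required")
    return float(rna_pct - np.mean(dna_pcts))


def call_pyro(assay: PyroAssay, per_replicate: bool = True) -> PyroCall:
    """Apply the reciprocal-direction, threshold-exceeding decision rule.

    With ``per_replicate`` (default) every pairing of a BxC with a CxB
    replicate must independently satisfy: opposite-signed DNA-corrected
    biases and an absolute difference above ``threshold_pct``. The averaged
    mode tests replicate-mean corrected biases instead.
    """
    bxc = {r: dna_correct(v, assay.dna_bias) for (c, r), v in assay.rna_bias.items() if c == "BxC"}
    cxb = {r: dna_correct(v, assay.dna_bias) for (c, r), v in assay.rna_bias.items() if c == "CxB"}
    if per_replicate:
        pairings = [(a, b) for a in bxc.values() for b in cxb.values()]
    else:
        pairings = [(float(np.mean(list(bxc.values()))), float(np.mean(list(cxb.values()))))]

    deltas = [abs(a - b) for a, b in pairings]
    opposite = [a * b < 0 for a, b in pairings]
    delta_pct = min(deltas)
    ok = all(opposite) and all(d > assay.threshold_pct for d in deltas)

    if ok:
        # BxC corrected > 0 means B (the maternal strain in BxC) is over-
        # represented: with CxB biased the other way this is maternal bias.
        direction = "maternal" if min(bxc.values()) > 0 else "paternal"
    else:
        direction = "none"
    sd = assay.threshold_pct / 2.0
    z_units = delta_pct / sd if sd > 0 else float("inf")
    return PyroCall(
        assay_id=assay.assay_id,
        status="imprinted" if ok else "not_imprinted",
        delta_pct=float(delta_pct),
        z_units=float(z_units),
        direction=direction,
    )


def assays_from_table(table: pd.DataFrame, threshold_pct: float = DEFAULT_THRESHOLD_PCT) -> list[PyroAssay]:
    """Build :class:`PyroAssay` objects from the flat measurement TSV."""
    assays = []
    for assay_id, group in table.groupby("assay_id", sort=False):
        rna = group[group["material"] == "RNA"]
        dna = group[group["material"] == "DNA"]
        assays.append(
            PyroAssay(
                assay_id=str(assay_id),
                rna_bias={
                    (str(r["cross"]), int(r["replicate"])): float(r["pct_B"])
                    for _, r in rna.iterrows()
                },
                dna_bias=tuple(float(v) for v in dna["pct_B"]),
                threshold_pct=threshold_pct,
            )
        )
    return assays


def call_pyro_table(table: pd.DataFrame, threshold_pct: float = DEFAULT_THRESHOLD_PCT, per_replicate: bool = True) -> pd.DataFrame:
    """Call every assay in a measurement table; one output row per assay."""
    calls = [call_pyro(a, per_replicate=per_replicate) for a in assays_from_table(table, threshold_pct)]
    return pd.DataFrame(
        [
            {
                "assay_id": c.assay_id,
                "delta_pct": c.delta_pct,
                "z_units": c.z_units,
                "status": c.status,
                "direction": c.direction,
            }
            for c in calls
        ]
    )
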