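"""Synthetic reciprocal-cross allelic count datasets with known truth.

The generator emulates the statistical structure that drives imprinting
detection and its failure modes.  For SNP k of gene g in sample s, the
probability that a read carries the B (C57BL/6J) allele is

    theta = logistic( s_g + e_k + b_{g,s} + I_g * beta_g * u )

where

* ``s_g``       — per-gene strain effect (cross-symmetric cis bias),
* ``e_k``       — per-SNP systematic offset shared by *all* samples
                  (sequence-dependent library/alignment bias; inflates
                  same-exon discordance but, being identical in both
                  crosses, cannot mimic imprinting),
* ``b_{g,s}``   — per-sample-by-gene biological deviation (this is what
                  produces reciprocal-looking false positives in mock
                  comparisons),
* ``I_g beta_g u`` — the parent-of-origin effect: ``u`` is +1 when the
  expressed parental allele is B in that sample's cross (and the sample's
  sex matches, for sex-specific genes), -1 when it is C, 0 otherwise.

Counts are beta-binomial with overdispersion ``rho`` (binomial at rho = 0),
at per-SNP-per-sample depths drawn log-normally.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io import GeneModel

DEFAULT_SAMPLES = (
    ("BxC_M1", "BxC", "M", "brain", 1),
    ("BxC_F1", "BxC", "F", "brain", 1),
    ("CxB_M1", "CxB", "M", "brain", 1),
    ("CxB_F1", "CxB", "F", "brain", 1),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a reciprocal-cross dataset.

    Noise defaults describe a plausibly messy bulk RNA-seq experiment:
    moderate cis strain effects, sequence-dependent per-SNP offsets large
    enough to corrupt same-exon concordance, and mild biological variation
    plus overdispersion. Set ``snp_bias_sd = bio_sd = rho = 0`` for the pure
    random-sampling regime.
    """

    n_genes: int = 200
    snps_per_gene_mean: float = 3.0
    snps_per_gene_max: int = 8
    #: candidate gaps (bp) between consecutive SNPs; values <= 40 create
    #: pairs the concordance analysis must exclude.
    snp_spacing_choices: tuple[int, ...] = (25, 60, 120, 300)
    depth_median: float = 50.0
    depth_log_sd: float = 1.0
    frac_imprinted: float = 0.05
    beta_imprint_mean: float = 2.5
    beta_imprint_sd: float = 0.5
    frac_sex_specific: float = 0.0
    frac_known: float = 1.0  # fraction of imprinted genes in the "known" catalog
    strain_effect_sd: float = 0.3
    snp_bias_sd: float = 0.0
    bio_sd: float = 0.0
    rho: float = 0.0
    samples: tuple[tuple[str, str, str, str, int], ...] = DEFAULT_SAMPLES
    chroms: tuple[str, ...] = ("chr1", "chr2", "chr3", "chr4", "chr5")
    seed: int | None = None

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not 0 <= self.frac_imprinted <= 1:
            raise ConfigError("frac_imprinted must lie in [0, 1]")
        if not 0 <= self.frac_sex_specific <= 1:
            raise ConfigError("frac_sex_specific must lie in [0, 1]")
        if not 0 <= self.frac_known <= 1:
            raise ConfigError("frac_known must lie in [0, 1]")
        if not 0 <= self.rho < 1:
            raise ConfigError("rho must lie in [0, 1)")
        for name in ("strain_effect_sd", "snp_bias_sd", "bio_sd", "depth_log_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.snps_per_gene_max < 1:
            raise ConfigError("snps_per_gene_max must be >= 1")

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.samples), columns=["sample_id", "cross", "sex", "tissue", "replicate"]
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Generative parameters realized for one dataset."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strain_effect, imprinted, direction, beta, sex_specific, target_sex, known
    snp_effects: pd.DataFrame  # snp_id, gene_id, systematic_offset
    bio_effects: pd.DataFrame  # gene_id, sample_id, deviation

    def catalog(self) -> pd.DataFrame:
        """Known-imprinted-gene catalog derived from the truth table."""
        known = self.genes[self.genes["known"]]
        return pd.DataFrame(
            {
                "gene_id": known["gene_id"],
                "name": known["gene_id"],
                "chrom": known["chrom"],
                "start": known["start"],
                "end": known["end"],
                "expressed_allele": known["direction"],
            }
        ).reset_index(drop=True)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _parental_sign(cross: str, direction: str) -> int:
    """+1 when the expressed parental allele is B in this cross, else -1."""
    maternal_is_b = cross == "BxC"
    if direction == "maternal":
        return 1 if maternal_is_b else -1
    return -1 if maternal_is_b else 1


def generate(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[GeneModel], SyntheticTruth]:
    """Draw one dataset: (counts, SNP table, gene models, truth).

    The SNP table already carries gene/exon assignment (the generator knows
    it); :func:`recimprint.io.assign_snps` on the returned models must
    reproduce it, which the tests exercise.
    """
    rng = np.random.default_rng(config.seed)
    samples = config.samples_frame()

    # --- gene-level truth -------------------------------------------------
    gene_ids = np.array([f"gene{g:05d}" for g in range(config.n_genes)])
    strain_effects = rng.normal(0.0, config.strain_effect_sd, config.n_genes)
    imprinted = rng.random(config.n_genes) < config.frac_imprinted
    directions = np.where(rng.random(config.n_genes) < 0.5, "maternal", "paternal")
    betas = np.clip(rng.normal(config.beta_imprint_mean, config.beta_imprint_sd, config.n_genes), 0.1, None)
    sex_specific = imprinted & (rng.random(config.n_genes) < config.frac_sex_specific)
    target_sex = np.where(rng.random(config.n_genes) < 0.5, "M", "F")
    known = imprinted & (rng.random(config.n_genes) < config.frac_known)

    # --- layout -----------------------------------------------------------
    n_snps_per_gene = np.minimum(
        1 + rng.poisson(max(config.snps_per_gene_mean - 1.0, 0.0), config.n_genes),
        config.snps_per_gene_max,
    )
    chrom_of = np.array([config.chroms[g % len(config.chroms)] for g in range(config.n_genes)])
    cursor = {c: 1000 for c in config.chroms}
    models: list[GeneModel] = []
    snp_rows = []
    bases = np.array(list("ACGT"))
    for g in range(config.n_genes):
        chrom = chrom_of[g]
        start = cursor[chrom]
        gaps = rng.choice(config.snp_spacing_choices, size=max(n_snps_per_gene[g] - 1, 0))
        positions = start + 50 + np.concatenate([[0], np.cumsum(gaps)]).astype(int)
        end = int(positions[-1]) + 50
        # split SNP runs into exons of at most 3 SNPs to exercise collapsing;
        # margin kept below half the smallest SNP gap so exons never overlap
        margin = max(1, min(10, (min(config.snp_spacing_choices) - 1) // 2))
        exon_bounds = []
        for i in range(0, len(positions), 3):
            chunk = positions[i : i + 3]
            exon_bounds.append((int(chunk[0]) - margin, int(chunk[-1]) + margin))
        models.append(
            GeneModel(
                gene_id=gene_ids[g],
                chrom=chrom,
                strand="+" if g % 2 == 0 else "-",
                exons=tuple(exon_bounds),
                coding=True,
                known_imprinted=directions[g] if known[g] else None,
            )
        )
        for j, pos in enumerate(positions):
            allele_b = rng.choice(bases)
            allele_c = rng.choice(bases[bases != allele_b])
            snp_rows.append(
                {
                    "chrom": chrom,
                    "pos": int(pos),
                    "snp_id": f"{gene_ids[g]}_snp{j}",
                    "allele_B": allele_b,
                    "allele_C": allele_c,
                    "gene_id": gene_ids[g],
                    "exon_id": f"{gene_ids[g]}:exon{j // 3}",
                }
            )
        cursor[chrom] = end + 5000
    snps = pd.DataFrame(snp_rows)

    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chrom_of,
            "start": [m.start for m in models],
            "end": [m.end for m in models],
            "strain_effect": strain_effects,
            "imprinted": imprinted,
            "direction": np.where(imprinted, directions, "none"),
            "beta": np.where(imprinted, betas, 0.0),
            "sex_specific": sex_specific,
            "target_sex": np.where(sex_specific, target_sex, ""),
            "known": known,
        }
    )

    # --- per-SNP and per-sample-by-gene effects ---------------------------
    snp_offsets = rng.normal(0.0, config.snp_bias_sd, len(snps))
    snp_effects = pd.DataFrame(
        {"snp_id": snps["snp_id"], "gene_id": snps["gene_id"], "systematic_offset": snp_offsets}
    )
    n_samples = len(samples)
    bio = rng.normal(0.0, config.bio_sd, (config.n_genes, n_samples))
    bio_effects = pd.DataFrame(
        {
            "gene_id": np.repeat(gene_ids, n_samples),
            "sample_id": np.tile(samples["sample_id"].to_numpy(), config.n_genes),
            "deviation": bio.ravel(),
        }
    )

    # --- counts -----------------------------------------------------------
    gene_index = {gid: g for g, gid in enumerate(gene_ids)}
    gene_of_snp = snps["gene_id"].map(gene_index).to_numpy()
    count_frames = []
    for s_idx, sample in enumerate(samples.itertuples(index=False)):
        u = np.zeros(config.n_genes)
        for g in range(config.n_genes):
            if not imprinted[g]:
                continue
            if sex_specific[g] and sample.sex != target_sex[g]:
                continue
            u[g] = _parental_sign(sample.cross, directions[g])
        logit = (
            strain_effects[gene_of_snp]
            + snp_offsets
            + bio[gene_of_snp, s_idx]
            + (imprinted[gene_of_snp] * betas[gene_of_snp] * u[gene_of_snp])
        )
        theta = _logistic(logit)
        depth = np.maximum(
            np.round(rng.lognormal(np.log(config.depth_median), config.depth_log_sd, len(snps))), 1
        ).astype(np.int64)
        if config.rho > 0:
            a = theta * (1 - config.rho) / config.rho
            b = (1 - theta) * (1 - config.rho) / config.rho
            p_draw = rng.beta(a, b)
        else:
            p_draw = theta
        count_b = rng.binomial(depth, p_draw)
        count_frames.append(
            pd.DataFrame(
                {
                    "snp_id": snps["snp_id"],
                    "sample_id": sample.sample_id,
                    "count_B": count_b,
                    "count_C": depth - count_b,
                }
            )
        )
    counts = pd.concat(count_frames, ignore_index=True)
    truth = SyntheticTruth(genes=truth_genes, snp_effects=snp_effects, bio_effects=bio_effects)
    return counts, snps, models, truth


def truth_eval(
    table: pd.DataFrame,
    truth: SyntheticTruth,
    thresholds: Sequence[float],
    min_reads: int = 10,
) -> pd.DataFrame:
    """Confusion counts of a gene-level comparison table against the truth.

    ``table`` is a :func:`recimprint.calls.comparison_table` over genes
    (index = gene_id). Per threshold: a gene is called positive when it is
    powered, reciprocal, and significant in both samples; truth positives
    are the genes simulated as imprinted. Reports TP/FP/FN/TN plus the true
    FDR and recall among powered genes.
    """
    truth_map = truth.genes.set_index("gene_id")["imprinted"]
    unknown = set(table.index) - set(truth_map.index)
    if unknown:
        raise ValidationError(f"calls reference genes absent from truth: {sorted(unknown)[:5]}")
    is_true = truth_map.reindex(table.index).to_numpy(bool)
    powered = ((table["n_1"] >= min_reads) & (table["n_2"] >= min_reads)).to_numpy()
    rows = []
    for t in thresholds:
        called = (
            powered
            & table["reciprocal"].to_numpy()
            & (table["p_1"] < t).to_numpy()
            & (table["p_2"] < t).to_numpy()
        )
        tp = int((called & is_true).sum())
        fp = int((called & ~is_true).sum())
        fn = int((~called & powered & is_true).sum())
        tn = int((~called & powered & ~is_true).sum())
        rows.append(
            {
                "threshold": t,
                "TP": tp,
                "FP": fp,
                "FN": fn,
                "TN": tn,
                "true_fdr": fp / (tp + fp) if tp + fp else float("nan"),
                "recall": tp / (tp + fn) if tp + fn else float("nan"),
            }
        )
    return pd.DataFrame(rows)
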