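"""Readers/writers for counts, samples, SNPs, gene models, and catalogs.

Conventions
-----------
* Genomic intervals are 0-based half-open internally (BED native).  SNP
  positions arrive 1-based (VCF ``POS`` or the ``pos`` column of the flat
  TSV) and are shifted by -1 on ingest; writers shift back.
* Allelic counts are labelled ``count_B`` (C57BL/6J allele) and ``count_C``
  (CAST/EiJ allele) regardless of cross direction.
* Strand is carried on gene models but ignored by every statistic: the
  counts are allele-level, not strand-level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import CrossReferenceError, FormatError, ValidationError

VALID_CROSSES = {"BxC", "CxB"}
VALID_SEXES = {"M", "F", "unknown"}
NUCLEOTIDES = {"A", "C", "G", "T"}

COUNT_COLUMNS = ["snp_id", "sample_id", "count_B", "count_C"]
SAMPLE_COLUMNS = ["sample_id", "cross", "sex", "tissue", "replicate"]
SNP_COLUMNS = ["chrom", "pos", "snp_id", "allele_B", "allele_C"]


@dataclass(frozen=True)
class GeneModel:
    """Collapsed gene model: the union of exons over all isoforms.

    ``exons`` are 0-based half-open intervals, sorted and non-overlapping
    after :func:`collapse_gene_models`.
    """

    gene_id: str
    chrom: str
    strand: str = "."
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)
    coding: bool = True
    known_imprinted: str | None = None  # "maternal" | "paternal" | "unknown" | None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def total_exonic_bases(self) -> int:
        return sum(e - s for s, e in self.exons)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV (sample_id, cross, sex, tissue, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, SAMPLE_COLUMNS, "sample table")
    return validate_samples(df)


def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, SAMPLE_COLUMNS, "sample table")
    df = df.copy()
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise CrossReferenceError(f"duplicate sample_id {dup!r}")
    bad_cross = set(df["cross"]) - VALID_CROSSES
    if bad_cross:
        raise ValidationError(f"unknown cross value(s) {sorted(bad_cross)}; expected {sorted(VALID_CROSSES)}")
    bad_sex = set(df["sex"]) - VALID_SEXES
    if bad_sex:
        raise ValidationError(f"unknown sex value(s) {sorted(bad_sex)}; expected {sorted(VALID_SEXES)}")
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    if (df["replicate"] < 1).any():
        raise ValidationError("replicate must be >= 1")
    return df


def read_counts(path: str | Path, samples: pd.DataFrame) -> pd.DataFrame:
    """Read and validate a per-SNP allelic count TSV.

    Every ``sample_id`` must exist in ``samples`` and every
    ``(snp_id, sample_id)`` pair must be unique.
    """
    df = pd.read_csv(path, sep="\t")
    return validate_counts(df, samples)


def validate_counts(df: pd.DataFrame, samples: pd.DataFrame | None = None) -> pd.DataFrame:
    _require_columns(df, COUNT_COLUMNS, "count table")
    df = df.copy()
    for col in ("count_B", "count_C"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValidationError(f"{col}: non-numeric count")
        if (vals != vals.round()).any():
            raise ValidationError(f"{col}: counts must be integers")
        if (vals < 0).any():
            raise ValidationError(f"{col}: counts must be non-negative")
        df[col] = vals.astype(np.int64)
    dup = df.duplicated(subset=["snp_id", "sample_id"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise CrossReferenceError(
            f"duplicate count row for (snp_id={row['snp_id']!r}, sample_id={row['sample_id']!r})"
        )
    if samples is not None:
        unknown = set(df["sample_id"]) - set(samples["sample_id"])
        if unknown:
            raise CrossReferenceError(f"count rows reference unknown sample_id(s) {sorted(unknown)}")
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=COUNT_COLUMNS)


def read_snps(path: str | Path) -> pd.DataFrame:
    """Read the flat SNP TSV (chrom, pos [1-based], snp_id, allele_B, allele_C)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str})
    _require_columns(df, SNP_COLUMNS, "SNP table")
    df = df.copy()
    df["pos"] = pd.to_numeric(df["pos"]).astype(np.int64) - 1  # store 0-based
    return validate_snps(df)


def validate_snps(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a SNP table already in internal (0-based) coordinates."""
    _require_columns(df, SNP_COLUMNS, "SNP table")
    for col in ("allele_B", "allele_C"):
        bad = set(df[col]) - NUCLEOTIDES
        if bad:
            raise ValidationError(f"{col}: invalid nucleotide(s) {sorted(bad)}")
    if (df["allele_B"] == df["allele_C"]).any():
        snp = df.loc[df["allele_B"] == df["allele_C"], "snp_id"].iloc[0]
        raise ValidationError(f"SNP {snp!r}: allele_B equals allele_C")
    if (df["pos"] < 0).any():
        raise ValidationError("SNP position out of range after 1-based -> 0-based conversion")
    return df


def write_snps(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["pos"] = out["pos"] + 1  # back to 1-based on disk
    cols = SNP_COLUMNS + [c for c in ("gene_id", "exon_id") if c in out.columns]
    out.to_csv(path, sep="\t", index=False, columns=cols)


def read_snps_vcf(path: str | Path, strain_map: dict[str, str] | str | Path) -> pd.DataFrame:
    """Read SNPs from a minimal VCF plus a REF/ALT -> strain assignment.

    ``strain_map`` maps ``"REF"``/``"ALT"`` to ``"B"``/``"C"`` (e.g. the B
    allele is the reference when reads were aligned to the C57BL/6J
    assembly), or is a path to a two-column TSV with columns ``role``
    (REF/ALT) and ``strain`` (B/C).
    """
    import pysam

    if not isinstance(strain_map, dict):
        mdf = pd.read_csv(strain_map, sep="\t", dtype=str)
        _require_columns(mdf, ["role", "strain"], "strain map")
        strain_map = dict(zip(mdf["role"], mdf["strain"]))
    if set(strain_map.keys()) != {"REF", "ALT"} or set(strain_map.values()) != {"B", "C"}:
        raise FormatError("strain map must assign REF and ALT to strains B and C")

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValidationError(f"SNP {rec.id or rec.pos}: exactly one ALT allele required")
            alleles = {"REF": rec.ref, "ALT": rec.alts[0]}
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos - 1,  # pysam reports 1-based POS
                    "snp_id": rec.id if rec.id else f"{rec.chrom}:{rec.pos}",
                    "allele_B": alleles["REF"] if strain_map["REF"] == "B" else alleles["ALT"],
                    "allele_C": alleles["REF"] if strain_map["REF"] == "C" else alleles["ALT"],
                }
            )
    return validate_snps(pd.DataFrame(rows, columns=SNP_COLUMNS))


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if s >= e:
            raise ValidationError(f"invalid interval [{s}, {e}): start must be < end")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def collapse_gene_models(isoforms: Iterable[GeneModel]) -> list[GeneModel]:
    """Collapse transcript isoforms into one model per gene.

    The collapsed exon set is the interval union of all isoform exons, so a
    read mapping anywhere in any isoform is attributed to the gene. A gene
    is flagged coding if any isoform is.
    """
    by_gene: dict[str, list[GeneModel]] = {}
    order: list[str] = []
    for iso in isoforms:
        if iso.gene_id not in by_gene:
            order.append(iso.gene_id)
        by_gene.setdefault(iso.gene_id, []).append(iso)
    out = []
    for gid in order:
        group = by_gene[gid]
        chroms = {g.chrom for g in group}
        if len(chroms) > 1:
            raise ValidationError(f"gene {gid!r}: isoforms on multiple chromosomes {sorted(chroms)}")
        exons = _merge_intervals(iv for g in group for iv in g.exons)
        strands = {g.strand for g in group}
        out.append(
            GeneModel(
                gene_id=gid,
                chrom=group[0].chrom,
                strand=strands.pop() if len(strands) == 1 else ".",
                exons=exons,
                coding=any(g.coding for g in group),
                known_imprinted=next((g.known_imprinted for g in group if g.known_imprinted), None),
            )
        )
    return out


def assign_snps(snps: pd.DataFrame, models: Sequence[GeneModel]) -> pd.DataFrame:
    """Assign each SNP to every gene whose collapsed exons contain it.

    Returns one row per (SNP, gene) assignment with ``gene_id`` and
    ``exon_id`` filled (``exon_id = "<gene>:exon<i>"`` by exon rank).
    Unassigned SNPs are retained with empty ``gene_id``.  SNPs landing in
    more than one overlapping gene appear once per gene and are flagged
    ``multi_gene``.
    """
    trees: dict[str, IntervalTree] = {}
    for m in models:
        tree = trees.setdefault(m.chrom, IntervalTree())
        for i, (s, e) in enumerate(m.exons):
            tree[s:e] = (m.gene_id, f"{m.gene_id}:exon{i}")
    rows = []
    for rec in snps.itertuples(index=False):
        hits = sorted(trees[rec.chrom][rec.pos]) if rec.chrom in trees else []
        base = rec._asdict()
        if not hits:
            rows.append({**base, "gene_id": "", "exon_id": "", "multi_gene": False})
            continue
        genes_hit = {iv.data[0] for iv in hits}
        for iv in hits:
            rows.append(
                {**base, "gene_id": iv.data[0], "exon_id": iv.data[1], "multi_gene": len(genes_hit) > 1}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BED12 gene models


def read_gene_models_bed12(path: str | Path) -> list[GeneModel]:
    """Read collapsed gene models from BED12.

    ``thickStart == thickEnd`` encodes a non-coding model; ``itemRgb`` is
    ignored. Exons are reconstructed from blockStarts/blockSizes.
    """
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 requires 12 columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise FormatError(f"{path}:{lineno}: blockCount disagrees with block lists")
            chrom_start = int(start)
            exons = tuple((chrom_start + off, chrom_start + off + sz) for off, sz in zip(starts, sizes))
            if exons[-1][1] != int(end):
                raise FormatError(f"{path}:{lineno}: blocks do not span chromEnd")
            models.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    coding=thick_end > thick_start,
                )
            )
    return models


def write_gene_models_bed12(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start, end = m.start, m.end
            sizes = ",".join(str(e - s) for s, e in m.exons)
            offsets = ",".join(str(s - start) for s, _ in m.exons)
            thick = (start, end) if m.coding else (start, start)
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(start),
                        str(end),
                        m.gene_id,
                        "0",
                        m.strand if m.strand in "+-" else ".",
                        str(thick[0]),
                        str(thick[1]),
                        "0",
                        str(len(m.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def read_known_catalog(path: str | Path) -> pd.DataFrame:
    """Read the known-imprinted-gene catalog TSV.

    Columns: gene_id, name, chrom, start, end, expressed_allele
    (maternal/paternal/unknown). Coordinates are 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["gene_id", "name", "chrom", "start", "end", "expressed_allele"], "known catalog")
    if (df["start"] >= df["end"]).any():
        raise ValidationError("known catalog: start must be < end")
    return df


def read_pyro_table(path: str | Path) -> pd.DataFrame:
    """Read pyrosequencing measurements (assay_id, cross, replicate, material, pct_B)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["assay_id", "cross", "replicate", "material", "pct_B"], "pyro table")
    bad = set(df["material"]) - {"RNA", "DNA"}
    if bad:
        raise ValidationError(f"pyro table: material must be RNA or DNA, got {sorted(bad)}")
    if ((df["pct_B"] < 0) | (df["pct_B"] > 100)).any():
        raise ValidationError("pyro table: pct_B must lie in [0, 100]")
    return df
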