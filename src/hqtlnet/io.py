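"""Readers and writers for the external formats the pipeline touches.

VCF is read with cyvcf2; the remaining formats (BED3/BED4, BEDPE, TSV
tables, PLINK ``.blocks.det``-style block files) are plain columnar text
handled with pandas. Coordinates are converted to the internal 0-based
half-open convention on ingest and back on egress.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    ExpressionTable,
    GenomicInterval,
    GenotypeTable,
    Loop,
    ParseError,
    RegionCounts,
    RunConfig,
    ValidationError,
)

log = logging.getLogger("hqtlnet")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotypes(vcf_path: str | Path) -> GenotypeTable:
    """Load phased diploid genotypes from a VCF into a :class:`GenotypeTable`.

    Dosage is the count of alternate alleles. Positions are converted to
    0-based. Missing genotypes become -1 haplotypes; records with any
    unphased genotype are flagged in ``phased``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error surface
        raise ParseError(f"{vcf_path}: cannot open VCF ({exc})") from exc

    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    hap1_rows, hap2_rows, phased_rows = [], [], []
    for i, rec in enumerate(vcf):
        if rec.ID is None:
            raise ParseError(f"{vcf_path}: record {i + 1} ({rec.CHROM}:{rec.POS}) has no ID")
        alt = rec.ALT[0] if rec.ALT else "."
        h1 = np.empty(len(samples), dtype=np.int8)
        h2 = np.empty(len(samples), dtype=np.int8)
        ph = np.empty(len(samples), dtype=bool)
        for j, gt in enumerate(rec.genotypes):
            # cyvcf2 genotype: [allele_a, allele_b, phased_flag]
            if len(gt) < 3:
                raise ParseError(
                    f"{vcf_path}: non-diploid GT at record {i + 1} sample {samples[j]}"
                )
            a, b, phased = gt[0], gt[1], bool(gt[-1])
            h1[j] = a if a >= 0 else -1
            h2[j] = b if b >= 0 else -1
            ph[j] = phased or a < 0 or b < 0
        ids.append(rec.ID)
        chroms.append(rec.CHROM)
        poss.append(rec.POS - 1)  # to 0-based
        refs.append(rec.REF)
        alts.append(alt)
        hap1_rows.append(h1)
        hap2_rows.append(h2)
        phased_rows.append(ph)

    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=pd.Index(ids, name="id"),
    )
    n = len(variants)
    hap1 = np.vstack(hap1_rows) if n else np.empty((0, len(samples)), dtype=np.int8)
    hap2 = np.vstack(hap2_rows) if n else np.empty((0, len(samples)), dtype=np.int8)
    phased = np.vstack(phased_rows) if n else np.empty((0, len(samples)), dtype=bool)
    gt = GenotypeTable(variants, samples, hap1, hap2, phased)
    n_unphased = int((~gt.phased).sum())
    if n_unphased:
        warnings.warn(f"{vcf_path}: {n_unphased} unphased genotype(s) flagged")
    return gt


def write_genotypes(gt: GenotypeTable, vcf_path: str | Path) -> None:
    """Write a phased VCF v4.2 (positions back to 1-based)."""
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = pd.unique(gt.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gt.samples)
            + "\n"
        )
        order = np.lexsort((gt.variants["pos"].to_numpy(),
                            gt.variants["chrom"].to_numpy()))
        for i in order:
            row = gt.variants.iloc[i]
            cells = []
            for j in range(gt.n_samples):
                a, b = gt.hap1[i, j], gt.hap2[i, j]
                sep = "|" if gt.phased[i, j] else "/"
                sa = "." if a < 0 else str(int(a))
                sb = "." if b < 0 else str(int(b))
                cells.append(f"{sa}{sep}{sb}")
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t{gt.variants.index[i]}\t"
                f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# BED / BEDPE
# ---------------------------------------------------------------------------

def read_peaks(bed_path: str | Path) -> list[GenomicInterval]:
    """Read a BED3 peak file (0-based half-open, as BED is natively)."""
    rows = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{bed_path}:{ln}: fewer than 3 BED columns")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise ParseError(f"{bed_path}:{ln}: {exc}") from exc
            rows.append(iv)
    _check_sorted_disjoint(rows, bed_path)
    return rows


def _check_sorted_disjoint(ivs: list[GenomicInterval], path) -> None:
    by_chrom: dict[str, int] = {}
    for iv in ivs:
        prev = by_chrom.get(iv.chrom)
        if prev is not None and iv.start < prev:
            raise ValidationError(
                f"{path}: intervals on {iv.chrom} unsorted or overlapping at {iv.start}"
            )
        by_chrom[iv.chrom] = iv.end


def write_bed(intervals, path: str | Path, support=None) -> None:
    """Write BED3, or BED4 with a per-interval support column."""
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            extra = f"\t{support[k]}" if support is not None else ""
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{extra}\n")


def read_loops(bedpe_path: str | Path, mark: str = "H3K27ac") -> list[Loop]:
    """Read loops from BEDPE; PET count is the score (8th) column.

    Interchromosomal rows are skipped with a warning; a non-integer PET
    count is a parse error.
    """
    loops: list[Loop] = []
    n_skipped = 0
    with open(bedpe_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) < 8:
                raise ParseError(f"{bedpe_path}:{ln}: fewer than 8 BEDPE columns")
            if p[0] != p[3]:
                n_skipped += 1
                continue
            try:
                pets = int(p[7])
            except ValueError as exc:
                raise ParseError(
                    f"{bedpe_path}:{ln}: non-integer PET count {p[7]!r}"
                ) from exc
            a = GenomicInterval(p[0], int(p[1]), int(p[2]))
            b = GenomicInterval(p[3], int(p[4]), int(p[5]))
            if a.start > b.start:
                a, b = b, a
            loops.append(Loop(a, b, pets, mark=mark))
    if n_skipped:
        log.warning("%s: skipped %d interchromosomal loop row(s)", bedpe_path, n_skipped)
        warnings.warn(f"{bedpe_path}: skipped {n_skipped} interchromosomal row(s)")
    return loops


def write_loops(loops: list[Loop], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            fh.write(
                f"{lp.anchor_a.chrom}\t{lp.anchor_a.start}\t{lp.anchor_a.end}\t"
                f"{lp.anchor_b.chrom}\t{lp.anchor_b.start}\t{lp.anchor_b.end}\t"
                f".\t{lp.pet_count}\n"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_counts(tsv_path: str | Path, size_factor_path: str | Path | None = None) -> RegionCounts:
    df = pd.read_csv(tsv_path, sep="\t")
    sf = None
    if size_factor_path is not None:
        sft = pd.read_csv(size_factor_path, sep="\t", index_col=0)
        sf = sft.iloc[:, 0]
    try:
        return RegionCounts(df, sf)
    except ValidationError as exc:
        raise ValidationError(f"{tsv_path}: {exc}") from exc


def write_counts(rc: RegionCounts, tsv_path: str | Path,
                 size_factor_path: str | Path | None = None) -> None:
    rc.counts.to_csv(tsv_path, sep="\t", index=False)
    if size_factor_path is not None:
        rc.size_factors.rename("size_factor").to_frame().to_csv(
            size_factor_path, sep="\t", index_label="sample_id"
        )


def read_expression(tsv_path: str | Path,
                    library_size_path: str | Path | None = None) -> ExpressionTable:
    cpm = pd.read_csv(tsv_path, sep="\t", index_col=0)
    libs = None
    if library_size_path is not None:
        libs = pd.read_csv(library_size_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionTable(cpm, libs)


def write_expression(expr: ExpressionTable, tsv_path: str | Path,
                     library_size_path: str | Path | None = None) -> None:
    expr.cpm.to_csv(tsv_path, sep="\t", index_label="gene_id")
    if library_size_path is not None and expr.library_sizes is not None:
        expr.library_sizes.rename("library_size").to_frame().to_csv(
            library_size_path, sep="\t", index_label="sample_id"
        )


def read_catalog(tsv_path: str | Path) -> pd.DataFrame:
    """Risk-catalog index SNPs: columns ``index_snp_id``, ``trait``."""
    df = pd.read_csv(tsv_path, sep="\t")
    for col in ("index_snp_id", "trait"):
        if col not in df.columns:
            raise ParseError(f"{tsv_path}: missing column {col!r}")
    if df.duplicated(["index_snp_id", "trait"]).any():
        raise ValidationError(f"{tsv_path}: duplicate (index_snp_id, trait) rows")
    return df


def write_catalog(catalog: pd.DataFrame, tsv_path: str | Path) -> None:
    catalog.to_csv(tsv_path, sep="\t", index=False)


def read_blocks(tsv_path: str | Path) -> pd.DataFrame:
    """PLINK ``.blocks.det``-style haplotype blocks.

    Expected columns: ``chrom``, ``start`` (1-based bp, converted to
    0-based), ``end``, ``nsnps``, ``snps`` (pipe-separated ids). Returns a
    frame indexed by ``block_id`` with the snp list parsed and a 0-based
    half-open interval.
    """
    df = pd.read_csv(tsv_path, sep="\t")
    for col in ("chrom", "start", "end", "nsnps", "snps"):
        if col not in df.columns:
            raise ParseError(f"{tsv_path}: missing column {col!r}")
    df = df.copy()
    df["snps"] = df["snps"].map(lambda s: s.split("|"))
    bad = df["snps"].map(len) != df["nsnps"]
    if bad.any():
        raise ValidationError(f"{tsv_path}: nsnps disagrees with snp list length")
    df["start"] = df["start"].astype(int) - 1  # to 0-based
    df["end"] = df["end"].astype(int)
    df.index = pd.Index([f"block{k}" for k in range(len(df))], name="block_id")
    return df


def write_blocks(blocks: pd.DataFrame, tsv_path: str | Path) -> None:
    out = blocks.copy()
    out["snps"] = out["snps"].map("|".join)
    out["start"] = out["start"].astype(int) + 1  # back to 1-based
    out.to_csv(tsv_path, sep="\t", index=False)


def read_gene_annotation(tsv_path: str | Path) -> pd.DataFrame:
    """Gene model table: gene_id, chrom, tss, tes (0-based bp), strand."""
    df = pd.read_csv(tsv_path, sep="\t", index_col="gene_id")
    for col in ("chrom", "tss", "tes", "strand"):
        if col not in df.columns:
            raise ParseError(f"{tsv_path}: missing column {col!r}")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValidationError(f"{tsv_path}: strand must be '+' or '-'")
    return df


def write_gene_annotation(genes: pd.DataFrame, tsv_path: str | Path) -> None:
    genes.to_csv(tsv_path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Config and run manifests
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def write_manifest(path: str | Path, stage: str, cfg: RunConfig, **extra) -> None:
    """JSON run manifest echoing the seed and parameters of a stage."""
    payload = {"stage": stage, "config": cfg.to_dict(), **extra}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
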