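"""Core domain containers shared across the pipeline.

All genomic coordinates are stored 0-based half-open internally. VCF
positions are converted on ingest (pos - 1) and egress (pos + 1); BED and
BEDPE are native.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

VALID_MARKS = ("H3K27ac", "H3K4me1", "CTCF")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


class ParseError(ValueError):
    """Raised when an external file cannot be parsed."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class Variant:
    """A biallelic variant with the metadata the enrichment stage bins on.

    ``tss_distance`` is the absolute distance (bp) to the nearest 5'
    transcription start site; ``maf`` is the minor allele frequency.
    """

    id: str
    chrom: str
    pos: int  # 0-based internally
    ref_allele: str
    alt_allele: str
    maf: float = np.nan
    tss_distance: float = np.nan

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"variant {self.id}: negative position")
        if not np.isnan(self.maf) and not (0.0 <= self.maf <= 0.5):
            raise ValidationError(f"variant {self.id}: MAF {self.maf} outside [0, 0.5]")


@dataclass(frozen=True)
class Loop:
    """A chromatin loop: two anchors joined by ``pet_count`` paired-end tags."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    pet_count: int
    mark: str = "H3K27ac"

    def __post_init__(self) -> None:
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValidationError("loop anchors must be intrachromosomal")
        if self.anchor_a.start > self.anchor_b.start:
            raise ValidationError("anchor_a must precede anchor_b")
        if self.pet_count < 0:
            raise ValidationError("pet_count must be non-negative")
        if self.mark not in VALID_MARKS:
            raise ValidationError(f"unknown mark {self.mark!r}")

    @property
    def span(self) -> float:
        """Distance between anchor midpoints."""
        return self.anchor_b.midpoint - self.anchor_a.midpoint


AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


def is_autosome(chrom: str) -> bool:
    return chrom in AUTOSOMES


class GenotypeTable:
    """Phased diploid genotypes for variants x samples.

    Parameters
    ----------
    variants
        DataFrame indexed by variant id with columns ``chrom``, ``pos``
        (0-based), ``ref``, ``alt`` and optionally ``maf``, ``tss_distance``.
    samples
        Sample identifiers, one per haplotype-pair column.
    hap1, hap2
        Arrays of shape (n_variants, n_samples) holding 0 (ref), 1 (alt)
        or -1 (missing).
    phased
        Boolean array (n_variants, n_samples); False marks genotypes whose
        haplotype order is not meaningful.
    """

    def __init__(
        self,
        variants: pd.DataFrame,
        samples: list[str],
        hap1: np.ndarray,
        hap2: np.ndarray,
        phased: np.ndarray | None = None,
    ) -> None:
        variants = variants.copy()
        if variants.index.has_duplicates:
            dups = variants.index[variants.index.duplicated()].tolist()
            raise ValidationError(f"duplicate variant ids: {dups[:5]}")
        hap1 = np.asarray(hap1, dtype=np.int8)
        hap2 = np.asarray(hap2, dtype=np.int8)
        n_var, n_samp = hap1.shape
        if hap2.shape != (n_var, n_samp) or len(variants) != n_var:
            raise ValidationError("haplotype array shapes disagree with variant table")
        if len(samples) != n_samp:
            raise ValidationError("sample list length disagrees with haplotype arrays")
        if phased is None:
            phased = np.ones((n_var, n_samp), dtype=bool)
        self.variants = variants
        self.samples = list(samples)
        self.hap1 = hap1
        self.hap2 = hap2
        self.phased = np.asarray(phased, dtype=bool)
        if "maf" not in self.variants.columns or self.variants["maf"].isna().all():
            self.variants["maf"] = self.maf()

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosages(self) -> np.ndarray:
        """Alternate-allele dosage matrix (0/1/2; -1 where missing)."""
        d = self.hap1 + self.hap2
        d[(self.hap1 < 0) | (self.hap2 < 0)] = -1
        return d.astype(np.int8)

    def dosage(self, variant_id: str) -> np.ndarray:
        i = self.variants.index.get_loc(variant_id)
        d = self.hap1[i] + self.hap2[i]
        d = d.astype(np.int8)
        d[(self.hap1[i] < 0) | (self.hap2[i] < 0)] = -1
        return d

    def haplotypes(self, variant_id: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.variants.index.get_loc(variant_id)
        return self.hap1[i], self.hap2[i]

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency from non-missing haplotypes."""
        out = np.full(self.n_variants, np.nan)
        for i in range(self.n_variants):
            h = np.concatenate([self.hap1[i], self.hap2[i]])
            h = h[h >= 0]
            if h.size == 0:
                continue
            p = h.mean()
            out[i] = min(p, 1.0 - p)
        return out

    def is_het(self, variant_id: str) -> np.ndarray:
        h1, h2 = self.haplotypes(variant_id)
        return (h1 >= 0) & (h2 >= 0) & (h1 != h2)

    def subset(self, variant_ids: Iterable[str]) -> "GenotypeTable":
        ids = list(variant_ids)
        idx = [self.variants.index.get_loc(v) for v in ids]
        return GenotypeTable(
            self.variants.iloc[idx],
            self.samples,
            self.hap1[idx],
            self.hap2[idx],
            self.phased[idx],
        )


class RegionCounts:
    """Allele-specific and region-total read counts per SNP region x sample.

    ``counts`` is a long-format frame with columns ``snp_id``, ``sample_id``,
    ``ref_as``, ``alt_as``, ``total_region``. Allele-specific reads can only
    arise in heterozygotes; homozygous samples must carry ref_as = alt_as = 0
    (validated against genotypes where available).
    """

    REQUIRED = ["snp_id", "sample_id", "ref_as", "alt_as", "total_region"]

    def __init__(self, counts: pd.DataFrame, size_factors: pd.Series | None = None):
        missing = [c for c in self.REQUIRED if c not in counts.columns]
        if missing:
            raise ValidationError(f"counts table missing columns: {missing}")
        counts = counts.copy()
        for c in ("ref_as", "alt_as", "total_region"):
            if (counts[c] < 0).any():
                raise ValidationError(f"negative values in column {c!r}")
        bad = counts["ref_as"] + counts["alt_as"] > counts["total_region"]
        if bad.any():
            row = counts[bad].iloc[0]
            raise ValidationError(
                f"ref_as + alt_as > total_region for snp {row['snp_id']} "
                f"sample {row['sample_id']}"
            )
        if counts.duplicated(["snp_id", "sample_id"]).any():
            raise ValidationError("duplicate (snp_id, sample_id) rows")
        self.counts = counts
        samples = pd.Index(counts["sample_id"].unique())
        if size_factors is None:
            size_factors = pd.Series(1.0, index=samples)
        self.size_factors = size_factors.astype(float)
        if (self.size_factors <= 0).any():
            raise ValidationError("size factors must be positive")

    @property
    def snp_ids(self) -> list[str]:
        return list(dict.fromkeys(self.counts["snp_id"]))

    def for_snp(self, snp_id: str, samples: list[str]) -> pd.DataFrame:
        """Counts for one SNP aligned to ``samples`` order (absent -> zeros)."""
        sub = self.counts[self.counts["snp_id"] == snp_id].set_index("sample_id")
        sub = sub.reindex(samples)
        sub[["ref_as", "alt_as", "total_region"]] = (
            sub[["ref_as", "alt_as", "total_region"]].fillna(0).astype(int)
        )
        sub["size_factor"] = self.size_factors.reindex(samples).fillna(1.0).to_numpy()
        return sub


@dataclass
class ExpressionTable:
    """Library-size-scaled expression (CPM), genes x samples.

    ``library_sizes`` (total mapped reads per sample) allow de-normalising
    CPM back to expected counts for negative-binomial modelling.
    """

    cpm: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.cpm.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression table")
        if self.library_sizes is not None:
            self.library_sizes = self.library_sizes.reindex(self.cpm.columns)
            if self.library_sizes.isna().any() or (self.library_sizes <= 0).any():
                raise ValidationError("library sizes must be positive for all samples")

    @property
    def samples(self) -> list[str]:
        return list(self.cpm.columns)

    def counts(self) -> pd.DataFrame:
        """Expected integer counts recovered from CPM via library sizes."""
        if self.library_sizes is None:
            raise ValidationError("library sizes required to recover counts")
        scale = self.library_sizes / 1e6
        return (self.cpm * scale).round().astype(np.int64)


@dataclass
class RunConfig:
    """All stage parameters with defaults at the pipeline's reference values."""

    seed: int = 0
    # consensus peaks
    min_support: int = 13
    merge_gap: int = 147
    # combined haplotype test
    min_as_reads: int = 15
    min_as_reads_replication: int = 10
    fwer_significant: float = 0.1
    fwer_suggestive: float = 0.2
    es_bound: float = 64.0
    # risk enrichment
    n_bins_maf: int = 10
    n_bins_tss: int = 10
    n_perm_enrichment: int = 1000
    # eQTL scan
    cis_window: int = 1_000_000
    maf_min: float = 0.05
    cv_min: float = 0.15
    fdr_q: float = 0.05
    r2_prune: float = 0.8
    # joint models
    n_perm_d2: int = 10_000
    min_block_variants: int = 6
    dprime_strong: float = 0.8
    r2_independent: float = 0.6
    dprime_independent: float = 0.6
    # loops
    min_pets: int = 4
    min_loop_span: int = 5_000
    max_loop_span: int = 2_000_000
    promoter_upstream: int = 10_000

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
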