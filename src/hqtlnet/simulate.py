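"""Synthetic-data generators with the statistical structure the pipeline assumes.

The generators emulate the study design the pipeline targets: ~25
lymphoblastoid cell lines for the histone-QTL arm and ~358 individuals for
the expression arm. LD is modelled by finite haplotype pools per block
(each sample draws two haplotypes independently from the block's pool), so
within-block LD is set exactly by pool composition and blocks are mutually
independent. Allele-specific counts follow the beta-binomial/negative-
binomial generative model of the combined haplotype test; expression is
negative binomial with additive eQTL/hQTL effects on the log scale plus a
multiplicative interaction; library sizes are log-normal around 30 million
reads.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ExpressionTable,
    GenomicInterval,
    GenotypeTable,
    Loop,
    RegionCounts,
    ValidationError,
)

MEAN_LIBRARY_SIZE = 30e6  # reads per RNA-seq sample


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass
class BlockSpec:
    """One haplotype block: a finite pool of haplotypes with frequencies."""

    chrom: str
    start: int
    haplotypes: list[tuple[int, ...]]
    frequencies: list[float]
    spacing: int = 500

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise ValidationError("empty haplotype pool")
        lens = {len(h) for h in self.haplotypes}
        if len(lens) != 1:
            raise ValidationError("pool haplotypes must have equal length")
        freqs = np.asarray(self.frequencies, dtype=float)
        if freqs.size != len(self.haplotypes) or np.any(freqs < 0):
            raise ValidationError("frequencies must be non-negative, one per haplotype")
        if abs(freqs.sum() - 1.0) > 1e-8:
            raise ValidationError("pool frequencies must sum to 1")

    @property
    def n_variants(self) -> int:
        return len(self.haplotypes[0])


@dataclass
class HqtlSpec:
    """Allelic-imbalance effect at one SNP region.

    ``log2_effect`` is log2(alpha/beta); ``as_overdispersion`` is the
    beta-binomial rho; ``depth_dispersion`` the negative-binomial phi.
    """

    snp_id: str
    log2_effect: float = 0.0
    as_overdispersion: float = 0.05
    depth_dispersion: float = 20.0
    mean_as_depth: float = 30.0
    mean_region_depth: float = 200.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.as_overdispersion < 1.0):
            raise ValidationError("as_overdispersion must lie in [0, 1)")
        if min(self.mean_as_depth, self.mean_region_depth) <= 0:
            raise ValidationError("depths must be positive")


@dataclass
class GeneModel:
    """Negative-binomial expression model for one gene.

    log mean counts = mu0 + beta_e * d_e + beta_h * d_h + gamma * d_e * d_h,
    with 0/1/2 dosages, before the library-size offset.
    """

    gene_id: str
    mu0: float = 4.0
    eqtl_snp: str | None = None
    beta_e: float = 0.0
    hqtl_snp: str | None = None
    beta_h: float = 0.0
    gamma: float = 0.0
    phi: float = 10.0


@dataclass
class SimSpec:
    """Top-level simulation specification."""

    n_samples: int = 25
    blocks: list[BlockSpec] = field(default_factory=list)
    hqtls: list[HqtlSpec] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    seed: int = 0


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def random_pool(n_variants: int, n_haplotypes: int, rng: np.random.Generator,
                min_maf: float = 0.1, max_tries: int = 200) -> tuple[list, list]:
    """Random haplotype pool in which every variant is polymorphic with
    pool-level MAF at least ``min_maf``."""
    for _ in range(max_tries):
        haps = rng.integers(0, 2, size=(n_haplotypes, n_variants))
        freqs = rng.dirichlet(np.full(n_haplotypes, 2.0))
        p = freqs @ haps
        if np.all((p >= min_maf) & (p <= 1 - min_maf)):
            return [tuple(int(a) for a in h) for h in haps], list(freqs)
    raise ValidationError("could not generate a polymorphic pool; relax min_maf")


def default_blocks(n_blocks: int, variants_per_block: int, rng: np.random.Generator,
                   chrom: str = "chr1", block_gap: int = 50_000,
                   spacing: int = 500, n_haplotypes: int = 6,
                   min_maf: float = 0.1) -> list[BlockSpec]:
    """Convenience layout: equally spaced random-pool blocks on one autosome."""
    blocks = []
    pos = 10_000
    for _ in range(n_blocks):
        haps, freqs = random_pool(variants_per_block, n_haplotypes, rng, min_maf)
        blocks.append(BlockSpec(chrom, pos, haps, freqs, spacing=spacing))
        pos += variants_per_block * spacing + block_gap
    return blocks


def simulate_genotypes(spec: SimSpec) -> tuple[GenotypeTable, pd.DataFrame]:
    """Draw phased genotypes; returns the table and a ``.blocks.det``-style
    block frame (0-based half-open intervals, snp lists)."""
    rng = np.random.default_rng(spec.seed)
    ids, chroms, poss, block_rows = [], [], [], []
    hap1_cols, hap2_cols = [], []
    for bi, blk in enumerate(spec.blocks):
        haps = np.asarray(blk.haplotypes, dtype=np.int8)
        choice1 = rng.choice(len(haps), size=spec.n_samples, p=blk.frequencies)
        choice2 = rng.choice(len(haps), size=spec.n_samples, p=blk.frequencies)
        h1 = haps[choice1].T  # (n_variants, n_samples)
        h2 = haps[choice2].T
        snp_ids = [f"b{bi}v{vi}" for vi in range(blk.n_variants)]
        positions = [blk.start + vi * blk.spacing for vi in range(blk.n_variants)]
        ids.extend(snp_ids)
        chroms.extend([blk.chrom] * blk.n_variants)
        poss.extend(positions)
        hap1_cols.append(h1)
        hap2_cols.append(h2)
        block_rows.append({
            "chrom": blk.chrom, "start": positions[0], "end": positions[-1] + 1,
            "nsnps": blk.n_variants, "snps": snp_ids,
        })
    samples = [f"s{j}" for j in range(spec.n_samples)]
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss,
         "ref": ["A"] * len(ids), "alt": ["G"] * len(ids)},
        index=pd.Index(ids, name="id"),
    )
    hap1 = np.vstack(hap1_cols) if hap1_cols else np.empty((0, spec.n_samples), np.int8)
    hap2 = np.vstack(hap2_cols) if hap2_cols else np.empty((0, spec.n_samples), np.int8)
    gt = GenotypeTable(variants, samples, hap1, hap2)
    blocks = pd.DataFrame(block_rows)
    blocks.index = pd.Index([f"block{k}" for k in range(len(blocks))], name="block_id")
    return gt, blocks


# ---------------------------------------------------------------------------
# allele-specific counts
# ---------------------------------------------------------------------------

def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Poisson conditioned on being positive."""
    draws = rng.poisson(lam, size=size)
    while np.any(draws == 0):
        zero = draws == 0
        draws[zero] = rng.poisson(lam, size=int(zero.sum()))
    return draws


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, pi: float,
                   rho: float) -> np.ndarray:
    if rho <= 0:
        return rng.binomial(n, pi)
    a = pi * (1 - rho) / rho
    b = (1 - pi) * (1 - rho) / rho
    p = rng.beta(a, b, size=n.shape)
    return rng.binomial(n, p)


def _negative_binomial(rng: np.random.Generator, mu: np.ndarray,
                       phi: float) -> np.ndarray:
    lam = rng.gamma(shape=phi, scale=np.asarray(mu) / phi)
    return rng.poisson(lam)


def simulate_as_counts(gt: GenotypeTable, hqtls: list[HqtlSpec] | HqtlSpec,
                       seed: int, size_factors: pd.Series | None = None) -> RegionCounts:
    """Allele-specific and region-total counts for each hQTL spec.

    Heterozygotes draw an AS depth from a zero-truncated Poisson and split
    it beta-binomially with reference fraction ``pi = alpha/(alpha+beta)``;
    homozygotes carry no AS reads. Every sample draws a region total from a
    negative binomial whose mean scales with genotype as
    ``(g_ref * alpha + g_alt * beta) / 2``.
    """
    if isinstance(hqtls, HqtlSpec):
        hqtls = [hqtls]
    rng = np.random.default_rng(seed)
    if size_factors is None:
        size_factors = pd.Series(1.0, index=pd.Index(gt.samples))
    rows = []
    for spec in hqtls:
        if spec.snp_id not in gt.variants.index:
            raise ValidationError(f"hqtl snp {spec.snp_id} not in genotypes")
        dosage = gt.dosage(spec.snp_id).astype(float)
        es = 2.0 ** spec.log2_effect
        alpha = 2.0 * es / (1.0 + es)
        beta = 2.0 - alpha
        pi = alpha / 2.0
        het = dosage == 1
        n_samp = gt.n_samples
        ref = np.zeros(n_samp, dtype=int)
        alt = np.zeros(n_samp, dtype=int)
        if het.any():
            n_as = _truncated_poisson(rng, spec.mean_as_depth, int(het.sum()))
            r = _beta_binomial(rng, n_as, pi, spec.as_overdispersion)
            ref[het] = r
            alt[het] = n_as - r
        g_alt = np.where(dosage >= 0, dosage, 1.0)
        g_ref = 2.0 - g_alt
        mu = (spec.mean_region_depth * size_factors.to_numpy()
              * (g_ref * alpha + g_alt * beta) / 2.0)
        total = _negative_binomial(rng, mu, spec.depth_dispersion)
        total = np.maximum(total, ref + alt)  # AS reads are a subset of the region
        for j, samp in enumerate(gt.samples):
            rows.append((spec.snp_id, samp, int(ref[j]), int(alt[j]), int(total[j])))
    counts = pd.DataFrame(rows, columns=RegionCounts.REQUIRED)
    return RegionCounts(counts, size_factors)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(gt: GenotypeTable, genes: list[GeneModel], seed: int,
                        library_size_sd: float = 0.1,
                        sample_noise_sd: float = 0.0) -> ExpressionTable:
    """Negative-binomial expression emitted as library-size-scaled CPM.

    ``sample_noise_sd`` adds a shared log-normal per-sample factor,
    emulating the technical confounding that factor-normalisation pipelines
    remove from real data.
    """
    rng = np.random.default_rng(seed)
    n = gt.n_samples
    libs = MEAN_LIBRARY_SIZE * np.exp(rng.normal(0.0, library_size_sd, size=n))
    sample_factor = (np.exp(rng.normal(0.0, sample_noise_sd, size=n))
                     if sample_noise_sd > 0 else np.ones(n))
    rows = {}
    for gm in genes:
        log_mu = np.full(n, gm.mu0, dtype=float)
        if gm.eqtl_snp is not None:
            d_e = np.clip(gt.dosage(gm.eqtl_snp).astype(float), 0, None)
        else:
            d_e = np.zeros(n)
        if gm.hqtl_snp is not None:
            d_h = np.clip(gt.dosage(gm.hqtl_snp).astype(float), 0, None)
        else:
            d_h = np.zeros(n)
        log_mu += gm.beta_e * d_e + gm.beta_h * d_h + gm.gamma * d_e * d_h
        mu = np.exp(log_mu) * sample_factor * libs / MEAN_LIBRARY_SIZE
        counts = _negative_binomial(rng, mu, gm.phi)
        rows[gm.gene_id] = counts / libs * 1e6
    cpm = pd.DataFrame(rows, index=pd.Index(gt.samples)).T
    cpm.index.name = "gene_id"
    return ExpressionTable(cpm, pd.Series(libs, index=pd.Index(gt.samples)))


def simulate_gene_annotation(n_genes: int, rng: np.random.Generator,
                             chrom: str = "chr1", start: int = 5_000,
                             gene_length: int = 20_000,
                             gene_gap: int = 80_000) -> pd.DataFrame:
    """Equally spaced gene models with alternating strand."""
    rows = []
    pos = start
    for g in range(n_genes):
        strand = "+" if g % 2 == 0 else "-"
        if strand == "+":
            tss, tes = pos, pos + gene_length
        else:
            tss, tes = pos + gene_length, pos
        rows.append({"gene_id": f"gene{g}", "chrom": chrom, "tss": tss,
                     "tes": tes, "strand": strand})
        pos += gene_length + gene_gap
    return pd.DataFrame(rows).set_index("gene_id")


def annotate_tss_distance(gt: GenotypeTable, genes: pd.DataFrame) -> None:
    """Fill ``tss_distance`` (|bp| to the nearest 5' TSS) in the variant table."""
    dist = np.full(gt.n_variants, np.nan)
    for chrom, sub in genes.groupby("chrom"):
        tss = np.sort(sub["tss"].to_numpy())
        on_chrom = gt.variants["chrom"].to_numpy() == chrom
        pos = gt.variants["pos"].to_numpy()[on_chrom]
        j = np.searchsorted(tss, pos)
        left = np.abs(pos - tss[np.clip(j - 1, 0, tss.size - 1)])
        right = np.abs(tss[np.clip(j, 0, tss.size - 1)] - pos)
        dist[on_chrom] = np.minimum(left, right)
    gt.variants["tss_distance"] = dist


# ---------------------------------------------------------------------------
# loops and risk catalogs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoopLayout:
    """Requested loop: two anchor intervals, PET count and mark."""

    chrom: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    pet_count: int = 10
    mark: str = "H3K27ac"


def simulate_loops(layout: list[LoopLayout]) -> list[Loop]:
    """Materialise loops exactly as laid out (anchors ordered)."""
    loops = []
    for item in layout:
        a = GenomicInterval(item.chrom, item.a_start, item.a_end)
        b = GenomicInterval(item.chrom, item.b_start, item.b_end)
        if a.start > b.start:
            a, b = b, a
        loops.append(Loop(a, b, item.pet_count, mark=item.mark))
    return loops


def loops_to_promoters(gt: GenotypeTable, snp_ids: list[str],
                       genes: pd.DataFrame, gene_ids: list[str],
                       anchor_halfwidth: int = 2_500,
                       pet_count: int = 10, mark: str = "H3K27ac") -> list[Loop]:
    """One loop per (snp, gene) pair joining an anchor over the SNP to an
    anchor over the gene promoter."""
    layout = []
    for snp, gene in zip(snp_ids, gene_ids):
        row = gt.variants.loc[snp]
        grow = genes.loc[gene]
        if row["chrom"] != grow["chrom"]:
            raise ValidationError("loop anchors must share a chromosome")
        tss = int(grow["tss"])
        layout.append(LoopLayout(
            row["chrom"],
            int(row["pos"]) - anchor_halfwidth, int(row["pos"]) + anchor_halfwidth,
            tss - anchor_halfwidth, tss + anchor_halfwidth,
            pet_count=pet_count, mark=mark,
        ))
    return simulate_loops(layout)


def simulate_risk_catalog(blocks: pd.DataFrame, hqtl_ids: set[str] | list[str],
                          fold: float, seed: int,
                          background_rate: float = 0.05,
                          trait: str = "synthetic_trait") -> pd.DataFrame:
    """Catalog of index SNPs with controllable hQTL enrichment.

    Each block enters the catalog (via a randomly chosen index SNP) with
    probability ``background_rate``, inflated by ``fold`` for blocks
    containing an hQTL, so hQTL catalog membership is overrepresented by
    ``fold`` in expectation.
    """
    if fold < 1:
        raise ValidationError("enrichment fold must be >= 1")
    rng = np.random.default_rng(seed)
    hqtl_ids = set(hqtl_ids)
    snp_lists = list(blocks["snps"])
    has_hqtl = np.fromiter(
        (any(s in hqtl_ids for s in snps) for snps in snp_lists),
        dtype=bool, count=len(snp_lists),
    )
    p = np.where(has_hqtl, np.minimum(background_rate * fold, 1.0),
                 background_rate)
    selected = rng.random(len(snp_lists)) < p
    rows = [
        {"index_snp_id": snps[rng.integers(len(snps))], "trait": trait}
        for snps, sel in zip(snp_lists, selected) if sel
    ]
    return pd.DataFrame(rows, columns=["index_snp_id", "trait"])


# ---------------------------------------------------------------------------
# per-individual peak sets
# ---------------------------------------------------------------------------

def simulate_peak_sets(true_peaks: list[GenomicInterval], n_individuals: int,
                       seed: int, presence_prob: float = 0.8,
                       jitter: int = 20) -> list[list[GenomicInterval]]:
    """Per-individual reproducible peak calls around shared true peaks.

    Each individual observes each true peak with probability
    ``presence_prob``, with uniform boundary jitter of up to ``jitter`` bp.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_individuals):
        peaks = []
        for iv in true_peaks:
            if rng.random() >= presence_prob:
                continue
            ds = int(rng.integers(-jitter, jitter + 1))
            de = int(rng.integers(-jitter, jitter + 1))
            start = max(0, iv.start + ds)
            end = max(start + 1, iv.end + de)
            peaks.append(GenomicInterval(iv.chrom, start, end))
        peaks.sort(key=lambda p: (p.chrom, p.start))
        # enforce disjointness after jitter
        cleaned = []
        for p in peaks:
            if cleaned and p.chrom == cleaned[-1].chrom and p.start < cleaned[-1].end:
                cleaned[-1] = GenomicInterval(p.chrom, cleaned[-1].start,
                                              max(cleaned[-1].end, p.end))
            else:
                cleaned.append(p)
        out.append(cleaned)
    return out
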