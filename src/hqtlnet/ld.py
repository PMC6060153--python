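"""Linkage-disequilibrium statistics and proxy pruning from phased data.

LD is always computed from phased haplotypes by tallying the 2x2 haplotype
table; unphased genotypes are rejected rather than resolved by EM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenotypeTable, ValidationError


class UndefinedLdError(ValueError):
    """LD is undefined for a monomorphic variant."""


@dataclass(frozen=True)
class LdStats:
    """Pairwise LD: raw D, normalized D' in [0,1], and r^2."""

    d: float
    d_prime: float
    r2: float


def _haplotype_pair(gt: GenotypeTable, a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    ia = gt.variants.index.get_loc(a)
    ib = gt.variants.index.get_loc(b)
    if not (gt.phased[ia].all() and gt.phased[ib].all()):
        raise ValidationError(f"unphased genotypes for {a} or {b}; LD requires phase")
    ha = np.concatenate([gt.hap1[ia], gt.hap2[ia]])
    hb = np.concatenate([gt.hap1[ib], gt.hap2[ib]])
    keep = (ha >= 0) & (hb >= 0)
    return ha[keep], hb[keep]


def ld_from_haplotype_counts(n_ab: int, n_aB: int, n_Ab: int, n_AB: int) -> LdStats:
    """LD statistics from a 2x2 haplotype count table.

    Uppercase denotes the alternate allele at each locus: ``n_AB`` counts
    haplotypes carrying the alternate allele at both loci.
    """
    n = n_ab + n_aB + n_Ab + n_AB
    if n == 0:
        raise UndefinedLdError("no haplotypes")
    p_A = (n_AB + n_Ab) / n  # alt at locus 1
    p_B = (n_AB + n_aB) / n  # alt at locus 2
    if p_A in (0.0, 1.0) or p_B in (0.0, 1.0):
        raise UndefinedLdError("monomorphic variant; LD undefined")
    p_AB = n_AB / n
    d = p_AB - p_A * p_B
    q_A, q_B = 1 - p_A, 1 - p_B
    if d >= 0:
        d_max = min(p_A * q_B, q_A * p_B)
    else:
        d_max = min(p_A * p_B, q_A * q_B)
    d_prime = 0.0 if d == 0 else abs(d) / d_max
    r2 = d * d / (p_A * q_A * p_B * q_B)
    return LdStats(d=d, d_prime=min(d_prime, 1.0), r2=min(r2, 1.0))


def ld_stats(variant_a: str, variant_b: str, gt: GenotypeTable) -> LdStats:
    """Pairwise LD between two variants from their phased haplotypes."""
    ha, hb = _haplotype_pair(gt, variant_a, variant_b)
    n_AB = int(np.sum((ha == 1) & (hb == 1)))
    n_Ab = int(np.sum((ha == 1) & (hb == 0)))
    n_aB = int(np.sum((ha == 0) & (hb == 1)))
    n_ab = int(np.sum((ha == 0) & (hb == 0)))
    return ld_from_haplotype_counts(n_ab, n_aB, n_Ab, n_AB)


def prune_proxies(results: pd.DataFrame, gt: GenotypeTable,
                  r2_max: float = 0.8,
                  snp_col: str = "snp_id", p_col: str = "p_nominal") -> list[str]:
    """Greedy LD pruning: scan SNPs in ascending p; retain a SNP iff its r^2
    against every already-retained SNP is below ``r2_max``.

    Monomorphic pairs (undefined LD) are treated as unlinked.
    """
    ordered = results.sort_values(p_col, kind="mergesort")
    retained: list[str] = []
    for snp in ordered[snp_col]:
        ok = True
        for kept in retained:
            try:
                if ld_stats(snp, kept, gt).r2 >= r2_max:
                    ok = False
                    break
            except UndefinedLdError:
                continue
        if ok:
            retained.append(snp)
    return retained


def blocks_for_variants(blocks: pd.DataFrame) -> dict[str, str]:
    """Map variant id -> block id from a parsed blocks table."""
    out: dict[str, str] = {}
    for block_id, row in blocks.iterrows():
        for snp in row["snps"]:
            out[snp] = block_id
    return out
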