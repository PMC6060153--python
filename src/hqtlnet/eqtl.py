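"""Cis-eQTL mapping: inverse-normal transform, windowed linear scan, FDR,
and LD proxy pruning.

The scan regresses rank-based inverse-normal expression on alternate-allele
dosage for every (SNP, gene) pair with less than the window distance
between the SNP and the transcript boundary, subject to MAF and
coefficient-of-variation filters; Benjamini-Hochberg FDR is applied across
all tested pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ld import prune_proxies
from .multtest import bh_fdr
from .types import ExpressionTable, GenotypeTable, RunConfig, ValidationError


def normalize_expression(cpm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene rank-based inverse-normal transform (Blom offset).

    Each gene's values are replaced by normal quantiles at
    ``(rank - 3/8) / (n + 1/4)`` with ties given their average rank, so any
    monotone transform of the input yields identical output.
    """
    out = {}
    n = cpm.shape[1]
    for gene, row in cpm.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.allclose(vals, vals[0]):
            raise ValidationError(f"gene {gene} has constant expression")
        ranks = stats.rankdata(vals, method="average")
        out[gene] = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    res = pd.DataFrame(out, index=cpm.columns).T
    res.index.name = cpm.index.name
    return res


def _transcript_distance(pos: int, tss: int, tes: int) -> int:
    """bp from a SNP to the nearest edge of the transcript interval (0 inside)."""
    lo, hi = min(tss, tes), max(tss, tes)
    if lo <= pos < hi:
        return 0
    return lo - pos if pos < lo else pos - hi + 1


def cis_scan(gt: GenotypeTable, expr: ExpressionTable, genes: pd.DataFrame,
             config: RunConfig | None = None) -> pd.DataFrame:
    """Windowed cis scan of standardized expression on dosage.

    Returns one row per candidate (snp, gene) pair with OLS estimates for
    tested pairs and an exclusion ``reason`` ("window", "maf", "cv",
    "expressed") otherwise. ``q_value`` is BH across tested pairs;
    ``significant`` flags q <= the configured FDR level.
    """
    cfg = config or RunConfig()
    cpm = expr.cpm[gt.samples]

    frac_pos = (cpm > 0).mean(axis=1)
    cv = cpm.std(axis=1, ddof=1) / cpm.mean(axis=1).replace(0, np.nan)
    gene_reason = {}
    for gene in cpm.index:
        if gene not in genes.index:
            gene_reason[gene] = "annotation"
        elif frac_pos[gene] <= 0.5:
            gene_reason[gene] = "expressed"
        elif not (cv[gene] >= cfg.cv_min):
            gene_reason[gene] = "cv"
        else:
            gene_reason[gene] = None
    ok_genes = [g for g, r in gene_reason.items() if r is None]
    norm = normalize_expression(cpm.loc[ok_genes]) if ok_genes else pd.DataFrame()

    maf = gt.variants["maf"].to_numpy()
    chrom = gt.variants["chrom"].to_numpy()
    pos = gt.variants["pos"].to_numpy()
    dosages = gt.dosages().astype(float)

    rows = []
    for gene in cpm.index:
        if gene_reason[gene] == "annotation":
            continue
        grow = genes.loc[gene]
        on_chrom = np.flatnonzero(chrom == grow["chrom"])
        for i in on_chrom:
            snp = gt.variants.index[i]
            dist = _transcript_distance(int(pos[i]), int(grow["tss"]), int(grow["tes"]))
            if dist >= cfg.cis_window:
                rows.append((snp, gene, np.nan, np.nan, np.nan, False, "window"))
                continue
            if gene_reason[gene] is not None:
                rows.append((snp, gene, np.nan, np.nan, np.nan, False,
                             gene_reason[gene]))
                continue
            if not (maf[i] >= cfg.maf_min):
                rows.append((snp, gene, np.nan, np.nan, np.nan, False, "maf"))
                continue
            d = dosages[i]
            y = norm.loc[gene].to_numpy()
            keep = d >= 0
            d_k, y_k = d[keep], y[keep]
            n = d_k.size
            vx = d_k.var()
            if n < 3 or vx == 0:
                rows.append((snp, gene, np.nan, np.nan, np.nan, False, "degenerate"))
                continue
            beta = np.cov(d_k, y_k, ddof=1)[0, 1] / d_k.var(ddof=1)
            resid = y_k - y_k.mean() - beta * (d_k - d_k.mean())
            sigma2 = (resid @ resid) / (n - 2)
            se = np.sqrt(sigma2 / (d_k.var(ddof=1) * (n - 1)))
            t = beta / se if se > 0 else np.inf * np.sign(beta)
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
            rows.append((snp, gene, beta, t, p, True, ""))

    df = pd.DataFrame(rows, columns=["snp_id", "gene_id", "beta", "t_stat",
                                     "p_nominal", "tested", "reason"])
    df["q_value"] = np.nan
    df["significant"] = False
    tested = df["tested"].to_numpy()
    if tested.any():
        rej, q = bh_fdr(df.loc[tested, "p_nominal"].to_numpy(), q=cfg.fdr_q)
        df.loc[tested, "q_value"] = q
        df.loc[tested, "significant"] = rej
    return df


def lead_and_prune(results: pd.DataFrame, gt: GenotypeTable,
                   r2_max: float = 0.8) -> pd.DataFrame:
    """Per-gene greedy LD pruning of significant eQTLs (retain r^2 < r2_max).

    The retained SNP with the smallest nominal p per gene is its lead.
    """
    sig = results[results["significant"]]
    kept_rows = []
    for gene, sub in sig.groupby("gene_id"):
        retained = prune_proxies(sub, gt, r2_max=r2_max)
        sub_kept = sub[sub["snp_id"].isin(retained)].copy()
        lead = sub_kept["p_nominal"].idxmin()
        sub_kept["is_lead"] = sub_kept.index == lead
        kept_rows.append(sub_kept)
    if not kept_rows:
        out = results.iloc[0:0].copy()
        out["is_lead"] = pd.Series(dtype=bool)
        return out
    return pd.concat(kept_rows, ignore_index=True)
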