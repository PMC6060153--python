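"""Negative-binomial joint-effect models in chromatin-loop networks.

Two analyses share the same NB GLM core (log link, profile-ML dispersion,
as in MASS ``glm.nb``):

* the local haplotype-block analysis, which asks whether the hQTL genotype
  explains expression variance (D^2 = (null deviance - residual deviance) /
  null deviance) beyond the eQTL or any other variant on the block, with a
  permutation null built by substituting each non-QTL block variant for the
  hQTL;
* the distal eQTL x hQTL interaction scan, which fits
  ``counts ~ 1 + d_e + d_h + d_e * d_h`` for LD-independent pairs inside
  the eQTL target gene's chromatin network and tests the interaction
  coefficient by a two-tailed z-test, with BH FDR across pairs.

Loop-topology labels (Anchored / Unanchored / Looped / Off-target / Joint /
Disjoint) classify each pair's position in the filtered H3K27ac loop graph,
and quadrant labels classify coefficient signs (eQTL main effect x
interaction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .cht import nb_loglik
from .ld import blocks_for_variants, ld_stats, UndefinedLdError
from .multtest import bh_fdr
from .types import (
    ExpressionTable,
    GenomicInterval,
    GenotypeTable,
    Loop,
    RunConfig,
    ValidationError,
)

QUADRANTS = {
    (1, -1): "enhancing-opposed",
    (-1, 1): "repressive-opposed",
    (1, 1): "enhancing-concordant",
    (-1, -1): "repressive-concordant",
}

TOPOLOGIES = ("Anchored", "Unanchored", "Looped", "Off-target", "Joint", "Disjoint")


# ---------------------------------------------------------------------------
# NB GLM with profile-ML dispersion
# ---------------------------------------------------------------------------

@dataclass
class JointModelFit:
    """An NB GLM fit with the deviance-explained statistic."""

    params: np.ndarray
    bse: np.ndarray
    alpha: float  # NB dispersion (variance mu + alpha mu^2); theta = 1/alpha
    null_deviance: float
    residual_deviance: float
    d2: float
    converged: bool

    def z(self, idx: int) -> float:
        return float(self.params[idx] / self.bse[idx])

    def p_wald(self, idx: int) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z(idx))))


def _mle_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Profile ML of the NB dispersion alpha given fitted means."""
    def neg(log_alpha: float) -> float:
        return -float(nb_loglik(y, mu, 1.0 / math.exp(log_alpha)).sum())

    res = optimize.minimize_scalar(neg, bounds=(math.log(1e-8), math.log(1e3)),
                                   method="bounded", options={"xatol": 1e-6})
    return math.exp(res.x)


def fit_nb_glm(y, X, alpha: float | None = None) -> JointModelFit:
    """Fit a log-link negative-binomial GLM by IRLS.

    When ``alpha`` is None the dispersion is profiled out by alternating
    IRLS fits with ML updates of alpha (the ``glm.nb`` behaviour); passing
    a fixed ``alpha`` fits at that dispersion. Null and residual deviances
    are both evaluated at the final dispersion, so D^2 lies in [0, 1].
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("rank-deficient design matrix")
    if np.any(y < 0):
        raise ValidationError("negative response counts")

    profile = alpha is None
    a = alpha if alpha is not None else 0.1
    res = None
    converged = True
    for _ in range(25):
        fam = sm.families.NegativeBinomial(alpha=max(a, 1e-8))
        try:
            res = sm.GLM(y, X, family=fam).fit(maxiter=100, tol=1e-9)
        except Exception:
            converged = False
            break
        if not profile:
            break
        a_new = _mle_alpha(y, res.mu)
        if abs(math.log(max(a_new, 1e-10)) - math.log(max(a, 1e-10))) < 1e-6:
            a = a_new
            break
        a = a_new
    if res is None:
        nan = np.full(X.shape[1], np.nan)
        return JointModelFit(nan, nan, a, np.nan, np.nan, np.nan, False)
    converged = converged and bool(res.converged)
    # refit at the final dispersion so deviances share one alpha
    fam = sm.families.NegativeBinomial(alpha=max(a, 1e-8))
    res = sm.GLM(y, X, family=fam).fit(maxiter=100, tol=1e-9)
    null_dev = float(res.null_deviance)
    resid_dev = float(res.deviance)
    d2 = 0.0 if null_dev <= 0 else max(0.0, (null_dev - resid_dev) / null_dev)
    return JointModelFit(
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        alpha=a,
        null_deviance=null_dev,
        residual_deviance=resid_dev,
        d2=min(d2, 1.0),
        converged=converged,
    )


def _interaction_design(d_e: np.ndarray, d_h: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(d_e), d_e, d_h, d_e * d_h])


# ---------------------------------------------------------------------------
# loop filtering and the chromatin-network graph
# ---------------------------------------------------------------------------

def filter_loops(loops: list[Loop], min_pets: int = 4,
                 min_len: int = 5_000, max_len: int = 2_000_000) -> list[Loop]:
    """Keep loops with enough PET support and anchor-midpoint span within
    [min_len, max_len]."""
    return [
        lp for lp in loops
        if lp.pet_count >= min_pets and min_len <= lp.span <= max_len
    ]


class LoopGraph:
    """Chromatin networks from a loop list.

    Overlapping anchors are merged into nodes; loops are edges; the
    connected components are the chromatin networks.
    """

    def __init__(self, loops: list[Loop]):
        self.loops = list(loops)
        anchors = []
        for lp in self.loops:
            anchors.append(lp.anchor_a)
            anchors.append(lp.anchor_b)
        merged: dict[str, list[list[int]]] = {}
        for iv in sorted(anchors, key=lambda v: (v.chrom, v.start)):
            lst = merged.setdefault(iv.chrom, [])
            if lst and iv.start < lst[-1][1]:
                lst[-1][1] = max(lst[-1][1], iv.end)
            else:
                lst.append([iv.start, iv.end])
        self._nodes: dict[str, list[tuple[int, int]]] = {
            c: [tuple(x) for x in lst] for c, lst in merged.items()
        }
        g = nx.Graph()
        for c, lst in self._nodes.items():
            for node in lst:
                g.add_node((c, node))
        for lp in self.loops:
            na = self.node_at(lp.anchor_a.chrom, int(lp.anchor_a.midpoint))
            nb = self.node_at(lp.anchor_b.chrom, int(lp.anchor_b.midpoint))
            if na is not None and nb is not None:
                g.add_edge(na, nb)
        self.graph = g
        self._component: dict = {}
        for k, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                self._component[node] = k

    def node_at(self, chrom: str, pos: int):
        for node in self._nodes.get(chrom, []):
            if node[0] <= pos < node[1]:
                return (chrom, node)
        return None

    def nodes_overlapping(self, iv: GenomicInterval) -> list:
        return [
            (iv.chrom, node) for node in self._nodes.get(iv.chrom, [])
            if node[0] < iv.end and iv.start < node[1]
        ]

    def component_at(self, chrom: str, pos: int):
        node = self.node_at(chrom, pos)
        return None if node is None else self._component[node]

    def components_overlapping(self, iv: GenomicInterval) -> set:
        return {self._component[n] for n in self.nodes_overlapping(iv)}

    def anchors_containing(self, chrom: str, pos: int) -> list[GenomicInterval]:
        out = []
        for lp in self.loops:
            for anc in (lp.anchor_a, lp.anchor_b):
                if anc.contains(chrom, pos):
                    out.append(anc)
        return out

    def loops_containing(self, chrom: str, pos: int) -> list[Loop]:
        return [
            lp for lp in self.loops
            if lp.anchor_a.contains(chrom, pos) or lp.anchor_b.contains(chrom, pos)
        ]


def target_range(gene_row: pd.Series, upstream: int = 10_000) -> GenomicInterval:
    """Strand-aware target range: 10 kb upstream of the TSS through the TES."""
    tss, tes = int(gene_row["tss"]), int(gene_row["tes"])
    lo, hi = min(tss, tes), max(tss, tes)
    if gene_row["strand"] == "+":
        lo = max(lo - upstream, 0)
    else:
        hi = hi + upstream
    return GenomicInterval(gene_row["chrom"], lo, max(hi, lo + 1))


# ---------------------------------------------------------------------------
# local D^2 haplotype analysis
# ---------------------------------------------------------------------------

def dosage_d2(y: np.ndarray, dosage: np.ndarray,
              alpha: float | None = None) -> float:
    """D^2 of a single-dosage NB model (used to rank candidate lead eQTLs)."""
    keep = dosage >= 0
    X = np.column_stack([np.ones(int(keep.sum())), dosage[keep].astype(float)])
    return fit_nb_glm(y[keep], X, alpha=alpha).d2


def eligible_blocks(blocks: pd.DataFrame, eqtls: pd.DataFrame,
                    hqtls: pd.DataFrame, gt: GenotypeTable,
                    expr_counts: pd.DataFrame,
                    config: RunConfig | None = None) -> pd.DataFrame:
    """Blocks eligible for the local D^2 analysis.

    Keeps blocks of at least ``min_block_variants`` variants containing an
    eQTL-hQTL pair in strong LD (D' >= 0.8) but not highly correlated
    (r^2 < 0.6). The lead eQTL is the one whose dosage alone explains the
    most deviance of its target gene (max D^2); the lead hQTL is the most
    significant CHT hit on the block.

    ``eqtls`` needs columns snp_id / gene_id; ``hqtls`` needs snp_id /
    p_nominal; ``expr_counts`` is the genes x samples count frame.
    """
    cfg = config or RunConfig()
    out = []
    for block_id, row in blocks.iterrows():
        snps = [s for s in row["snps"] if s in gt.variants.index]
        if len(snps) < cfg.min_block_variants:
            continue
        block_eqtls = eqtls[eqtls["snp_id"].isin(snps)]
        block_hqtls = hqtls[hqtls["snp_id"].isin(snps)]
        if block_eqtls.empty or block_hqtls.empty:
            continue
        candidates = []
        for _, erow in block_eqtls.iterrows():
            for _, hrow in block_hqtls.iterrows():
                if erow["snp_id"] == hrow["snp_id"]:
                    continue
                try:
                    ld = ld_stats(erow["snp_id"], hrow["snp_id"], gt)
                except UndefinedLdError:
                    continue
                if ld.d_prime >= cfg.dprime_strong and ld.r2 < cfg.r2_independent:
                    candidates.append((erow, hrow))
        if not candidates:
            continue
        # lead eQTL by max single-dosage D^2 on its target gene
        best_d2, lead_e = -1.0, None
        for erow, _ in candidates:
            if erow["gene_id"] not in expr_counts.index:
                continue
            y = expr_counts.loc[erow["gene_id"], gt.samples].to_numpy(dtype=float)
            d2 = dosage_d2(y, gt.dosage(erow["snp_id"]))
            if d2 > best_d2:
                best_d2, lead_e = d2, erow
        if lead_e is None:
            continue
        hsub = [h for e, h in candidates if e["snp_id"] == lead_e["snp_id"]]
        lead_h = min(hsub, key=lambda h: h["p_nominal"])
        out.append({
            "block_id": block_id,
            "lead_eqtl": lead_e["snp_id"],
            "lead_hqtl": lead_h["snp_id"],
            "gene_id": lead_e["gene_id"],
            "eqtl_d2": best_d2,
        })
    return pd.DataFrame(out, columns=["block_id", "lead_eqtl", "lead_hqtl",
                                      "gene_id", "eqtl_d2"])


@dataclass
class D2PermResult:
    """Permutation test of the hQTL's deviance contribution on one block."""

    block_id: str
    lead_eqtl: str
    lead_hqtl: str
    observed_d2: float
    null_d2: np.ndarray  # one value per distinct substitution
    perm_p: float
    ci_low: float
    ci_high: float
    n_perm: int


def d2_scan(block_snps: list[str], eqtl: str, hqtl: str, y: np.ndarray,
            gt: GenotypeTable, n_perm: int = 10_000, seed: int = 0,
            block_id: str = "") -> D2PermResult:
    """Observed vs permuted D^2 for one haplotype block.

    The observed statistic is the D^2 of the full joint model
    ``y ~ 1 + d_e + d_h + d_e * d_h``; the null substitutes each non-QTL
    block variant for the hQTL. When fewer distinct substitutions than
    ``n_perm`` exist they are exhausted and resampled with replacement up
    to ``n_perm``. ``perm_p`` uses the add-one estimator; the 95% CI is
    Clopper-Pearson on the exceedance count.
    """
    others = [s for s in block_snps if s not in (eqtl, hqtl)]
    if len(others) < 1:
        raise ValidationError("block has no non-QTL variant to permute over")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    d_e = gt.dosage(eqtl).astype(float)

    def joint_d2(d_h: np.ndarray) -> float:
        keep = (d_e >= 0) & (d_h >= 0)
        X = _interaction_design(d_e[keep], d_h[keep])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            # collinear substitution: no extra information beyond the eQTL
            X = X[:, :2]
        return fit_nb_glm(y[keep], X).d2

    observed = joint_d2(gt.dosage(hqtl).astype(float))
    distinct = np.array([joint_d2(gt.dosage(s).astype(float)) for s in others])
    if len(distinct) >= n_perm:
        null = rng.choice(distinct, size=n_perm, replace=False)
    else:
        null = np.concatenate([
            distinct, rng.choice(distinct, size=n_perm - len(distinct), replace=True)
        ])
    exceed = int(np.sum(null >= observed))
    perm_p = (1 + exceed) / (1 + n_perm)
    lo, hi = _clopper_pearson(1 + exceed, 1 + n_perm)
    return D2PermResult(block_id, eqtl, hqtl, observed, distinct,
                        perm_p, lo, hi, n_perm)


def _clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    a = (1 - conf) / 2
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - a, k + 1, n - k))
    return lo, hi


# ---------------------------------------------------------------------------
# distal interaction scan
# ---------------------------------------------------------------------------

def all_nine_combinations(d_e: np.ndarray, d_h: np.ndarray) -> bool:
    """True iff every (eQTL, hQTL) in {0,1,2}^2 dosage combination occurs."""
    keep = (d_e >= 0) & (d_h >= 0)
    combos = {(int(a), int(b)) for a, b in zip(d_e[keep], d_h[keep])}
    return len(combos) == 9


def eligible_pairs(eqtls: pd.DataFrame, hqtl_ids: list[str],
                   loops: list[Loop], blocks: pd.DataFrame,
                   gt: GenotypeTable, genes: pd.DataFrame,
                   config: RunConfig | None = None) -> pd.DataFrame:
    """Distal eQTL x hQTL candidate pairs with exclusion reasons.

    A pair passes when: LD-independent (r^2 < 0.6 and D' < 0.6), on
    separate haplotype blocks, hQTL inside an H3K27ac loop anchor, the
    hQTL's loop component connected to the eQTL target gene's range, and
    all nine genotype combinations observed. ``loops`` should already be
    PET/span filtered.
    """
    cfg = config or RunConfig()
    graph = LoopGraph([lp for lp in loops if lp.mark == "H3K27ac"])
    snp_block = blocks_for_variants(blocks)
    rows = []
    for _, erow in eqtls.iterrows():
        evar = gt.variants.loc[erow["snp_id"]]
        grow = genes.loc[erow["gene_id"]]
        t_range = target_range(grow, cfg.promoter_upstream)
        target_comps = graph.components_overlapping(t_range)
        for hq in hqtl_ids:
            if hq == erow["snp_id"]:
                continue
            reason = ""
            hvar = gt.variants.loc[hq]
            try:
                ld = ld_stats(erow["snp_id"], hq, gt)
                independent = (ld.r2 < cfg.r2_independent
                               and ld.d_prime < cfg.dprime_independent)
            except UndefinedLdError:
                independent = True
            if not independent:
                reason = "ld"
            elif snp_block.get(hq) is not None and \
                    snp_block.get(hq) == snp_block.get(erow["snp_id"]):
                reason = "same_block"
            elif not graph.anchors_containing(hvar["chrom"], int(hvar["pos"])):
                reason = "anchor"
            elif graph.component_at(hvar["chrom"], int(hvar["pos"])) not in target_comps:
                reason = "network"
            elif not all_nine_combinations(gt.dosage(erow["snp_id"]),
                                           gt.dosage(hq)):
                reason = "genotype_combinations"
            rows.append({
                "eqtl_id": erow["snp_id"], "hqtl_id": hq,
                "gene_id": erow["gene_id"],
                "eligible": reason == "", "reason": reason,
            })
    return pd.DataFrame(rows, columns=["eqtl_id", "hqtl_id", "gene_id",
                                       "eligible", "reason"])


def interaction_scan(pairs: pd.DataFrame, expr_counts: pd.DataFrame,
                     gt: GenotypeTable,
                     config: RunConfig | None = None) -> pd.DataFrame:
    """Fit the joint NB model per eligible pair and FDR-correct the
    interaction z-tests. Returns one row per fitted pair with coefficients,
    p/q values and the quadrant label."""
    cfg = config or RunConfig()
    use = pairs[pairs.get("eligible", pd.Series(True, index=pairs.index))]
    rows = []
    for _, pr in use.iterrows():
        d_e = gt.dosage(pr["eqtl_id"]).astype(float)
        d_h = gt.dosage(pr["hqtl_id"]).astype(float)
        keep = (d_e >= 0) & (d_h >= 0)
        y = expr_counts.loc[pr["gene_id"], gt.samples].to_numpy(dtype=float)[keep]
        fit = fit_nb_glm(y, _interaction_design(d_e[keep], d_h[keep]))
        rows.append({
            "eqtl_id": pr["eqtl_id"], "hqtl_id": pr["hqtl_id"],
            "gene_id": pr["gene_id"],
            "intercept": fit.params[0], "beta_eqtl": fit.params[1],
            "beta_hqtl": fit.params[2], "gamma": fit.params[3],
            "se_gamma": fit.bse[3],
            "z_interaction": fit.z(3) if fit.converged else np.nan,
            "p_interaction": fit.p_wald(3) if fit.converged else np.nan,
            "d2": fit.d2, "converged": fit.converged,
            "quadrant": classify_quadrant(fit) if fit.converged else "boundary",
        })
    df = pd.DataFrame(rows)
    if len(df):
        ok = df["p_interaction"].notna()
        q = np.full(len(df), np.nan)
        sig = np.zeros(len(df), dtype=bool)
        if ok.any():
            rej, qv = bh_fdr(df.loc[ok, "p_interaction"].to_numpy(), q=cfg.fdr_q)
            q[ok.to_numpy()] = qv
            sig[ok.to_numpy()] = rej
        df["q_value"] = q
        df["significant"] = sig
    return df


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_topology(hqtl_id: str, eqtl_id: str, gene_id: str,
                      gt: GenotypeTable, loops: list[Loop],
                      genes: pd.DataFrame, blocks: pd.DataFrame,
                      promoter_upstream: int = 10_000,
                      graph: LoopGraph | None = None) -> str:
    """Loop-topology label for one eQTL/hQTL/gene triplet.

    Labels are evaluated in fixed precedence, first match wins:

    1. ``Anchored`` - some anchor contains both SNPs;
    2. ``Unanchored`` - the hQTL is in no loop anchor;
    3. ``Looped`` - a loop joins an anchor holding the hQTL to an anchor
       holding the eQTL;
    4. ``Off-target`` - no loop containing the hQTL has an anchor
       overlapping the target gene range (TSS - 10 kb upstream, strand
       aware, through the TES);
    5. ``Joint`` - some loop connects an anchor overlapping the hQTL's
       haplotype block to one overlapping the eQTL's block;
    6. ``Disjoint`` - otherwise.
    """
    if gene_id not in genes.index:
        raise ValidationError(f"gene {gene_id} missing annotation")
    graph = graph or LoopGraph(loops)
    hvar = gt.variants.loc[hqtl_id]
    evar = gt.variants.loc[eqtl_id]
    h_chrom, h_pos = hvar["chrom"], int(hvar["pos"])
    e_chrom, e_pos = evar["chrom"], int(evar["pos"])

    h_anchors = graph.anchors_containing(h_chrom, h_pos)
    if any(a.contains(e_chrom, e_pos) for a in h_anchors):
        return "Anchored"
    if not h_anchors:
        return "Unanchored"
    h_loops = graph.loops_containing(h_chrom, h_pos)
    for lp in h_loops:
        partner = (lp.anchor_b if lp.anchor_a.contains(h_chrom, h_pos)
                   else lp.anchor_a)
        if partner.contains(e_chrom, e_pos):
            return "Looped"
    t_range = target_range(genes.loc[gene_id], promoter_upstream)
    reaches = any(
        lp.anchor_a.overlaps(t_range) or lp.anchor_b.overlaps(t_range)
        for lp in h_loops
    )
    if not reaches:
        return "Off-target"
    snp_block = blocks_for_variants(blocks)
    hb, eb = snp_block.get(hqtl_id), snp_block.get(eqtl_id)
    if hb is not None and eb is not None:
        h_iv = GenomicInterval(blocks.loc[hb, "chrom"],
                               int(blocks.loc[hb, "start"]),
                               int(blocks.loc[hb, "end"]))
        e_iv = GenomicInterval(blocks.loc[eb, "chrom"],
                               int(blocks.loc[eb, "start"]),
                               int(blocks.loc[eb, "end"]))
        for lp in graph.loops:
            ab = (lp.anchor_a.overlaps(h_iv) and lp.anchor_b.overlaps(e_iv))
            ba = (lp.anchor_b.overlaps(h_iv) and lp.anchor_a.overlaps(e_iv))
            if ab or ba:
                return "Joint"
    return "Disjoint"


def classify_quadrant(fit: JointModelFit) -> str:
    """Quadrant of (eQTL main effect, interaction) coefficient signs.

    A zero coefficient yields the tie label ``boundary`` (excluded from
    quadrant counts).
    """
    be = float(fit.params[1])
    ga = float(fit.params[3])
    if be == 0.0 or ga == 0.0:
        return "boundary"
    return QUADRANTS[(int(np.sign(be)), int(np.sign(ga)))]
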