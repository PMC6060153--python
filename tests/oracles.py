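"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (per-base arrays, explicit stepdown
loops, hand-coded IRLS) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def holm_stepdown(pvals, alpha):
    """Explicit Holm step-down: sorted rejections + adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    reject = np.zeros(m, dtype=bool)
    adjusted = np.zeros(m)
    running = 0.0
    halted = False
    for k, idx in enumerate(order):
        adj = min((m - k) * p[idx], 1.0)
        running = max(running, adj)
        adjusted[idx] = running
        if not halted and p[idx] <= alpha / (m - k):
            reject[idx] = True
        else:
            halted = True
    return reject, adjusted


def bh_stepup(pvals, q):
    """Explicit BH step-up: rejections + q-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    reject = np.zeros(m, dtype=bool)
    qvals = np.zeros(m)
    kmax = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            kmax = k
    for k in range(kmax):
        reject[order[k]] = True
    running = 1.0
    for k in range(m, 0, -1):
        running = min(running, m * p[order[k - 1]] / k)
        qvals[order[k - 1]] = running
    return reject, qvals


# ---------------------------------------------------------------------------
# consensus peaks: per-base coverage counting
# ---------------------------------------------------------------------------

def coverage_consensus(per_individual, min_support, merge_gap, length=20_000):
    """Per-base oracle on a single chromosome; returns [(start, end), ...]."""
    cov = np.zeros(length, dtype=int)
    for peaks in per_individual:
        for (start, end) in peaks:
            cov[start:end] += 1
    passing = cov >= min_support
    regions = []
    start = None
    for i in range(length):
        if passing[i] and start is None:
            start = i
        elif not passing[i] and start is not None:
            regions.append([start, i])
            start = None
    if start is not None:
        regions.append([start, length])
    merged = []
    for s, e in regions:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(r) for r in merged]


# ---------------------------------------------------------------------------
# Fisher one-sided p as a hypergeometric tail sum
# ---------------------------------------------------------------------------

def hypergeom_tail(a, b, c, d):
    """P(X >= a) for X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b), term by term."""
    N = a + b + c + d
    K = a + c
    n = a + b
    total = 0.0
    for x in range(a, min(K, n) + 1):
        total += stats.hypergeom.pmf(x, N, K, n)
    return total


# ---------------------------------------------------------------------------
# LD from explicit haplotype tallies
# ---------------------------------------------------------------------------

def ld_tally(hap_a, hap_b):
    """(d, d_prime, r2) from two 0/1 haplotype vectors, tallied by loop."""
    n = len(hap_a)
    counts = {"AB": 0, "Ab": 0, "aB": 0, "ab": 0}
    for x, y in zip(hap_a, hap_b):
        key = ("A" if x else "a") + ("B" if y else "b")
        counts[key] += 1
    p_A = (counts["AB"] + counts["Ab"]) / n
    p_B = (counts["AB"] + counts["aB"]) / n
    p_AB = counts["AB"] / n
    d = p_AB - p_A * p_B
    if d >= 0:
        dmax = min(p_A * (1 - p_B), (1 - p_A) * p_B)
    else:
        dmax = min(p_A * p_B, (1 - p_A) * (1 - p_B))
    dprime = abs(d) / dmax if d != 0 else 0.0
    r2 = d * d / (p_A * (1 - p_A) * p_B * (1 - p_B))
    return d, dprime, r2


def greedy_prune(snps, pvals, r2_matrix, r2_max):
    """Exhaustive greedy pruning oracle over a known r^2 matrix."""
    order = np.argsort(pvals, kind="mergesort")
    retained = []
    for i in order:
        if all(r2_matrix[i][j] < r2_max for j in retained):
            retained.append(i)
    return [snps[i] for i in retained]


# ---------------------------------------------------------------------------
# negative-binomial GLM: hand-coded IRLS at fixed dispersion
# ---------------------------------------------------------------------------

def nb_irls(y, X, alpha, maxiter=200, tol=1e-12):
    """IRLS for a log-link NB GLM at fixed alpha (variance mu + alpha mu^2).

    Returns (coef, residual_deviance, null_deviance); deviances follow the
    standard NB deviance formula.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)

    def fit(Xd):
        beta = np.zeros(Xd.shape[1])
        beta[0] = np.log(max(y.mean(), 1e-8))
        for _ in range(maxiter):
            eta = Xd @ beta
            mu = np.exp(np.clip(eta, -30, 30))
            w = mu / (1.0 + alpha * mu)
            z = eta + (y - mu) / mu
            wx = Xd * w[:, None]
            new = np.linalg.solve(Xd.T @ wx, wx.T @ z)
            if np.max(np.abs(new - beta)) < tol:
                beta = new
                break
            beta = new
        return beta, np.exp(np.clip(Xd @ beta, -30, 30))

    def deviance(mu):
        with np.errstate(divide="ignore", invalid="ignore"):
            term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        term2 = (y + 1.0 / alpha) * np.log((1 + alpha * y) / (1 + alpha * mu))
        return float(2.0 * np.sum(term1 - term2))

    coef, mu = fit(X)
    _, mu0 = fit(np.ones((y.size, 1)))
    return coef, deviance(mu), deviance(mu0)


# ---------------------------------------------------------------------------
# loop topology truth table
# ---------------------------------------------------------------------------

def topology_truth(h_pos, e_pos, loops, target, h_block, e_block):
    """Brute-force topology label.

    ``loops`` is a list of ((a_start, a_end), (b_start, b_end)); all
    intervals are (start, end) on one chromosome; positions are ints.
    Precedence: Anchored, Unanchored, Looped, Off-target, Joint, Disjoint.
    """
    def inside(iv, pos):
        return iv[0] <= pos < iv[1]

    def overlap(iv, jv):
        return iv[0] < jv[1] and jv[0] < iv[1]

    anchors = [iv for lp in loops for iv in lp]
    if any(inside(iv, h_pos) and inside(iv, e_pos) for iv in anchors):
        return "Anchored"
    if not any(inside(iv, h_pos) for iv in anchors):
        return "Unanchored"
    for a, b in loops:
        if (inside(a, h_pos) and inside(b, e_pos)) or \
           (inside(b, h_pos) and inside(a, e_pos)):
            return "Looped"
    h_loops = [lp for lp in loops if inside(lp[0], h_pos) or inside(lp[1], h_pos)]
    if not any(overlap(a, target) or overlap(b, target) for a, b in h_loops):
        return "Off-target"
    for a, b in loops:
        if (overlap(a, h_block) and overlap(b, e_block)) or \
           (overlap(b, h_block) and overlap(a, e_block)):
            return "Joint"
    return "Disjoint"
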