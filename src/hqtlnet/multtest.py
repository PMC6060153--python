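"""Multiple-testing procedures: Holm step-down FWER and Benjamini-Hochberg FDR.

Thin wrappers around ``statsmodels.stats.multitest.multipletests`` that fix
the conventions used throughout the pipeline (adjusted p-values returned in
input order; FWER tiers at 0.1 / 0.2).
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

TIER_SIGNIFICANT = "significant"
TIER_SUGGESTIVE = "suggestive"
TIER_NS = "ns"


def holm_adjust(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down: returns (reject flags, adjusted p-values).

    Adjusted p_(k) = running max of (m-k+1) * p_(k), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, adj


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (reject flags, q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, qvals


def fwer_tier(fwer_adjusted: float, significant: float = 0.1,
              suggestive: float = 0.2) -> str:
    """Tier label for a Holm-adjusted p-value."""
    if fwer_adjusted <= significant:
        return TIER_SIGNIFICANT
    if fwer_adjusted <= suggestive:
        return TIER_SUGGESTIVE
    return TIER_NS
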