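"""Shared statistical primitives: rank-sum tests, BH correction, Spearman
screens and the hypergeometric overlap test.

These wrap scipy/statsmodels; exact-enumeration oracles for the small-sample
cases live in the test suite, not here.
"""

from __future__ import annotations

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs pass through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def rank_sum_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value per row of two dense matrices.

    Rows where every value in both groups is identical get p = 1 (no
    evidence, and the tie-corrected statistic is undefined there). The exact
    null distribution is used automatically for small tie-free groups.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    res = scipy.stats.mannwhitneyu(x, y, axis=1, alternative="two-sided", method="auto")
    p = np.asarray(res.pvalue, dtype=float)
    flat = (x.max(axis=1) == x.min(axis=1)) & (y.max(axis=1) == y.min(axis=1)) & (
        x.max(axis=1) == y.max(axis=1)
    )
    p[flat] = 1.0
    return np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)


def log2fc(mean_a: np.ndarray, mean_b: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """log2 fold change of de-logged group means with a pseudocount."""
    return np.log2((np.asarray(mean_a) + pseudocount) / (np.asarray(mean_b) + pseudocount))


def spearman_rows(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p of each row of ``x`` against vector ``y``.

    Constant rows (or a constant covariate) yield NaN rho and NaN p. The
    p-value uses the t approximation, matching scipy.stats.spearmanr.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations for a Spearman screen")
    rx = scipy.stats.rankdata(x, axis=1)
    ry = scipy.stats.rankdata(y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    sx = np.sqrt((rx**2).sum(axis=1))
    sy = np.sqrt((ry**2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ry) / denom
    rho[denom == 0] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    p[np.isnan(rho)] = np.nan
    return rho, p


def hypergeom_overlap_p(overlap: int, universe: int, size_a: int, size_b: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap) for two sets in a universe.

    Empty sets give p = 1 by convention (P(X >= 0) = 1 covers that case).
    """
    if size_a == 0 or size_b == 0 or overlap <= 0:
        return 1.0
    return float(scipy.stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))
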