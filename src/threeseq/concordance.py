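"""Frozen-vs-FFPET agreement metrics.

Per matched sample pair, agreement of expression profiles is summarized by
Spearman's rho (average ranks for ties; tag counts tie frequently).  Platform
means over the matched pairs are compared with an exact paired Wilcoxon
signed-rank test.  Agreement of differential-expression results between
preparations is summarized by the Pearson correlation of the per-gene
modified t vectors and by the first principal-component (total least
squares) axis of their scatter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

WILCOXON_EXACT_MAX_N = 25


# ---------------------------------------------------------------------------
# Rank correlations
# ---------------------------------------------------------------------------

def spearman_pair(x, y) -> float:
    """Spearman's rho with average ranks for ties; NaN if either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of >=3 values")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("Spearman rho undefined for a constant vector")
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def matched_correlations(
    expr_frozen: pd.DataFrame,
    expr_ffpet: pd.DataFrame,
    sheet: pd.DataFrame,
    platform: str = "3SEQ",
) -> pd.DataFrame:
    """One Spearman rho per matched frozen/FFPET pair over the common genes.

    Pairs come from ``pair_key`` rows of the sample sheet; a pair whose
    sample is absent from either matrix is skipped with a warning.  Cells
    missing on either side (microarray path) are excluded pairwise.
    """
    rows = []
    for key, grp in sheet.dropna(subset=["pair_key"]).groupby("pair_key"):
        by_prep = grp.set_index("preparation")["sample_id"]
        if not {"frozen", "FFPET"} <= set(by_prep.index):
            continue
        s_frozen, s_ffpet = by_prep["frozen"], by_prep["FFPET"]
        if s_frozen not in expr_frozen.columns or s_ffpet not in expr_ffpet.columns:
            warnings.warn(f"pair {key!r}: sample missing from a matrix; skipped")
            continue
        common = expr_frozen.index.intersection(expr_ffpet.index)
        x = expr_frozen.loc[common, s_frozen].to_numpy(dtype=float)
        y = expr_ffpet.loc[common, s_ffpet].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        rows.append(
            {
                "pair_key": key,
                "platform": platform,
                "spearman_rho": spearman_pair(x[ok], y[ok]),
                "n_genes": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows, columns=["pair_key", "platform", "spearman_rho", "n_genes"])


def mean_matched(
    table: pd.DataFrame,
    platform: str | None = None,
    restrict_to_pairs=None,
) -> float:
    """Arithmetic mean rho over matched pairs, optionally for one platform
    and/or a restricted pair set."""
    sel = table
    if platform is not None:
        sel = sel[sel["platform"] == platform]
    if restrict_to_pairs is not None:
        sel = sel[sel["pair_key"].isin(set(restrict_to_pairs))]
    if sel.empty:
        raise ValueError("no matched correlations selected")
    return float(sel["spearman_rho"].mean())


# ---------------------------------------------------------------------------
# Exact paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    statistic: float        # W+ = sum of ranks of positive differences
    n: int                  # nonzero differences used
    p_one_sided: float      # P(W+ >= observed): evidence the differences are positive
    p_two_sided: float
    exact: bool


def paired_wilcoxon_exact(diffs) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test with an exact null for small n.

    Zero differences are dropped before ranking (Wilcoxon's convention);
    ties among |differences| get average ranks.  For n <= 25 the null
    distribution of W+ is computed exactly over all 2^n sign assignments;
    beyond that a normal approximation with continuity and tie corrections
    is used.  The two-sided p is twice the smaller tail, capped at 1.
    """
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return WilcoxonResult(0.0, 0, 1.0, 1.0, True)
    ranks = stats.rankdata(np.abs(diffs))          # average ranks, may be half-integer
    w_plus = float(ranks[diffs > 0].sum())
    if n <= WILCOXON_EXACT_MAX_N:
        p_ge, p_le = _exact_tails(ranks, w_plus)
        return WilcoxonResult(
            w_plus, n, p_ge, min(1.0, 2.0 * min(p_ge, p_le)), exact=True
        )
    mean = ranks.sum() / 2.0
    var = float((ranks**2).sum()) / 4.0
    z_ge = (w_plus - mean - 0.5) / math.sqrt(var)
    z_le = (w_plus - mean + 0.5) / math.sqrt(var)
    p_ge = float(stats.norm.sf(z_ge))
    p_le = float(stats.norm.cdf(z_le))
    return WilcoxonResult(w_plus, n, p_ge, min(1.0, 2.0 * min(p_ge, p_le)), exact=False)


def _exact_tails(ranks: np.ndarray, w_plus: float) -> tuple[float, float]:
    """Exact P(W+ >= w) and P(W+ <= w) over all 2^n equiprobable sign vectors.

    Computed by convolving the per-rank two-point distributions (equivalent
    to full enumeration).  Average ranks are half-integers, so everything is
    scaled by 2 to stay on an integer lattice.
    """
    scaled = np.rint(2.0 * ranks).astype(int)
    total = int(scaled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w_scaled = int(round(2.0 * w_plus))
    p_ge = float(dist[w_scaled:].sum())
    p_le = float(dist[: w_scaled + 1].sum())
    return p_ge, p_le


# ---------------------------------------------------------------------------
# t-statistic agreement
# ---------------------------------------------------------------------------

def t_stat_correlation(d_a: pd.Series, d_b: pd.Series) -> float:
    """Pearson correlation of two aligned per-gene t-statistic vectors."""
    a, b = d_a.align(d_b, join="inner")
    x = a.to_numpy(dtype=float)
    y = b.to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("Pearson correlation undefined for a constant vector")
        return float("nan")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def principal_axis(d_a: pd.Series, d_b: pd.Series) -> tuple[float, float]:
    """First principal-component line (slope, intercept) through the centroid.

    This is the total-least-squares axis of the (d_a, d_b) scatter: the
    leading eigenvector of the 2x2 covariance matrix.
    """
    a, b = d_a.align(d_b, join="inner")
    x = a.to_numpy(dtype=float)
    y = b.to_numpy(dtype=float)
    cov = np.cov(x, y, ddof=1)
    if not np.all(np.isfinite(cov)) or np.allclose(cov, 0):
        raise ValueError("degenerate covariance; principal axis undefined")
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, int(np.argmax(eigvals))]
    if v[0] == 0:
        raise ValueError("principal axis is vertical (zero variance along x)")
    slope = float(v[1] / v[0])
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept
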