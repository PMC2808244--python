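"""Modified t-statistics and symmetric-cutoff permutation FDR.

The per-gene statistic is the SAM-style two-sample t of Tusher et al.:

    d_i = (mean_SFT,i - mean_DTF,i) / (s_i + s0)

with s_i the pooled standard deviation

    s_i = sqrt( (1/n1 + 1/n2) / (n1 + n2 - 2)
                * ( SS_SFT,i + SS_DTF,i ) )

and s0 a small positive constant (default 0.05) that stabilizes genes with
tiny variance.  Negative d means higher expression in DTF, positive in SFT.

The FDR at the symmetric cutoff c = |d_i| is estimated from label
permutations as

    FDR(c) = mean_b #{ |d*_b| >= c } / #{ |d| >= c },  capped at 1,

where d*_b are the statistics recomputed (same s0) under the b-th permuted
label assignment.  When the number of distinct label assignments with the
observed group sizes is small, every distinct assignment is enumerated once
(which includes the observed assignment); otherwise B assignments are drawn
uniformly at random with a mandatory seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd

S0_DEFAULT = 0.05
B_DEFAULT = 150
EXHAUSTIVE_CAP = 20_000
FDR_CUT_DEFAULT = 0.01


@dataclass
class PermutationPlan:
    """How to permute class labels: exhaustively or B random draws."""

    B: int = B_DEFAULT
    seed: int | None = None
    exhaustive_cap: int = EXHAUSTIVE_CAP

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


def _group_masks(labels: pd.Series | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    groups = set(labels)
    if groups != {"DTF", "SFT"}:
        raise ValueError(f"labels must be exactly {{'DTF','SFT'}}, got {sorted(groups)}")
    return labels == "SFT", labels == "DTF"


def _d_for_masks(X: np.ndarray, sft: np.ndarray, s0: float) -> np.ndarray:
    """Vectorized d over genes (rows of X) for one or many label assignments.

    ``sft`` is a boolean matrix (n_assignments x n_samples); returns
    (n_assignments x n_genes).  Assumes complete data.
    """
    sft = np.atleast_2d(sft)
    n = X.shape[1]
    n1 = sft.sum(axis=1)  # SFT
    n2 = n - n1
    W1 = sft.astype(float)
    W2 = (~sft).astype(float)
    # both groups summed directly (not via total - group1) so that swapping
    # the labels negates d bit-exactly and complement assignments tie exactly
    sum1 = W1 @ X.T                     # assignments x genes
    sum2 = W2 @ X.T
    Xsq = X**2
    sumsq1 = W1 @ Xsq.T
    sumsq2 = W2 @ Xsq.T
    mean1 = sum1 / n1[:, None]
    mean2 = sum2 / n2[:, None]
    ss = (sumsq1 - n1[:, None] * mean1**2) + (sumsq2 - n2[:, None] * mean2**2)
    ss = np.maximum(ss, 0.0)  # guard tiny negative round-off
    factor = ((1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2))[:, None]
    s = np.sqrt(factor * ss)
    return (mean1 - mean2) / (s + s0)


def modified_t(
    expr: pd.DataFrame, labels: pd.Series | np.ndarray, s0: float = S0_DEFAULT
) -> pd.Series:
    """Per-gene modified t between SFT and DTF samples (columns of ``expr``).

    Missing values (microarray path) are excluded per gene; a gene with
    fewer than two observed values in either group gets d = NaN.  Each group
    must have at least two samples overall.
    """
    sft, dtf = _group_masks(labels)
    if sft.sum() < 2 or dtf.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    X = expr.to_numpy(dtype=float)
    if not np.isnan(X).any():
        d = _d_for_masks(X, sft[None, :], s0)[0]
        return pd.Series(d, index=expr.index, name="d")
    # missing-aware path, per gene
    out = np.full(X.shape[0], np.nan)
    for i in range(X.shape[0]):
        x1 = X[i, sft]
        x2 = X[i, dtf]
        x1 = x1[~np.isnan(x1)]
        x2 = x2[~np.isnan(x2)]
        n1, n2 = len(x1), len(x2)
        if n1 < 2 or n2 < 2:
            continue
        ss = ((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()
        s = math.sqrt((1 / n1 + 1 / n2) / (n1 + n2 - 2) * ss)
        out[i] = (x1.mean() - x2.mean()) / (s + s0)
    return pd.Series(out, index=expr.index, name="d")


def _assignment_masks(
    labels: np.ndarray, plan: PermutationPlan
) -> tuple[np.ndarray, bool]:
    """Boolean SFT-membership matrix for the permutation set.

    Exhaustive when C(n, n_sft) <= plan.exhaustive_cap, else B random draws.
    """
    n = len(labels)
    n_sft = int((labels == "SFT").sum())
    n_distinct = math.comb(n, n_sft)
    if n_distinct <= plan.exhaustive_cap:
        masks = np.zeros((n_distinct, n), dtype=bool)
        for b, idx in enumerate(combinations(range(n), n_sft)):
            masks[b, list(idx)] = True
        return masks, True
    if plan.seed is None:
        raise ValueError("a seed is required for non-exhaustive permutation sampling")
    rng = np.random.default_rng(plan.seed)
    masks = np.zeros((plan.B, n), dtype=bool)
    for b in range(plan.B):
        masks[b, rng.choice(n, size=n_sft, replace=False)] = True
    return masks, False


def permutation_fdr(
    expr: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    d: pd.Series,
    plan: PermutationPlan | None = None,
    s0: float = S0_DEFAULT,
) -> pd.Series:
    """Symmetric-cutoff permutation FDR for each gene's cutoff c = |d_i|."""
    plan = plan or PermutationPlan()
    labels = np.asarray(labels)
    X = expr.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("permutation FDR requires complete data; drop NaN genes first")
    masks, _ = _assignment_masks(labels, plan)
    # one assignment at a time, through the exact code path used for the
    # observed d: assignments equal (or complementary) to the observed
    # labeling then reproduce |d| bit-exactly, so ties at the cutoff are
    # counted the way the printed formula intends
    d_perm = np.vstack([_d_for_masks(X, m[None, :], s0) for m in masks])
    B = d_perm.shape[0]
    perm_abs = np.sort(np.abs(d_perm).ravel())
    obs_abs_sorted = np.sort(np.abs(d.to_numpy()))
    c = np.abs(d.to_numpy())
    n_perm_ge = len(perm_abs) - np.searchsorted(perm_abs, c, side="left")
    n_obs_ge = len(obs_abs_sorted) - np.searchsorted(obs_abs_sorted, c, side="left")
    fdr = np.minimum(1.0, (n_perm_ge / B) / n_obs_ge)
    return pd.Series(fdr, index=d.index, name="fdr")


def de_table(
    expr: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    s0: float = S0_DEFAULT,
    plan: PermutationPlan | None = None,
) -> pd.DataFrame:
    """Compute d and fdr for every gene; columns ``d`` and ``fdr``."""
    d = modified_t(expr, labels, s0=s0)
    fdr = permutation_fdr(expr, labels, d, plan=plan, s0=s0)
    return pd.DataFrame({"d": d, "fdr": fdr})


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def fdr_curve(results: pd.DataFrame) -> pd.DataFrame:
    """(genes called, FDR) pairs for cutoffs at each ranked |d|.

    Genes are ranked by |d| descending; the k-th pair is (k, fdr of the
    k-th-ranked gene), i.e. the FDR at cutoff |d_(k)|.
    """
    ranked = results.reindex(results["d"].abs().sort_values(ascending=False).index)
    return pd.DataFrame(
        {
            "genes_called": np.arange(1, len(ranked) + 1),
            "fdr": ranked["fdr"].to_numpy(),
            "cutoff": ranked["d"].abs().to_numpy(),
        }
    )


def significant_genes(
    results: pd.DataFrame, fdr_cut: float = FDR_CUT_DEFAULT
) -> dict[str, list[str]]:
    """Genes with fdr strictly below the cut, split by direction.

    DTF-high genes have d < 0, SFT-high d > 0 (d = 0 genes are reported in
    neither direction).
    """
    hit = results[results["fdr"] < fdr_cut]
    return {
        "DTF": list(hit.index[hit["d"] < 0]),
        "SFT": list(hit.index[hit["d"] > 0]),
    }


def top_k_by_direction(
    results: pd.DataFrame,
    direction: str,
    k: int = 1000,
    mode: str = "rank",
    fdr_cut: float = 0.05,
) -> list[str]:
    """Ranked gene list for one direction.

    ``mode='rank'``: the k genes with the most extreme d in the direction
    (most negative for DTF, most positive for SFT), restricted to genes whose
    sign actually favors that direction.  ``mode='fdr'`` (the fallback used
    when few genes reach significance): all genes in the direction with
    fdr < ``fdr_cut``, ranked the same way.
    """
    if direction not in ("DTF", "SFT"):
        raise ValueError("direction must be 'DTF' or 'SFT'")
    d = results["d"]
    sel = results[d < 0] if direction == "DTF" else results[d > 0]
    ranked = sel.reindex(sel["d"].abs().sort_values(ascending=False).index)
    if mode == "fdr":
        return list(ranked.index[ranked["fdr"] < fdr_cut])
    if mode != "rank":
        raise ValueError(f"unknown mode {mode!r}")
    if k > len(ranked):
        warnings.warn(
            f"requested top {k} {direction} genes but only {len(ranked)} available"
        )
    return list(ranked.index[:k])


def list_overlap(lists: dict[str, list[str] | set[str]]) -> pd.DataFrame:
    """Counts and percentages for every intersection region of <=4 gene lists.

    One row per non-empty membership pattern (e.g. in lists A and B but not
    C); counts sum to the union size and percentages are relative to it.
    """
    if len(lists) > 4:
        raise ValueError("at most 4 lists supported")
    names = list(lists)
    sets = {name: set(lists[name]) for name in names}
    union: set[str] = set().union(*sets.values()) if sets else set()
    rows = []
    for pattern in product([True, False], repeat=len(names)):
        if not any(pattern):
            continue
        region = set(union)
        for name, inside in zip(names, pattern):
            region &= sets[name] if inside else (union - sets[name])
        rows.append(
            {
                **{name: inside for name, inside in zip(names, pattern)},
                "count": len(region),
                "percent": 100.0 * len(region) / len(union) if union else 0.0,
            }
        )
    return pd.DataFrame(rows)
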