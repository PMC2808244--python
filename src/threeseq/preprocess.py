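"""Gene filtering, transformation, and per-sample centering/scaling.

Two data paths share this module.  Tag-count matrices are integer, complete
(zeros are data, never missing), filtered on a minimum total read count, and
optionally log-transformed before standardization.  Microarray log-ratio
matrices carry missing values: probes are first collapsed to gene level by
averaging, then genes with too little valid data are removed.  Either path
ends in per-sample centering and scaling (mean 0, SD 1 over observed values,
sample SD with the n-1 convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

MIN_TOTAL_READS = 25
MIN_VALID_FRACTION = 0.70


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples matrix with a provenance tag.

    Missing values are NaN (microarray path only; transformed tag counts are
    complete by construction).
    """

    data: pd.DataFrame
    provenance: str  # {"tag_counts_transformed", "microarray_log_ratio"}

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# Tag-count path
# ---------------------------------------------------------------------------

def min_total_reads_filter(
    counts: pd.DataFrame, min_total: int = MIN_TOTAL_READS
) -> pd.DataFrame:
    """Keep genes with at least ``min_total`` reads summed across samples."""
    return counts.loc[counts.sum(axis=1) >= min_total]


def transform_counts(counts: pd.DataFrame, mode: str = "log2p1") -> ExpressionMatrix:
    """Transform non-negative counts: ``log2p1`` -> log2(c+1); ``raw`` -> identity."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if mode == "log2p1":
        data = np.log2(counts.astype(float) + 1.0)
    elif mode == "raw":
        data = counts.astype(float).copy()
    else:
        raise ValueError(f"unknown transform mode {mode!r}")
    return ExpressionMatrix(data, provenance="tag_counts_transformed")


# ---------------------------------------------------------------------------
# Microarray path
# ---------------------------------------------------------------------------

def collapse_probes(
    probe_ratios: pd.DataFrame, probe_to_gene: pd.Series | dict
) -> tuple[pd.DataFrame, int]:
    """Average multiple probes of the same gene symbol.

    ``probe_ratios`` is probes x samples (log2 ratios, NaN = invalid spot);
    ``probe_to_gene`` maps probe id -> gene symbol.  Probes without a mapping
    are dropped; the number dropped is returned alongside the gene matrix.
    A cell whose probes are all missing stays missing.
    """
    mapping = pd.Series(probe_to_gene).astype(str).str.upper()
    known = probe_ratios.index.intersection(mapping.index)
    n_dropped = len(probe_ratios.index) - len(known)
    kept = probe_ratios.loc[known]
    genes = mapping.loc[known]
    collapsed = kept.groupby(genes.values).mean()
    collapsed.index.name = "gene"
    return collapsed.sort_index(), n_dropped


def valid_fraction_filter(
    matrix: pd.DataFrame, min_fraction: float = MIN_VALID_FRACTION
) -> pd.DataFrame:
    """Keep genes observed (non-missing) in at least ``min_fraction`` of samples."""
    observed = matrix.notna().mean(axis=1)
    return matrix.loc[observed >= min_fraction]


# ---------------------------------------------------------------------------
# Shared
# ---------------------------------------------------------------------------

def center_scale(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each sample to mean 0, SD 1 over its observed values.

    Missing cells are excluded from the moments and left missing.  A sample
    with (near-)constant observed values cannot be scaled and is an error.
    """
    data = matrix.data
    mean = data.mean(axis=0, skipna=True)
    sd = data.std(axis=0, ddof=1, skipna=True)
    degenerate = ~(sd > 0)
    if degenerate.any():
        bad = list(data.columns[degenerate])
        raise ValueError(f"cannot scale constant sample(s): {bad}")
    return replace(matrix, data=(data - mean) / sd)


def intersect_genes(
    a: pd.DataFrame, b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict two matrices to their common gene roster, sorted."""
    common = a.index.intersection(b.index).sort_values()
    if len(common) == 0:
        raise ValueError("gene rosters have an empty intersection")
    return a.loc[common], b.loc[common]


def count_pipeline(
    counts: pd.DataFrame,
    min_total: int = MIN_TOTAL_READS,
    transform: str = "log2p1",
) -> ExpressionMatrix:
    """Convenience chain for the tag-count path: filter, transform, standardize."""
    filtered = min_total_reads_filter(counts, min_total=min_total)
    if filtered.empty:
        warnings.warn("no genes pass the minimum-reads filter")
        return ExpressionMatrix(filtered.astype(float), "tag_counts_transformed")
    return center_scale(transform_counts(filtered, mode=transform))
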