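"""Genes expressed exclusively (or almost exclusively) in one tumor group.

For each gene the pooled read fraction per group is computed over the
filtered roster:

    frac_G(gene) = (reads for the gene summed over group-G samples)
                   / (all reads summed over group-G samples)

and the exclusivity ratio is frac_DTF / frac_SFT (infinite when the SFT
fraction is zero but the DTF fraction is not).  A high ratio means the gene
is expressed in DTF with (almost) no expression in SFT; a ratio near zero
means the opposite.  The reported lists require a gene to pass the fold (or
strict exclusivity) and minimum-read thresholds on BOTH tissue preparations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MIN_READS = 100
MIN_FOLD = 100.0


def exclusivity_scores(
    counts: pd.DataFrame, labels: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Per-gene pooled counts, fractions, ratio, and exclusivity flag.

    ``counts`` should already be restricted to the analysis roster (the
    >=25-total-reads filter).  Columns of the result: reads_dtf, reads_sft,
    frac_dtf, frac_sft, ratio, exclusive_in.
    """
    labels = np.asarray(labels)
    if set(labels) != {"DTF", "SFT"}:
        raise ValueError("labels must contain exactly the groups DTF and SFT")
    reads_dtf = counts.loc[:, labels == "DTF"].sum(axis=1)
    reads_sft = counts.loc[:, labels == "SFT"].sum(axis=1)
    total_dtf = int(reads_dtf.sum())
    total_sft = int(reads_sft.sum())
    if total_dtf == 0 or total_sft == 0:
        raise ValueError("a group has zero total reads; cannot form fractions")
    frac_dtf = reads_dtf / total_dtf
    frac_sft = reads_sft / total_sft
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = frac_dtf / frac_sft          # inf when frac_sft == 0, dtf > 0
    ratio = ratio.where(~((frac_dtf == 0) & (frac_sft == 0)), np.nan)
    exclusive_in = pd.Series("none", index=counts.index, name="exclusive_in")
    exclusive_in[(reads_sft == 0) & (reads_dtf > 0)] = "DTF"
    exclusive_in[(reads_dtf == 0) & (reads_sft > 0)] = "SFT"
    return pd.DataFrame(
        {
            "reads_dtf": reads_dtf.astype(int),
            "reads_sft": reads_sft.astype(int),
            "frac_dtf": frac_dtf,
            "frac_sft": frac_sft,
            "ratio": ratio,
            "exclusive_in": exclusive_in,
        }
    )


def _passes(
    rec: pd.DataFrame,
    direction: str,
    min_reads: int,
    min_fold: float,
    reads_scope: str,
) -> pd.Series:
    if direction == "DTF":
        fold_ok = (rec["exclusive_in"] == "DTF") | (rec["ratio"] >= min_fold)
        favored_reads = rec["reads_dtf"]
    else:
        fold_ok = (rec["exclusive_in"] == "SFT") | (rec["ratio"] <= 1.0 / min_fold)
        favored_reads = rec["reads_sft"]
    if reads_scope == "all":
        reads_ok = rec["reads_dtf"] + rec["reads_sft"] >= min_reads
    elif reads_scope == "favored":
        reads_ok = favored_reads >= min_reads
    else:
        raise ValueError("reads_scope must be 'all' or 'favored'")
    return fold_ok & reads_ok


def exclusive_gene_list(
    records_frozen: pd.DataFrame,
    records_ffpet: pd.DataFrame,
    min_reads: int = MIN_READS,
    min_fold: float = MIN_FOLD,
    reads_scope: str = "all",
) -> dict[str, list[str]]:
    """Genes exclusive (or >= min_fold enriched) in one group on BOTH preparations.

    ``reads_scope`` chooses whether the minimum-read threshold counts reads
    from both groups ('all') or only the favored group ('favored').
    Returned lists are disjoint between directions.
    """
    out: dict[str, list[str]] = {}
    for direction in ("DTF", "SFT"):
        pass_frozen = _passes(records_frozen, direction, min_reads, min_fold, reads_scope)
        pass_ffpet = _passes(records_ffpet, direction, min_reads, min_fold, reads_scope)
        common = records_frozen.index.intersection(records_ffpet.index)
        both = pass_frozen.reindex(common, fill_value=False) & pass_ffpet.reindex(
            common, fill_value=False
        )
        out[direction] = sorted(common[both])
    return out
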