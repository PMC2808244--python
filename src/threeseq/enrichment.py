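"""Gene-set over-representation with the EASE score.

The EASE score is a conservative ("jackknifed") variant of the one-sided
Fisher exact test used by DAVID: one gene is removed from the list-by-set
overlap before computing the hypergeometric enrichment tail, which can only
weaken the evidence.  With a background of ``n_bg`` genes, ``n_set_bg`` of
which belong to the set, and a query list of ``n_list`` genes of which
``n_hits`` are in the set:

    EASE p = P( X >= max(n_hits - 1, 0) ),   X ~ Hypergeom(n_bg, n_set_bg, n_list)

The tail is evaluated in log space through the survival function of the
hypergeometric distribution.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("threeseq")

MIN_GENES = 10
P_CUT = 0.05


def _check_margins(n_hits: int, n_list: int, n_set_bg: int, n_bg: int) -> None:
    if not (0 <= n_hits <= min(n_list, n_set_bg) <= n_bg and n_list <= n_bg):
        raise ValueError(
            f"inconsistent 2x2 margins: hits={n_hits}, list={n_list}, "
            f"set={n_set_bg}, background={n_bg}"
        )


def fisher_p(n_hits: int, n_list: int, n_set_bg: int, n_bg: int) -> float:
    """Un-jackknifed one-sided (enrichment) Fisher exact p."""
    _check_margins(n_hits, n_list, n_set_bg, n_bg)
    return float(np.exp(stats.hypergeom.logsf(n_hits - 1, n_bg, n_set_bg, n_list)))


def ease_score(n_hits: int, n_list: int, n_set_bg: int, n_bg: int) -> float:
    """EASE score: the enrichment tail with one overlap gene removed."""
    _check_margins(n_hits, n_list, n_set_bg, n_bg)
    k = max(n_hits - 1, 0)
    return float(np.exp(stats.hypergeom.logsf(k - 1, n_bg, n_set_bg, n_list)))


def enrich(
    query_list: Iterable[str],
    gene_sets: Mapping[str, set[str]],
    background: Iterable[str],
    min_genes: int = MIN_GENES,
    p_cut: float = P_CUT,
) -> pd.DataFrame:
    """Over-represented sets among ``query_list`` against ``background``.

    Gene sets are intersected with the background before counting; genes
    dropped that way are logged.  Only sets contributing at least
    ``min_genes`` query genes and reaching an EASE score below ``p_cut`` are
    reported, sorted by EASE score.  Symbols compare case-insensitively.
    """
    background_set = {g.upper() for g in background}
    query = {g.upper() for g in query_list}
    stray = query - background_set
    if stray:
        raise ValueError(
            f"{len(stray)} query gene(s) absent from background, e.g. "
            f"{sorted(stray)[:10]}"
        )
    n_bg = len(background_set)
    n_list = len(query)
    rows = []
    for name, members in gene_sets.items():
        members_up = {m.upper() for m in members}
        in_bg = members_up & background_set
        dropped = len(members_up) - len(in_bg)
        if dropped:
            logger.info("set %s: %d member(s) outside background dropped", name, dropped)
        n_set_bg = len(in_bg)
        n_hits = len(query & in_bg)
        if n_hits < min_genes or n_set_bg == 0:
            continue
        p = ease_score(n_hits, n_list, n_set_bg, n_bg)
        if p < p_cut:
            rows.append(
                {
                    "set": name,
                    "n_hits": n_hits,
                    "n_list": n_list,
                    "n_set_bg": n_set_bg,
                    "n_bg": n_bg,
                    "ease_p": p,
                }
            )
    out = pd.DataFrame(
        rows, columns=["set", "n_hits", "n_list", "n_set_bg", "n_bg", "ease_p"]
    )
    return out.sort_values(["ease_p", "set"], kind="stable").reset_index(drop=True)
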