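"""Tag filtering and strand-aware attribution of tags to genes.

A tag is attributed to a gene when it lies within the gene span extended by
``flank`` bp (default 1000) on either side and maps on the gene's strand.
Within one gene the category follows the fixed precedence
UTR3 > CODING_EXON > INTRON > FLANK_1KB (any base-pair overlap counts).
A tag eligible for two or more genes goes to the gene whose 3' end is
nearest; an exact tie is AMBIGUOUS and unassigned.  A tag inside a gene on
the wrong strand is WRONG_ORIENTATION; a tag with no gene within the flank
is INTERGENIC.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .formats_io import AlignedTag, GeneModel, validate_sample_sheet

DEFAULT_FLANK = 1000
MAX_MISMATCH = 1


class Category(str, Enum):
    UTR3 = "UTR3"
    CODING_EXON = "CODING_EXON"
    INTRON = "INTRON"
    FLANK_1KB = "FLANK_1KB"
    WRONG_ORIENTATION = "WRONG_ORIENTATION"
    INTERGENIC = "INTERGENIC"
    DISCARDED_NONUNIQUE = "DISCARDED_NONUNIQUE"
    DISCARDED_MISMATCH = "DISCARDED_MISMATCH"
    AMBIGUOUS = "AMBIGUOUS"


#: categories that attribute the tag to a gene
ASSIGNED_CATEGORIES = (
    Category.UTR3,
    Category.CODING_EXON,
    Category.INTRON,
    Category.FLANK_1KB,
)

_PRECEDENCE = {c: i for i, c in enumerate(ASSIGNED_CATEGORIES)}


@dataclass(slots=True)
class TagAssignment:
    tag: AlignedTag
    symbol: str | None
    category: Category

    def __post_init__(self) -> None:
        has_symbol = self.symbol is not None
        if has_symbol != (self.category in ASSIGNED_CATEGORIES):
            raise ValueError(
                f"symbol must be present iff assigned (got {self.symbol!r}, "
                f"{self.category})"
            )


@dataclass
class TagCountMatrix:
    """Genes x samples integer counts with the sample sheet attached."""

    counts: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def group_labels(self) -> pd.Series:
        sheet = self.sample_sheet.set_index("sample_id")
        return sheet.loc[self.samples, "group"]


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_tags(
    tags: Iterable[AlignedTag], max_mismatch: int = MAX_MISMATCH
) -> tuple[list[AlignedTag], Counter]:
    """Discard non-unique tags and tags with more than ``max_mismatch`` mismatches.

    Returns the kept tags and a tally of discards per reason.
    """
    kept: list[AlignedTag] = []
    tally: Counter = Counter()
    for tag in tags:
        if not tag.is_unique:
            tally[Category.DISCARDED_NONUNIQUE] += 1
        elif tag.n_mismatch > max_mismatch:
            tally[Category.DISCARDED_MISMATCH] += 1
        else:
            kept.append(tag)
    return kept, tally


# ---------------------------------------------------------------------------
# Gene interval index
# ---------------------------------------------------------------------------

class GeneIndex:
    """Interval index over gene models with a fixed flank extension."""

    def __init__(self, genes: Sequence[GeneModel], flank: int = DEFAULT_FLANK):
        if flank < 0:
            raise ValueError("flank must be >= 0")
        self.flank = flank
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for gene in self.genes:
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            tree.addi(max(0, gene.tx_start - flank), gene.tx_end + flank, gene)

    def overlapping(self, tag: AlignedTag) -> list[GeneModel]:
        tree = self._trees.get(tag.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(tag.start, tag.end)]
        hits.sort(key=lambda g: (g.tx_start, g.symbol))  # order-independence
        return hits


def _overlaps(tag: AlignedTag, interval: tuple[int, int]) -> bool:
    return tag.start < interval[1] and interval[0] < tag.end


def _category_within_gene(tag: AlignedTag, gene: GeneModel) -> Category:
    if gene.utr3 is not None and _overlaps(tag, gene.utr3):
        return Category.UTR3
    if any(_overlaps(tag, exon) for exon in gene.coding_exons):
        return Category.CODING_EXON
    if _overlaps(tag, (gene.tx_start, gene.tx_end)):
        return Category.INTRON
    return Category.FLANK_1KB


def _distance_to_point(tag: AlignedTag, point: int) -> int:
    # distance from the tag interval [start, end) to a genomic coordinate
    if point < tag.start:
        return tag.start - point
    if point > tag.end:
        return point - tag.end
    return 0


def assign_tag(tag: AlignedTag, index: GeneIndex) -> TagAssignment:
    """Attribute one filtered tag to a gene (or a non-assigned category)."""
    candidates = index.overlapping(tag)
    eligible = [g for g in candidates if g.strand == tag.strand]
    if not eligible:
        intragenic = any(
            _overlaps(tag, (g.tx_start, g.tx_end)) for g in candidates
        )
        cat = Category.WRONG_ORIENTATION if intragenic else Category.INTERGENIC
        return TagAssignment(tag, None, cat)
    if len(eligible) == 1:
        gene = eligible[0]
    else:
        # tie-break: nearest 3' end; exact tie -> ambiguous
        dists = [(_distance_to_point(tag, g.three_prime_end), g) for g in eligible]
        dists.sort(key=lambda item: item[0])
        if dists[0][0] == dists[1][0]:
            return TagAssignment(tag, None, Category.AMBIGUOUS)
        gene = dists[0][1]
    return TagAssignment(tag, gene.symbol, _category_within_gene(tag, gene))


def assign_tags(
    tags: Iterable[AlignedTag],
    genes: Sequence[GeneModel],
    flank: int = DEFAULT_FLANK,
) -> list[TagAssignment]:
    index = GeneIndex(genes, flank=flank)
    return [assign_tag(tag, index) for tag in tags]


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def build_counts(
    tags: Iterable[AlignedTag],
    genes: Sequence[GeneModel],
    sample_sheet: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    exclude_introns: bool = False,
) -> tuple[TagCountMatrix, list[TagAssignment]]:
    """Count attributed tags per (gene, sample) from pre-filtered tags.

    Conservation holds per sample: assigned + unassigned = input tags.
    With ``exclude_introns`` intronic tags keep their category but are not
    counted toward the gene (the stricter exon/UTR-only reading).
    """
    sample_sheet = validate_sample_sheet(sample_sheet)
    samples = list(sample_sheet["sample_id"])
    assignments = assign_tags(tags, genes, flank=flank)
    counted = {c for c in ASSIGNED_CATEGORIES}
    if exclude_introns:
        counted.discard(Category.INTRON)
    known_samples = set(samples)
    cells: Counter = Counter()
    for a in assignments:
        if a.tag.sample_id not in known_samples:
            raise ValueError(f"sample {a.tag.sample_id!r} missing from sample sheet")
        if a.category in counted:
            cells[(a.symbol, a.tag.sample_id)] += 1
    roster = sorted({g.symbol for g in genes})
    counts = pd.DataFrame(0, index=pd.Index(roster, name="gene"), columns=samples)
    for (symbol, sample), n in cells.items():
        counts.loc[symbol, sample] = n
    return TagCountMatrix(counts, sample_sheet), assignments


def category_summary(assignments: Sequence[TagAssignment]) -> pd.DataFrame:
    """Per-sample fractions of attributed tags over the assigned categories.

    Columns are the four assigned categories; rows per sample sum to 1.
    """
    rows: dict[str, Counter] = {}
    for a in assignments:
        if a.category in ASSIGNED_CATEGORIES:
            rows.setdefault(a.tag.sample_id, Counter())[a.category.value] += 1
    table = pd.DataFrame(
        [
            {"sample_id": s, **{c.value: rows[s].get(c.value, 0) for c in ASSIGNED_CATEGORIES}}
            for s in sorted(rows)
        ]
    )
    if table.empty:
        return pd.DataFrame(
            columns=["sample_id", *(c.value for c in ASSIGNED_CATEGORIES)]
        )
    table = table.set_index("sample_id")
    return table.div(table.sum(axis=1), axis=0)


def discard_summary(tally: Counter) -> pd.DataFrame:
    """Tidy view of the filter_tags discard tally."""
    return pd.DataFrame(
        [{"reason": cat.value, "n": n} for cat, n in sorted(tally.items())]
    )
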