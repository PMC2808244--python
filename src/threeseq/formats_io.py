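"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals
(the BED convention).  GFF3 input, which is 1-based closed, is converted on
read.  Gene symbols are uppercased on read so that rosters coming from
different files compare case-insensitively.

Alignment dialect
-----------------
Tag alignments are consumed and produced as a 6+2 column BED:

    chrom  start  end  name  score  strand  [sample_id]  [unique]

where ``score`` carries the aligner's mismatch count (0, 1, 2, ...) and the
optional eighth column flags mapping uniqueness (``1``/``0``; absent means
unique).  The seventh column carries the sample identifier; when absent the
``default_sample`` argument is used.  Only the first 25 bp (``seed_length``)
of a record define the mapped interval; longer records are truncated on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger("threeseq")

SEED_LENGTH = 25

#: itemRgb values used for strand-colored browser tracks.
FORWARD_COLOR = "0,0,255"
REVERSE_COLOR = "255,0,0"

GROUPS = ("DTF", "SFT")
PREPARATIONS = ("frozen", "FFPET")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class AlignedTag:
    """One mapped 3'-tag read (a 25 bp seed alignment)."""

    chrom: str
    start: int
    end: int
    strand: str
    n_mismatch: int = 0
    is_unique: bool = True
    sample_id: str = "sample"
    read_id: str = "."

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for tag {self.read_id}"
            )
        if self.n_mismatch < 0:
            raise ValueError("n_mismatch must be >= 0")


@dataclass(slots=True, frozen=True)
class GeneModel:
    """A gene collapsed to one model per symbol.

    ``coding_exons`` are the coding portions of exons, sorted and
    non-overlapping; ``utr3``, when present, abuts the 3' end of the
    transcript span (the right end on ``+``, the left end on ``-``).
    """

    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    coding_exons: tuple[tuple[int, int], ...] = ()
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.symbol}: strand must be '+' or '-'")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"{self.symbol}: invalid span")
        prev = self.tx_start
        for lo, hi in self.coding_exons:
            if lo < prev or hi > self.tx_end or lo >= hi:
                raise ValueError(f"{self.symbol}: bad coding exon ({lo}, {hi})")
            prev = hi
        if self.utr3 is not None:
            lo, hi = self.utr3
            if lo >= hi:
                raise ValueError(f"{self.symbol}: degenerate utr3")
            end_ok = hi == self.tx_end if self.strand == "+" else lo == self.tx_start
            if not end_ok or lo < self.tx_start or hi > self.tx_end:
                raise ValueError(f"{self.symbol}: utr3 must abut the 3' end")

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the poly-A-proximal end of the span."""
        return self.tx_end if self.strand == "+" else self.tx_start


# ---------------------------------------------------------------------------
# Tag alignments (BED6+2)
# ---------------------------------------------------------------------------

def read_alignments(
    path: str | Path,
    default_sample: str = "sample",
    seed_length: int = SEED_LENGTH,
) -> Iterator[AlignedTag]:
    """Stream tags from a BED-like alignment file (dialect in module docs)."""
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >=6 tab-separated columns "
                    f"(strand column required), got {len(fields)}"
                )
            chrom, start_s, end_s, name, score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
                n_mismatch = int(score)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from None
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinate {start}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            if end - start > seed_length:
                # only the seed defines the mapped interval; the seed is the
                # 5'-most part of the read, which on '-' is the interval's end
                if strand == "+":
                    end = start + seed_length
                else:
                    start = end - seed_length
            sample_id = fields[6] if len(fields) > 6 else default_sample
            is_unique = fields[7] != "0" if len(fields) > 7 else True
            yield AlignedTag(
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                n_mismatch=n_mismatch,
                is_unique=is_unique,
                sample_id=sample_id,
                read_id=name,
            )


def write_alignments(tags: Iterable[AlignedTag], path: str | Path) -> None:
    """Write tags in the canonical 8-column dialect (inverse of the reader)."""
    with Path(path).open("w") as fh:
        for t in tags:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.read_id}\t{t.n_mismatch}\t"
                f"{t.strand}\t{t.sample_id}\t{1 if t.is_unique else 0}\n"
            )


# ---------------------------------------------------------------------------
# Gene annotation (BED12 / GFF3)
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from BED12 or GFF3, collapsing to one model per symbol.

    Multi-transcript symbols are collapsed to the union span; the 3'-most
    coding end defines the 3'UTR.  Models are returned sorted by
    (chrom, tx_start).  A symbol annotated on conflicting strands is an error.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "gff3" if suffix in (".gff", ".gff3") else "bed12"
    if fmt == "bed12":
        raw = _read_bed12(path)
    elif fmt == "gff3":
        raw = _read_gff3(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return _collapse_by_symbol(raw)


@dataclass
class _RawTranscript:
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)


def _read_bed12(path: Path) -> list[_RawTranscript]:
    out: list[_RawTranscript] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            block_sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
            block_starts = [int(x) for x in f[11].rstrip(",").split(",") if x]
            tx = _RawTranscript(name.upper(), chrom, strand, start, end)
            for off, size in zip(block_starts, block_sizes):
                exon = (start + off, start + off + size)
                lo = max(exon[0], thick_start)
                hi = min(exon[1], thick_end)
                if lo < hi:  # thickStart==thickEnd => non-coding, no CDS
                    tx.cds_intervals.append((lo, hi))
            out.append(tx)
    return out


def _gff3_attributes(field9: str) -> dict[str, str]:
    attrs = {}
    for item in field9.rstrip(";").split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def _read_gff3(path: Path) -> list[_RawTranscript]:
    """Minimal GFF3 reader for gene / (mRNA) / CDS features.

    1-based closed coordinates are converted to 0-based half-open.  CDS
    features are attached to their gene through the Parent chain (one level
    of mRNA indirection supported) or a shared ``gene_id``.
    """
    genes: dict[str, _RawTranscript] = {}
    parent_of: dict[str, str] = {}  # mRNA ID -> gene ID
    pending_cds: list[tuple[str, int, int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: GFF3 requires 9 columns")
            chrom, _, ftype, start1, end1, _, strand, _, attr_s = f[:9]
            start, end = int(start1) - 1, int(end1)
            attrs = _gff3_attributes(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
                symbol = attrs.get("Name") or attrs.get("gene_id") or gid
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: gene without ID/Name")
                genes[gid] = _RawTranscript(symbol.upper(), chrom, strand, start, end)
            elif ftype in ("mRNA", "transcript"):
                tid = attrs.get("ID")
                parent = attrs.get("Parent")
                if tid and parent:
                    parent_of[tid] = parent
            elif ftype == "CDS":
                parent = attrs.get("Parent") or attrs.get("gene_id")
                if parent:
                    pending_cds.append((parent, start, end))
    for parent, start, end in pending_cds:
        gid = parent_of.get(parent, parent)
        if gid in genes:
            genes[gid].cds_intervals.append((start, end))
        else:
            logger.warning("CDS with unresolvable parent %s dropped", parent)
    return list(genes.values())


def _merge_intervals(ivals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for lo, hi in sorted(ivals):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return tuple((lo, hi) for lo, hi in merged)


def _collapse_by_symbol(raw: Sequence[_RawTranscript]) -> list[GeneModel]:
    by_symbol: dict[str, list[_RawTranscript]] = {}
    for tx in raw:
        by_symbol.setdefault(tx.symbol, []).append(tx)
    models = []
    for symbol, txs in by_symbol.items():
        strands = {t.strand for t in txs}
        if len(strands) > 1:
            raise ValueError(f"symbol {symbol} annotated on conflicting strands")
        chroms = {t.chrom for t in txs}
        if len(chroms) > 1:
            raise ValueError(f"symbol {symbol} annotated on multiple chromosomes")
        strand = strands.pop()
        tx_start = min(t.start for t in txs)
        tx_end = max(t.end for t in txs)
        coding = _merge_intervals(iv for t in txs for iv in t.cds_intervals)
        utr3 = None
        if coding:
            if strand == "+":
                cds_end = max(hi for _, hi in coding)
                if cds_end < tx_end:
                    utr3 = (cds_end, tx_end)
            else:
                cds_start = min(lo for lo, _ in coding)
                if cds_start > tx_start:
                    utr3 = (tx_start, cds_start)
        models.append(
            GeneModel(symbol, txs[0].chrom, strand, tx_start, tx_end, coding, utr3)
        )
    models.sort(key=lambda g: (g.chrom, g.tx_start, g.symbol))
    return models


def write_annotation_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 (one row per collapsed model)."""
    with Path(path).open("w") as fh:
        for g in genes:
            if g.coding_exons:
                thick_start = min(lo for lo, _ in g.coding_exons)
                thick_end = max(hi for _, hi in g.coding_exons)
                blocks = list(g.coding_exons)
                # make blocks span the whole record as BED12 requires
                if blocks[0][0] > g.tx_start:
                    blocks.insert(0, (g.tx_start, blocks[0][0]))
                if blocks[-1][1] < g.tx_end:
                    blocks.append((blocks[-1][1], g.tx_end))
                blocks = list(_merge_intervals(blocks))
            else:
                thick_start = thick_end = g.tx_start
                blocks = [(g.tx_start, g.tx_end)]
            sizes = ",".join(str(hi - lo) for lo, hi in blocks) + ","
            offsets = ",".join(str(lo - g.tx_start) for lo, _ in blocks) + ","
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.symbol}\t0\t{g.strand}\t"
                f"{thick_start}\t{thick_end}\t0\t{len(blocks)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV: sample_id, group, preparation[, pair_key]."""
    sheet = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "group", "preparation"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if "pair_key" not in sheet.columns:
        sheet = sheet.assign(pair_key=pd.NA)
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s): {dups}")
    bad_group = set(sheet["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown group(s) {sorted(bad_group)}; expected {GROUPS}")
    bad_prep = set(sheet["preparation"]) - set(PREPARATIONS)
    if bad_prep:
        raise ValueError(
            f"unknown preparation(s) {sorted(bad_prep)}; expected {PREPARATIONS}"
        )
    for key, grp in sheet.dropna(subset=["pair_key"]).groupby("pair_key"):
        if len(grp) == 2:
            if grp["preparation"].nunique() != 2 or grp["group"].nunique() != 1:
                raise ValueError(
                    f"pair_key {key!r}: a matched pair must differ in preparation "
                    "and share the tumor group"
                )
    return sheet.reset_index(drop=True)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into {set name: set of uppercased member symbols}."""
    sets: dict[str, set[str]] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                warnings.warn(f"{path}:{lineno}: skipping GMT line with <3 fields")
                continue
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {m.upper() for m in fields[2:] if m}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with Path(path).open("w") as fh:
        for name in sets:
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


# ---------------------------------------------------------------------------
# Browser tracks
# ---------------------------------------------------------------------------

def write_track(tags: Iterable[AlignedTag], path: str | Path, name: str = "3SEQ") -> None:
    """Write a strand-colored BED9 track (forward blue, reverse red)."""
    with Path(path).open("w") as fh:
        fh.write(f'track name="{name}" itemRgb="On"\n')
        for t in tags:
            color = FORWARD_COLOR if t.strand == "+" else REVERSE_COLOR
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.read_id}\t{t.n_mismatch}\t"
                f"{t.strand}\t{t.start}\t{t.end}\t{color}\n"
            )


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, kind: str = "counts") -> pd.DataFrame:
    """Read a genes x samples TSV (first column symbols, header sample ids).

    ``kind='counts'`` treats duplicate symbols as a hard error; the matrix is
    integer and has no missing values (zeros are data).  ``kind='microarray'``
    averages duplicate symbols with a warning and preserves NA cells.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str).str.upper()
    df.index.name = "gene"
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        if kind == "counts":
            raise ValueError(f"duplicate gene symbols in count matrix: {dups[:10]}")
        warnings.warn(f"averaging {len(dups)} duplicate symbol(s) in microarray matrix")
        df = df.groupby(level=0, sort=False).mean()
    if kind == "counts":
        if df.isna().any().any():
            raise ValueError("count matrix contains missing values")
        df = df.astype(int)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", na_rep="NA")
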