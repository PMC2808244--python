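"""Synthetic 3'-tag sequencing experiments with known truth.

The generator emulates the structure of a two-group tag-sequencing study:

* a toy genome of non-overlapping genes on alternating strands, each with
  coding exons, introns and a 3'UTR;
* two tumor groups (DTF, SFT) whose per-gene transcript abundances follow a
  log-normal baseline, a configurable fraction of genes differentially
  expressed at a fixed fold change (split evenly by direction), and
  per-sample counts drawn negative-binomially and scaled to a target
  library size;
* exactly one sequenced 25 bp tag per transcript molecule, positioned near
  the transcript 3' end.  Intact RNA (frozen) is fragmented to 100-200
  bases, so the tag sits 100-200 b upstream of the poly-A site; degraded
  RNA (FFPET) yields tags concentrated within 0-80 b of it.  A
  preparation-specific fraction of tags is mispositioned uniformly within
  the gene body, emulating internal oligo-dT priming at A-rich stretches
  and annotation mismatch -- the mechanisms that place real tags in coding
  exons and introns;
* contamination: ~20% of all reads are unmappable poly-A stretches, plus
  configurable non-unique and 2-mismatch fractions, all of which the
  quantifier must discard.

Everything is deterministic under (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .formats_io import AlignedTag, GeneModel

READ_LEN = 25

#: distance (b) from the poly-A site to a tag's 3' edge, by preparation
FRAG_WINDOWS = {"frozen": (100, 200), "ffpet": (0, 80)}

#: fraction of tags mispositioned uniformly within the gene body
MISPOSITIONED = {"frozen": 0.65, "ffpet": 0.50}


@dataclass
class SimConfig:
    """Study conditions for one simulated preparation arm."""

    n_genes: int = 2000
    n_dtf: int = 6
    n_sft: int = 6
    de_fraction: float = 0.10
    fold_change: float = 4.0
    dispersion: float = 0.15
    mean_library_size: int = 100_000
    polyA_fraction: float = 0.20
    nonunique_fraction: float = 0.05
    mismatch2_fraction: float = 0.02
    mismatch1_fraction: float = 0.10   # kept reads carrying one mismatch
    prep: str = "ffpet"
    frag_window: tuple[int, int] | None = None   # None -> preparation default
    mispositioned_fraction: float | None = None  # None -> preparation default
    read_len: int = READ_LEN
    seed: int = 0
    # toy gene structure (bp)
    chrom: str = "chrS"
    chrom_length: int | None = None    # None -> just large enough
    exon_length: int = 400
    n_exons: int = 3
    intron_length: int = 750
    utr3_length: int = 300
    min_gap: int = 1200                # > flank + read_len: no cross-gene ambiguity

    def __post_init__(self) -> None:
        for name in ("de_fraction", "polyA_fraction", "nonunique_fraction",
                     "mismatch2_fraction", "mismatch1_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fold_change <= 1.0:
            raise ValueError("fold_change must be > 1")
        if self.prep not in FRAG_WINDOWS:
            raise ValueError(f"prep must be one of {sorted(FRAG_WINDOWS)}")
        if self.frag_window is None:
            self.frag_window = FRAG_WINDOWS[self.prep]
        if self.mispositioned_fraction is None:
            self.mispositioned_fraction = MISPOSITIONED[self.prep]
        lo, hi = self.frag_window
        if not (0 <= lo < hi):
            raise ValueError("frag_window must be a positive-length window")

    @property
    def gene_span(self) -> int:
        return (
            self.n_exons * self.exon_length
            + (self.n_exons - 1) * self.intron_length
            + self.utr3_length
        )

    @property
    def sheet_preparation(self) -> str:
        return "FFPET" if self.prep == "ffpet" else "frozen"


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> list[GeneModel]:
    """Non-overlapping genes on alternating strands, deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    span = config.gene_span
    required = config.n_genes * (span + config.min_gap) + config.min_gap
    chrom_length = config.chrom_length
    if chrom_length is None:
        chrom_length = required
    if chrom_length < required:
        raise ValueError(
            f"{config.n_genes} genes need a chromosome of >= {required} bp "
            f"(got {chrom_length})"
        )
    slack = chrom_length - required
    extra = rng.multinomial(slack, np.ones(config.n_genes) / config.n_genes) if slack else np.zeros(config.n_genes, dtype=int)
    genes = []
    pos = config.min_gap
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        pos += int(extra[i])
        strand = "+" if i % 2 == 0 else "-"
        start, end = pos, pos + span
        if strand == "+":
            exons = [
                (
                    start + j * (config.exon_length + config.intron_length),
                    start + j * (config.exon_length + config.intron_length) + config.exon_length,
                )
                for j in range(config.n_exons)
            ]
            utr3 = (end - config.utr3_length, end)
        else:
            exons = [
                (
                    end - j * (config.exon_length + config.intron_length) - config.exon_length,
                    end - j * (config.exon_length + config.intron_length),
                )
                for j in reversed(range(config.n_exons))
            ]
            utr3 = (start, start + config.utr3_length)
        genes.append(
            GeneModel(
                symbol=f"G{i + 1:0{width}d}",
                chrom=config.chrom,
                strand=strand,
                tx_start=start,
                tx_end=end,
                coding_exons=tuple(exons),
                utr3=utr3,
            )
        )
        pos = end + config.min_gap
    return genes


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def sample_ids(config: SimConfig) -> list[str]:
    prep = config.sheet_preparation
    return [f"DTF{i + 1:02d}_{prep}" for i in range(config.n_dtf)] + [
        f"SFT{i + 1:02d}_{prep}" for i in range(config.n_sft)
    ]


def make_sample_sheet(config: SimConfig) -> pd.DataFrame:
    """Sample sheet for one arm; pair_key joins the same tumor across preps."""
    rows = []
    for sid in sample_ids(config):
        group = sid[:3]
        rows.append(
            {
                "sample_id": sid,
                "group": group,
                "preparation": config.sheet_preparation,
                "pair_key": sid.split("_")[0],
            }
        )
    return pd.DataFrame(rows)


def simulate_expression(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ground-truth DE structure and per-sample transcript counts.

    Returns (truth, counts): truth has per-gene expected counts per group,
    a DE flag, and direction; counts is genes x samples, negative binomial
    with the configured dispersion (Poisson in the dispersion -> 0 limit),
    scaled so each sample's expected total is the mean library size.
    """
    rng = np.random.default_rng(config.seed + 1)
    g = config.n_genes
    width = len(str(g))
    symbols = [f"G{i + 1:0{width}d}" for i in range(g)]
    base = rng.lognormal(mean=0.0, sigma=1.0, size=g)
    n_de = int(round(config.de_fraction * g))
    de_idx = rng.choice(g, size=n_de, replace=False)
    direction = np.full(g, "none", dtype=object)
    direction[de_idx[: n_de // 2]] = "DTF"     # up in DTF
    direction[de_idx[n_de // 2:]] = "SFT"      # up in SFT
    w_dtf = base * np.where(direction == "DTF", config.fold_change, 1.0)
    w_sft = base * np.where(direction == "SFT", config.fold_change, 1.0)
    mu_dtf = config.mean_library_size * w_dtf / w_dtf.sum()
    mu_sft = config.mean_library_size * w_sft / w_sft.sum()
    truth = pd.DataFrame(
        {
            "mean_dtf": mu_dtf,
            "mean_sft": mu_sft,
            "is_de": direction != "none",
            "direction": direction,
            "fold_change": np.where(direction == "none", 1.0, config.fold_change),
        },
        index=pd.Index(symbols, name="gene"),
    )
    cols = {}
    for sid in sample_ids(config):
        mu = mu_dtf if sid.startswith("DTF") else mu_sft
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            lam = rng.gamma(shape, mu / shape)
        else:
            lam = mu
        cols[sid] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=truth.index)
    return truth, counts


# ---------------------------------------------------------------------------
# Tags
# ---------------------------------------------------------------------------

def _place_tag(
    gene: GeneModel, offset: int, mispositioned_start: int | None, read_len: int
) -> tuple[int, int]:
    """Genomic interval of one tag on its gene's strand."""
    if mispositioned_start is not None:
        start = gene.tx_start + mispositioned_start
        return start, start + read_len
    if gene.strand == "+":
        end = gene.tx_end - offset
        start = max(gene.tx_start, end - read_len)
        return start, end
    start = gene.tx_start + offset
    end = min(gene.tx_end, start + read_len)
    return start, end


def simulate_tags(
    counts: pd.DataFrame,
    genes: list[GeneModel],
    config: SimConfig,
) -> tuple[list[AlignedTag], pd.DataFrame]:
    """Emit one aligned tag per transcript molecule, plus contamination.

    Returns (tags, truth_counts) where truth_counts records the emitted
    true-tag count per gene and sample (identical to ``counts``).  Junk
    fractions are interpreted as fractions of all emitted reads: poly-A and
    non-unique reads are flagged non-unique, 2-mismatch reads carry
    n_mismatch = 2, so all are removed by the standard filter.
    """
    rng = np.random.default_rng(config.seed + 2)
    by_symbol = {gene.symbol: gene for gene in genes}
    missing = set(counts.index) - set(by_symbol)
    if missing:
        raise ValueError(f"counts reference unknown genes, e.g. {sorted(missing)[:5]}")
    lo, hi = config.frag_window
    span = config.gene_span
    chrom_length = config.chrom_length or (
        config.n_genes * (span + config.min_gap) + config.min_gap
    )
    tags: list[AlignedTag] = []
    serial = 0
    junk_frac = config.polyA_fraction + config.nonunique_fraction + config.mismatch2_fraction
    if junk_frac >= 1.0:
        raise ValueError("junk fractions must sum to < 1")
    for sid in counts.columns:
        col = counts[sid]
        n_true = int(col.sum())
        for symbol, c in col.items():
            c = int(c)
            if c == 0:
                continue
            gene = by_symbol[symbol]
            offsets = rng.integers(lo, hi + 1, size=c)
            mis = rng.random(c) < config.mispositioned_fraction
            mis_starts = rng.integers(0, gene.tx_end - gene.tx_start - config.read_len + 1, size=c)
            mm1 = rng.random(c) < config.mismatch1_fraction
            for j in range(c):
                start, end = _place_tag(
                    gene,
                    int(offsets[j]),
                    int(mis_starts[j]) if mis[j] else None,
                    config.read_len,
                )
                serial += 1
                tags.append(
                    AlignedTag(
                        chrom=gene.chrom,
                        start=start,
                        end=end,
                        strand=gene.strand,
                        n_mismatch=1 if mm1[j] else 0,
                        is_unique=True,
                        sample_id=sid,
                        read_id=f"t{serial}",
                    )
                )
        # contamination, as fractions of the total emitted for this sample
        total = n_true / (1.0 - junk_frac) if junk_frac > 0 else n_true
        junk_specs = [
            (int(round(total * config.polyA_fraction)), False, 0, "polyA"),
            (int(round(total * config.nonunique_fraction)), False, 0, "nonuniq"),
            (int(round(total * config.mismatch2_fraction)), True, 2, "mm2"),
        ]
        for n_junk, unique, n_mm, tagname in junk_specs:
            if n_junk <= 0:
                continue
            starts = rng.integers(0, chrom_length - config.read_len, size=n_junk)
            strands = rng.choice(["+", "-"], size=n_junk)
            for j in range(n_junk):
                serial += 1
                tags.append(
                    AlignedTag(
                        chrom=config.chrom,
                        start=int(starts[j]),
                        end=int(starts[j]) + config.read_len,
                        strand=str(strands[j]),
                        n_mismatch=n_mm,
                        is_unique=unique,
                        sample_id=sid,
                        read_id=f"{tagname}{serial}",
                    )
                )
    truth_counts = counts.copy()
    return tags, truth_counts


# ---------------------------------------------------------------------------
# One-call experiment
# ---------------------------------------------------------------------------

@dataclass
class SimulatedExperiment:
    config: SimConfig
    genes: list[GeneModel]
    truth: pd.DataFrame
    counts: pd.DataFrame          # true transcript counts (genes x samples)
    tags: list[AlignedTag] = field(default_factory=list)
    sample_sheet: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_experiment(config: SimConfig, with_tags: bool = True) -> SimulatedExperiment:
    """Genome + expression (+ aligned tags) for one preparation arm."""
    genes = simulate_genome(config)
    truth, counts = simulate_expression(config)
    tags: list[AlignedTag] = []
    if with_tags:
        tags, _ = simulate_tags(counts, genes, config)
    return SimulatedExperiment(
        config=config,
        genes=genes,
        truth=truth,
        counts=counts,
        tags=tags,
        sample_sheet=make_sample_sheet(config),
    )


def paired_prep_configs(config: SimConfig) -> tuple[SimConfig, SimConfig]:
    """Frozen and FFPET arms of the same tumors (identical truth counts)."""
    frozen = replace(config, prep="frozen", frag_window=None, mispositioned_fraction=None)
    ffpet = replace(config, prep="ffpet", frag_window=None, mispositioned_fraction=None)
    return frozen, ffpet
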