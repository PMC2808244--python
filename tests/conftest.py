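import numpy as np
import pandas as pd
import pytest

from threeseq import AlignedTag, GeneModel


@pytest.fixture
def toy_genes():
    """Three well-separated genes: two forward, one reverse."""
    return [
        GeneModel(
            symbol="GA", chrom="chr1", strand="+", tx_start=10_000, tx_end=13_000,
            coding_exons=((10_000, 10_400), (11_000, 11_400), (12_000, 12_700)),
            utr3=(12_700, 13_000),
        ),
        GeneModel(
            symbol="GB", chrom="chr1", strand="-", tx_start=20_000, tx_end=23_000,
            coding_exons=((20_300, 21_000), (22_000, 23_000)),
            utr3=(20_000, 20_300),
        ),
        GeneModel(
            symbol="GC", chrom="chr2", strand="+", tx_start=5_000, tx_end=8_000,
            coding_exons=((5_000, 7_500),),
            utr3=(7_500, 8_000),
        ),
    ]


def make_tag(chrom="chr1", start=12_800, strand="+", n_mismatch=0, is_unique=True,
             sample_id="s1", read_id="r"):
    return AlignedTag(
        chrom=chrom, start=start, end=start + 25, strand=strand,
        n_mismatch=n_mismatch, is_unique=is_unique, sample_id=sample_id,
        read_id=read_id,
    )


@pytest.fixture
def two_group_sheet():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "group": ["DTF", "DTF", "SFT", "SFT"],
            "preparation": ["frozen"] * 4,
            "pair_key": [pd.NA] * 4,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20100119)
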