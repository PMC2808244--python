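"""Tag filtering and gene attribution, checked against brute-force scans."""

import numpy as np
import pandas as pd
import pytest

from threeseq import formats_io as io
from threeseq import quantify as q
from threeseq.formats_io import AlignedTag, GeneModel
from threeseq.quantify import Category

from conftest import make_tag


class TestFilterTags:
    def test_mismatch_and_uniqueness_rules(self):
        tags = [
            make_tag(n_mismatch=2, read_id="mm2"),
            make_tag(is_unique=False, read_id="nonuniq"),
            make_tag(n_mismatch=1, read_id="mm1"),
            make_tag(n_mismatch=0, read_id="clean"),
        ]
        kept, tally = q.filter_tags(tags)
        assert [t.read_id for t in kept] == ["mm1", "clean"]  # <=1 mismatch inclusive
        assert tally[Category.DISCARDED_MISMATCH] == 1
        assert tally[Category.DISCARDED_NONUNIQUE] == 1

    def test_nonunique_checked_before_mismatch(self):
        # a non-unique 2-mismatch read counts once, as non-unique
        kept, tally = q.filter_tags([make_tag(n_mismatch=2, is_unique=False)])
        assert not kept and tally[Category.DISCARDED_NONUNIQUE] == 1


class TestAssignTag:
    def test_flank_downstream_assignment(self, toy_genes):
        # + strand tag 800 bp downstream of GA's 3' end (13000)
        index = q.GeneIndex(toy_genes, flank=1000)
        a = q.assign_tag(make_tag(start=13_800), index)
        assert a.symbol == "GA" and a.category == Category.FLANK_1KB

    def test_beyond_flank_is_intergenic(self, toy_genes):
        index = q.GeneIndex(toy_genes, flank=1000)
        a = q.assign_tag(make_tag(start=14_500), index)
        assert a.symbol is None and a.category == Category.INTERGENIC

    def test_wrong_orientation_inside_gene(self, toy_genes):
        index = q.GeneIndex(toy_genes, flank=1000)
        a = q.assign_tag(make_tag(start=12_800, strand="-"), index)
        assert a.symbol is None and a.category == Category.WRONG_ORIENTATION

    def test_category_precedence(self, toy_genes):
        index = q.GeneIndex(toy_genes, flank=1000)
        cases = {
            12_800: Category.UTR3,        # inside GA's utr3
            11_100: Category.CODING_EXON,
            11_600: Category.INTRON,
        }
        for start, expected in cases.items():
            a = q.assign_tag(make_tag(start=start), index)
            assert (a.symbol, a.category) == ("GA", expected)

    def test_utr3_precedes_exon_on_boundary_overlap(self):
        # tag straddling the CDS/UTR boundary counts as UTR3
        gene = GeneModel("G", "chr1", "+", 0, 1000, ((0, 800),), utr3=(800, 1000))
        index = q.GeneIndex([gene], flank=0)
        a = q.assign_tag(make_tag(start=790), index)
        assert a.category == Category.UTR3

    def test_tie_break_nearest_three_prime_end(self):
        g1 = GeneModel("NEAR", "chr1", "+", 0, 1000)
        g2 = GeneModel("FAR", "chr1", "+", 1500, 2500)
        index = q.GeneIndex([g1, g2], flank=1000)
        # tag at 1100: 100 bp past NEAR's 3' end (1000), 400 bp before FAR's span
        # but FAR's 3' end is 2500 -> NEAR wins
        a = q.assign_tag(make_tag(start=1100), index)
        assert a.symbol == "NEAR" and a.category == Category.FLANK_1KB

    def test_exact_tie_is_ambiguous(self):
        gA = GeneModel("A", "chr1", "+", 0, 1000)       # 3' end 1000
        gB = GeneModel("B", "chr1", "+", 1050, 1425)    # 3' end 1425
        index = q.GeneIndex([gA, gB], flank=1000)
        # tag [1200, 1225): 200 bp from A's 3' end and 200 bp from B's
        a = q.assign_tag(AlignedTag("chr1", 1200, 1225, "+"), index)
        assert a.symbol is None and a.category == Category.AMBIGUOUS

    def test_order_independence(self, toy_genes, rng):
        tags = [make_tag(start=int(s), read_id=str(i))
                for i, s in enumerate(rng.integers(9000, 25_000, size=200))]
        fwd = q.assign_tags(tags, toy_genes)
        rev = q.assign_tags(tags, list(reversed(toy_genes)))
        assert [(a.symbol, a.category) for a in fwd] == [
            (a.symbol, a.category) for a in rev
        ]


def brute_force_assign(tag, genes, flank):
    """All-pairs reference implementation of the attribution rules."""
    eligible = []
    intragenic_any_strand = False
    for g in genes:
        if g.chrom != tag.chrom:
            continue
        in_span = tag.start < g.tx_end and g.tx_start < tag.end
        in_flank = tag.start < g.tx_end + flank and max(0, g.tx_start - flank) < tag.end
        if in_span:
            intragenic_any_strand = True
        if in_flank and g.strand == tag.strand:
            eligible.append(g)
    if not eligible:
        if intragenic_any_strand:
            return None, Category.WRONG_ORIENTATION
        return None, Category.INTERGENIC
    def dist(g):
        p = g.three_prime_end
        if p < tag.start:
            return tag.start - p
        if p > tag.end:
            return p - tag.end
        return 0
    eligible.sort(key=dist)
    if len(eligible) > 1 and dist(eligible[0]) == dist(eligible[1]):
        return None, Category.AMBIGUOUS
    g = eligible[0]
    def overlaps(iv):
        return tag.start < iv[1] and iv[0] < tag.end
    if g.utr3 and overlaps(g.utr3):
        return g.symbol, Category.UTR3
    if any(overlaps(e) for e in g.coding_exons):
        return g.symbol, Category.CODING_EXON
    if overlaps((g.tx_start, g.tx_end)):
        return g.symbol, Category.INTRON
    return g.symbol, Category.FLANK_1KB


def random_annotation(rng, n_genes):
    genes = []
    pos = 0
    for i in range(n_genes):
        pos += int(rng.integers(200, 3000))
        length = int(rng.integers(300, 4000))
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = pos, pos + length
        cds_len = int(rng.integers(0, length))
        if cds_len >= 50:
            if strand == "+":
                coding = ((start, start + cds_len),)
                utr3 = (start + cds_len, end) if cds_len < length else None
            else:
                coding = ((end - cds_len, end),)
                utr3 = (start, end - cds_len) if cds_len < length else None
        else:
            coding, utr3 = (), None
        genes.append(GeneModel(f"R{i}", "chr1", strand, start, end, coding, utr3))
        pos = end
    return genes


class TestBruteForceAgreement:
    @pytest.mark.parametrize("trial", range(5))
    def test_matches_all_pairs_scan(self, trial):
        rng = np.random.default_rng(1000 + trial)
        genes = random_annotation(rng, n_genes=int(rng.integers(5, 50)))
        extent = genes[-1].tx_end + 2000
        flank = int(rng.choice([0, 100, 1000]))
        index = q.GeneIndex(genes, flank=flank)
        for _ in range(500):
            start = int(rng.integers(0, extent))
            tag = AlignedTag("chr1", start, start + 25,
                             "+" if rng.random() < 0.5 else "-")
            got = q.assign_tag(tag, index)
            want_symbol, want_cat = brute_force_assign(tag, genes, flank)
            assert (got.symbol, got.category) == (want_symbol, want_cat)


class TestBuildCounts:
    def test_all_zero_with_no_tags(self, toy_genes, two_group_sheet):
        matrix, _ = q.build_counts([], toy_genes, two_group_sheet)
        assert matrix.counts.shape == (3, 4)
        assert (matrix.counts == 0).all().all()

    def test_unit_mass(self, toy_genes, two_group_sheet):
        matrix, _ = q.build_counts(
            [make_tag(start=12_800, sample_id="s2")], toy_genes, two_group_sheet
        )
        assert matrix.counts.loc["GA", "s2"] == 1
        assert matrix.counts.to_numpy().sum() == 1

    def test_hand_enumerated_fixture(self, toy_genes, two_group_sheet):
        tags = (
            # 8 tags in GA's UTR3 from s1
            [make_tag(start=12_750 + 10 * i, sample_id="s1") for i in range(8)]
            # 5 tags in GB (minus strand UTR3) from s3
            + [make_tag(start=20_050 + i, strand="-", sample_id="s3") for i in range(5)]
            # 3 intronic GA tags from s2
            + [make_tag(start=11_500 + i, sample_id="s2") for i in range(3)]
            # 2 wrong-orientation tags (inside GA, minus strand)
            + [make_tag(start=12_100, strand="-", sample_id="s1") for _ in range(2)]
            # 2 intergenic tags
            + [make_tag(start=30_000, sample_id="s4") for _ in range(2)]
        )
        matrix, assignments = q.build_counts(tags, toy_genes, two_group_sheet)
        expected = pd.DataFrame(
            0, index=["GA", "GB", "GC"], columns=["s1", "s2", "s3", "s4"]
        )
        expected.loc["GA", "s1"] = 8
        expected.loc["GB", "s3"] = 5
        expected.loc["GA", "s2"] = 3
        assert (matrix.counts.values == expected.values).all()
        # conservation: assigned + unassigned = input, per sample
        by_sample = {}
        for a in assignments:
            by_sample.setdefault(a.tag.sample_id, []).append(a)
        for sample, asgs in by_sample.items():
            assigned = sum(a.category in q.ASSIGNED_CATEGORIES for a in asgs)
            assert assigned == matrix.counts[sample].sum()
            assert len(asgs) == sum(1 for t in tags if t.sample_id == sample)

    def test_unknown_sample_is_error(self, toy_genes, two_group_sheet):
        with pytest.raises(ValueError, match="mystery"):
            q.build_counts(
                [make_tag(sample_id="mystery")], toy_genes, two_group_sheet
            )

    def test_exclude_introns_drops_only_intronic_counts(self, toy_genes, two_group_sheet):
        tags = [make_tag(start=11_600, sample_id="s1"),
                make_tag(start=12_800, sample_id="s1")]
        loose, _ = q.build_counts(tags, toy_genes, two_group_sheet)
        strict, _ = q.build_counts(tags, toy_genes, two_group_sheet, exclude_introns=True)
        assert loose.counts.loc["GA", "s1"] == 2
        assert strict.counts.loc["GA", "s1"] == 1

    def test_flank_monotonicity(self, toy_genes, two_group_sheet, rng):
        tags = [make_tag(start=int(s), read_id=str(i))
                for i, s in enumerate(rng.integers(8000, 26_000, size=300))]
        counts = {}
        for flank in (0, 500, 1000):
            m, _ = q.build_counts(tags, toy_genes, two_group_sheet, flank=flank)
            counts[flank] = m.counts
        assert (counts[0] <= counts[500]).all().all()
        assert (counts[500] <= counts[1000]).all().all()


class TestCategorySummary:
    def test_all_utr3(self, toy_genes, two_group_sheet):
        tags = [make_tag(start=12_800, sample_id="s1") for _ in range(5)]
        _, asg = q.build_counts(tags, toy_genes, two_group_sheet)
        summary = q.category_summary(asg)
        assert summary.loc["s1", "UTR3"] == 1.0

    def test_fractions_sum_to_one(self, toy_genes, two_group_sheet, rng):
        tags = [make_tag(start=int(s), read_id=str(i), sample_id=f"s{1 + i % 4}")
                for i, s in enumerate(rng.integers(9000, 24_000, size=400))]
        _, asg = q.build_counts(tags, toy_genes, two_group_sheet)
        summary = q.category_summary(asg)
        assert np.allclose(summary.sum(axis=1), 1.0, atol=1e-12)
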