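"""MAF I/O, inversion calling, feature coverage, RepeatMasker parsing,
TE/feature composition and ORF scanning."""

import numpy as np
import pytest

from rateshift import (
    AlignmentBlock,
    FeatureInterval,
    detect_inversions,
    feature_coverage,
    find_orfs,
    make_block_fixture,
    make_feature_fixture,
    make_te_fixture,
    read_maf,
    read_repeatmasker_out,
    te_feature_overlap,
    write_maf,
)
from rateshift.regionmap import ORFRecord, SpeciesAnchor, majority_strand
from rateshift.synthetic import make_locus_blocks_fixture, write_te_table


class TestMafIO:
    def test_round_trip(self, tmp_path):
        blocks = make_block_fixture(4, {1}, seed=0)
        p = tmp_path / "toy.maf"
        write_maf(blocks, p)
        back = read_maf(p, reference="mouse")
        assert len(back) == 4
        for orig, rec in zip(blocks, back):
            assert orig.anchors == rec.anchors

    def test_negative_strand_coordinates_converted(self, tmp_path):
        # hand conversion: start=40, size=8 on '-' of a 500 bp source
        # maps to forward interval [500-40-8, 500-40) = [452, 460)
        p = tmp_path / "neg.maf"
        p.write_text(
            "##maf version=1\n"
            "a score=1.0\n"
            "s mouse.chr1 100 8 + 1000 ACGTACGT\n"
            "s rat.chr2    40 8 - 500  ACGTACGT\n"
            "\n"
        )
        (block,) = read_maf(p, reference="mouse")
        rat = block.anchors["rat"]
        assert (rat.start, rat.end, rat.strand) == (452, 460, "-")
        assert block.anchors["mouse"].start == 100

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.maf"
        p.write_text("##maf version=1\n")
        assert read_maf(p) == []


class TestDetectInversions:
    def test_planted_blocks_recovered_exactly(self):
        blocks = make_block_fixture(8, {1, 2, 6}, seed=3)
        called = detect_inversions(blocks, "rat")
        # pitch 500 from 1000: block i spans [1000+500i, 1200+500i)
        assert called == [("chr1", 1500, 2200), ("chr1", 4000, 4200)]

    def test_all_same_strand_empty(self):
        assert detect_inversions(make_block_fixture(6, set(), seed=0), "rat") == []

    def test_order_invariant(self):
        blocks = make_block_fixture(10, {3, 4, 8}, seed=1)
        shuffled = [blocks[i] for i in np.random.default_rng(0).permutation(10)]
        assert detect_inversions(blocks, "rat") == detect_inversions(shuffled, "rat")

    def test_absent_query_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            detect_inversions(make_block_fixture(3, set(), seed=0), "opossum")

    def test_majority_is_length_weighted(self):
        # one long '+' block outweighs two short '-' blocks
        def block(start, ln, strand):
            text = "A" * ln
            return AlignmentBlock(
                {
                    "mouse": SpeciesAnchor("c", start, start + ln, "+", 10_000, text),
                    "rat": SpeciesAnchor("c", start, start + ln, strand, 10_000, text),
                },
                "mouse",
            )

        blocks = [block(0, 5000, "+"), block(6000, 100, "-"), block(8000, 100, "-")]
        assert majority_strand(blocks, "rat") == "+"
        assert len(detect_inversions(blocks, "rat")) == 2


class TestFeatureCoverage:
    def test_locus_fixture_states(self):
        blocks, planted = make_locus_blocks_fixture()
        feats = make_feature_fixture()
        cov = feature_coverage(blocks, feats, ["rat", "human"])
        human = cov[cov.species == "human"].set_index("feature")
        # first antisense exon sits wholly inside the first planted inversion
        assert human.loc["Ak158810.exon1", "state"] == "covered"
        assert bool(human.loc["Ak158810.exon1", "inverted"])
        # rat shares mouse orientation everywhere
        assert not cov[cov.species == "rat"]["inverted"].any()
        assert ((cov.fraction >= 0) & (cov.fraction <= 1)).all()

    def test_absent_feature(self):
        blocks = make_block_fixture(2, set(), seed=0)
        feats = [FeatureInterval("far", "chr1", 50_000, 51_000)]
        cov = feature_coverage(blocks, feats, ["rat"])
        assert cov.iloc[0].state == "absent" and cov.iloc[0].fraction == 0.0

    def test_partial_inverted_feature(self):
        # feature 500 bp, 40% covered by one flipped block among a '+'
        # majority chain -> partial + inverted flag
        def block(start, ln, strand):
            text = "A" * ln
            return AlignmentBlock(
                {
                    "mouse": SpeciesAnchor("c", start, start + ln, "+", 10_000, text),
                    "rat": SpeciesAnchor("c", start, start + ln, strand, 10_000, text),
                },
                "mouse",
            )

        blocks = [block(0, 2000, "+"), block(3000, 200, "-")]
        feat = FeatureInterval("f", "c", 3000, 3500)
        row = feature_coverage(blocks, [feat], ["rat"], threshold=0.5).iloc[0]
        assert row.state == "partial"
        assert row.fraction == pytest.approx(0.4)
        assert bool(row.inverted)


class TestRepeatMasker:
    HEADER = (
        "   SW   perc perc perc  query  position in query  matching repeat\n"
        "score   div. del. ins.  sequence begin end (left) repeat class/family begin end (left) ID\n"
        "\n"
    )

    def test_single_hit_parsed(self, tmp_path):
        p = tmp_path / "one.out"
        p.write_text(
            self.HEADER + " 463  12.4  0.0  0.0  chr14  1401  1600  (0)  +  MIR  SINE/MIR  1  200  (0)  1\n"
        )
        (ann,) = read_repeatmasker_out(p)
        assert (ann.name, ann.repeat_class) == ("MIR", "SINE")
        assert (ann.start, ann.end) == (1400, 1600)  # 1-based begin converted

    def test_simple_repeat_is_other_and_droppable(self, tmp_path):
        p = tmp_path / "simple.out"
        p.write_text(
            self.HEADER
            + " 20  5.0  0.0  0.0  chr14  10  50  (0)  +  (TA)n  Simple_repeat  1  40  (0)  1\n"
            + " 99  9.0  0.0  0.0  chr14  90  190  (0)  +  L1MD3  LINE/L1  1  100  (0)  2\n"
        )
        all_anns = read_repeatmasker_out(p)
        assert [a.repeat_class for a in all_anns] == ["Other", "LINE"]
        ancient = read_repeatmasker_out(p, ancient_only=True)
        assert [a.name for a in ancient] == ["L1MD3"]

    def test_empty_body(self, tmp_path):
        p = tmp_path / "empty.out"
        p.write_text(self.HEADER)
        assert read_repeatmasker_out(p) == []

    def test_malformed_record_rejected(self, tmp_path):
        p = tmp_path / "bad.out"
        p.write_text(self.HEADER + "  not a record\n")
        with pytest.raises(ValueError, match="malformed"):
            read_repeatmasker_out(p)

    def test_fixture_table_round_trip(self, tmp_path):
        mouse = [t for t in make_te_fixture() if t.species == "mouse"]
        p = tmp_path / "fixture.out"
        write_te_table(mouse, p)
        back = read_repeatmasker_out(p)
        assert [(a.name, a.repeat_class, a.start, a.end) for a in back] == [
            (t.name, t.repeat_class, t.start, t.end) for t in mouse
        ]


class TestTEComposition:
    def test_intron1_hosts_first_four_elements(self):
        mouse = [t for t in make_te_fixture() if t.species == "mouse"]
        table = te_feature_overlap(mouse, make_feature_fixture()).set_index("feature")
        assert table.loc["Pldi.intron1", "elements"] == "A, B, C, D"

    def test_last_exon_hosts_five_elements(self):
        mouse = [t for t in make_te_fixture() if t.species == "mouse"]
        table = te_feature_overlap(mouse, make_feature_fixture()).set_index("feature")
        assert table.loc["Ak158810.exon5", "elements"] == "G, H, I, J, K"
        # the ambiguous alternative reading: the distinct fourth element
        # replaced by a second copy of the B1F element
        alt = [t for t in make_te_fixture(exon5_reading="I") if t.species == "mouse"]
        alt_table = te_feature_overlap(alt, make_feature_fixture()).set_index("feature")
        assert alt_table.loc["Ak158810.exon5", "elements"] == "G, H, I, I, K"

    def test_boundary_touch_is_not_overlap(self):
        from rateshift import TEAnnotation

        te = TEAnnotation("MIR", "SINE", "mouse", "c", 100, 200)
        feats = [FeatureInterval("left", "c", 0, 100), FeatureInterval("right", "c", 200, 300)]
        table = te_feature_overlap([te], feats)
        assert (table.n_te == 0).all()

    def test_total_assignments_match_brute_force(self):
        rng = np.random.default_rng(5)
        from rateshift import TEAnnotation

        tes, feats = [], []
        for i in range(40):
            s = int(rng.integers(0, 5000))
            tes.append(TEAnnotation(f"te{i}", "Other", "mouse", "c", s, s + int(rng.integers(1, 400))))
        for i in range(15):
            s = int(rng.integers(0, 5000))
            feats.append(FeatureInterval(f"f{i}", "c", s, s + int(rng.integers(1, 600))))
        table = te_feature_overlap(tes, feats)
        brute = sum(
            1
            for t in tes
            for f in feats
            if max(t.start, f.start) < min(t.end, f.end)
        )
        assert int(table.n_te.sum()) == brute


def orf_oracle(seq, min_aa, frames):
    """Exhaustive reference scan: every ATG position, walked codon by codon."""
    from Bio.Seq import Seq

    results = set()
    strands = [(seq, True)] + ([(str(Seq(seq).reverse_complement()), False)] if frames == "six" else [])
    n = len(seq)
    for work, sense in strands:
        for i in range(n - 2):
            if work[i : i + 3] != "ATG":
                continue
            for j in range(i + 3, n - 2, 3):
                codon = work[j : j + 3]
                if codon in {"TAA", "TAG", "TGA"}:
                    aa = (j + 3 - i) // 3 - 1
                    if aa >= min_aa:
                        if sense:
                            results.add((i % 3 + 1, i, j + 3, aa))
                        else:
                            results.add((-(i % 3 + 1), n - (j + 3), n - i, aa))
                    break
    return results


class TestORFs:
    def test_minimal_orf(self):
        scan = find_orfs("ATGAAATGA", min_aa=0)
        assert scan.orfs == [ORFRecord(frame=1, start=0, end=9, length_aa=2)]

    def test_no_start_codon(self):
        assert find_orfs("CCCCCCTAA", min_aa=0).orfs == []

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError, match="non-DNA"):
            find_orfs("ATGXXXTAA")

    @pytest.mark.parametrize("frames", ["sense", "six"])
    def test_agrees_with_exhaustive_oracle(self, frames):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(300, 3000))
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, n))
            scan = find_orfs(seq, min_aa=10, frames=frames)
            got = {(o.frame, o.start, o.end, o.length_aa) for o in scan.orfs}
            assert got == orf_oracle(seq, 10, frames)

    def test_sorted_longest_first(self):
        tx = "ATGAAAAAAAAATGA" + "ATGAAATGA"  # a 4 aa ORF followed by a 2 aa ORF
        scan = find_orfs(tx, min_aa=0)
        lengths = [o.length_aa for o in scan.orfs]
        assert lengths == sorted(lengths, reverse=True)
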