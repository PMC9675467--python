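"""Guide geometry, indel bookkeeping and PTC/NMD prediction."""

import numpy as np
import pytest
from Bio.Seq import Seq

from pascrispr import (
    NotAlleleSpecificError,
    TranscriptModel,
    Variant,
    apply_indel,
    classify_pas,
    design_guide,
    predict_ptc_nmd,
)
from pascrispr._seq import revcomp


def ref_generating_context(rng, pam_start=30, length=80):
    """Random contig with one plus-strand AGG PAM whose middle G is the SNP."""
    seq = list(rng.choice(list("AT"), size=length))
    seq[pam_start - 1 : pam_start + 2] = list("AGG")
    seq = "".join(seq)
    variant = Variant("c", pam_start, "G", "C", id="pas")
    return seq, variant


class TestDesign:
    def test_plus_strand_geometry(self):
        rng = np.random.default_rng(0)
        seq, variant = ref_generating_context(rng)
        rec = classify_pas(variant, seq)
        (design,) = design_guide(rec, seq, "G")
        i = 29  # PAM window start
        assert design.pam_window == (i, i + 3)
        assert design.protospacer == seq[i - 20 : i]
        assert design.cut_site == i - 3  # blunt cut between positions 17|18
        assert design.pam_sequence == "AGG"

    def test_minus_strand_by_strand_symmetry(self):
        """Designing on the reverse-complemented contig with the plus-strand
        rule is the independent oracle for the minus-strand branch."""
        rng = np.random.default_rng(1)
        seq_rc, variant_rc = ref_generating_context(rng, pam_start=30, length=80)
        seq = revcomp(seq_rc)
        pos = len(seq) - 1 - variant_rc.position
        variant = Variant("c", pos, "C", "G", id="pas")  # complement alleles
        rec = classify_pas(variant, seq)
        (design,) = design_guide(rec, seq, "C")
        rec_rc = classify_pas(variant_rc, seq_rc)
        (oracle,) = design_guide(rec_rc, seq_rc, "G")
        assert design.strand == "-"
        assert design.protospacer == oracle.protospacer
        # mirrored coordinates: window and cut site reflect through the contig
        assert design.pam_window == (
            len(seq) - oracle.pam_window[1],
            len(seq) - oracle.pam_window[0],
        )
        assert design.cut_site == len(seq) - oracle.cut_site

    def test_targets_only_the_pam_carrying_allele(self):
        """A reference-generating PAS yields a design for the reference
        (mutant-linked) allele only; asking for the other allele refuses."""
        rng = np.random.default_rng(2)
        seq, variant = ref_generating_context(rng)
        rec = classify_pas(variant, seq)
        designs = design_guide(rec, seq, "G")
        assert [d.target_allele for d in designs] == ["G"]
        with pytest.raises(NotAlleleSpecificError, match="PAM-generating allele"):
            design_guide(rec, seq, "C")

    def test_pam_near_contig_end_refused(self):
        seq = "TTTTTAGGTT" + "T" * 30
        variant = Variant("c", 6, "G", "A")
        rec = classify_pas(variant, seq)
        with pytest.raises(ValueError, match="too close"):
            design_guide(rec, seq, "G")

    def test_non_pas_refused(self):
        rec = classify_pas(Variant("c", 3, "A", "T"), "TTTATTTT")
        with pytest.raises(NotAlleleSpecificError, match="not allele-specific"):
            design_guide(rec, "TTTATTTT", "A")


def three_exon_transcript():
    """Toy gene: exons [0,18), [24,42), [48,66); CDS over the full span.

    Spliced CDS (54 nt) is ATG + 16 ordinary codons + TAA.
    """
    codons = ["ATG"] + ["GCA"] * 16 + ["TAA"]
    cds = "".join(codons)
    seq = cds[:18] + "TTTTTT" + cds[18:36] + "TTTTTT" + cds[36:]
    return TranscriptModel("c", ((0, 18), (24, 42), (48, 66)), 0, 66, sequence=seq)


class TestApplyIndel:
    def test_deletion_bookkeeping(self):
        t = three_exon_transcript()
        edited = apply_indel(t, (30, 1))  # 1-nt deletion in exon 2
        assert edited.net_indel == -1
        assert len(edited.spliced_sequence()) == len(t.spliced_sequence()) - 1
        assert edited.exons == ((0, 18), (24, 41), (47, 65))
        assert edited.junction_positions() == [18, 35]

    def test_in_frame_deletion_shortens_protein_by_one(self):
        t = three_exon_transcript()
        edited = apply_indel(t, (27, 3))  # one whole GCA codon
        pred = predict_ptc_nmd(edited)
        # oracle: translate the edited spliced CDS with the standard table
        oracle = str(Seq(edited.spliced_sequence()).translate(to_stop=True))
        assert pred.protein == oracle
        assert len(pred.protein) == 16  # was 17 aa
        assert pred.frame_class == "in_frame"
        assert not pred.nmd_predicted  # stop still the terminal one

    def test_stop_insertion_is_immediate_ptc(self):
        t = three_exon_transcript()
        edited = apply_indel(t, (6, "TAATAA"))  # codon boundary in exon 1
        pred = predict_ptc_nmd(edited)
        assert pred.stop_codon_spliced == 6
        assert pred.stop_exon_index == 0
        # toy gene is short: the stop ends 33 nt before the last junction,
        # under the 55-nt rule, so no NMD despite being an early PTC
        assert pred.distance_to_last_junction == 33
        assert not pred.nmd_predicted
        oracle = str(Seq(edited.spliced_sequence()).translate(to_stop=True))
        assert pred.protein == oracle == "MA"

    def test_junction_spanning_deletion_rejected(self):
        t = three_exon_transcript()
        with pytest.raises(ValueError, match="splice junction"):
            apply_indel(t, (16, 5))

    def test_intronic_indel_rejected(self):
        t = three_exon_transcript()
        with pytest.raises(ValueError, match="intronic"):
            apply_indel(t, (20, 1))


def transcript_with_stop_distance(d):
    """Two-exon gene whose planted stop ends exactly d nt before the junction."""
    exon1 = "ATG" + "GGA" * 4 + "TAA" + "C" * d
    exon2 = "GGA" * 10
    seq = exon1 + "TTTTTT" + exon2
    e1 = len(exon1)
    return TranscriptModel(
        "c", ((0, e1), (e1 + 6, e1 + 6 + len(exon2))), 0, e1 + 6 + len(exon2), sequence=seq
    )


class TestNmdRule:
    def test_threshold_exact_at_54_and_55(self):
        pred54 = predict_ptc_nmd(transcript_with_stop_distance(54))
        pred55 = predict_ptc_nmd(transcript_with_stop_distance(55))
        assert pred54.distance_to_last_junction == 54 and not pred54.nmd_predicted
        assert pred55.distance_to_last_junction == 55 and pred55.nmd_predicted

    def test_stop_in_last_exon_never_nmd(self):
        t = three_exon_transcript()
        pred = predict_ptc_nmd(t)
        assert pred.stop_exon_index == 2
        assert not pred.nmd_predicted

    def test_nonstop_flagged(self):
        seq = "ATG" + "GCA" * 10 + "TTTTTT" + "GCA" * 5
        t = TranscriptModel("c", ((0, 33), (39, 54)), 0, 54, sequence=seq)
        pred = predict_ptc_nmd(t)
        assert pred.nonstop and not pred.nmd_predicted

    def test_early_frameshift_stop_in_long_gene(self):
        """A frameshift stop landing in an early exon of a many-exon gene,
        far upstream of the last junction, is NMD-predicted."""
        # TTA GCA repeats are stop-free in frame but a -1 frameshift reads
        # TAG almost immediately
        cds = "ATG" + "TTAGCA" * 98 + "TAA"  # 594 nt
        seq = ""
        exons = []
        pos = 0
        for chunk_start in range(0, len(cds), 15):
            chunk = cds[chunk_start : chunk_start + 15]
            exons.append((pos, pos + len(chunk)))
            seq += chunk + "TTTT"
            pos += len(chunk) + 4
        seq = seq[:-4]
        t = TranscriptModel("c", tuple(exons), 0, exons[-1][1], sequence=seq)
        edited = apply_indel(t, (exons[10][0], 1))  # frameshift in exon 11 of 40
        pred = predict_ptc_nmd(edited)
        assert pred.frame_class == "out_of_frame"
        assert pred.stop_exon_index <= 11
        assert pred.nmd_predicted

    def test_in_frame_indel_without_stop_never_nmd(self):
        """Net length 0 mod 3 with no introduced stop keeps the terminal
        stop, so NMD is never predicted."""
        rng = np.random.default_rng(3)
        t = three_exon_transcript()
        for _ in range(20):
            # delete a random whole codon-aligned 3-mer inside exon 2
            pos = int(rng.choice([24, 27, 30, 33, 36]))
            edited = apply_indel(t, (pos, 3))
            pred = predict_ptc_nmd(edited)
            assert pred.frame_class == "in_frame"
            if "*" not in pred.protein:
                assert not pred.nmd_predicted

    def test_translation_matches_biopython_on_random_cds(self):
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            n_codons = int(rng.integers(5, 40))
            cds = "ATG" + "".join(rng.choice(bases, size=3 * n_codons))
            seq = cds + "TTTTTT" + "GCAGCA"
            t = TranscriptModel("c", ((0, len(cds)), (len(cds) + 6, len(cds) + 12)),
                                0, len(cds) + 12, sequence=seq)
            pred = predict_ptc_nmd(t)
            oracle = str(Seq(t.spliced_sequence()).translate(to_stop=True))
            assert pred.protein == oracle
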