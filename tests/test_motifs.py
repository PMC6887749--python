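import numpy as np
import pytest

from famsurvey.exceptions import ComparisonError
from famsurvey.io import AMINO_ACIDS, CisElementDefinition, GeneModel, MotifDefinition
from famsurvey.motifs import (PromoterRecord, compare_promoter_alleles,
                              extract_promoter, motif_width_stats,
                              reverse_complement, scan_cis_elements,
                              scan_protein_motifs)
from famsurvey.resources import default_cis_elements, default_motifs

from oracles import naive_element_offsets, naive_motif_hits

MOTIF13 = MotifDefinition("13", "ALJLGLLWWQSDSNN")
WBOX = CisElementDefinition("W-box", "TTGAC", "stress")

# the 17 bp segment distinguishing the vigorous-rootstock promoter allele
# from the dwarfing-rootstock one; it carries a single W-box
DELETION_17BP = "GAACCGTCTTGACATGT"


class TestScanProteinMotifs:
    def test_extended_alphabet_j_matches_i(self):
        protein = "MKV" + "ALILGLLWWQSDSNN" + "KR"
        hits = scan_protein_motifs(protein, [MOTIF13])
        assert len(hits) == 1
        assert hits[0].start == 4
        assert hits[0].mismatches == 0  # J covers both I and L

    def test_all_glycine_no_hits(self):
        assert scan_protein_motifs("G" * 200, default_motifs()) == []

    def test_motif_wider_than_protein_no_hits(self):
        assert scan_protein_motifs("ALJLG", [MOTIF13]) == []

    def test_matches_naive_window_oracle(self):
        """Scanner hits equal a naive per-window mismatch count with
        leftmost-greedy non-overlap, over 100 seeded random proteins."""
        rng = np.random.default_rng(12)
        motifs = default_motifs()[:6] + [MOTIF13]
        for _ in range(100):
            protein = "".join(rng.choice(list(AMINO_ACIDS),
                                         size=int(rng.integers(50, 500))))
            hits = scan_protein_motifs(protein, motifs)
            for motif in motifs:
                got = [(h.start, h.mismatches) for h in hits
                       if h.motif_id == motif.motif_id]
                got.sort()
                assert got == naive_motif_hits(protein, motif.consensus)

    def test_hits_sorted_n_to_c(self):
        rng = np.random.default_rng(18)
        protein = "".join(rng.choice(list(AMINO_ACIDS), size=400))
        hits = scan_protein_motifs(protein, default_motifs())
        starts = [h.start for h in hits]
        assert starts == sorted(starts)


class TestMotifWidthStats:
    def test_packaged_motif_table(self):
        # the 20-motif table: widths span 15 to 50 residues
        assert motif_width_stats(default_motifs()) == (20, 15, 50)

    def test_single_motif(self):
        motif1 = [m for m in default_motifs() if m.motif_id == "1"]
        assert motif_width_stats(motif1) == (1, 41, 41)

    def test_extremes(self):
        motifs = [MotifDefinition("a", "ACDEFG"),
                  MotifDefinition("b", "A" * 200)]
        assert motif_width_stats(motifs) == (2, 6, 200)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            motif_width_stats([])


def _plus_gene(start_cds, contig_len=10000):
    return GeneModel("g+", "c", "+", start_cds, start_cds + 299,
                     exons=[(start_cds, start_cds + 299)],
                     cds=[(start_cds, start_cds + 299)])


class TestExtractPromoter:
    def test_plus_strand_window(self):
        rng = np.random.default_rng(3)
        contig = "".join(rng.choice(list("ACGT"), size=10000))
        genome = {"c": contig}
        record = extract_promoter(genome, _plus_gene(3001))
        assert record.length == 2000
        assert not record.truncated
        assert record.sequence == contig[1000:3000]

    def test_minus_strand_window(self):
        rng = np.random.default_rng(3)
        contig = "".join(rng.choice(list("ACGT"), size=10000))
        model = GeneModel("g-", "c", "-", 4701, 5000,
                          exons=[(4701, 5000)], cds=[(4701, 5000)])
        record = extract_promoter({"c": contig}, model)
        assert record.sequence == reverse_complement(contig[5000:7000])
        assert record.length == 2000

    def test_contig_edge_truncates_and_flags(self):
        rng = np.random.default_rng(3)
        contig = "".join(rng.choice(list("ACGT"), size=1000))
        record = extract_promoter({"c": contig}, _plus_gene(150))
        assert record.length == 149
        assert record.truncated

    def test_strand_flip_consistency(self):
        """Reverse-complementing the contig while flipping the gene's
        strand and coordinates yields the identical promoter string."""
        rng = np.random.default_rng(8)
        contig = "".join(rng.choice(list("ACGT"), size=9000))
        model = _plus_gene(4001, 9000)
        forward = extract_promoter({"c": contig}, model).sequence

        flipped_contig = reverse_complement(contig)
        n = len(contig)
        flipped = GeneModel("g+", "c", "-",
                            n - model.end + 1, n - model.start + 1,
                            exons=[(n - model.end + 1, n - model.start + 1)],
                            cds=[(n - model.end + 1, n - model.start + 1)])
        backward = extract_promoter({"c": flipped_contig}, flipped).sequence
        assert forward == backward


class TestScanCisElements:
    def _record(self, seq):
        return PromoterRecord(gene_id="g", sequence=seq, length=len(seq))

    def test_wbox_found_at_printed_offset(self):
        record = scan_cis_elements(self._record("GAACCGTCTTGACATGT"), [WBOX])
        assert record.element_counts["W-box"] == 1
        assert record.hit_positions["W-box"] == [9]

    def test_mutated_wbox_not_found(self):
        # the TTGAC -> TTCAC point mutation abolishes the site
        record = scan_cis_elements(self._record("GAACCGTCTTCACATGT"), [WBOX])
        assert record.element_counts["W-box"] == 0

    def test_overlapping_occurrences_all_counted(self):
        element = CisElementDefinition("e", "ACGT")
        record = scan_cis_elements(self._record("ACGTACGT"), [element])
        assert record.element_counts["e"] == 2
        assert record.hit_positions["e"] == [1, 5]

    def test_iupac_degenerate_matching(self):
        element = CisElementDefinition("tata", "TATAWAW")
        record = scan_cis_elements(self._record("GGTATATATGG"), [element])
        assert record.element_counts["tata"] == 1

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(44)
        dictionary = default_cis_elements()
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            record = scan_cis_elements(self._record(seq), dictionary)
            for element in dictionary:
                assert record.hit_positions[element.name] == \
                    naive_element_offsets(seq, element.pattern)


def _cg_background(rng, length):
    """Promoter background without A or T: no dictionary element can
    occur in it or across its junctions."""
    return "".join(rng.choice(list("CG"), size=length))


class TestComparePromoterAlleles:
    def _alleles(self):
        rng = np.random.default_rng(6)
        robusta = _cg_background(rng, 798) + DELETION_17BP + _cg_background(rng, 1185)
        m9 = robusta[:798] + robusta[798 + 17:]
        return robusta, m9

    def test_seventeen_bp_deletion_recovered(self):
        robusta, m9 = self._alleles()
        result = compare_promoter_alleles(robusta, m9, default_cis_elements())
        assert len(result.deletion_segments) == 1
        segment = result.deletion_segments[0]
        assert segment.length == 17
        assert segment.sequence == DELETION_17BP
        assert segment.offset == 799
        assert segment.in_allele == "a"
        assert result.lost_elements == {"W-box": 1}
        assert result.gained_elements == {}

    def test_identical_alleles_empty_diff(self):
        robusta, _ = self._alleles()
        result = compare_promoter_alleles(robusta, robusta,
                                          default_cis_elements())
        assert result.deletion_segments == []
        assert result.lost_elements == {}
        assert result.gained_elements == {}

    def test_point_mutation_loses_wbox_without_deletion(self):
        robusta, _ = self._alleles()
        mutated = robusta.replace("TTGAC", "TTCAC")
        result = compare_promoter_alleles(robusta, mutated,
                                          default_cis_elements())
        assert result.deletion_segments == []
        assert result.lost_elements == {"W-box": 1}

    def test_swapping_alleles_swaps_lost_and_gained(self):
        robusta, m9 = self._alleles()
        fwd = compare_promoter_alleles(robusta, m9, default_cis_elements())
        rev = compare_promoter_alleles(m9, robusta, default_cis_elements())
        assert fwd.lost_elements == rev.gained_elements
        assert fwd.gained_elements == rev.lost_elements

    def test_degenerate_alignment_refused(self):
        with pytest.raises(ComparisonError):
            compare_promoter_alleles("A" * 200, "C" * 200,
                                     default_cis_elements())
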