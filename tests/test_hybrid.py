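"""Hybrid-gene construction, transcripts, ITIMs, PCR, identity tracts."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from lilrcnv.errors import LilrError
from lilrcnv.hybrid import (
    GeneModel,
    PrimerPair,
    build_hybrid,
    find_tandem_acceptors,
    insilico_pcr,
    intersect_genes,
    longest_identity_tract,
    scan_itims,
    splice_gene,
    splice_transcript,
    translate_cdna,
)
from lilrcnv.regions import GenomicInterval
from lilrcnv.sv import DeletionCall

from oracles import itim_positions, lcs_dp, pcr_products_bruteforce

IV = GenomicInterval


def _call(start, end, chrom="chrS"):
    return DeletionCall(interval=IV(chrom, start, end), support=10)


dna = st.text(alphabet="ACGT", min_size=1)


class TestIntersectGenes:
    def test_disjoint_deletion_empty_report(self, locus):
        assert intersect_genes(_call(1000, 2000), locus.genes) == []

    def test_planted_hybrid_deletion_anatomy(self, locus):
        effects = {
            e.gene: e for e in intersect_genes(_call(locus.del_start, locus.del_end), locus.genes)
        }
        assert effects["B5"].exons_deleted == [13]
        assert not effects["B5"].fully_deleted
        assert effects["A6"].fully_deleted
        assert effects["B3"].exons_deleted == list(range(1, 12))
        assert not effects["B3"].fully_deleted

    @given(st.data())
    def test_matches_per_exon_overlap_oracle(self, locus, data):
        start = data.draw(st.integers(50000, 97000))
        length = data.draw(st.integers(100, 40000))
        call = _call(start, min(start + length, 97999))
        report = {e.gene: e for e in intersect_genes(call, locus.genes)}
        for gene in locus.genes:
            deleted = [
                i
                for i, ex in enumerate(gene.exons, 1)
                if call.interval.start <= ex.start and ex.end <= call.interval.end
            ]
            truncated = [
                i
                for i, ex in enumerate(gene.exons, 1)
                if i not in deleted
                and ex.start < call.interval.end
                and call.interval.start < ex.end
            ]
            if deleted or truncated:
                assert report[gene.gene if hasattr(gene, "gene") else gene.name].exons_deleted == deleted
                assert report[gene.name].exons_truncated == truncated
            else:
                assert gene.name not in report


class TestBuildHybrid:
    def test_planted_deletion_fuses_b5_and_b3(self, locus):
        model = build_hybrid(_call(locus.del_start, locus.del_end), locus.genes)
        assert model is not None
        assert model.five_prime_gene == "B5"
        assert model.three_prime_gene == "B3"
        assert model.retained_5p_exons == list(range(1, 13))
        assert model.retained_3p_exons == [12, 13]
        assert model.fused_name == "B5-3"

    def test_deletion_within_one_intron_is_not_hybrid(self, locus):
        intron = locus.b5.introns()[5]
        assert build_hybrid(_call(intron.start + 10, intron.end - 10), locus.genes) is None

    def test_exonic_breakpoint_warns_truncating(self, locus):
        exon13 = locus.b3.exons[12]
        with pytest.warns(UserWarning, match="truncating"):
            assert build_hybrid(_call(locus.del_start, exon13.start + 5), locus.genes) is None

    def test_opposite_strand_genes_guarded(self):
        plus = GeneModel("P", "+", [IV("c", 100, 200), IV("c", 400, 500)])
        minus = GeneModel("M", "-", [IV("c", 1400, 1500), IV("c", 1100, 1200)])
        assert build_hybrid(_call(250, 1300, chrom="c"), [plus, minus]) is None


class TestSpliceTranscript:
    def test_hybrid_cdna_equals_manual_concatenation(self, locus):
        model = build_hybrid(_call(locus.del_start, locus.del_end), locus.genes)
        iso = splice_transcript(model, locus.genes, locus.genome())
        manual = "".join(
            locus.reference[e.start : e.end] for e in locus.b5.exons[:12]
        ) + "".join(locus.reference[e.start : e.end] for e in locus.b3.exons[11:])
        assert iso.cdna == manual

    def test_shift_removes_exactly_three_nt(self, locus):
        iso0 = splice_gene(locus.b5, locus.genome())
        iso3 = splice_gene(locus.b5, locus.genome(), shifts={8: 3})
        assert len(iso0.cdna) - len(iso3.cdna) == 3
        # and the reading frame is preserved
        assert (len(iso0.cdna) - len(iso3.cdna)) % 3 == 0
        p0 = translate_cdna(iso0)
        p3 = translate_cdna(iso3)
        assert len(p0) - len(p3) == 1

    def test_minus_strand_is_reverse_complement_of_plus(self):
        genome = {"c": "ACGTAACCGGTTACGTACGTAACCGGTTAAACCCGGGTTT"}
        plus = GeneModel("P", "+", [IV("c", 2, 8), IV("c", 12, 18)])
        minus = GeneModel("M", "-", [IV("c", 12, 18), IV("c", 2, 8)])
        iso_p = splice_gene(plus, genome)
        iso_m = splice_gene(minus, genome)
        assert iso_m.cdna == str(Seq(iso_p.cdna).reverse_complement())

    def test_exon_outside_genome_error(self):
        gene = GeneModel("G", "+", [IV("c", 0, 30)])
        with pytest.raises(LilrError):
            splice_gene(gene, {"c": "ACGT"})


class TestTandemAcceptors:
    def test_canonical_nagnag_flagged(self):
        #                 intron........AG exon: CAG...
        genome = {"c": "TTTTTTTTTTTTTTAGCAGAAACCCTTT"}
        gene = GeneModel("G", "+", [IV("c", 2, 6), IV("c", 16, 28)])
        assert find_tandem_acceptors(genome, gene, 2) == {0, 3}

    def test_plain_acceptor_not_flagged(self):
        genome = {"c": "TTTTTTTTTTTTGCAGGAACCCTTTTTT"}
        gene = GeneModel("G", "+", [IV("c", 2, 6), IV("c", 16, 28)])
        assert find_tandem_acceptors(genome, gene, 2) == {0}

    def test_planted_nagnags_found_exactly(self, locus):
        """Only the two planted tandem acceptors exist on the toy locus."""
        flagged = []
        for gene in locus.genes:
            for exon_no in range(2, 14):
                if 3 in find_tandem_acceptors(locus.genome(), gene, exon_no):
                    flagged.append((gene.name, exon_no))
        assert flagged == [("B5", 8), ("B3", 12)]

    def test_first_exon_has_no_acceptor(self, locus):
        assert find_tandem_acceptors(locus.genome(), locus.b5, 1) == {0}


class TestScanItims:
    def test_no_hits_in_poly_a(self):
        assert scan_itims("AAAAAA") == []

    def test_single_consensus_instance(self):
        hits = scan_itims("GGVTYAQLGG")
        assert len(hits) == 1
        assert hits[0].protein_position == 3
        assert hits[0].matched_hexamer == "VTYAQL"

    def test_two_hits_enumerated(self):
        seq = "SAYAAVGGGGITYSSL"
        hits = scan_itims(seq)
        assert [h.protein_position for h in hits] == itim_positions(seq)
        assert len(hits) == 2

    def test_non_amino_acid_rejected(self):
        with pytest.raises(LilrError):
            scan_itims("SAYB1V")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYSIVL", min_size=6, max_size=80))
    def test_matches_window_enumeration_oracle(self, seq):
        assert [h.protein_position for h in scan_itims(seq)] == itim_positions(seq)

    def test_hybrid_protein_itim_arithmetic(self, locus):
        """Fused-protein ITIMs = retained 3'-gene hits + retained 5'-gene hits."""
        model = build_hybrid(_call(locus.del_start, locus.del_end), locus.genes)
        iso = splice_transcript(model, locus.genes, locus.genome())
        fused = len(scan_itims(translate_cdna(iso)))
        b5_part = splice_gene(locus.b5, locus.genome(), exons=range(1, 13))
        b3_part = splice_gene(locus.b3, locus.genome(), exons=range(12, 14))
        assert fused == len(scan_itims(translate_cdna(b5_part))) + len(
            scan_itims(translate_cdna(b3_part))
        )
        # the deletion strips the B5 tail ITIMs and the first B3 ITIM
        assert fused == 3
        assert len(scan_itims(translate_cdna(splice_gene(locus.b5, locus.genome())))) == 3
        assert len(scan_itims(translate_cdna(splice_gene(locus.b3, locus.genome())))) == 4


class TestInsilicoPcr:
    F = "CCTGCACAGCTGAGTCCAGT"
    R = "TTAGTCATCTTTGAGTCAGGTGAG"

    def test_constructed_template_product_length(self):
        template = self.F + "A" * 100 + str(Seq(self.R).reverse_complement())
        products = insilico_pcr(template, PrimerPair(self.F, self.R))
        assert [p[0] for p in products] == [len(self.F) + 100 + len(self.R)]

    def test_no_reverse_site_no_product(self):
        template = self.F + "A" * 200
        assert insilico_pcr(template, PrimerPair(self.F, self.R)) == []

    def test_cloning_tails_ignored(self):
        template = "GG" + self.F + "C" * 80 + str(Seq(self.R).reverse_complement()) + "AA"
        tailed = PrimerPair("AATAATTTAATTAA" + self.F, "AATAATGCGGCCGC" + self.R)
        products = insilico_pcr(template, tailed)
        assert [p[0] for p in products] == [len(self.F) + 80 + len(self.R)]

    def test_short_primer_rejected(self):
        with pytest.raises(LilrError):
            PrimerPair("ACGTACGT", self.R)

    @given(st.data())
    def test_matches_bruteforce_site_scan(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        template = "".join(rng.choice(list("ACGT"), size=2000))
        f = template[100:120]
        r_site = template[1500:1520]
        primers = PrimerPair(f, str(Seq(r_site).reverse_complement()))
        got = [p[0] for p in insilico_pcr(template, primers)]
        expected = pcr_products_bruteforce(template, f, r_site)
        assert got == expected


class TestLongestIdentityTract:
    def test_identical_sequences(self):
        t = longest_identity_tract("A" * 100, "A" * 100)
        assert (t.length, t.pos_a, t.pos_b) == (100, 0, 0)

    def test_disjoint_alphabets(self):
        assert longest_identity_tract("AAAA", "TTTT").length == 0

    def test_empty_input_error(self):
        with pytest.raises(LilrError):
            longest_identity_tract("", "ACGT")

    @given(st.data())
    def test_matches_quadratic_dp_oracle(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        a = "".join(rng.choice(list("ACGT"), size=300))
        b = "".join(rng.choice(list("ACGT"), size=300))
        # plant a shared block sometimes
        if data.draw(st.booleans()):
            block = "".join(rng.choice(list("ACGT"), size=40))
            a = a[:50] + block + a[90:]
            b = b[:200] + block + b[240:]
        t = longest_identity_tract(a, b)
        size, pa, pb = lcs_dp(a, b)
        assert t.length == size
        assert a[t.pos_a : t.pos_a + t.length] == b[t.pos_b : t.pos_b + t.length]

    @given(dna, dna)
    def test_symmetric_in_length(self, a, b):
        assert longest_identity_tract(a, b).length == longest_identity_tract(b, a).length

    def test_planted_269bp_tract_on_toy_locus(self, locus):
        b5_i12 = locus.b5.introns()[11]
        b3_i11 = locus.b3.introns()[10]
        t = longest_identity_tract(
            locus.reference[b5_i12.start : b5_i12.end],
            locus.reference[b3_i11.start : b3_i11.end],
        )
        assert t.length == locus.cfg.identity_tract == 269
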