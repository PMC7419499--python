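"""Consequence-term assignment, impact mapping and tabulation."""
import numpy as np
import pytest
from Bio.Seq import Seq

from tailvar import (
    GenomeAnnotation,
    Reference,
    VariantRecord,
    classify,
    impact_of,
    tabulate,
)
from tailvar.annotation import Gene, Transcript
from tailvar.consequences import ClassificationError, ConsistencyError
from tailvar.reference import revcomp


def _plus_fixture():
    """Single '+' gene on a 400 bp chromosome with known codons.

    mRNA (coding starts at exon position 0): ATG AAA TAC GGT ... TAA
    """
    coding = "ATG" + "AAA" + "TAC" + "GGT" + "CTT" * 20  # no internal stop
    mrna = coding + "TAA"
    start = 50
    seq = "C" * start + mrna + "C" * (400 - start - len(mrna))
    ref = Reference({"chr1": seq})
    e = start + len(mrna)
    tx = Transcript("T1", "G1", "chr1", "+", [(start, e)], [(start, e - 3)],
                    [(e - 3, e)])
    ann = GenomeAnnotation([Gene("G1", "chr1", "+", [tx])])
    return ref, ann, start


def _var(pos0, ref, alt):
    return VariantRecord("chr1", pos0 + 1, ref, [alt])


class TestCodingCalls:
    def test_third_base_silent_substitution(self):
        ref, ann, s = _plus_fixture()
        # codon AAA, third base A->G -> AAG, Lys->Lys
        _, summary = classify(_var(s + 5, "A", "G"), ann, ref)
        assert summary.term == "synonymous" and summary.impact == "LOW"
        assert summary.codon_change == "AAA>AAG"

    def test_stop_gained_from_tac(self):
        ref, ann, s = _plus_fixture()
        # codon TAC, third base C->A -> TAA
        _, summary = classify(_var(s + 8, "C", "A"), ann, ref)
        assert summary.term == "stop_gained" and summary.impact == "HIGH"

    def test_missense(self):
        ref, ann, s = _plus_fixture()
        # codon AAA first base A->G -> GAA, Lys->Glu
        _, summary = classify(_var(s + 3, "A", "G"), ann, ref)
        assert summary.term == "missense" and summary.impact == "MODERATE"
        assert summary.aa_change == "K2E"

    def test_start_lost(self):
        ref, ann, s = _plus_fixture()
        _, summary = classify(_var(s, "A", "G"), ann, ref)
        assert summary.term == "start_lost" and summary.impact == "HIGH"

    def test_stop_lost_and_stop_retained(self):
        ref, ann, s = _plus_fixture()
        stop0 = s + 3 * 24  # TAA
        _, summary = classify(_var(stop0 + 1, "A", "C"), ann, ref)  # TCA
        assert summary.term == "stop_lost" and summary.impact == "HIGH"
        _, summary = classify(_var(stop0 + 1, "A", "G"), ann, ref)  # TGA
        assert summary.term == "stop_retained" and summary.impact == "LOW"

    def test_minus_strand_classified_on_reverse_complement(self):
        # '-' gene: genome holds revcomp(mRNA); genomic C->T in the third
        # codon position is a transcript-strand G->A
        coding = "ATG" + "AAG" + "CTT" * 10
        mrna = coding + "TGA"
        start = 40
        glen = len(mrna)
        seq = "A" * start + revcomp(mrna) + "A" * (300 - start - glen)
        ref = Reference({"chr1": seq})
        e = start + glen
        # transcript coordinates run right-to-left: stop codon leftmost
        tx = Transcript("T1", "G1", "chr1", "-", [(start, e)], [(start + 3, e)],
                        [(start, start + 3)])
        ann = GenomeAnnotation([Gene("G1", "chr1", "-", [tx])])
        # codon AAG third base G: transcript offset 5 -> genomic e-1-5
        pos0 = e - 1 - 5
        assert ref.base("chr1", pos0) == "C"  # complement of G
        _, summary = classify(_var(pos0, "C", "T"), ann, ref)
        assert summary.term == "synonymous"  # AAG -> AAA, Lys->Lys
        assert summary.codon_change == "AAG>AAA"


class TestNonCoding:
    def _utr_fixture(self):
        utr5, coding, utr3 = "GGGGG", "ATG" + "CTT" * 5 + "TAA", "GGGGG"
        start = 30
        mrna = utr5 + coding + utr3
        seq = "A" * start + mrna + "A" * (200 - start - len(mrna))
        ref = Reference({"chr1": seq})
        c0 = start + len(utr5)
        c1 = c0 + len(coding) - 3
        tx = Transcript("T1", "G1", "chr1", "+", [(start, start + len(mrna))],
                        [(c0, c1)], [(c1, c1 + 3)])
        return ref, GenomeAnnotation([Gene("G1", "chr1", "+", [tx])]), start, len(mrna)

    def test_utrs_by_orientation(self):
        ref, ann, s, L = self._utr_fixture()
        _, summary = classify(_var(s + 2, "G", "C"), ann, ref)
        assert summary.term == "five_prime_utr"
        _, summary = classify(_var(s + L - 2, "G", "C"), ann, ref)
        assert summary.term == "three_prime_utr"

    def test_intron_upstream_downstream_intergenic(self):
        ref, ann, s = _plus_fixture()
        # two-exon gene for the intron case
        seq = ref.sequence("chr1")
        ref2 = Reference({"chr1": seq + "C" * 20_000})
        tx = Transcript("T2", "G2", "chr1", "+", [(50, 80), (150, 230)])
        ann2 = GenomeAnnotation([Gene("G2", "chr1", "+", [tx])])
        _, summary = classify(_var(100, ref2.base("chr1", 100), "T"
                                   if ref2.base("chr1", 100) != "T" else "G"),
                              ann2, ref2)
        assert summary.term == "intron"
        _, summary = classify(_var(30, "C", "T"), ann2, ref2)
        assert summary.term == "upstream_gene"
        _, summary = classify(_var(300, "C", "T"), ann2, ref2)
        assert summary.term == "downstream_gene"
        _, summary = classify(_var(10_000, "C", "T"), ann2, ref2)
        assert summary.term == "intergenic"

    def test_strand_flips_up_and_downstream(self):
        ref = Reference({"chr1": "C" * 1000})
        tx = Transcript("T1", "G1", "chr1", "-", [(400, 600)])
        ann = GenomeAnnotation([Gene("G1", "chr1", "-", [tx])])
        _, summary = classify(_var(300, "C", "T"), ann, ref)
        assert summary.term == "downstream_gene"
        _, summary = classify(_var(700, "C", "T"), ann, ref)
        assert summary.term == "upstream_gene"


class TestConsistencyAndImpact:
    def test_ref_mismatch_raises(self):
        ref, ann, s = _plus_fixture()
        with pytest.raises(ConsistencyError):
            classify(_var(s + 5, "T", "G"), ann, ref)

    def test_impact_mapping(self):
        assert impact_of("missense") == "MODERATE"
        assert impact_of("intron") == "MODIFIER"
        assert impact_of("stop_gained") == "HIGH"
        assert impact_of("synonymous") == "LOW"
        with pytest.raises(ClassificationError):
            impact_of("frameshift_banana")


def _independent_codon_oracle(rec, tx, reference):
    """Six-step oracle: locate codon, substitute, translate both, compare."""
    pos0 = rec.pos - 1
    off = tx.genomic_to_spliced(pos0, tx.cds)
    if off is None:
        return None
    cds = tx.coding_sequence(reference)
    ci, cp = divmod(off, 3)
    ref_codon = cds[3 * ci: 3 * ci + 3]
    alt_t = rec.alt[0] if tx.strand == "+" else revcomp(rec.alt[0])
    alt_codon = ref_codon[:cp] + alt_t + ref_codon[cp + 1:]
    a, b = str(Seq(ref_codon).translate()), str(Seq(alt_codon).translate())
    if ci == 0 and alt_codon != "ATG":
        return "start_lost"
    if b == "*":
        return "stop_gained"
    return "synonymous" if a == b else "missense"


class TestOnSyntheticCohort:
    def test_planted_coding_consequences_recovered_exactly(self, cohort):
        by_key = {r.key: r for r in cohort.records}
        planted = [r for r in cohort.truth.rows if r.expected_term]
        counts = {}
        for row in planted:
            _, summary = classify(by_key[row.key], cohort.annotation, cohort.reference)
            assert summary.term == row.expected_term
            counts[summary.term] = counts.get(summary.term, 0) + 1
        cfg = cohort.config
        assert counts == {"missense": cfg.n_missense, "synonymous": cfg.n_synonymous,
                          "stop_gained": cfg.n_stop_gained}

    def test_agrees_with_independent_codon_oracle(self, cohort):
        checked = 0
        for rec in cohort.records:
            if len(rec.alt) != 1:
                continue
            for gene in cohort.annotation.by_chrom[rec.chrom]:
                for tx in gene.transcripts:
                    expect = _independent_codon_oracle(rec, tx, cohort.reference)
                    if expect is None:
                        continue
                    calls, _ = classify(rec, cohort.annotation, cohort.reference)
                    got = [c.term for c in calls if c.transcript_id == tx.transcript_id]
                    assert got == [expect]
                    checked += 1
        assert checked >= 10

    def test_tabulate_partitions_all_variants(self, cohort, cascade):
        summaries = [
            classify(r, cohort.annotation, cohort.reference)[1]
            for r in cascade.survivors
        ]
        table = tabulate(summaries)
        n = len(summaries)
        assert table[table.kind == "term"]["count"].sum() == n
        assert table[table.kind == "impact"]["count"].sum() == n
        assert tabulate([])["count"].sum() == 0
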