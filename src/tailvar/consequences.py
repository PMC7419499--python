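"""Functional consequence classification of filtered SNPs.

Each biallelic SNP is classified against every overlapping or nearby
transcript; the per-variant summary is the most severe call under a fixed
severity order. Coding calls translate the reference and substituted codon
with the standard genetic code (reverse-complemented for '-'-strand
transcripts).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio.Seq import Seq

from .annotation import Gene, GenomeAnnotation, Transcript
from .reference import Reference, revcomp
from .vcfio import VariantKey, VariantRecord

# most severe first
SEVERITY_ORDER = (
    "stop_gained",
    "stop_lost",
    "start_lost",
    "missense",
    "stop_retained",
    "synonymous",
    "five_prime_utr",
    "three_prime_utr",
    "other",
    "intron",
    "upstream_gene",
    "downstream_gene",
    "intergenic",
)

IMPACT_OF_TERM: Dict[str, str] = {
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "missense": "MODERATE",
    "synonymous": "LOW",
    "stop_retained": "LOW",
    "five_prime_utr": "MODIFIER",
    "three_prime_utr": "MODIFIER",
    "intron": "MODIFIER",
    "upstream_gene": "MODIFIER",
    "downstream_gene": "MODIFIER",
    "intergenic": "MODIFIER",
    "other": "MODIFIER",
}

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ClassificationError(ValueError):
    pass


class ConsistencyError(ValueError):
    pass


@dataclass
class ConsequenceCall:
    variant_key: VariantKey
    term: str
    impact: str
    gene_id: Optional[str] = None
    transcript_id: Optional[str] = None
    codon_change: Optional[str] = None
    aa_change: Optional[str] = None


def impact_of(term: str) -> str:
    """Severity tier of a consequence term (HIGH/MODERATE/LOW/MODIFIER)."""
    try:
        return IMPACT_OF_TERM[term]
    except KeyError:
        raise ClassificationError(f"unknown consequence term {term!r}") from None


def _severity_rank(term: str) -> int:
    return SEVERITY_ORDER.index(term)


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _coding_call(
    variant: VariantRecord, tx: Transcript, reference: Reference, pos0: int
) -> Optional[ConsequenceCall]:
    """Classify a position inside the CDS or stop codon of one transcript."""
    alt = variant.alt[0]
    alt_t = alt if tx.strand == "+" else _COMP[alt]

    stop_off = tx.genomic_to_spliced(pos0, tx.stop_codon) if tx.stop_codon else None
    if stop_off is not None:
        ref_codon = tx.spliced_sequence(reference, tx.stop_codon)
        alt_codon = ref_codon[:stop_off] + alt_t + ref_codon[stop_off + 1:]
        term = "stop_retained" if alt_codon in _STOPS else "stop_lost"
        return ConsequenceCall(
            variant.key, term, impact_of(term), tx.gene_id, tx.transcript_id,
            codon_change=f"{ref_codon}>{alt_codon}",
            aa_change=f"*>{'*' if alt_codon in _STOPS else _translate(alt_codon)}",
        )

    off = tx.genomic_to_spliced(pos0, tx.cds)
    if off is None:
        return None
    cds_seq = tx.coding_sequence(reference)
    ci, cp = divmod(off, 3)
    ref_codon = cds_seq[3 * ci: 3 * ci + 3]
    if len(ref_codon) < 3:  # trailing partial codon in a malformed model
        return None
    alt_codon = ref_codon[:cp] + alt_t + ref_codon[cp:][1:]
    ref_aa, alt_aa = _translate(ref_codon), _translate(alt_codon)
    if ci == 0 and alt_codon != "ATG":
        term = "start_lost"
    elif alt_aa == "*":
        term = "stop_gained"
    elif ref_aa == alt_aa:
        term = "synonymous"
    else:
        term = "missense"
    return ConsequenceCall(
        variant.key, term, impact_of(term), tx.gene_id, tx.transcript_id,
        codon_change=f"{ref_codon}>{alt_codon}",
        aa_change=f"{ref_aa}{ci + 1}{alt_aa}",
    )


def _transcript_call(
    variant: VariantRecord, tx: Transcript, reference: Reference
) -> Optional[ConsequenceCall]:
    pos0 = variant.pos - 1
    if tx.start <= pos0 < tx.end:
        coding = _coding_call(variant, tx, reference, pos0)
        if coding is not None:
            return coding
        in_exon = any(s <= pos0 < e for s, e in tx.exons)
        if not in_exon:
            term = "intron"
        else:
            # exonic, non-coding: UTR side by transcript orientation
            if tx.cds:
                cds_lo = tx.cds[0][0]
                cds_hi = max(e for _, e in tx.cds + tx.stop_codon)
                if tx.strand == "+":
                    term = "five_prime_utr" if pos0 < cds_lo else "three_prime_utr"
                else:
                    term = "five_prime_utr" if pos0 >= cds_hi else "three_prime_utr"
            else:
                term = "other"  # non-coding transcript exon
        return ConsequenceCall(
            variant.key, term, impact_of(term), tx.gene_id, tx.transcript_id
        )
    return None


def _flank_call(
    variant: VariantRecord, tx: Transcript, up_down_bp: int
) -> Optional[ConsequenceCall]:
    pos0 = variant.pos - 1
    if tx.start - up_down_bp <= pos0 < tx.start:
        term = "upstream_gene" if tx.strand == "+" else "downstream_gene"
    elif tx.end <= pos0 < tx.end + up_down_bp:
        term = "downstream_gene" if tx.strand == "+" else "upstream_gene"
    else:
        return None
    return ConsequenceCall(
        variant.key, term, impact_of(term), tx.gene_id, tx.transcript_id
    )


def classify(
    variant: VariantRecord,
    annotation: GenomeAnnotation,
    reference: Reference,
    up_down_bp: int = 5000,
) -> Tuple[List[ConsequenceCall], ConsequenceCall]:
    """All per-transcript consequence calls for a SNP plus the most severe
    summary call (ties broken by transcript order)."""
    if not variant.is_biallelic_snp:
        raise ClassificationError(f"not a biallelic SNP: {variant.key}")
    pos0 = variant.pos - 1
    ref_base = reference.base(variant.chrom, pos0)
    if ref_base != variant.ref:
        raise ConsistencyError(
            f"{variant.chrom}:{variant.pos} REF {variant.ref} disagrees with "
            f"reference base {ref_base}"
        )
    calls: List[ConsequenceCall] = []
    for gene in annotation.by_chrom.get(variant.chrom, []):
        for tx in gene.transcripts:
            call = _transcript_call(variant, tx, reference)
            if call is None:
                call = _flank_call(variant, tx, up_down_bp)
            if call is not None:
                calls.append(call)
    if not calls:
        calls = [ConsequenceCall(variant.key, "intergenic", impact_of("intergenic"))]
    summary = min(calls, key=lambda c: _severity_rank(c.term))
    return calls, summary


def tabulate(summaries: Iterable[ConsequenceCall]) -> pd.DataFrame:
    """Counts of summary calls by term and by impact (each a partition)."""
    summaries = list(summaries)
    by_term = Counter(c.term for c in summaries)
    by_impact = Counter(c.impact for c in summaries)
    rows = [("term", t, by_term.get(t, 0)) for t in SEVERITY_ORDER]
    rows += [("impact", i, by_impact.get(i, 0)) for i in ("HIGH", "MODERATE", "LOW", "MODIFIER")]
    return pd.DataFrame(rows, columns=["kind", "category", "count"])
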