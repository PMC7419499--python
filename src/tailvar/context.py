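"""Sequence- and annotation-derived context for the SNP confidence filters.

Four context sources feed the filter cascade:

* homopolymer run length of the alternate allele at a site,
* simple-sequence-repeat (microsatellite) tracts, flanked by 3 bp,
* splice-junction intronic flanks (5 bp at each intron end),
* regions transcribed on both strands (opposite-strand gene-body overlap).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping

import numpy as np

from .annotation import GenomeAnnotation
from .intervals import GenomicInterval, MaskSet, intersect_intervals, merge_intervals
from .reference import Reference


class CoordinateError(ValueError):
    pass


# MISA-convention minimum copy numbers per motif length.
_DEFAULT_MIN_COPIES = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass
class SSRParams:
    """Perfect-microsatellite detection thresholds.

    min_copies maps motif length (1-6 bp) to the minimum number of full
    tandem copies; flank_bp extends each reported tract on both sides.
    """

    min_copies: Dict[int, int] = field(default_factory=lambda: dict(_DEFAULT_MIN_COPIES))
    flank_bp: int = 3

    def __post_init__(self) -> None:
        if set(self.min_copies) - set(range(1, 7)):
            raise ValueError("motif lengths must be 1-6")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")


def homopolymer_run(
    reference: Reference, chrom: str, pos_1based: int, alt_base: str
) -> int:
    """Length of the single-base run through the site after substituting
    the alternate base at the (1-based) position.

    This recomputes the homopolymer context from the reference alone, so the
    filter is reproducible on any VCF regardless of caller annotations.
    """
    alt_base = alt_base.upper()
    if alt_base not in "ACGT" or len(alt_base) != 1:
        raise ValueError(f"alt base must be one of A/C/G/T, got {alt_base!r}")
    pos0 = pos_1based - 1
    n = reference.length(chrom)
    if not (0 <= pos0 < n):
        raise CoordinateError(f"{chrom}:{pos_1based} outside chromosome (len {n})")
    run = 1
    i = pos0 - 1
    while i >= 0 and reference.base(chrom, i) == alt_base:
        run += 1
        i -= 1
    i = pos0 + 1
    while i < n and reference.base(chrom, i) == alt_base:
        run += 1
        i += 1
    return run


def _is_primitive(motif: str) -> bool:
    """True if the motif is not itself a tandem repetition of a shorter unit."""
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[: d] * (m // d):
            return False
    return True


def detect_ssr_regions(
    reference: Reference, params: SSRParams | None = None
) -> List[GenomicInterval]:
    """Perfect tandem-repeat tracts (motif length 1-6) meeting the per-length
    copy minima, extended by the flank, clipped to the chromosome and merged.

    A tract is the maximal stretch with period m; it is attributed to the
    primitive motif only, so an (AT)n tract is reported once, not as (AT)
    and (TA) and (ATAT).
    """
    params = params or SSRParams()
    raw: List[GenomicInterval] = []
    for chrom in reference.chroms:
        seq = reference.sequence(chrom)
        n = len(seq)
        if n == 0:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for m, min_copies in sorted(params.min_copies.items()):
            if n <= m:
                continue
            eq = arr[m:] == arr[:-m]
            if not eq.any():
                continue
            # boundaries of runs of True in eq
            padded = np.concatenate(([False], eq, [False]))
            diff = np.diff(padded.astype(np.int8))
            starts = np.flatnonzero(diff == 1)
            ends = np.flatnonzero(diff == -1)
            for j0, j1 in zip(starts, ends):
                tract_len = (j1 - j0) + m  # maximal stretch with period m
                if tract_len // m < min_copies:
                    continue
                if not _is_primitive(seq[j0: j0 + m]):
                    continue
                s = max(0, int(j0) - params.flank_bp)
                e = min(n, int(j0) + tract_len + params.flank_bp)
                raw.append(GenomicInterval(chrom, s, e, "ssr"))
    return merge_intervals(raw) if raw else []


def splice_junction_mask(
    annotation: GenomeAnnotation, flank_bp: int = 5
) -> List[GenomicInterval]:
    """Intronic flanks of every splice junction: the first and last
    ``flank_bp`` bases of each intron, merged per chromosome.

    Single-exon transcripts contribute nothing; for introns shorter than
    twice the flank the two flanks are clipped to the intron.
    """
    raw: List[GenomicInterval] = []
    for tx in annotation.transcripts():
        for s, e in tx.introns:
            raw.append(GenomicInterval(tx.chrom, s, min(s + flank_bp, e), "junction"))
            raw.append(GenomicInterval(tx.chrom, max(e - flank_bp, s), e, "junction"))
    return merge_intervals(raw) if raw else []


def bidirectional_mask(annotation: GenomeAnnotation) -> List[GenomicInterval]:
    """Regions covered by gene bodies on both strands.

    Computed as the intersection of the union of '+'-strand gene bodies with
    the union of '-'-strand gene bodies. Overlapping same-strand genes do
    not create a mask.
    """
    plus = [
        GenomicInterval(g.chrom, g.start, g.end, "bidirectional")
        for g in annotation.genes
        if g.strand == "+"
    ]
    minus = [
        GenomicInterval(g.chrom, g.start, g.end, "bidirectional")
        for g in annotation.genes
        if g.strand == "-"
    ]
    return intersect_intervals(plus, minus, label="bidirectional")


def build_masks(
    reference: Reference,
    annotation: GenomeAnnotation,
    ssr_params: SSRParams | None = None,
    junction_flank_bp: int = 5,
) -> Dict[str, MaskSet]:
    """All three positional masks used by the filter cascade, keyed by name."""
    return {
        "ssr": MaskSet(detect_ssr_regions(reference, ssr_params), label="ssr"),
        "junction": MaskSet(
            splice_junction_mask(annotation, junction_flank_bp), label="junction"
        ),
        "bidirectional": MaskSet(bidirectional_mask(annotation), label="bidirectional"),
    }
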