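"""Stringent SNP confidence cascade.

Stage order (each stage only sees the previous stage's survivors):

1. ``biallelic_snp``  — single-base ref/alt, exactly one alternate allele
   (indels and multiallelic sites are dropped here).
2. ``hard_filter``    — site annotation cut-offs: DP < 10, homopolymer run
   of the alt allele > 5 (recomputed from the reference), MQ < 40,
   MQRankSum < -12.5, QD < 2, ReadPosRankSum < -8. A missing annotation
   cannot trigger its rule.
3. ``alt_support``    — a sample's variant call is valid only with >= 3 reads
   supporting the alternate allele; failing calls are set to missing and the
   site survives if at least one valid supported call remains.
4. ``mask``           — drop sites inside SSR (+/-3 bp), splice-junction
   (5 bp intronic flanks) or bidirectional-transcription masks.
5. ``known``          — keep sites catalogued (same chrom/pos/ref/alt) in the
   known-SNP database; survivors get the database rsID, the rest are novel.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .context import homopolymer_run
from .intervals import MaskSet
from .reference import Reference
from .vcfio import GenotypeCall, KnownVariantDB, VariantKey, VariantRecord

STAGES = ("input", "biallelic_snp", "hard_filter", "alt_support", "mask", "known")


class CoordinateError(ValueError):
    pass


@dataclass(frozen=True)
class HardFilterThresholds:
    """Site-annotation cut-offs; all comparisons are strict inequalities."""

    min_dp: int = 10
    max_hrun: int = 5
    min_mq: float = 40.0
    min_mq_rank_sum: float = -12.5
    min_qd: float = 2.0
    min_read_pos_rank_sum: float = -8.0


@dataclass
class FilterResult:
    passed: bool
    failed_rules: List[str] = field(default_factory=list)


@dataclass
class FilterTrace:
    """Per-run audit: survivor counts per stage and per-variant outcomes."""

    stage_counts: List[Tuple[str, int, int]] = field(default_factory=list)  # (stage, survivors, removed)
    removed_at: Dict[VariantKey, Tuple[str, Tuple[str, ...]]] = field(default_factory=dict)

    def record_stage(self, stage: str, survivors: int, removed: int) -> None:
        self.stage_counts.append((stage, survivors, removed))

    @property
    def survivors_per_stage(self) -> List[int]:
        return [n for _, n, _ in self.stage_counts]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.stage_counts, columns=["stage", "survivors", "removed"])


@dataclass
class CascadeResult:
    survivors: List[VariantRecord]
    trace: FilterTrace


def hard_filter(
    variant: VariantRecord,
    hrun: int,
    thresholds: HardFilterThresholds = HardFilterThresholds(),
) -> FilterResult:
    """Evaluate the annotation cut-offs; name every violated rule.

    A missing INFO key passes its rule: what cannot be evaluated cannot
    eliminate a site.
    """
    info = variant.info
    failed: List[str] = []

    def val(key: str) -> Optional[float]:
        v = info.get(key)
        if v is None:
            return None
        if not isinstance(v, (int, float)):
            raise TypeError(f"non-numeric INFO {key}={v!r}")
        return float(v)

    dp = val("DP")
    if dp is not None and dp < thresholds.min_dp:
        failed.append("depth")
    if hrun > thresholds.max_hrun:
        failed.append("homopolymer")
    mq = val("MQ")
    if mq is not None and mq < thresholds.min_mq:
        failed.append("mapping_quality")
    mqrs = val("MQRankSum")
    if mqrs is not None and mqrs < thresholds.min_mq_rank_sum:
        failed.append("mq_rank_sum")
    qd = val("QD")
    if qd is not None and qd < thresholds.min_qd:
        failed.append("quality_by_depth")
    rprs = val("ReadPosRankSum")
    if rprs is not None and rprs < thresholds.min_read_pos_rank_sum:
        failed.append("read_pos_rank_sum")
    return FilterResult(passed=not failed, failed_rules=failed)


def biallelic_snp_filter(variant: VariantRecord) -> bool:
    """Keep only sites with exactly one single-base alternate allele."""
    return variant.is_biallelic_snp


def alt_support_filter(call: GenotypeCall, min_alt_reads: int = 3) -> bool:
    """Validity of one sample's variant call by alternate-read support.

    Only variant calls (carrying >= 1 alt allele) are judged; hom-ref or
    missing calls are not variant calls, so the rule does not apply and
    True is returned. A variant call lacking AD is invalid.
    """
    if not call.is_variant:
        return True
    alt_idx = max(a for a in call.alleles if a is not None)
    ad = call.alt_depth(alt_idx)
    return ad is not None and ad >= min_alt_reads


def mask_filter(
    variant: VariantRecord, masks: Mapping[str, MaskSet]
) -> Tuple[bool, List[str]]:
    """Fail iff the position lies in any mask; list every containing mask."""
    labels = [
        name for name, mask in masks.items() if mask.contains(variant.chrom, variant.pos - 1)
    ]
    return (not labels, labels)


def known_filter(
    variant: VariantRecord, db: KnownVariantDB
) -> Tuple[bool, Optional[str]]:
    """Pass iff (chrom, pos, ref, alt) is catalogued; return the rsID."""
    rsid = db.lookup(variant.chrom, variant.pos, variant.ref, variant.alt[0])
    return (rsid is not None, rsid)


def run_cascade(
    variants: Iterable[VariantRecord],
    reference: Reference,
    masks: Mapping[str, MaskSet],
    db: KnownVariantDB,
    panel=None,
    thresholds: HardFilterThresholds = HardFilterThresholds(),
    min_alt_reads: int = 3,
    pooled_support: bool = False,
) -> CascadeResult:
    """Apply the full confidence cascade and report per-stage survivors.

    ``pooled_support=True`` judges alternate-read support on the summed AD
    across samples instead of per sample (both readings of the >= 3-read
    rule are supported; per-sample is the default).

    The ``panel`` argument is accepted for interface symmetry with the
    breed-comparison stage; no filter rule is breed-aware.
    """
    trace = FilterTrace()
    current: List[VariantRecord] = [v.copy() for v in variants]
    trace.record_stage("input", len(current), 0)

    def advance(stage: str, keep: List[VariantRecord], n_before: int) -> List[VariantRecord]:
        trace.record_stage(stage, len(keep), n_before - len(keep))
        return keep

    # 1. SNP-only, biallelic
    keep = []
    for v in current:
        if biallelic_snp_filter(v):
            keep.append(v)
        else:
            trace.removed_at[v.key] = ("biallelic_snp", ("biallelic_snp",))
    current = advance("biallelic_snp", keep, len(current))

    # 2. hard annotation cut-offs (homopolymer run recomputed from reference)
    keep = []
    for v in current:
        if v.chrom not in reference:
            raise CoordinateError(f"contig {v.chrom} absent from reference")
        hrun = homopolymer_run(reference, v.chrom, v.pos, v.alt[0])
        res = hard_filter(v, hrun, thresholds)
        if res.passed:
            keep.append(v)
        else:
            trace.removed_at[v.key] = ("hard_filter", tuple(res.failed_rules))
    current = advance("hard_filter", keep, len(current))

    # 3. per-sample alternate-read support
    keep = []
    for v in current:
        if pooled_support:
            total = sum(
                c.alt_depth(1) or 0 for c in v.genotypes if c.is_variant
            )
            ok = total >= min_alt_reads
        else:
            ok = False
            for call in v.genotypes:
                if not call.is_variant:
                    continue
                if alt_support_filter(call, min_alt_reads):
                    ok = True
                else:
                    # unsupported individual call -> missing genotype
                    call.alleles = (None, None)
                    call.allele_depths = None
        if ok:
            keep.append(v)
        else:
            trace.removed_at[v.key] = ("alt_support", ("alt_support",))
    current = advance("alt_support", keep, len(current))

    # 4. positional masks
    keep = []
    for v in current:
        passed, labels = mask_filter(v, masks)
        if passed:
            keep.append(v)
        else:
            trace.removed_at[v.key] = ("mask", tuple(labels))
    current = advance("mask", keep, len(current))

    # 5. known-SNP database
    keep = []
    for v in current:
        passed, rsid = known_filter(v, db)
        if passed:
            v.id = rsid
            keep.append(v)
        else:
            trace.removed_at[v.key] = ("known", ("novel",))
    current = advance("known", keep, len(current))

    return CascadeResult(survivors=current, trace=trace)
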