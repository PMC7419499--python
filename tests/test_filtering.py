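"""Confidence-cascade rules, boundary behaviour and whole-cascade properties."""
import numpy as np
import pytest

from tailvar import (
    GenotypeCall,
    HardFilterThresholds,
    KnownVariantDB,
    Reference,
    VariantRecord,
    alt_support_filter,
    biallelic_snp_filter,
    hard_filter,
    known_filter,
    mask_filter,
    run_cascade,
)
from tailvar.intervals import GenomicInterval, MaskSet


def _rec(info=None, alt=("G",), ref="A", pos=100, genotypes=()):
    base = {"DP": 30, "QD": 15.0, "MQ": 55.0, "MQRankSum": 0.0, "ReadPosRankSum": 0.0}
    if info is not None:
        base.update(info)
        base = {k: v for k, v in base.items() if v is not None}
    return VariantRecord("chr1", pos, ref, list(alt), info=base,
                         genotypes=list(genotypes))


class TestHardFilter:
    def test_low_depth_fails_depth_rule_only(self):
        res = hard_filter(_rec({"DP": 9}), hrun=1)
        assert not res.passed and res.failed_rules == ["depth"]

    def test_thresholds_are_strict_inequalities(self):
        rec = _rec({"DP": 10, "QD": 2.0, "MQ": 40.0, "MQRankSum": -12.5,
                    "ReadPosRankSum": -8.0})
        assert hard_filter(rec, hrun=5).passed

    def test_missing_annotation_cannot_trigger_its_rule(self):
        assert hard_filter(_rec({"MQRankSum": None}), hrun=1).passed

    def test_each_rule_fires_and_is_named(self):
        cases = [
            ({"MQ": 39.9}, "mapping_quality"),
            ({"MQRankSum": -12.6}, "mq_rank_sum"),
            ({"QD": 1.9}, "quality_by_depth"),
            ({"ReadPosRankSum": -8.1}, "read_pos_rank_sum"),
        ]
        for info, rule in cases:
            res = hard_filter(_rec(info), hrun=1)
            assert res.failed_rules == [rule]
        res = hard_filter(_rec(), hrun=6)
        assert res.failed_rules == ["homopolymer"]

    def test_multiple_violations_all_named(self):
        res = hard_filter(_rec({"DP": 5, "MQ": 10.0}), hrun=7)
        assert set(res.failed_rules) == {"depth", "homopolymer", "mapping_quality"}


class TestBiallelicSNP:
    def test_single_alt_passes(self):
        assert biallelic_snp_filter(_rec(alt=("G",)))

    def test_two_alts_fail(self):
        assert not biallelic_snp_filter(_rec(alt=("G", "T")))

    def test_indel_fails(self):
        assert not biallelic_snp_filter(_rec(ref="AC", alt=("A",)))
        assert not biallelic_snp_filter(_rec(ref="A", alt=("AC",)))


class TestAltSupport:
    def test_two_supporting_reads_fail(self):
        assert not alt_support_filter(GenotypeCall("s", (0, 1), (10, 2), 12))

    def test_three_supporting_reads_pass(self):
        assert alt_support_filter(GenotypeCall("s", (0, 1), (10, 3), 13))

    def test_hom_ref_call_not_applicable(self):
        assert alt_support_filter(GenotypeCall("s", (0, 0), (20, 0), 20))

    def test_variant_call_without_ad_is_invalid(self):
        assert not alt_support_filter(GenotypeCall("s", (0, 1), None, 13))


class TestMaskAndKnown:
    def test_mask_labels_list_every_containing_mask(self):
        masks = {
            "ssr": MaskSet([GenomicInterval("chr1", 90, 110)]),
            "junction": MaskSet([GenomicInterval("chr1", 95, 105)]),
            "bidirectional": MaskSet([GenomicInterval("chr1", 500, 600)]),
        }
        passed, labels = mask_filter(_rec(pos=100), masks)
        assert not passed and set(labels) == {"ssr", "junction"}
        passed, labels = mask_filter(_rec(pos=300), masks)
        assert passed and labels == []

    def test_known_requires_allele_identity(self):
        db = KnownVariantDB({("chr1", 100, "A", "G"): "rs42"})
        ok, rsid = known_filter(_rec(alt=("G",)), db)
        assert ok and rsid == "rs42"
        ok, _ = known_filter(_rec(alt=("T",)), db)  # same position, other alt
        assert not ok
        ok, _ = known_filter(_rec(pos=101, alt=("G",)), db)
        assert not ok


def _brute_force_survivors(records, reference, masks, db, min_alt_reads=3):
    """Independent re-evaluation of every cascade predicate from scratch."""
    out = set()
    for rec in records:
        if not (len(rec.alt) == 1 and len(rec.ref) == 1 and len(rec.alt[0]) == 1
                and rec.ref in "ACGT" and rec.alt[0] in "ACGT"):
            continue
        seq = reference.sequence(rec.chrom)
        i, b = rec.pos - 1, rec.alt[0]
        sub = seq[:i] + b + seq[i + 1:]
        run, j = 1, i - 1
        while j >= 0 and sub[j] == b:
            run, j = run + 1, j - 1
        j = i + 1
        while j < len(sub) and sub[j] == b:
            run, j = run + 1, j + 1
        info = rec.info
        if (info.get("DP", 1e9) < 10 or run > 5 or info.get("MQ", 1e9) < 40
                or info.get("MQRankSum", 0) < -12.5 or info.get("QD", 1e9) < 2
                or info.get("ReadPosRankSum", 0) < -8):
            continue
        if not any(
            c.is_variant and c.allele_depths is not None
            and c.allele_depths[1] >= min_alt_reads
            for c in rec.genotypes
        ):
            continue
        if any(iv.chrom == rec.chrom and iv.start <= i < iv.end
               for m in masks.values() for iv in m):
            continue
        if db.lookup(rec.chrom, rec.pos, rec.ref, rec.alt[0]) is None:
            continue
        out.add(rec.key)
    return out


class TestCascade:
    def test_empty_input(self, cohort):
        res = run_cascade([], cohort.reference, cohort.masks, cohort.known_db)
        assert res.survivors == [] and res.trace.survivors_per_stage == [0] * 6

    def test_stage_counts_non_increasing(self, cascade):
        counts = cascade.trace.survivors_per_stage
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_order_insensitivity(self, cohort, cascade):
        rng = np.random.default_rng(0)
        shuffled = [cohort.records[i] for i in rng.permutation(len(cohort.records))]
        res2 = run_cascade(shuffled, cohort.reference, cohort.masks, cohort.known_db)
        assert {r.key for r in res2.survivors} == {r.key for r in cascade.survivors}

    def test_idempotence(self, cohort, cascade):
        res2 = run_cascade(cascade.survivors, cohort.reference, cohort.masks,
                           cohort.known_db)
        assert [r.key for r in res2.survivors] == [r.key for r in cascade.survivors]
        assert all(n == len(cascade.survivors) for n in res2.trace.survivors_per_stage)

    def test_matches_brute_force_oracle(self, cohort, cascade):
        brute = _brute_force_survivors(
            cohort.records, cohort.reference, cohort.masks, cohort.known_db
        )
        assert {r.key for r in cascade.survivors} == brute

    def test_unsupported_individual_calls_become_missing(self, cohort, cascade):
        # survivors may retain no unsupported variant call
        for rec in cascade.survivors:
            for call in rec.genotypes:
                if call.is_variant:
                    assert call.allele_depths[1] >= 3

    def test_unknown_contig_raises(self, cohort):
        bad = _rec(pos=5)
        bad.chrom = "chrZ"
        with pytest.raises(Exception):
            run_cascade([bad], cohort.reference, cohort.masks, cohort.known_db)

    def test_pooled_support_keeps_jointly_supported_site(self, cohort, cascade):
        # take a known survivor site, weaken it to two carriers with 2 alt
        # reads each: per-sample reading drops it, pooled (2+2 >= 3) keeps it
        rec = cascade.survivors[0].copy()
        rec.genotypes = [
            GenotypeCall(s, (0, 1), (10, 2), 12) for s in cohort.samples[:2]
        ] + [GenotypeCall(s, (0, 0), (20, 0), 20) for s in cohort.samples[2:]]
        per_sample = run_cascade([rec], cohort.reference, cohort.masks,
                                 cohort.known_db)
        pooled = run_cascade([rec], cohort.reference, cohort.masks,
                             cohort.known_db, pooled_support=True)
        assert len(per_sample.survivors) == 0
        assert per_sample.trace.removed_at[rec.key][0] == "alt_support"
        assert len(pooled.survivors) == 1
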