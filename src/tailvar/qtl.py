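"""Colocalization of SNPs with trait-labelled QTL intervals.

QTL coordinates are 1-based inclusive (the convention of the public animal
QTL databases); a SNP at either end coordinate counts as inside. A SNP in
several QTLs of one trait counts once in that trait's distinct tally but
each hit counts in the SNP x QTL pair tally.
"""
from __future__ import annotations

import math
import warnings
from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .vcfio import VariantKey


class QTLFormatError(ValueError):
    pass


REQUIRED_COLUMNS = ("trait_name", "chrom", "start_1based", "end_1based", "qtl_id")


@dataclass(frozen=True)
class QTLRecord:
    qtl_id: str
    trait_name: str
    chrom: str
    start_1based: int
    end_1based: int  # inclusive

    def __post_init__(self) -> None:
        if self.start_1based > self.end_1based:
            raise QTLFormatError(
                f"{self.qtl_id}: start {self.start_1based} > end {self.end_1based}"
            )
        if not self.trait_name:
            raise QTLFormatError(f"{self.qtl_id}: empty trait name")

    def contains(self, chrom: str, pos_1based: int) -> bool:
        return chrom == self.chrom and self.start_1based <= pos_1based <= self.end_1based


def load_qtls(path, trait_whitelist: Optional[Iterable[str]] = None) -> List[QTLRecord]:
    """Read QTL records from TSV, keeping whitelist traits only.

    Malformed rows (start > end, empty trait) are skipped with a warning
    naming the file line; duplicate qtl_ids are kept — overlapping records
    of one QTL are real in curated databases.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise QTLFormatError(f"missing columns: {sorted(missing)}")
    whitelist = set(trait_whitelist) if trait_whitelist is not None else None
    records: List[QTLRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        if whitelist is not None and row["trait_name"] not in whitelist:
            continue
        try:
            records.append(
                QTLRecord(
                    qtl_id=str(row["qtl_id"]),
                    trait_name=str(row["trait_name"]),
                    chrom=str(row["chrom"]),
                    start_1based=int(row["start_1based"]),
                    end_1based=int(row["end_1based"]),
                )
            )
        except (QTLFormatError, ValueError) as exc:
            warnings.warn(f"{path} line {line_no}: rejected ({exc})", stacklevel=2)
    return records


@dataclass
class ColocalizationReport:
    distinct_snps: int
    snp_qtl_pairs: int
    per_trait_distinct: Dict[str, int]
    hits: pd.DataFrame  # one row per SNP x QTL pair


def colocalize(
    sites: Iterable[VariantKey], qtls: Sequence[QTLRecord]
) -> ColocalizationReport:
    """Overlap SNP positions with QTL intervals (inclusive ends).

    Reports distinct overlapping SNPs, total SNP x QTL pairs, and per-trait
    distinct SNP counts. Sorted interval sweep with binary search keeps it
    fast for large sets; results are order-independent.
    """
    by_chrom: Dict[str, List[QTLRecord]] = {}
    for q in qtls:
        by_chrom.setdefault(q.chrom, []).append(q)
    starts: Dict[str, List[int]] = {}
    for chrom, qs in by_chrom.items():
        qs.sort(key=lambda q: (q.start_1based, q.end_1based, q.qtl_id))
        starts[chrom] = [q.start_1based for q in qs]

    rows = []
    distinct: Set[VariantKey] = set()
    per_trait: Dict[str, Set[VariantKey]] = {}
    for key in sites:
        chrom, pos = key[0], key[1]
        qs = by_chrom.get(chrom)
        if not qs:
            continue
        hi = bisect_right(starts[chrom], pos)
        for q in qs[:hi]:  # start <= pos; check end
            if pos <= q.end_1based:
                rows.append((chrom, pos, key[2], key[3], q.qtl_id, q.trait_name))
                distinct.add(key)
                per_trait.setdefault(q.trait_name, set()).add(key)
    hits = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "qtl_id", "trait_name"]
    )
    return ColocalizationReport(
        distinct_snps=len(distinct),
        snp_qtl_pairs=len(rows),
        per_trait_distinct={t: len(s) for t, s in sorted(per_trait.items())},
        hits=hits,
    )


def percent_overlapping(n_overlapping: int, n_total: int) -> int:
    """Reported percentage, rounded half-up to the nearest integer."""
    if n_total == 0:
        raise ZeroDivisionError("no sites to compute a percentage over")
    return int(math.floor(100.0 * n_overlapping / n_total + 0.5))


def qtl_fraction(
    specific_sites: Iterable[VariantKey], qtls: Sequence[QTLRecord]
) -> Tuple[int, float]:
    """Percentage of breed-specific SNPs inside >= 1 QTL.

    Returns (rounded integer percentage for reporting, full-precision
    fraction). NaN fraction signals an empty site set.
    """
    sites = list(specific_sites)
    if not sites:
        return 0, float("nan")
    report = colocalize(sites, qtls)
    frac = report.distinct_snps / len(sites)
    return percent_overlapping(report.distinct_snps, len(sites)), frac
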