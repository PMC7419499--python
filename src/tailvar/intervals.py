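"""Genomic interval primitives shared by the masking and colocalization stages.

All in-memory coordinates are 0-based, half-open ``[start, end)``. File
formats convert at the boundary (VCF/GTF are 1-based inclusive, BED is
0-based half-open).
"""
from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A labelled half-open genomic interval."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Merge overlapping/adjacent intervals per chromosome.

    The result is sorted and pairwise disjoint; the label of the first
    interval in each merged cluster is kept (masks carry uniform labels).
    """
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e, cur_l = ivs[0].start, ivs[0].end, ivs[0].label
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e, cur_l))
                cur_s, cur_e, cur_l = iv.start, iv.end, iv.label
        merged.append(GenomicInterval(chrom, cur_s, cur_e, cur_l))
    return merged


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval], label: str = ""
) -> List[GenomicInterval]:
    """Intersection of two interval sets, per chromosome (two-pointer sweep)."""
    am = merge_intervals(a) if a else []
    bm = merge_intervals(b) if b else []
    a_by: Dict[str, List[GenomicInterval]] = {}
    for iv in am:
        a_by.setdefault(iv.chrom, []).append(iv)
    b_by: Dict[str, List[GenomicInterval]] = {}
    for iv in bm:
        b_by.setdefault(iv.chrom, []).append(iv)
    out: List[GenomicInterval] = []
    for chrom in sorted(set(a_by) & set(b_by)):
        xs, ys = a_by[chrom], b_by[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i].start, ys[j].start)
            e = min(xs[i].end, ys[j].end)
            if s < e:
                out.append(GenomicInterval(chrom, s, e, label))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


class MaskSet:
    """Normalized (merged, sorted) interval set with O(log n) point lookup."""

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = ""):
        self.label = label
        self.intervals: List[GenomicInterval] = merge_intervals(intervals) if intervals else []
        self._starts: Dict[str, List[int]] = {}
        self._ends: Dict[str, List[int]] = {}
        for iv in self.intervals:
            self._starts.setdefault(iv.chrom, []).append(iv.start)
            self._ends.setdefault(iv.chrom, []).append(iv.end)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def contains(self, chrom: str, pos0: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < self._ends[chrom][i]

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                name = iv.label or self.label or "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")

    @classmethod
    def from_bed(cls, path, label: str = "") -> "MaskSet":
        ivs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                ivs.append(GenomicInterval(f[0], int(f[1]), int(f[2]),
                                           f[3] if len(f) > 3 else label))
        return cls(ivs, label=label)


def point_in_mask(
    intervals: "MaskSet | Sequence[GenomicInterval]", chrom: str, pos_1based: int
) -> bool:
    """True iff the 1-based position falls inside the (normalized) mask."""
    mask = intervals if isinstance(intervals, MaskSet) else MaskSet(intervals)
    return mask.contains(chrom, pos_1based - 1)
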