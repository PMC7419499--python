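"""VCF-backed variant records and known-SNP database.

Reading goes through pysam; writing emits plain VCF v4.2 text. Positions
are 1-based in records (VCF convention); allele indices follow GT order.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pysam

INFO_KEYS = ("DP", "QD", "MQ", "MQRankSum", "ReadPosRankSum")

VariantKey = Tuple[str, int, str, str]  # (chrom, pos_1based, ref, alt)


class InputFormatError(ValueError):
    pass


@dataclass
class GenotypeCall:
    """One sample's genotype at a site: GT allele indices plus AD/DP."""

    sample_id: str
    alleles: Tuple[Optional[int], Optional[int]]
    allele_depths: Optional[Tuple[int, ...]] = None  # AD: ref then alts
    depth: Optional[int] = None

    @property
    def is_missing(self) -> bool:
        return self.alleles[0] is None and self.alleles[1] is None

    @property
    def is_variant(self) -> bool:
        """Carries at least one non-reference allele."""
        return any(a is not None and a > 0 for a in self.alleles)

    @property
    def is_het(self) -> bool:
        a, b = self.alleles
        return a is not None and b is not None and a != b

    @property
    def is_hom_alt(self) -> bool:
        a, b = self.alleles
        return a is not None and a == b and a > 0

    @property
    def is_hom_ref(self) -> bool:
        return self.alleles == (0, 0)

    def alt_depth(self, alt_index: int = 1) -> Optional[int]:
        if self.allele_depths is None or alt_index >= len(self.allele_depths):
            return None
        return self.allele_depths[alt_index]

    @property
    def gt_string(self) -> str:
        return "/".join("." if a is None else str(a) for a in self.alleles)


@dataclass
class VariantRecord:
    """One VCF site: position, alleles, site INFO and per-sample calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: List[str]
    id: Optional[str] = None
    qual: Optional[float] = None
    info: Dict[str, float] = field(default_factory=dict)
    genotypes: List[GenotypeCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputFormatError(f"position must be >= 1, got {self.pos}")
        for key, val in self.info.items():
            if val is not None and not isinstance(val, (int, float)):
                raise InputFormatError(
                    f"non-numeric INFO value {key}={val!r} at {self.chrom}:{self.pos}"
                )

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alt) and \
            self.ref in "ACGT" and all(a in "ACGT" for a in self.alt)

    @property
    def is_biallelic_snp(self) -> bool:
        return len(self.alt) == 1 and self.is_snp

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, ",".join(self.alt))

    def call_for(self, sample_id: str) -> Optional[GenotypeCall]:
        for call in self.genotypes:
            if call.sample_id == sample_id:
                return call
        return None

    def copy(self) -> "VariantRecord":
        return replace(
            self,
            alt=list(self.alt),
            info=dict(self.info),
            genotypes=[replace(g) for g in self.genotypes],
        )


class KnownVariantDB:
    """Known-SNP lookup keyed by (chrom, pos, ref, alt) -> rsID.

    Matching requires allele identity, not just position: a different
    substitution at a catalogued position is still novel.
    """

    def __init__(self, entries: Mapping[VariantKey, str] | None = None):
        self._db: Dict[VariantKey, str] = dict(entries or {})

    def __len__(self) -> int:
        return len(self._db)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._db

    def add(self, chrom: str, pos: int, ref: str, alt: str, rsid: str) -> None:
        self._db[(chrom, pos, ref, alt)] = rsid

    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> Optional[str]:
        return self._db.get((chrom, pos, ref, alt))

    def items(self):
        return self._db.items()

    @classmethod
    def from_vcf(cls, path) -> "KnownVariantDB":
        db = cls()
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    if len(rec.ref) == 1 and len(alt) == 1:
                        db.add(rec.contig, rec.pos, rec.ref, alt, rec.id or ".")
        return db

    def write_vcf(self, path, contigs: Mapping[str, int]) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom, length in contigs.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for (chrom, pos, ref, alt), rsid in sorted(self._db.items()):
                fh.write(f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# VCF reading / writing

def read_vcf(path) -> Tuple[List[str], List[VariantRecord]]:
    """Load a VCF into (sample names, variant records) via pysam."""
    records: List[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            info: Dict[str, float] = {}
            for key in INFO_KEYS:
                if key in rec.info:
                    val = rec.info[key]
                    if isinstance(val, tuple):
                        val = val[0]
                    info[key] = float(val) if key != "DP" else int(val)
            calls: List[GenotypeCall] = []
            for name in samples:
                s = rec.samples[name]
                gt = s.get("GT", (None, None))
                if gt is None or len(gt) == 0:
                    gt = (None, None)
                elif len(gt) == 1:
                    gt = (gt[0], gt[0])
                ad = s.get("AD")
                if ad is not None and all(a is None for a in ad):
                    ad = None
                calls.append(
                    GenotypeCall(
                        sample_id=name,
                        alleles=(gt[0], gt[1]),
                        allele_depths=tuple(int(a) for a in ad) if ad is not None else None,
                        depth=s.get("DP"),
                    )
                )
            records.append(
                VariantRecord(
                    chrom=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=list(rec.alts or ()),
                    id=None if rec.id in (None, ".") else rec.id,
                    qual=rec.qual,
                    info=info,
                    genotypes=calls,
                )
            )
    return samples, records


def _fmt_info(info: Mapping[str, float]) -> str:
    if not info:
        return "."
    parts = []
    for key in INFO_KEYS:
        if key in info and info[key] is not None:
            val = info[key]
            parts.append(f"{key}={int(val)}" if key == "DP" else f"{key}={val:g}")
    return ";".join(parts) if parts else "."


def write_vcf(
    path,
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    contigs: Mapping[str, int],
) -> None:
    """Write VCF v4.2 with GT:AD:DP per sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth of coverage">\n')
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">\n')
        fh.write('##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if samples:
            header += "\tFORMAT\t" + "\t".join(samples)
        fh.write(header + "\n")
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            row = [
                rec.chrom,
                str(rec.pos),
                rec.id or ".",
                rec.ref,
                ",".join(rec.alt),
                "." if rec.qual is None else f"{rec.qual:g}",
                ".",
                _fmt_info(rec.info),
            ]
            if samples:
                row.append("GT:AD:DP")
                by_sample = {c.sample_id: c for c in rec.genotypes}
                for name in samples:
                    call = by_sample.get(name)
                    if call is None:
                        row.append("./.:.:.")
                        continue
                    ad = (
                        ",".join(str(a) for a in call.allele_depths)
                        if call.allele_depths is not None
                        else "."
                    )
                    dp = "." if call.depth is None else str(call.depth)
                    row.append(f"{call.gt_string}:{ad}:{dp}")
            fh.write("\t".join(row) + "\n")
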