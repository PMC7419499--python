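"""Gene-model container and GTF round-trip.

The model is deliberately small: genes with one or more transcripts, each
transcript a sorted list of exon intervals plus CDS intervals (stop codon
excluded, Ensembl convention) and an optional stop-codon interval. This is
everything the mask computation and consequence classification need.
"""
from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import gffutils

from .reference import Reference, revcomp

Interval = Tuple[int, int]  # 0-based half-open


class AnnotationError(ValueError):
    pass


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: List[Interval] = field(default_factory=list)  # sorted genomic order
    cds: List[Interval] = field(default_factory=list)  # stop codon excluded
    stop_codon: List[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        self.stop_codon = sorted(self.stop_codon)
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if prev[1] > nxt[0]:
                raise AnnotationError(
                    f"overlapping/unsorted exons in {self.transcript_id}"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> List[Interval]:
        return [(a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    # -- coordinate mapping ------------------------------------------------
    def transcript_order(self, intervals: Sequence[Interval]) -> List[Interval]:
        """Intervals ordered 5'→3' along the transcript."""
        ivs = sorted(intervals)
        return ivs if self.strand == "+" else ivs[::-1]

    def genomic_to_spliced(self, pos0: int, intervals: Sequence[Interval]) -> Optional[int]:
        """Offset of a genomic position within the spliced, stranded
        concatenation of ``intervals`` (e.g. the coding sequence), or None."""
        off = 0
        for s, e in self.transcript_order(intervals):
            if s <= pos0 < e:
                return off + (pos0 - s if self.strand == "+" else e - 1 - pos0)
            off += e - s
        return None

    def spliced_to_genomic(self, offset: int, intervals: Sequence[Interval]) -> int:
        off = offset
        for s, e in self.transcript_order(intervals):
            if off < e - s:
                return s + off if self.strand == "+" else e - 1 - off
            off -= e - s
        raise IndexError(f"offset {offset} beyond spliced length")

    def spliced_sequence(self, reference: Reference, intervals: Sequence[Interval]) -> str:
        parts = [reference.sequence(self.chrom, s, e) for s, e in sorted(intervals)]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)

    def coding_sequence(self, reference: Reference) -> str:
        return self.spliced_sequence(reference, self.cds)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: List[Transcript] = field(default_factory=list)
    gene_name: str = ""

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


class GenomeAnnotation:
    """All genes of a genome, indexed by id and by chromosome."""

    def __init__(self, genes: Sequence[Gene]):
        self.genes: List[Gene] = list(genes)
        self.by_id: Dict[str, Gene] = {g.gene_id: g for g in self.genes}
        self.by_chrom: Dict[str, List[Gene]] = {}
        for g in self.genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
        for glist in self.by_chrom.values():
            glist.sort(key=lambda g: g.start)

    def __len__(self) -> int:
        return len(self.genes)

    def transcripts(self) -> Iterator[Transcript]:
        for g in self.genes:
            yield from g.transcripts

    # -- GTF I/O (Ensembl dialect, 1-based inclusive) ----------------------
    def write_gtf(self, path) -> None:
        def attrs(gene: Gene, tx: Optional[Transcript] = None) -> str:
            a = f'gene_id "{gene.gene_id}"; '
            if tx is not None:
                a += f'transcript_id "{tx.transcript_id}"; '
            if gene.gene_name:
                a += f'gene_name "{gene.gene_name}"; '
            return a.strip()

        with open(path, "w") as fh:
            fh.write("#!genome-build synthetic\n")
            for gene in self.genes:
                fh.write(
                    f"{gene.chrom}\ttailvar\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                    f"{gene.strand}\t.\t{attrs(gene)}\n"
                )
                for tx in gene.transcripts:
                    fh.write(
                        f"{gene.chrom}\ttailvar\ttranscript\t{tx.start + 1}\t{tx.end}\t.\t"
                        f"{tx.strand}\t.\t{attrs(gene, tx)}\n"
                    )
                    for s, e in tx.exons:
                        fh.write(
                            f"{gene.chrom}\ttailvar\texon\t{s + 1}\t{e}\t.\t"
                            f"{tx.strand}\t.\t{attrs(gene, tx)}\n"
                        )
                    cum = 0
                    for s, e in tx.transcript_order(tx.cds):
                        frame = (3 - cum % 3) % 3
                        fh.write(
                            f"{gene.chrom}\ttailvar\tCDS\t{s + 1}\t{e}\t.\t"
                            f"{tx.strand}\t{frame}\t{attrs(gene, tx)}\n"
                        )
                        cum += e - s
                    for s, e in tx.stop_codon:
                        fh.write(
                            f"{gene.chrom}\ttailvar\tstop_codon\t{s + 1}\t{e}\t.\t"
                            f"{tx.strand}\t0\t{attrs(gene, tx)}\n"
                        )

    @classmethod
    def read_gtf(cls, path) -> "GenomeAnnotation":
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        txs: Dict[str, Transcript] = {}
        gene_meta: Dict[str, Tuple[str, str, str]] = {}  # id -> (chrom, strand, name)
        for f in db.features_of_type("gene"):
            name = f.attributes.get("gene_name", [""])[0]
            gene_meta[f.attributes["gene_id"][0]] = (f.seqid, f.strand, name)
        for ftype, target in (("exon", "exons"), ("CDS", "cds"), ("stop_codon", "stop_codon")):
            for f in db.features_of_type(ftype):
                tid = f.attributes["transcript_id"][0]
                gid = f.attributes["gene_id"][0]
                if tid not in txs:
                    txs[tid] = Transcript(tid, gid, f.seqid, f.strand)
                getattr(txs[tid], target).append((f.start - 1, f.end))
        genes: Dict[str, Gene] = {}
        for tx in txs.values():
            tx.exons.sort()
            tx.cds.sort()
            tx.stop_codon.sort()
            if tx.gene_id not in genes:
                chrom, strand, name = gene_meta.get(
                    tx.gene_id, (tx.chrom, tx.strand, "")
                )
                genes[tx.gene_id] = Gene(tx.gene_id, chrom, strand, gene_name=name)
            genes[tx.gene_id].transcripts.append(tx)
        return cls(list(genes.values()))
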