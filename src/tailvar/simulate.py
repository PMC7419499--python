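"""Self-contained synthetic two-breed cohort with a planted truth table.

The generator emulates the post-calling inputs of an RNA-seq SNP-discovery
study on two sheep breeds (4 + 4 animals): a small reference genome with
deliberately planted homopolymer runs and microsatellite tracts, a gene
annotation with at least one antisense-overlapping gene pair per
chromosome, per-sample and merged VCFs carrying the caller-style site
annotations (DP, QD, MQ, MQRankSum, ReadPosRankSum) and GT:AD:DP calls, a
known-SNP database, QTL intervals, gene sets and a DEG table.

Every planted site belongs to exactly one class: breed-specific (A or B),
shared, `novel` (absent from the known database) or one of seven artifact
classes, each of which violates exactly one rule of the confidence cascade
so the intended removal stage is unambiguous.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation import Gene, GenomeAnnotation, Transcript
from .breeds import BreedPanel
from .context import build_masks, homopolymer_run
from .intervals import MaskSet
from .reference import Reference, revcomp
from .vcfio import (
    GenotypeCall,
    KnownVariantDB,
    VariantKey,
    VariantRecord,
    write_vcf,
)


class ConfigurationError(ValueError):
    pass


ARTIFACT_CLASSES = (
    "low_depth",
    "low_support",
    "multiallelic",
    "high_hrun",
    "in_ssr",
    "in_junction_flank",
    "in_bidirectional",
)

# cascade stage at which each planted class must be removed
CLASS_STAGE: Dict[str, str] = {
    "multiallelic": "biallelic_snp",
    "low_depth": "hard_filter",
    "high_hrun": "hard_filter",
    "low_support": "alt_support",
    "in_ssr": "mask",
    "in_junction_flank": "mask",
    "in_bidirectional": "mask",
    "novel": "known",
}

GOOD_CLASSES = ("specific_A", "specific_B", "shared")

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationConfig:
    """Study-design knobs of the synthetic cohort.

    Defaults mirror the emulated study: two breeds of four animals each and
    a known-SNP database covering ~94% of the sites that reach the
    database-lookup stage (the number of `novel` sites is derived from
    ``known_db_fraction`` unless ``n_novel`` is given explicitly).
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 100_000
    n_genes: int = 16
    n_breed_a_samples: int = 4
    n_breed_b_samples: int = 4
    n_specific_a: int = 50
    n_specific_b: int = 50
    n_shared: int = 100
    n_artifacts_per_class: int = 10
    n_novel: Optional[int] = None
    known_db_fraction: float = 0.94
    up_downstream_bp: int = 5000
    breed_a_name: str = "breedA"
    breed_b_name: str = "breedB"
    # coding-consequence plants (drawn from the shared-site budget)
    n_missense: int = 10
    n_synonymous: int = 5
    n_stop_gained: int = 3
    n_deg_overlap: int = 7

    def __post_init__(self) -> None:
        counts = (
            self.n_chromosomes, self.n_genes, self.n_specific_a, self.n_specific_b,
            self.n_shared, self.n_artifacts_per_class,
            self.n_breed_a_samples, self.n_breed_b_samples,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be >= 0")
        if self.chrom_length_bp <= 0:
            raise ConfigurationError("chrom_length_bp must be positive")
        if not (0.0 < self.known_db_fraction <= 1.0):
            raise ConfigurationError("known_db_fraction must be in (0, 1]")
        if self.n_shared < self.n_missense + self.n_synonymous + self.n_stop_gained:
            raise ConfigurationError("coding plants exceed the shared-site budget")

    @property
    def resolved_n_novel(self) -> int:
        if self.n_novel is not None:
            return self.n_novel
        n_good = self.n_specific_a + self.n_specific_b + self.n_shared
        f = self.known_db_fraction
        return int(round(n_good * (1.0 - f) / f))

    @property
    def sample_ids_a(self) -> List[str]:
        return [f"{self.breed_a_name}_{i + 1}" for i in range(self.n_breed_a_samples)]

    @property
    def sample_ids_b(self) -> List[str]:
        return [f"{self.breed_b_name}_{i + 1}" for i in range(self.n_breed_b_samples)]

    @property
    def samples(self) -> List[str]:
        return self.sample_ids_a + self.sample_ids_b


@dataclass
class TruthRow:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str  # comma-joined for multiallelic
    planted_class: str
    expected_term: str  # planted coding consequence, or ""
    genotypes: Dict[str, str]  # sample -> GT string

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


class TruthTable:
    """Ledger of every planted site and its intended downstream fate."""

    def __init__(self, rows: Sequence[TruthRow], samples: Sequence[str]):
        self.rows = sorted(rows, key=lambda r: (r.chrom, r.pos))
        self.samples = list(samples)
        keys = [r.key for r in self.rows]
        if len(set(keys)) != len(keys):
            raise ConfigurationError("duplicate planted site in truth table")

    def __len__(self) -> int:
        return len(self.rows)

    def of_class(self, planted_class: str) -> List[TruthRow]:
        return [r for r in self.rows if r.planted_class == planted_class]

    def keys_of_class(self, planted_class: str) -> Set[VariantKey]:
        return {r.key for r in self.of_class(planted_class)}

    @property
    def surviving_keys(self) -> Set[VariantKey]:
        """Sites the full cascade must keep (breed-specific and shared)."""
        return {r.key for r in self.rows if r.planted_class in GOOD_CLASSES}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "planted_class": r.planted_class,
                "expected_term": r.expected_term,
                **{s: r.genotypes.get(s, "./.") for s in self.samples},
            }
            for r in self.rows
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        fixed = ["chrom", "pos", "ref", "alt", "planted_class", "expected_term"]
        samples = [c for c in df.columns if c not in fixed]
        rows = [
            TruthRow(
                chrom=str(r["chrom"]), pos=int(r["pos"]), ref=str(r["ref"]),
                alt=str(r["alt"]), planted_class=str(r["planted_class"]),
                expected_term=str(r["expected_term"]),
                genotypes={s: str(r[s]) for s in samples},
            )
            for _, r in df.iterrows()
        ]
        return cls(rows, samples)


class SimulatedReference(Reference):
    """Reference with a record of deliberately planted repeat context."""

    def __init__(self, seqs):
        super().__init__(seqs)
        self.planted_ssrs: List[Tuple[str, int, int, str, int]] = []  # chrom,s,e,motif,copies
        self.planted_homopolymers: List[Tuple[str, int, int, str]] = []  # chrom,s,e,base
        self.reserved_end: Dict[str, int] = {}


# ---------------------------------------------------------------------------
# stage 1: reference

def generate_reference(config: SimulationConfig) -> SimulatedReference:
    """Random genome with recorded homopolymer runs and SSR tracts.

    Repeats are planted in a reserved head region of each chromosome so the
    later gene layout cannot collide with them.
    """
    if config.chrom_length_bp < 10_000:
        raise ConfigurationError("chrom_length_bp must be >= 10,000")
    rng = np.random.default_rng([config.seed, 0])
    L = config.chrom_length_bp
    seqs = {}
    for i in range(config.n_chromosomes):
        chrom = f"chr{i + 1}"
        seqs[chrom] = "".join(np.array(list(_BASES))[rng.integers(0, 4, size=L)])
    ref = SimulatedReference(seqs)

    n_hruns = math.ceil((config.n_artifacts_per_class + 2) / max(config.n_chromosomes, 1))
    ssr_plan = [("AT", 8), ("CAG", 6), ("A", 12), ("GATA", 5), ("AT", 9)]
    for chrom in ref.chroms:
        cursor = 200

        def plant(tract: str) -> Tuple[int, int]:
            nonlocal cursor
            s, e = cursor, cursor + len(tract)
            ref.write(chrom, s, tract)
            # break the repeat at both boundaries so the tract length is exact
            for bpos, clash in ((s - 1, tract[-1]), (e, _boundary_clash(tract, e - s))):
                choices = [b for b in _BASES if b != clash and b != ref.base(chrom, bpos)]
                pick = choices[rng.integers(0, len(choices))]
                ref.write(chrom, bpos, pick)
            cursor = e + 25
            return s, e

        for _ in range(n_hruns):
            base = _BASES[rng.integers(0, 4)]
            run_len = int(rng.integers(6, 9))
            s, e = plant(base * run_len)
            ref.planted_homopolymers.append((chrom, s, e, base))
        for motif, copies in ssr_plan:
            s, e = plant(motif * copies)
            ref.planted_ssrs.append((chrom, s, e, motif, copies))
        ref.reserved_end[chrom] = cursor
    return ref


def _boundary_clash(tract: str, offset: int) -> str:
    """Base that would extend the tract's periodicity at ``offset``."""
    # period = motif length of the tract; infer from the smallest repeat unit
    for m in range(1, len(tract) + 1):
        if len(tract) % m == 0 and tract == tract[:m] * (len(tract) // m):
            return tract[offset % m]
    return tract[0]


# ---------------------------------------------------------------------------
# stage 2: annotation (embeds transcript sequence into the reference)

def generate_annotation(
    reference: SimulatedReference, config: SimulationConfig
) -> GenomeAnnotation:
    """Lay out genes and write their transcript sequence into the reference.

    Per chromosome the first gene hosts a nested antisense gene inside its
    (enlarged) first intron, providing the opposite-strand overlap the
    bidirectional-transcription mask needs. All CDSs are valid: ATG start,
    no internal stop, stop codon at the end.
    """
    rng = np.random.default_rng([config.seed, 1])
    L = config.chrom_length_bp
    genes: List[Gene] = []
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1

    gid = [0]

    def next_ids() -> Tuple[str, str]:
        gid[0] += 1
        return f"GENE{gid[0]:04d}", f"TX{gid[0]:04d}"

    for ci, chrom in enumerate(reference.chroms):
        cursor = reference.reserved_end.get(chrom, 200) + 400
        for g_i in range(per_chrom[ci]):
            if cursor > L - 6000:
                raise ConfigurationError(
                    f"genome too small for {per_chrom[ci]} genes on {chrom}"
                )
            host = g_i == 0
            strand = "+" if g_i % 2 == 0 else "-"
            gene = _build_gene(reference, chrom, cursor, strand, rng, next_ids, host)
            genes.append(gene)
            if host:
                intron = gene.transcripts[0].introns[0]
                nested = _build_gene(
                    reference, chrom, intron[0] + 150,
                    "-" if strand == "+" else "+", rng, next_ids, host=False,
                    small=True,
                )
                if nested.end > intron[1] - 20:
                    raise ConfigurationError("nested gene exceeds host intron")
                genes.append(nested)
            cursor = gene.end + int(rng.integers(400, 1200))
            if cursor > L - 3000 and g_i + 1 < per_chrom[ci]:
                raise ConfigurationError(
                    f"genome too small for {per_chrom[ci]} genes on {chrom}"
                )
    return GenomeAnnotation(genes)


def _build_gene(
    reference: SimulatedReference,
    chrom: str,
    start: int,
    strand: str,
    rng: np.random.Generator,
    next_ids,
    host: bool,
    small: bool = False,
) -> Gene:
    gene_id, tx_id = next_ids()
    if small:
        n_exons = 2
        utr5, utr3 = int(rng.integers(15, 26)), int(rng.integers(15, 26))
        n_codons = int(rng.integers(25, 41))
        introns = [int(rng.integers(60, 101))]
        min_exon = 15
    else:
        n_exons = int(rng.integers(2, 6))
        utr5, utr3 = int(rng.integers(20, 61)), int(rng.integers(20, 61))
        n_codons = int(rng.integers(60, 151))
        introns = [int(rng.integers(80, 401)) for _ in range(n_exons - 1)]
        if host:
            introns[0] = 1200
        min_exon = 30
    cds_len = 3 * n_codons  # start codon included, stop codon separate
    tx_len = utr5 + cds_len + 3 + utr3

    # split the transcript into n_exons parts of >= min_exon bases
    lens = np.full(n_exons, min_exon)
    extra = tx_len - min_exon * n_exons
    if extra < 0:
        raise ConfigurationError("transcript too short for exon count")
    lens = lens + rng.multinomial(extra, [1.0 / n_exons] * n_exons)

    exons: List[Tuple[int, int]] = []
    pos = start
    for k, elen in enumerate(lens):
        exons.append((pos, pos + int(elen)))
        pos += int(elen)
        if k < n_exons - 1:
            pos += introns[k]

    # build the mRNA: UTR5 + ATG + non-stop codons + stop + UTR3
    def rand_seq(n: int) -> str:
        return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=n)])

    codons = []
    while len(codons) < n_codons - 1:
        c = rand_seq(3)
        if c not in _STOPS:
            codons.append(c)
    stop = _STOPS[rng.integers(0, 3)]
    mrna = rand_seq(utr5) + "ATG" + "".join(codons) + stop + rand_seq(utr3)
    assert len(mrna) == tx_len

    # write the mRNA into the genome along the exons (transcript order)
    genomic_positions: List[int] = []
    ordered = exons if strand == "+" else exons[::-1]
    for s, e in ordered:
        rng_pos = range(s, e) if strand == "+" else range(e - 1, s - 1, -1)
        genomic_positions.extend(rng_pos)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for t, gpos in enumerate(genomic_positions):
        base = mrna[t] if strand == "+" else comp[mrna[t]]
        reference.write(chrom, gpos, base)

    def tx_interval_to_genomic(a: int, b: int) -> List[Tuple[int, int]]:
        positions = sorted(genomic_positions[a:b])
        out: List[Tuple[int, int]] = []
        run_s = prev = positions[0]
        for p in positions[1:]:
            if p == prev + 1:
                prev = p
            else:
                out.append((run_s, prev + 1))
                run_s = prev = p
        out.append((run_s, prev + 1))
        return out

    cds_iv = tx_interval_to_genomic(utr5, utr5 + cds_len)
    stop_iv = tx_interval_to_genomic(utr5 + cds_len, utr5 + cds_len + 3)
    tx = Transcript(tx_id, gene_id, chrom, strand, exons, cds_iv, stop_iv)
    return Gene(gene_id, chrom, strand, [tx], gene_name=gene_id.replace("GENE", "SYN"))


# ---------------------------------------------------------------------------
# stage 3: cohort

@dataclass
class CohortData:
    """Everything the simulator produced, in memory."""

    config: SimulationConfig
    reference: SimulatedReference
    annotation: GenomeAnnotation
    masks: Dict[str, MaskSet]
    records: List[VariantRecord]  # merged, all samples
    samples: List[str]
    panel_a: BreedPanel
    panel_b: BreedPanel
    truth: TruthTable
    known_db: KnownVariantDB
    qtls: pd.DataFrame
    gene_sets: pd.DataFrame
    deg_table: pd.DataFrame
    deg_overlap_genes: List[str]

    @property
    def specific_gene_ids(self) -> List[str]:
        """Genes whose body contains >= 1 planted breed-specific site."""
        out = set()
        for row in self.truth.rows:
            if row.planted_class not in ("specific_A", "specific_B"):
                continue
            for gene in self.annotation.by_chrom.get(row.chrom, []):
                if gene.contains(row.pos - 1):
                    out.add(gene.gene_id)
        return sorted(out)


def simulate_cohort(
    reference: SimulatedReference,
    annotation: GenomeAnnotation,
    config: SimulationConfig,
) -> CohortData:
    rng = np.random.default_rng([config.seed, 2])
    masks = build_masks(reference, annotation)
    occupied: Set[Tuple[str, int]] = set()

    def free(chrom: str, pos0: int) -> bool:
        return all((chrom, p) not in occupied for p in range(pos0 - 3, pos0 + 4))

    def take(chrom: str, pos0: int) -> None:
        occupied.add((chrom, pos0))

    def in_any_mask(chrom: str, pos0: int) -> bool:
        return any(m.contains(chrom, pos0) for m in masks.values())

    def pick_alt(chrom: str, pos0: int, ref_base: str) -> Optional[str]:
        """Transition-biased alt choice subject to the homopolymer cut-off."""
        options = [_TRANSITION[ref_base]] if rng.random() < 0.75 else []
        others = [b for b in _BASES if b not in (ref_base, _TRANSITION[ref_base])]
        options += list(np.array(others)[rng.permutation(len(others))])
        if _TRANSITION[ref_base] not in options:
            options.append(_TRANSITION[ref_base])
        for alt in options:
            if homopolymer_run(reference, chrom, pos0 + 1, str(alt)) <= 5:
                return str(alt)
        return None

    L = config.chrom_length_bp
    chroms = list(reference.chroms)

    def pick_clean_site() -> Tuple[str, int, str, str]:
        for _ in range(100_000):
            chrom = chroms[rng.integers(0, len(chroms))]
            pos0 = int(rng.integers(50, L - 50))
            if not free(chrom, pos0) or in_any_mask(chrom, pos0):
                continue
            ref_base = reference.base(chrom, pos0)
            alt = pick_alt(chrom, pos0, ref_base)
            if alt is None:
                continue
            take(chrom, pos0)
            return chrom, pos0, ref_base, alt
        raise ConfigurationError("could not place a clean site; genome too crowded")

    def pick_site_in(chrom: str, lo: int, hi: int, require_mask: Optional[str] = None,
                     forbid_masks: Sequence[str] = ()) -> Optional[Tuple[str, int, str, str]]:
        for _ in range(2000):
            pos0 = int(rng.integers(lo, hi))
            if not free(chrom, pos0):
                continue
            if require_mask is not None and not masks[require_mask].contains(chrom, pos0):
                continue
            if require_mask is None and in_any_mask(chrom, pos0):
                continue
            if any(masks[m].contains(chrom, pos0) for m in forbid_masks):
                continue
            ref_base = reference.base(chrom, pos0)
            alt = pick_alt(chrom, pos0, ref_base)
            if alt is None:
                continue
            take(chrom, pos0)
            return chrom, pos0, ref_base, alt
        return None

    # ---- planted coding consequences (shared-site budget) -----------------
    coding_sites: List[Tuple[str, int, str, str, str]] = []  # +expected term
    eligible_genes = [
        g for g in sorted(annotation.genes, key=lambda g: g.gene_id)
        if not masks["bidirectional"].contains(g.chrom, g.start)
        and not masks["bidirectional"].contains(g.chrom, g.end - 1)
    ]
    for term, count in (
        ("missense", config.n_missense),
        ("synonymous", config.n_synonymous),
        ("stop_gained", config.n_stop_gained),
    ):
        placed = 0
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 20_000:
                raise ConfigurationError(f"could not plant {count} {term} sites")
            gene = eligible_genes[rng.integers(0, len(eligible_genes))]
            tx = gene.transcripts[0]
            n_codons = tx.cds_length // 3
            ci = int(rng.integers(2, n_codons - 1))
            cp = int(rng.integers(0, 3))
            off = 3 * ci + cp
            pos0 = tx.spliced_to_genomic(off, tx.cds)
            if not free(gene.chrom, pos0) or in_any_mask(gene.chrom, pos0):
                continue
            cds_seq = tx.coding_sequence(reference)
            ref_codon = cds_seq[3 * ci: 3 * ci + 3]
            ref_aa = str(Seq(ref_codon).translate())
            ref_t = ref_codon[cp]
            found = None
            for alt_t in np.array([b for b in _BASES if b != ref_t])[rng.permutation(3)]:
                alt_codon = ref_codon[:cp] + alt_t + ref_codon[cp + 1:]
                alt_aa = str(Seq(alt_codon).translate())
                ok = (
                    (term == "missense" and alt_aa not in (ref_aa, "*"))
                    or (term == "synonymous" and alt_aa == ref_aa)
                    or (term == "stop_gained" and alt_aa == "*")
                )
                if not ok:
                    continue
                alt_g = alt_t if tx.strand == "+" else {"A": "T", "C": "G", "G": "C", "T": "A"}[alt_t]
                if homopolymer_run(reference, gene.chrom, pos0 + 1, alt_g) <= 5:
                    found = alt_g
                    break
            if found is None:
                continue
            take(gene.chrom, pos0)
            coding_sites.append(
                (gene.chrom, pos0, reference.base(gene.chrom, pos0), found, term)
            )
            placed += 1

    # ---- directed breed-specific sites inside genes (DEG-overlap anchor) --
    n_directed = min(config.n_deg_overlap, config.n_specific_a + config.n_specific_b)
    directed: List[Tuple[str, int, str, str, str]] = []  # +gene_id
    gene_order = [eligible_genes[i] for i in rng.permutation(len(eligible_genes))]
    for gene in gene_order:
        if len(directed) >= n_directed:
            break
        hit = pick_site_in(gene.chrom, gene.start, gene.end)
        if hit is not None:
            directed.append((*hit, gene.gene_id))
    if len(directed) < n_directed:
        raise ConfigurationError("could not anchor enough genic breed-specific sites")

    # ---- assemble the class -> site list --------------------------------
    n_novel = config.resolved_n_novel
    site_specs: List[Tuple[str, str, int, str, str, str]] = []  # class, chrom, pos0, ref, alt, term

    for i, (chrom, pos0, ref_b, alt, gene_id) in enumerate(directed):
        cls = "specific_A" if i % 2 == 0 else "specific_B"
        site_specs.append((cls, chrom, pos0, ref_b, alt, ""))
    n_a_left = config.n_specific_a - sum(1 for s in site_specs if s[0] == "specific_A")
    n_b_left = config.n_specific_b - sum(1 for s in site_specs if s[0] == "specific_B")
    for _ in range(n_a_left):
        site_specs.append(("specific_A", *pick_clean_site(), ""))
    for _ in range(n_b_left):
        site_specs.append(("specific_B", *pick_clean_site(), ""))
    for chrom, pos0, ref_b, alt, term in coding_sites:
        site_specs.append(("shared", chrom, pos0, ref_b, alt, term))
    for _ in range(config.n_shared - len(coding_sites)):
        site_specs.append(("shared", *pick_clean_site(), ""))
    for _ in range(n_novel):
        site_specs.append(("novel", *pick_clean_site(), ""))
    for cls in ("low_depth", "low_support", "multiallelic"):
        for _ in range(config.n_artifacts_per_class):
            site_specs.append((cls, *pick_clean_site(), ""))

    # high_hrun: the base just after a planted run, alt extends the run
    hrun_sites = 0
    for chrom, s, e, base in reference.planted_homopolymers:
        if hrun_sites >= config.n_artifacts_per_class:
            break
        pos0 = e
        if not free(chrom, pos0) or in_any_mask(chrom, pos0):
            continue
        ref_b = reference.base(chrom, pos0)
        if ref_b == base:
            continue
        assert homopolymer_run(reference, chrom, pos0 + 1, base) > 5
        take(chrom, pos0)
        site_specs.append(("high_hrun", chrom, pos0, ref_b, base, ""))
        hrun_sites += 1
    if hrun_sites < config.n_artifacts_per_class:
        raise ConfigurationError("not enough planted homopolymer runs")

    # mask-violating sites, each inside exactly its own mask
    mask_targets = (
        ("in_ssr", "ssr", ("junction", "bidirectional")),
        ("in_junction_flank", "junction", ("ssr", "bidirectional")),
        ("in_bidirectional", "bidirectional", ("ssr", "junction")),
    )
    for cls, mask_name, forbid in mask_targets:
        placed = 0
        intervals = list(masks[mask_name])
        order = rng.permutation(len(intervals))
        for idx in list(order) * 40:
            if placed >= config.n_artifacts_per_class:
                break
            iv = intervals[idx]
            hit = pick_site_in(iv.chrom, iv.start, iv.end, require_mask=mask_name,
                               forbid_masks=forbid)
            if hit is not None:
                site_specs.append((cls, *hit, ""))
                placed += 1
        if placed < config.n_artifacts_per_class:
            raise ConfigurationError(f"could not place {cls} sites")

    # ---- genotypes, INFO and records -------------------------------------
    samples = config.samples
    panel_a = BreedPanel(config.breed_a_name, tuple(config.sample_ids_a))
    panel_b = BreedPanel(config.breed_b_name, tuple(config.sample_ids_b))
    records: List[VariantRecord] = []
    truth_rows: List[TruthRow] = []

    def passing_info() -> Dict[str, float]:
        return {
            "DP": int(rng.integers(15, 61)),
            "QD": round(float(rng.uniform(5, 30)), 1),
            "MQ": round(float(rng.uniform(50, 60)), 1),
            "MQRankSum": round(float(rng.uniform(-2, 2)), 2),
            "ReadPosRankSum": round(float(rng.uniform(-2, 2)), 2),
        }

    def carrier_call(sample: str, low_support: bool = False) -> GenotypeCall:
        if low_support:
            dp = int(rng.integers(10, 31))
            return GenotypeCall(sample, (0, 1), (dp - 2, 2), dp)
        if rng.random() < 0.7:
            dp = int(rng.integers(12, 41))
            alt_reads = max(3, int(round(dp * rng.uniform(0.35, 0.65))))
            alt_reads = min(alt_reads, dp - 1)
            return GenotypeCall(sample, (0, 1), (dp - alt_reads, alt_reads), dp)
        dp = int(rng.integers(8, 31))
        return GenotypeCall(sample, (1, 1), (0, dp), dp)

    def ref_call(sample: str) -> GenotypeCall:
        if rng.random() < 0.05:
            return GenotypeCall(sample, (None, None), None, 0)
        dp = int(rng.integers(8, 31))
        return GenotypeCall(sample, (0, 0), (dp, 0), dp)

    def choose_carriers(ids: Sequence[str], at_least: int = 2) -> List[str]:
        n = len(ids)
        c = at_least + int(rng.binomial(max(n - at_least, 0), 0.4))
        picked = rng.permutation(n)[:c]
        return [ids[i] for i in picked]

    for cls, chrom, pos0, ref_b, alt, term in site_specs:
        info = passing_info()
        alts = [alt]
        calls: Dict[str, GenotypeCall] = {}
        if cls == "specific_A":
            for s in choose_carriers(config.sample_ids_a):
                calls[s] = carrier_call(s)
            for s in samples:
                calls.setdefault(s, ref_call(s))
        elif cls == "specific_B":
            for s in choose_carriers(config.sample_ids_b):
                calls[s] = carrier_call(s)
            for s in samples:
                calls.setdefault(s, ref_call(s))
        elif cls == "low_support":
            for s in choose_carriers(config.sample_ids_a) + choose_carriers(config.sample_ids_b):
                calls[s] = carrier_call(s, low_support=True)
            for s in samples:
                calls.setdefault(s, ref_call(s))
        elif cls == "multiallelic":
            others = [b for b in _BASES if b not in (ref_b, alt)]
            alt2 = others[rng.integers(0, len(others))]
            alts = [alt, alt2]
            carriers = choose_carriers(samples, at_least=3)
            for j, s in enumerate(carriers):
                gt = [(0, 1), (1, 2), (0, 2)][j % 3]
                dp = int(rng.integers(15, 40))
                ad = [0, 0, 0]
                for a in gt:
                    ad[a] += dp // 2
                ad[0] += dp - sum(ad)
                calls[s] = GenotypeCall(s, gt, tuple(ad), dp)
            for s in samples:
                calls.setdefault(s, GenotypeCall(s, (0, 0), (int(rng.integers(8, 31)), 0, 0), None))
        else:  # shared, novel, low_depth, high_hrun, mask classes
            for s in choose_carriers(config.sample_ids_a) + choose_carriers(config.sample_ids_b):
                calls[s] = carrier_call(s)
            for s in samples:
                calls.setdefault(s, ref_call(s))
        if cls == "low_depth":
            info["DP"] = 9

        rec = VariantRecord(
            chrom=chrom, pos=pos0 + 1, ref=ref_b, alt=alts,
            qual=round(float(rng.uniform(50, 2000)), 1), info=info,
            genotypes=[calls[s] for s in samples],
        )
        records.append(rec)
        truth_rows.append(
            TruthRow(
                chrom=chrom, pos=pos0 + 1, ref=ref_b, alt=",".join(alts),
                planted_class=cls, expected_term=term,
                genotypes={s: calls[s].gt_string for s in samples},
            )
        )

    records.sort(key=lambda r: (r.chrom, r.pos))
    truth = TruthTable(truth_rows, samples)

    # ---- known-SNP database ----------------------------------------------
    db = KnownVariantDB()
    rs = 100_000_001
    for row in truth.rows:
        if row.planted_class == "novel" or row.planted_class == "multiallelic":
            continue
        db.add(row.chrom, row.pos, row.ref, row.alt, f"rs{rs}")
        rs += 1
    for _ in range(40):  # decoy entries at unplanted positions
        chrom, pos0, ref_b, alt = pick_clean_site()
        db.add(chrom, pos0 + 1, ref_b, alt, f"rs{rs}")
        rs += 1

    # ---- QTL intervals -----------------------------------------------------
    traits = (
        "Tail fat deposition",
        "Total fat area",
        "Carcass fat percentage",
        "Subcutaneous fat thickness",
    )
    qtl_rows = []
    q = 1
    for chrom in chroms:
        for trait in traits:
            for _ in range(int(rng.integers(1, 3))):
                width = int(rng.integers(2000, 8001))
                start0 = int(rng.integers(0, L - width))
                qtl_rows.append((trait, chrom, start0 + 1, start0 + width, f"QTL{q:04d}"))
                q += 1
    anchor = next(r for r in truth.rows if r.planted_class == "specific_A")
    qtl_rows.append(
        ("Tail fat deposition", anchor.chrom, max(1, anchor.pos - 1500),
         anchor.pos + 1500, f"QTL{q:04d}")
    )
    qtls = pd.DataFrame(
        qtl_rows, columns=["trait_name", "chrom", "start_1based", "end_1based", "qtl_id"]
    )

    # ---- gene sets and DEG table ------------------------------------------
    all_genes = sorted(g.gene_id for g in annotation.genes)
    specific_genes = set()
    for row in truth.rows:
        if row.planted_class in ("specific_A", "specific_B"):
            for gene in annotation.by_chrom.get(row.chrom, []):
                if gene.contains(row.pos - 1):
                    specific_genes.add(gene.gene_id)
    specific_genes_sorted = sorted(specific_genes)
    non_specific = [g for g in all_genes if g not in specific_genes]

    def sample_genes(pool: List[str], k: int) -> List[str]:
        k = min(k, len(pool))
        idx = rng.permutation(len(pool))[:k]
        return sorted(pool[i] for i in idx)

    gene_set_rows = []
    term_defs = [
        ("GO:0006629", "lipid metabolic process",
         sample_genes(specific_genes_sorted, 12) + sample_genes(non_specific, 2)),
        ("GO:0008152", "metabolic process", sample_genes(all_genes, max(4, len(all_genes) // 3))),
        ("GO:0007155", "cell adhesion", sample_genes(non_specific, 5)),
        ("KEGG:03320", "PPAR signaling pathway", sample_genes(specific_genes_sorted, 5)),
    ]
    for tid, tname, members in term_defs:
        for g in sorted(set(members)):
            gene_set_rows.append((tid, tname, g))
    gene_sets = pd.DataFrame(gene_set_rows, columns=["term_id", "term_name", "gene_id"])

    overlap_genes = specific_genes_sorted[: config.n_deg_overlap]
    de_non_snp = sample_genes(non_specific, 8)
    flat = sample_genes([g for g in all_genes if g not in set(overlap_genes) | set(de_non_snp)], 12)
    deg_rows = []
    for g in overlap_genes + de_non_snp:
        deg_rows.append(
            (g, round(float(rng.uniform(1.0, 3.0)) * (1 if rng.random() < 0.5 else -1), 3),
             round(float(rng.uniform(1e-4, 0.04)), 5))
        )
    for g in flat:
        deg_rows.append(
            (g, round(float(rng.uniform(-0.5, 0.5)), 3), round(float(rng.uniform(0.2, 0.95)), 4))
        )
    deg_table = pd.DataFrame(deg_rows, columns=["gene_id", "log2fc", "fdr"]).sort_values(
        "gene_id"
    ).reset_index(drop=True)

    return CohortData(
        config=config, reference=reference, annotation=annotation, masks=masks,
        records=records, samples=samples, panel_a=panel_a, panel_b=panel_b,
        truth=truth, known_db=db, qtls=qtls, gene_sets=gene_sets,
        deg_table=deg_table, deg_overlap_genes=list(overlap_genes),
    )


def generate_cohort(config: SimulationConfig, out_dir=None) -> CohortData:
    """Run all three simulator stages; optionally write every artifact."""
    reference = generate_reference(config)
    annotation = generate_annotation(reference, config)
    cohort = simulate_cohort(reference, annotation, config)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: CohortData, out_dir) -> Dict[str, Path]:
    """Write the full artifact set; returns the path of each output."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "samples").mkdir(exist_ok=True)
    contigs = cohort.reference.chrom_lengths
    paths: Dict[str, Path] = {}

    paths["reference"] = out / "reference.fa"
    cohort.reference.write_fasta(paths["reference"])
    paths["gtf"] = out / "genes.gtf"
    cohort.annotation.write_gtf(paths["gtf"])
    paths["vcf"] = out / "cohort.vcf"
    write_vcf(paths["vcf"], cohort.records, cohort.samples, contigs)
    for sample in cohort.samples:
        sp = out / "samples" / f"{sample}.vcf"
        rows = []
        for rec in cohort.records:
            call = rec.call_for(sample)
            if call is not None and call.is_variant:
                single = rec.copy()
                single.genotypes = [call]
                rows.append(single)
        write_vcf(sp, rows, [sample], contigs)
        paths[f"sample:{sample}"] = sp
    paths["known"] = out / "known_snps.vcf"
    cohort.known_db.write_vcf(paths["known"], contigs)
    paths["qtl"] = out / "qtl.tsv"
    cohort.qtls.to_csv(paths["qtl"], sep="\t", index=False)
    paths["gene_sets"] = out / "gene_sets.tsv"
    cohort.gene_sets.to_csv(paths["gene_sets"], sep="\t", index=False)
    paths["deg"] = out / "deg.tsv"
    cohort.deg_table.to_csv(paths["deg"], sep="\t", index=False)
    paths["truth"] = out / "truth.tsv"
    cohort.truth.write_tsv(paths["truth"])
    paths["panel"] = out / "panel.tsv"
    panel_rows = [(s, cohort.panel_a.breed_name) for s in cohort.panel_a.sample_ids]
    panel_rows += [(s, cohort.panel_b.breed_name) for s in cohort.panel_b.sample_ids]
    pd.DataFrame(panel_rows, columns=["sample_id", "breed"]).to_csv(
        paths["panel"], sep="\t", index=False
    )
    return paths
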