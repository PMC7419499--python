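"""Breed-level comparison of filtered SNPs and cohort statistics.

Definitions:

* common-SNP (per breed): called with the variant allele in at least two
  animals of the breed.
* breed-specific SNP: a common-SNP of one breed at which every genotyped
  animal of the other breed is homozygous for the non-focal allele
  (operationally hom-ref for focal-alt sites); i.e. the SNP segregates in
  one breed only. Missing genotypes do not veto specificity unless strict
  mode is requested; sites absent from the other breed's calls count as
  homozygous reference.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .vcfio import VariantKey, VariantRecord

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class ConfigurationError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class BreedPanel:
    """A named breed and its ordered member sample identifiers."""

    breed_name: str
    sample_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ConfigurationError(f"duplicate sample ids in panel {self.breed_name}")

    def __len__(self) -> int:
        return len(self.sample_ids)


def load_panels(path) -> List[BreedPanel]:
    """Read a sidecar panel TSV with columns sample_id, breed."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "breed"} <= set(df.columns):
        raise ConfigurationError("panel TSV needs columns sample_id, breed")
    return [
        BreedPanel(breed, tuple(sub["sample_id"]))
        for breed, sub in df.groupby("breed", sort=True)
    ]


def common_snps(
    records: Iterable[VariantRecord], panel: BreedPanel, min_animals: int = 2
) -> Set[VariantKey]:
    """Sites at which >= min_animals panel members carry the alt allele."""
    if len(panel) == 0:
        raise ConfigurationError("empty breed panel")
    out: Set[VariantKey] = set()
    members = set(panel.sample_ids)
    for rec in records:
        carriers = sum(
            1
            for call in rec.genotypes
            if call.sample_id in members and call.is_variant
        )
        if carriers >= min_animals:
            out.add(rec.key)
    return out


def breed_specific_snps(
    common_a: Set[VariantKey],
    common_b: Set[VariantKey],
    records: Iterable[VariantRecord],
    panel_a: BreedPanel,
    panel_b: BreedPanel,
    require_complete: bool = False,
) -> Tuple[Set[VariantKey], Set[VariantKey]]:
    """Split the per-breed common sets into breed-specific sets.

    A site is specific to breed A iff it is common in A and every genotyped
    breed-B animal is homozygous reference there (and symmetrically for B).
    With ``require_complete`` a missing genotype in the other breed vetoes
    specificity.
    """
    if set(panel_a.sample_ids) & set(panel_b.sample_ids):
        raise ConfigurationError("breed panels overlap")
    by_key: Dict[VariantKey, VariantRecord] = {r.key: r for r in records}

    def other_breed_all_hom_ref(key: VariantKey, other: BreedPanel) -> bool:
        rec = by_key.get(key)
        if rec is None:
            return True  # absent from other breed's calls -> hom-ref
        members = set(other.sample_ids)
        for call in rec.genotypes:
            if call.sample_id not in members:
                continue
            if call.is_missing:
                if require_complete:
                    return False
                continue
            if not call.is_hom_ref:
                return False
        return True

    specific_a = {k for k in common_a if k not in common_b and other_breed_all_hom_ref(k, panel_b)}
    specific_b = {k for k in common_b if k not in common_a and other_breed_all_hom_ref(k, panel_a)}
    return specific_a, specific_b


def ts_tv_ratio(sites: Iterable[VariantKey]) -> float:
    """Transitions (A<->G, C<->T) over transversions for a site set.

    Returns NaN when no transversion (or no site) is present — the undefined
    ratio is signalled, not raised.
    """
    ts = tv = 0
    for _, _, ref, alt in sites:
        if (ref, alt) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return float("nan")
    return ts / tv


def het_hom_ratio(records: Iterable[VariantRecord], sample_id: str) -> float:
    """Heterozygous over homozygous-alt call count for one sample (NaN if
    the sample has no hom-alt call)."""
    het = hom = 0
    for rec in records:
        call = rec.call_for(sample_id)
        if call is None or not call.is_variant:
            continue
        if call.is_het:
            het += 1
        elif call.is_hom_alt:
            hom += 1
    if hom == 0:
        return float("nan")
    return het / hom


def snp_density(
    sites: Iterable[VariantKey],
    chrom_lengths: Mapping[str, int],
    window_bp: int,
) -> pd.DataFrame:
    """SNP counts per non-overlapping window tiling each chromosome."""
    if window_bp <= 0:
        raise ConfigurationError("window_bp must be positive")
    counts: Dict[str, np.ndarray] = {
        chrom: np.zeros(-(-length // window_bp), dtype=int)
        for chrom, length in chrom_lengths.items()
    }
    for chrom, pos, _, _ in sites:
        if chrom not in counts:
            raise ConfigurationError(f"site chromosome {chrom} not in chrom_lengths")
        if pos > chrom_lengths[chrom]:
            raise ConfigurationError(
                f"site {chrom}:{pos} beyond chromosome length {chrom_lengths[chrom]}"
            )
        counts[chrom][(pos - 1) // window_bp] += 1
    rows = []
    for chrom in chrom_lengths:
        for w, c in enumerate(counts[chrom]):
            start = w * window_bp
            rows.append(
                (chrom, start, min(start + window_bp, chrom_lengths[chrom]), int(c))
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


# ---------------------------------------------------------------------------
# Genotype PCA (EIGENSTRAT-style normalization)

@dataclass
class GenotypeMatrix:
    """Samples x sites alternate-allele dosage matrix (NaN = missing)."""

    samples: List[str]
    keys: List[VariantKey]
    dosages: np.ndarray  # (n_samples, n_sites), float, NaN for missing

    @classmethod
    def from_records(
        cls, records: Sequence[VariantRecord], samples: Sequence[str]
    ) -> "GenotypeMatrix":
        keys = [r.key for r in records]
        mat = np.full((len(samples), len(records)), np.nan)
        idx = {s: i for i, s in enumerate(samples)}
        for j, rec in enumerate(records):
            for call in rec.genotypes:
                i = idx.get(call.sample_id)
                if i is None or call.is_missing:
                    continue
                mat[i, j] = sum(1 for a in call.alleles if a is not None and a > 0)
        return cls(list(samples), keys, mat)


@dataclass
class PCAResult:
    samples: List[str]
    coordinates: np.ndarray  # (n_samples, n_components)
    explained: np.ndarray  # eigenvalue fractions, length n_components
    eigenvalues: np.ndarray


def genotype_pca(matrix: GenotypeMatrix, n_components: int = 2) -> PCAResult:
    """Principal components of the genotype matrix, EIGENSTRAT style.

    Missing dosages are imputed to the site mean; each site is centred and
    scaled by sqrt(p(1-p)) with the shrunk allele frequency
    p = (1 + sum g) / (2 + 2n); monomorphic (zero-variance) sites are
    dropped; the top eigenvectors of the sample-sample covariance are the
    sample coordinates.
    """
    g = matrix.dosages.astype(float).copy()
    n, m = g.shape
    if n < 2 or m < 2:
        raise DegenerateInputError("need >= 2 samples and >= 2 sites")
    col_mean = np.nanmean(g, axis=0)
    nan_mask = np.isnan(g)
    g[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    variable = g.std(axis=0) > 0
    if not variable.any():
        raise DegenerateInputError("all sites are monomorphic")
    g = g[:, variable]
    mu = g.mean(axis=0)
    p = (1.0 + g.sum(axis=0)) / (2.0 + 2.0 * n)
    x = (g - mu) / np.sqrt(p * (1.0 - p))
    cov = x @ x.T / x.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    k = min(n_components, len(eigval))
    pos = np.clip(eigval, 0.0, None)
    total = pos.sum()
    explained = pos[:k] / total if total > 0 else np.zeros(k)
    return PCAResult(
        samples=list(matrix.samples),
        coordinates=eigvec[:, :k],
        explained=explained,
        eigenvalues=eigval[:k],
    )
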