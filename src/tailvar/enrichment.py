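"""Over-representation analysis of SNP-bearing genes and DEG intersection.

The test is the one-sided hypergeometric tail P(X >= k) (identical to a
one-sided Fisher exact test) with Benjamini-Hochberg FDR control.
Significance tiers follow the reporting convention of the pipeline:
FDR < 0.05 "significant"; p < 0.05 and FDR < 0.3 "suggestive".
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class EnrichmentInputError(ValueError):
    pass


@dataclass
class GeneSet:
    term_id: str
    term_name: str
    genes: Set[str]

    def __post_init__(self) -> None:
        self.genes = set(self.genes)


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # study genes in the term
    n: int  # study size
    K: int  # term size (within background)
    N: int  # background size
    p_value: float
    fdr: float = float("nan")
    tier: str = "ns"


def load_gene_sets(path) -> List[GeneSet]:
    """Read term -> gene memberships from TSV (term_id, term_name, gene_id)."""
    df = pd.read_csv(path, sep="\t")
    need = {"term_id", "term_name", "gene_id"}
    if not need <= set(df.columns):
        raise EnrichmentInputError(f"gene-set TSV needs columns {sorted(need)}")
    sets = []
    for (tid, tname), sub in df.groupby(["term_id", "term_name"], sort=True):
        sets.append(GeneSet(tid, tname, set(sub["gene_id"])))
    return sets


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise EnrichmentInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrich(
    study_genes: Iterable[str],
    gene_sets: Sequence[GeneSet],
    background_genes: Iterable[str],
) -> List[EnrichmentResult]:
    """One-sided over-representation test of the study genes in each term.

    p = P(X >= k) for X ~ Hypergeometric(N, K, n), where N is the background
    size, K the term size restricted to the background, n the study size and
    k the observed overlap. Computed with the survival function of the exact
    distribution (log-space stable); BH-adjusted across terms.
    """
    study = set(study_genes)
    background = set(background_genes)
    stray = sorted(study - background)
    if stray:
        raise EnrichmentInputError(
            f"study genes absent from background: {', '.join(stray[:5])}"
        )
    n, N = len(study), len(background)
    results: List[EnrichmentResult] = []
    for gs in gene_sets:
        members = gs.genes & background
        K = len(members)
        k = len(members & study)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        results.append(EnrichmentResult(gs.term_id, gs.term_name, k, n, K, N, min(p, 1.0)))
    fdrs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
        if r.fdr < 0.05:
            r.tier = "significant"
        elif r.p_value < 0.05 and r.fdr < 0.3:
            r.tier = "suggestive"
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.term_id, r.term_name, r.k, r.K, r.n, r.N, r.p_value, r.fdr, r.tier)
            for r in results
        ],
        columns=["term_id", "term_name", "k", "K", "n", "N", "p_value", "fdr", "tier"],
    )


def intersect_deg(
    snp_genes: Iterable[str],
    deg_table: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Genes that both carry breed-specific SNPs and are differentially
    expressed (DEG FDR <= threshold), labelled up/down by log2FC sign.

    The DEG table needs columns gene_id, log2fc, fdr; duplicate gene rows
    are rejected.
    """
    need = {"gene_id", "log2fc", "fdr"}
    if not need <= set(deg_table.columns):
        raise EnrichmentInputError(f"DEG table needs columns {sorted(need)}")
    if deg_table["gene_id"].duplicated().any():
        dups = deg_table.loc[deg_table["gene_id"].duplicated(), "gene_id"].tolist()
        raise EnrichmentInputError(f"duplicate gene rows in DEG table: {dups[:5]}")
    snp_genes = set(snp_genes)
    sub = deg_table[
        deg_table["gene_id"].isin(snp_genes) & (deg_table["fdr"] <= fdr_threshold)
    ].copy()
    sub["direction"] = np.where(sub["log2fc"] > 0, "up", "down")
    return sub.sort_values("gene_id").reset_index(drop=True)
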