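"""Consequence annotation, QTL colocalization and gene-set enrichment of
the breed-specific SNPs.

Classifies every surviving SNP against the annotation (most-severe summary
per variant), intersects the breed-specific positions with the fatness QTL
intervals, and tests SNP-bearing genes for gene-set over-representation
(hypergeometric tail, BH FDR) plus DEG intersection.
"""
from tailvar import (
    GeneSet,
    SimulationConfig,
    breed_specific_snps,
    classify,
    common_snps,
    generate_cohort,
    hypergeometric_enrich,
    intersect_deg,
    qtl_fraction,
    run_cascade,
    tabulate,
)
from tailvar.qtl import QTLRecord, colocalize

cohort = generate_cohort(SimulationConfig(seed=1))
survivors = run_cascade(
    cohort.records, cohort.reference, cohort.masks, cohort.known_db
).survivors

summaries = [classify(r, cohort.annotation, cohort.reference)[1] for r in survivors]
table = tabulate(summaries)
print("consequence summary (terms with >= 1 SNP):")
print(table[table["count"] > 0].to_string(index=False))

ca = common_snps(survivors, cohort.panel_a)
cb = common_snps(survivors, cohort.panel_b)
sa, sb = breed_specific_snps(ca, cb, survivors, cohort.panel_a, cohort.panel_b)
qtls = [
    QTLRecord(str(r.qtl_id), r.trait_name, str(r.chrom),
              int(r.start_1based), int(r.end_1based))
    for r in cohort.qtls.itertuples()
]
rep = colocalize(sorted(sa | sb), qtls)
pct, _ = qtl_fraction(sorted(sa | sb), qtls)
print(f"\n{rep.distinct_snps} of {len(sa | sb)} breed-specific SNPs ({pct}%) "
      f"fall in {rep.snp_qtl_pairs} SNP x QTL positions")
for trait, n in rep.per_trait_distinct.items():
    print(f"  {trait:>26}: {n} SNPs")

study_genes = cohort.specific_gene_ids
background = sorted(g.gene_id for g in cohort.annotation.genes)
sets = [GeneSet(t, t, set(sub["gene_id"]))
        for t, sub in cohort.gene_sets.groupby("term_id")]
print(f"\nenrichment of {len(study_genes)} SNP-bearing genes "
      f"(background {len(background)}):")
for r in hypergeometric_enrich(study_genes, sets, background):
    print(f"  {r.term_id:>12}: k={r.k}/{r.K}  p={r.p_value:.4f}  "
          f"fdr={r.fdr:.4f}  [{r.tier}]")

joined = intersect_deg(set(study_genes), cohort.deg_table)
print(f"\n{len(joined)} genes both carry breed-specific SNPs and are "
      "differentially expressed:")
print(joined.to_string(index=False))
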