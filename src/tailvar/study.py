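"""Published summary numbers of the two-breed fat-tail RNA-seq study.

These are the printed per-sample sequencing/alignment statistics and
breed-specific SNP summaries of the study cohort (four fat-tailed
Lori-Bakhtiari and four thin-tailed Zel sheep) that the pipeline was
designed around. They serve as worked-example inputs: the package's
arithmetic (averages, partitions, QTL percentages, known/novel accounting)
must reproduce the printed headline figures from them.
"""
from __future__ import annotations

from typing import Dict, Tuple

# sample -> (raw read pairs, uniquely & concordantly mapped %)
SEQUENCING_SUMMARY: Dict[str, Tuple[int, float]] = {
    "Lori_Bakhtiari_1": (26_282_890, 78.58),
    "Lori_Bakhtiari_2": (20_075_866, 63.75),
    "Lori_Bakhtiari_3": (20_428_424, 61.64),
    "Lori_Bakhtiari_4": (18_061_231, 74.21),
    "Zel_1": (22_292_871, 71.61),
    "Zel_2": (20_164_542, 62.23),
    "Zel_3": (20_532_170, 64.36),
    "Zel_4": (26_926_569, 76.59),
}

# breed-specific SNP counts by consequence type
EFFECT_BY_TYPE: Dict[str, Dict[str, int]] = {
    "Lori_Bakhtiari": {
        "downstream_gene": 1_227,
        "upstream_gene": 144,
        "intergenic": 212,
        "three_prime_utr": 155,
        "five_prime_utr": 13,
        "intron": 310,
        "synonymous": 495,
        "missense": 209,
        "stop_gained": 1,
        "stop_lost": 0,
        "stop_retained": 0,
        "start_lost": 0,
        "other": 8,
    },
    "Zel": {
        "downstream_gene": 3_660,
        "upstream_gene": 581,
        "intergenic": 617,
        "three_prime_utr": 472,
        "five_prime_utr": 52,
        "intron": 1_208,
        "synonymous": 2_776,
        "missense": 1_054,
        "stop_gained": 3,
        "stop_lost": 1,
        "stop_retained": 1,
        "start_lost": 3,
        "other": 42,
    },
}

# breed-specific SNP counts by impact class
EFFECT_BY_IMPACT: Dict[str, Dict[str, int]] = {
    "Lori_Bakhtiari": {"HIGH": 1, "MODERATE": 209, "LOW": 501, "MODIFIER": 2_063},
    "Zel": {"HIGH": 7, "MODERATE": 1_054, "LOW": 2_791, "MODIFIER": 6_618},
}

# headline totals
BREED_SPECIFIC_TOTALS: Dict[str, int] = {"Lori_Bakhtiari": 2_774, "Zel": 10_470}

# breed-specific SNPs inside fatness QTL intervals
QTL_OVERLAP_COUNTS: Dict[str, int] = {"Lori_Bakhtiari": 724, "Zel": 2_905}

# confident SNPs after filtering, and the subset catalogued in the
# reference SNP database
CONFIDENT_SNPS_TOTAL = 120_049
KNOWN_SNPS = 112_344
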