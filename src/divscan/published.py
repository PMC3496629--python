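"""Bundled per-individual SNP summary counts for the 32 turkey individuals.

These are the printed summary statistics of the turkey resequencing study
the pipeline re-implements: for each of the 32 individuals across 11
populations (commercial lines L1-L7, heritage varieties BvSW, Nset and RP,
and the wild South Mexican population SM), the number of homozygous
non-reference SNPs, heterozygous SNPs, heterozygous SNPs restricted to
positions covered 5-10 fold, the number of bases covered 5-10 fold, and the
published heterozygosity per kb.  They serve as worked-example inputs: the
heterozygosity module recomputes het/kb and the per-population means from
the count columns and is checked against the printed values.
"""

from __future__ import annotations

import pandas as pd

WILD_POPULATIONS = frozenset({"SM"})

# sample, population, hom_nonref, het, het_5_10x, bases_5_10x, het_per_kb
_ROWS = [
    ("L1a", "L1", 663_406, 659_351, 369_849, 320_663_179, 1.15),
    ("L1b", "L1", 686_583, 648_928, 385_673, 396_624_720, 0.97),
    ("L1c", "L1", 626_434, 737_472, 403_423, 375_734_398, 1.07),
    ("L2a", "L2", 827_249, 755_318, 504_787, 532_961_711, 0.95),
    ("L2b", "L2", 896_728, 757_226, 514_059, 554_379_839, 0.93),
    ("L2c", "L2", 869_872, 562_653, 311_525, 329_283_144, 0.95),
    ("L3a", "L3", 568_439, 762_252, 519_228, 532_049_588, 0.98),
    ("L3b", "L3", 434_157, 427_393, 567_558, 527_841_728, 0.99),
    ("L3c", "L3", 608_276, 834_241, 164_167, 166_315_925, 1.08),
    ("L4a", "L4", 720_530, 616_567, 440_086, 454_905_713, 0.80),
    ("L4b", "L4", 760_762, 692_079, 385_458, 439_002_235, 0.97),
    ("L4c", "L4", 807_407, 618_335, 403_201, 503_650_627, 0.88),
    ("L5a", "L5", 666_287, 340_436, 160_698, 180_577_454, 0.89),
    ("L5b", "L5", 652_149, 352_682, 165_723, 144_150_087, 1.15),
    ("L5c", "L5", 736_951, 520_850, 251_977, 223_238_275, 1.13),
    ("L6a", "L6", 581_773, 294_736, 109_405, 115_435_304, 0.95),
    ("L6b", "L6", 644_421, 567_275, 330_736, 306_448_666, 1.08),
    ("L6c", "L6", 638_770, 579_232, 341_869, 348_094_277, 0.98),
    ("L7a", "L7", 736_881, 550_299, 300_174, 305_785_110, 0.98),
    ("L7b", "L7", 698_647, 379_941, 185_444, 161_035_610, 1.15),
    ("L7c", "L7", 730_143, 504_513, 275_118, 252_564_184, 1.09),
    ("BvSW1", "BvSW", 1_053_237, 417_544, 241_641, 372_524_318, 0.65),
    ("BvSW2", "BvSW", 1_071_513, 269_338, 103_333, 144_219_590, 0.72),
    ("BvSW3", "BvSW", 1_086_121, 525_262, 299_713, 369_633_525, 0.81),
    ("Nset1", "Nset", 643_308, 79_232, 25_217, 144_546_998, 0.17),
    ("Nset2", "Nset", 667_797, 519_815, 9_929, 4_717_330, 2.10),
    ("Nset3", "Nset", 773_183, 804_627, 454_052, 320_395_210, 1.42),
    ("RP1", "RP", 885_734, 510_427, 154_899, 167_716_001, 0.92),
    ("RP2", "RP", 842_442, 522_599, 276_752, 208_702_070, 1.33),
    ("SM1", "SM", 551_149, 69_199, 11_106, 9_379_558, 1.18),
    ("SM2", "SM", 551_380, 17_275, 2_030, 744_899, 2.73),
    ("SM3", "SM", 551_543, 44_784, 6_921, 6_868_381, 1.01),
]

# published per-population heterozygosity (het/kb)
POPULATION_HET = {
    "L1": 1.07, "L2": 0.94, "L3": 1.01, "L4": 0.88, "L5": 1.06, "L6": 1.00,
    "L7": 1.07, "BvSW": 0.73, "Nset": 1.23, "RP": 1.12, "SM": 1.64,
}

TI_TV_RATIO = 2.45   # published transition/transversion ratio of the SNP set
MEAN_FDR = 0.00002   # published mean heterozygous-call FDR per nucleotide


def individual_snp_table() -> pd.DataFrame:
    """The per-individual summary counts as a DataFrame."""
    return pd.DataFrame(_ROWS, columns=[
        "sample", "population", "hom_nonref", "het",
        "het_5_10x", "bases_5_10x", "het_per_kb_published"])
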