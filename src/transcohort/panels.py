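"""Bundled gene panels and centroid patterns used for sample classification.

The intrinsic panel holds the 45 PAM50 gene symbols usable on the profiling
platform (five of the published 50 -- NUF2, CXXC5, MIA, ORC6L, MYBL2 -- are
absent) grouped into the four canonical expression programs: luminal/ER,
proliferation, basal, and HER2/ERBB2 amplicon.

``resources/pam50_centroids_synthetic.tsv`` is a SYNTHETIC stand-in for the
published numeric subtype centroids: it encodes only the qualitative block
structure of the four intrinsic subtypes (luminal A = luminal-high /
proliferation-low, luminal B = luminal-high / proliferation-high, HER2-
enriched = amplicon-high, basal-like = luminal-low / proliferation-high /
basal-high) on a +/-1 scale.  Rank-based (Spearman) matching makes the
classification depend only on this ordering, not on absolute magnitudes.
"""

from __future__ import annotations

from importlib import resources as _res

import pandas as pd

from .datasets import GeneSet

# canonical expression programs over the 45 usable intrinsic genes
LUMINAL_GENES = (
    "ESR1", "PGR", "FOXA1", "NAT1", "SLC39A6", "MAPT", "BCL2",
    "BAG1", "BLVRA", "MLPH", "GPR160", "TMEM45B", "MDM2",
)
PROLIFERATION_GENES = (
    "ANLN", "BIRC5", "CCNB1", "CCNE1", "CDC20", "CDC6", "CENPF", "CEP55",
    "EXO1", "KIF2C", "MELK", "MKI67", "NDC80", "PTTG1", "RRM2", "TYMS",
    "UBE2C", "UBE2T",
)
BASAL_GENES = (
    "KRT5", "KRT14", "KRT17", "CDH3", "FOXC1", "SFRP1", "EGFR",
    "PHGDH", "ACTR3B",
)
HER2_GENES = ("ERBB2", "GRB7")
OTHER_GENES = ("MYC", "MMP11", "FGFR4")

PAM50_USABLE = LUMINAL_GENES + PROLIFERATION_GENES + BASAL_GENES + HER2_GENES + OTHER_GENES

INTRINSIC_SUBTYPES = ("LumA", "LumB", "ERBB2", "Basal")

# claudin-low recognition genes: epithelial (claudin/E-cadherin) block vs
# mesenchymal/EMT block; synthetic membership stand-in using real symbols
CLAUDIN_EPITHELIAL = ("CLDN3", "CLDN4", "CLDN7", "CDH1", "KRT8", "KRT18", "EPCAM")
CLAUDIN_MESENCHYMAL = ("VIM", "ZEB1", "ZEB2", "SNAI1", "SNAI2", "TWIST1", "MMP14")

# ECM cluster seed lists: ECM1 (immune/protease) and ECM3 (collagen/stromal)
ECM1_SEED = ("CTSS", "GZMK", "MMP7", "MMP9", "SELL", "SPOCK2", "VCAM1")
ECM3_SEED = (
    "SPARC", "BGN", "CDH11", "FN1", "LAMA4", "MMP2",
    "COL1A1", "COL1A2", "COL5A1", "COL5A2", "COL5A3",
    "COL6A1", "COL6A2", "COL6A3",
)


def pam50_panel() -> GeneSet:
    return GeneSet("PAM50_USABLE", "45 intrinsic genes present on platform", frozenset(PAM50_USABLE))


def claudin_low_panel() -> GeneSet:
    return GeneSet(
        "CLAUDIN_LOW",
        "epithelial + mesenchymal genes for claudin-low recognition (synthetic membership)",
        frozenset(CLAUDIN_EPITHELIAL + CLAUDIN_MESENCHYMAL),
    )


def ecm1_seed_set() -> GeneSet:
    return GeneSet("ECM1_SEED", "immune/protease ECM cluster markers", frozenset(ECM1_SEED))


def ecm3_seed_set() -> GeneSet:
    return GeneSet("ECM3_SEED", "collagen/stromal ECM cluster markers", frozenset(ECM3_SEED))


def load_intrinsic_centroids() -> pd.DataFrame:
    """Load the bundled synthetic centroid pattern table (gene x subtype)."""
    with _res.files("transcohort.resources").joinpath(
        "pam50_centroids_synthetic.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def intrinsic_centroid_patterns() -> pd.DataFrame:
    """Build the +/-1 block-pattern centroids (gene x subtype) in memory."""
    rows = {}
    for g in PAM50_USABLE:
        if g in LUMINAL_GENES:
            rows[g] = {"LumA": 1.0, "LumB": 1.0, "ERBB2": -0.5, "Basal": -1.0}
        elif g in PROLIFERATION_GENES:
            rows[g] = {"LumA": -1.0, "LumB": 1.0, "ERBB2": 0.5, "Basal": 1.0}
        elif g in BASAL_GENES:
            rows[g] = {"LumA": -1.0, "LumB": -1.0, "ERBB2": -1.0, "Basal": 1.0}
        elif g in HER2_GENES:
            rows[g] = {"LumA": 0.0, "LumB": 0.0, "ERBB2": 1.0, "Basal": -0.5}
        else:
            rows[g] = {"LumA": 0.0, "LumB": 0.0, "ERBB2": 0.5, "Basal": 0.0}
    return pd.DataFrame.from_dict(rows, orient="index")[list(INTRINSIC_SUBTYPES)]
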