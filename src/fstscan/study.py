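"""Design constants of the 96-bird layer genotyping panel.

The package's defaults emulate a chicken panel of three commercial
egg-layer breeds (seven lines, ten birds each) and fourteen non-commercial
fancy breeds pooled as an out-group, genotyped on three overlapping 600K
arrays.  Structure analysis arranges the birds into six analysis groups:
WL1, WL2&3, RIR1, RIR2, WR and OG.  These tables drive default simulation
configs and the sample/filter bookkeeping checks.
"""

from __future__ import annotations

import pandas as pd

from .fst import ComparisonSpec

#: breed ledger: name, abbreviation, lines, genotyped individuals, egg colour
BREED_TABLE = pd.DataFrame(
    [
        ("White Leghorn", "WL", 3, 30, "White"),
        ("Rhode Island Red", "RIR", 2, 20, "Brown"),
        ("White Rock", "WR", 2, 20, "Brown"),
        ("Asil", "OG/Asil", 1, 2, "Brown"),
        ("Brahma", "OG/Brah", 1, 2, "Brown"),
        ("Cochin", "OG/Coch", 1, 2, "Brown"),
        ("Fayoumi", "OG/Fayo", 1, 2, "White"),
        ("Gallus gallus gallus", "OG/Ggal", 1, 2, "Brown"),
        ("Gallus gallus spadiceus", "OG/Gspa", 1, 2, "Brown"),
        ("Green legged Partridge", "OG/GreP", 1, 2, "White"),
        ("Hungarian White Goedoelloe", "OG/HunW", 1, 2, "Brown"),
        ("Jaerhoens", "OG/Jaer", 1, 2, "White"),
        ("Malay", "OG/Mala", 1, 2, "Brown"),
        ("Marans", "OG/Mara", 1, 2, "Brown"),
        ("Orlov", "OG/Orlo", 1, 2, "White"),
        ("Paduaner", "OG/Padu", 1, 1, "White"),
        ("Transylvanian Naked Neck", "OG/Tran", 1, 1, "Brown"),
    ],
    columns=["breed", "abbreviation", "n_lines", "n_individuals", "egg_color"],
)

#: the six analysis groups and their sample sizes
GROUP_SIZES = {
    "WL1": 10,
    "WL2&3": 20,
    "RIR1": 10,
    "RIR2": 10,
    "WR": 20,
    "OG": 26,
}

COMMERCIAL_GROUPS = ("RIR1", "RIR2", "WR", "WL1", "WL2&3")
WHITE_GROUPS = ("WL1", "WL2&3")
BROWN_GROUPS = ("RIR1", "RIR2", "WR")
OUTGROUP = "OG"

#: SNP filter cascade stage counts for the merged three-array panel
SNPS_INPUT = 1_139_073
SNPS_REMOVED_MISSING = 148_712
SNPS_REMOVED_MAF = 74_202


def total_individuals() -> int:
    """Total genotyped birds, summed over the breed ledger."""
    return int(BREED_TABLE["n_individuals"].sum())


def commercial_vs_outgroup() -> ComparisonSpec:
    """Commercial layers vs out-group: out-group paired with each of the
    five commercial groups (five pairwise F_ST values averaged per SNP)."""
    return ComparisonSpec(
        "LY_vs_OG", tuple((OUTGROUP, g) for g in COMMERCIAL_GROUPS)
    )


def white_vs_brown() -> ComparisonSpec:
    """White vs brown egg layers: each white group paired with each brown
    group (six pairwise F_ST values averaged per SNP)."""
    return ComparisonSpec(
        "WL_vs_BL", tuple((w, b) for w in WHITE_GROUPS for b in BROWN_GROUPS)
    )


COMPARISON_TEMPLATES = {
    "commercial_vs_outgroup": commercial_vs_outgroup,
    "white_vs_brown": white_vs_brown,
}
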