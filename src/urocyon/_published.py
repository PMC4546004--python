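"""Published inputs bundled for the reproduction command.

The per-location haplotype occurrence table for the 785 bp concatenated
cytochrome-b + D-loop haplotypes, the per-fragment substitution rates, the
rho values read off the median-joining network, and the printed results they
should reproduce. Cell counts are stored as printed per location; totals are
always recomputed from cells (the printed grand totals contain a one-count
discrepancy in one column, so computed totals are authoritative here).
"""

from __future__ import annotations

import pandas as pd

from .dating import Fragment
from .io import CONCATENATED, HaplotypeCountTable

GEORGIA = "Georgia"

#: per-location counts of concatenated 785 bp haplotypes
TABLE1_COUNTS: dict[str, dict[str, int]] = {
    "Western Cascades": {"A-5": 7, "A-6": 1, "D-9": 3, "D-15": 3},
    "North Coast": {
        "A-5": 1, "B-3": 2, "D-9": 21, "D-10": 2, "D-11": 3, "D-12": 4, "D-15": 1,
    },
    "Central Coast": {"C-16": 1, "D-9": 1, "D-16": 6, "K-15": 1, "M-8": 1},
    "Southern California": {"L-18": 2},
    "Western Sierra/San Joaquin Valley": {"C-13": 5, "C-14": 1, "D-15": 4, "E-1": 3},
    "Sacramento Valley": {
        "A-5": 1, "B-2": 2, "B-3": 4, "C-13": 5, "D-2": 1, "D-9": 5,
        "D-12": 1, "D-15": 5, "E-1": 3,
    },
    "Eastern Sierra Nevada": {"J-13": 5},
    "Nevada": {"D-17": 1},
    "Washington": {"C-13": 1},
    "Island foxes": {"A-4": 4, "A-7": 5, "A-23": 2},
    GEORGIA: {"F-21": 6, "G-Uci22": 2, "H-19": 3, "H-20": 6, "H-Uci23": 5, "I-22": 5},
}

WESTERN_LOCATIONS = tuple(loc for loc in TABLE1_COUNTS if loc != GEORGIA)

#: island-fox counts by island (subsets of the "Island foxes" row)
ISLAND_COUNTS = {
    "Santa Cruz Isl.": {"A-4": 4},
    "San Nicolas Isl.": {"A-7": 5},
    "San Clemente Isl.": {"A-23": 2},
}

SEQUENCE_LENGTH_CONCATENATED = 785

#: two-fragment model behind the 785 bp composite rate
FRAGMENTS_785 = (Fragment("cytb", 363, 2.8), Fragment("dloop", 422, 17.75))
#: whole-mitogenome model (coding + control region)
FRAGMENTS_MITOGENOME = (Fragment("coding", 15478, 2.8), Fragment("dloop", 982, 17.75))

PRINTED_COMPOSITE_RATE_785 = 10.8  # % per million generations
PRINTED_PER_SEQ_RATE_785 = 8.51e-5  # mutations per sequence per generation
PRINTED_COMPOSITE_RATE_MITOGENOME = 3.7  # % per million generations

#: rho estimates for nested haplogroups of the 785 bp network:
#: (ancestor, descendant set label, rho, sd, printed TMRCA in generations)
RHO_TABLE = (
    ("Basal MV", "Island fox haplotypes", 1.5, 0.729, 17_625),
    ("Basal MV", "All western haplotypes", 5.22, 1.538, 61_335),
    ("Interior MV", "Mainland clade", 3.95, 1.237, 46_413),
    ("Interior MV", "Nested mainland clade", 4.26, 1.5, 50_055),
    ("Interior MV", "Yellow haplogroup", 1.2, 0.968, 14_100),
    ("Interior MV", "Gray haplogroup", 1.08, 1.003, 12_725),
    ("D-15", "White haplogroup", 0.4, 0.354, 4_700),
    ("A-4", "Pink haplogroup", 1.0, 0.914, 11_750),
    ("Interior MV", "Red haplogroup", 2.87, 1.187, 33_723),
)

#: whole-mitogenome rho for the western gray fox clade
MITOGENOME_RHO = 37.04
MITOGENOME_RHO_SD = 4.09
PRINTED_MITOGENOME_YEARS = 120_000  # at 2-year generations, nearest 10,000

#: east-west divergence arithmetic (percent per site)
NET_DIVERGENCE_INPUTS = {"d_xy": 2.93, "pi_x": 0.86, "pi_y": 0.58}
PRINTED_NET_DIVERGENCE = 2.2

#: coding-fragment divergence bracketed by canid clock calibrations
CYTB_DIVERGENCE_PCT = 1.3
CLOCK_RATE_RANGE = (1.6, 3.0)  # % per million years
PRINTED_DIVERGENCE_WINDOW = (813_000, 433_000)

#: printed diversity values the bundled counts should reproduce
PRINTED_DIVERSITY = {
    "west_concatenated": (0.90, 0.017),
    "georgia_dloop": (0.846, 0.027),
    "island_foxes": (0.691, 0.086),
}

GENERATION_TIME_YEARS = 2.0
AGE_DATA_N = 435
PRINTED_MEAN_ADULT_AGE = 1.72


def table1() -> HaplotypeCountTable:
    """The published occurrence table as a HaplotypeCountTable."""
    haplotypes: list[str] = []
    for counts in TABLE1_COUNTS.values():
        for h in counts:
            if h not in haplotypes:
                haplotypes.append(h)
    df = pd.DataFrame(
        0, index=list(TABLE1_COUNTS), columns=haplotypes, dtype=int
    )
    for loc, counts in TABLE1_COUNTS.items():
        for h, c in counts.items():
            df.loc[loc, h] = c
    return HaplotypeCountTable(
        df, level=CONCATENATED, sequence_length=SEQUENCE_LENGTH_CONCATENATED
    )
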