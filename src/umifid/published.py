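"""Published reference results of the UMI-bottleneck polymerase fidelity study.

These printed tables are inputs for reanalysis — aggregate statistics,
confidence-interval checks, LA/PCR ratios — and the source of realistic
polymerase presets for the simulator.

``RATE_TABLE``: one row per (polymerase, experiment) with the consensus
error count, the number of UMI tags, the printed per-base-per-cycle rate
(in 1e-5 units, with its 95% CI), the linear-amplification rate and the
LA-corrected rate.  Rates were printed for 20 first-PCR cycles and a
150-bp template; back-calculating the printed rates from the raw counts
implies an effective denominator length of ~154 bases (primer-adjacent
bases were evidently included), which is why ``EFFECTIVE_TEMPLATE_LENGTH``
is exposed alongside the nominal 150.

``SPECTRUM_6`` / ``SPECTRUM_12``: composition-normalized substitution-class
shares (percent) after 20 PCR cycles (strand-collapsed) and after one
linear-amplification synthesis (strand-aware).  The low-yield Phusion
assay was excluded from spectrum analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simdata import SUBSTITUTIONS, PolymeraseModel

__all__ = [
    "RATE_TABLE",
    "SPECTRUM_6",
    "SPECTRUM_12",
    "NOMINAL_TEMPLATE_LENGTH",
    "EFFECTIVE_TEMPLATE_LENGTH",
    "PCR_CYCLES",
    "polymerase_presets",
]

NOMINAL_TEMPLATE_LENGTH = 150
#: Denominator length implied by the printed rates (primer-adjacent bases).
EFFECTIVE_TEMPLATE_LENGTH = 154
PCR_CYCLES = 20

_RATE_ROWS = [
    # sample, experiment, error_count, umi_count, rate, ci_low, ci_high, la_rate, corrected
    ("Encyclo",        1, 24557, 185560, 4.30, 4.25, 4.35, 12.79, 3.68),
    ("Encyclo",        2, 14211, 101516, 4.55, 4.48, 4.62, 12.79, 3.93),
    ("Kapa HF",        1,   339,   7876, 1.40, 1.25, 1.55,  8.17, 1.00),
    ("Kapa HF",        2,  2519,  57052, 1.44, 1.38, 1.49,  8.17, 1.04),
    ("Phusion",        1,    30,   1348, 0.72, 0.47, 0.98,  4.99, 0.48),
    ("Phusion",        2,    23,   1351, 0.55, 0.33, 0.78,  4.99, 0.31),
    ("SD-HS",          1,  6714,  33076, 6.60, 6.46, 6.74, 26.89, 5.29),
    ("SD-HS",          2, 10362,  58518, 5.76, 5.66, 5.86, 26.89, 4.45),
    ("SNP-detect",     1,   457,  13870, 1.07, 0.97, 1.17,  5.04, 0.83),
    ("SNP-detect",     2,   848,  32310, 0.85, 0.80, 0.91,  5.04, 0.61),
    ("Taq-HS",         1,  1875,  15137, 4.03, 3.86, 4.20, 18.36, 3.13),
    ("Taq-HS",         2,  3113,  24082, 4.20, 4.07, 4.34, 18.36, 3.31),
    ("Tersus-buffer1", 1,  2550,  46927, 1.77, 1.70, 1.83,  5.98, 1.48),
    ("Tersus-buffer1", 2,  5504, 154226, 1.16, 1.13, 1.19,  5.98, 0.87),
    ("Tersus-buffer2", 1,  6282, 130891, 1.56, 1.52, 1.60,  5.10, 1.31),
    ("Tersus-buffer2", 2,  1299,  30683, 1.38, 1.30, 1.45,  5.10, 1.13),
    ("TruSeq",         1,   312,  14164, 0.72, 0.64, 0.79,  4.10, 0.52),
    ("TruSeq",         2,   362,  16705, 0.70, 0.63, 0.78,  4.10, 0.50),
    ("KTN",            1, 16802, 132733, 4.12, 4.06, 4.17, 12.92, 3.49),
    ("KTN",            2,  6298,  44331, 4.62, 4.51, 4.73, 12.92, 3.99),
]

RATE_TABLE = pd.DataFrame(
    _RATE_ROWS,
    columns=[
        "sample", "experiment", "error_count", "umi_count",
        "rate_1e5", "ci_low_1e5", "ci_high_1e5", "la_rate_1e5", "corrected_1e5",
    ],
)

# Strand-collapsed shares (percent) after 20 PCR cycles.
_SPECTRUM_6_ROWS = {
    "Encyclo":        [4, 59, 5, 2, 1, 29],
    "Kapa HF":        [2, 10, 2, 14, 1, 71],
    "SD-HS":          [3, 31, 14, 5, 17, 30],
    "SNP-detect":     [5, 27, 1, 2, 1, 64],
    "Taq-HS":         [3, 56, 7, 7, 2, 25],
    "Tersus-buffer1": [5, 35, 2, 6, 1, 52],
    "Tersus-buffer2": [5, 45, 2, 2, 1, 46],
    "TruSeq":         [6, 13, 3, 25, 3, 50],
    "KTN":            [4, 60, 4, 2, 1, 29],
}

SPECTRUM_6 = pd.DataFrame(
    _SPECTRUM_6_ROWS,
    index=["A>C/T>G", "A>G/T>C", "A>T/T>A", "C>A/G>T", "C>G/G>C", "C>T/G>A"],
).T

# Strand-aware shares (percent) after one linear-amplification synthesis.
_SPECTRUM_12_ROWS = {
    #                A>C A>G A>T C>A C>G C>T G>A G>C G>T T>A T>C T>G
    "Encyclo":        [6, 22,  3, 10,  2, 19, 25,  1,  1,  1, 11,  1],
    "Kapa HF":        [3,  4,  1, 42,  1, 23, 16,  1,  7,  0,  2,  0],
    "SD-HS":          [5, 11, 22,  8,  7, 13, 16,  3,  4,  4,  6,  0],
    "SNP-detect":     [8,  9,  0,  5,  2, 26, 42,  0,  1,  1,  6,  0],
    "Taq-HS":         [4, 15,  8, 24,  2, 13, 19,  1,  2,  4,  8,  0],
    "Tersus-buffer1": [9,  6,  0, 22,  1, 18, 38,  1,  1,  1,  4,  0],
    "Tersus-buffer2": [10, 10, 0,  6,  2, 22, 40,  1,  1,  1,  7,  0],
    "TruSeq":         [5,  3,  1, 43,  1,  8, 15,  1, 20,  0,  2,  0],
    "KTN":            [6, 24,  3,  8,  2, 19, 26,  0,  1,  1, 10,  0],
}

SPECTRUM_12 = pd.DataFrame(_SPECTRUM_12_ROWS, index=list(SUBSTITUTIONS)).T


def polymerase_presets(efficiency: float = 1.8) -> dict:
    """Simulator models built from the published measurements.

    The per-synthesis error rate is the published linear-amplification
    rate (a single synthesis event); the 12-class spectrum is the
    strand-aware linear-amplification spectrum, normalized.
    """
    presets = {}
    la = RATE_TABLE.drop_duplicates("sample").set_index("sample")["la_rate_1e5"]
    for name in SPECTRUM_12.index:
        weights = SPECTRUM_12.loc[name].to_numpy(dtype=float)
        presets[name] = PolymeraseModel(
            name=name,
            per_synthesis_error_rate=float(la[name]) * 1e-5,
            spectrum=weights / weights.sum(),
            efficiency=efficiency,
        )
    return presets
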