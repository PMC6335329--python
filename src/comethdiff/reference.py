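"""Published reference results for the RA and PD blood-methylation cohorts.

The differential co-methylation study this pipeline reproduces analyzed two
Illumina 450K cohorts — rheumatoid arthritis (GEO accession GSE42861, 354
cases / 335 controls, peripheral blood leukocytes) and Parkinson's disease
(GSE111629, 335 cases / 237 controls, whole blood) — collapsed to 21,225
genes, i.e. 225,239,700 gene pairs per condition.  This module embeds the
published summary results as plain data so the counting and percentage
machinery can be checked against them without the (multi-gigabyte) source
data:

* the two 8x8 control-to-case transition count matrices (rows = control
  interval, columns = case interval);
* the nine large-change gene pairs reported as shared between the two
  diseases with |r_case - r_control| > 0.8 in both.

These are inputs for verification, not outputs of this package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import DEFAULT_SCHEME, TransitionMatrix

N_GENES = 21_225
N_RA_CASE, N_RA_CONTROL = 354, 335
N_PD_CASE, N_PD_CONTROL = 335, 237

RA_TRANSITION_COUNTS: tuple[tuple[int, ...], ...] = (
    (77_481, 27_809, 80, 2, 0, 0, 0, 0),
    (7_299, 764_774, 1_286_473, 68_700, 108, 5, 0, 0),
    (2, 182_660, 5_696_562, 7_398_531, 482_134, 956, 13, 0),
    (0, 1_753, 1_784_109, 27_223_563, 20_688_414, 650_691, 716, 0),
    (0, 2, 26_663, 8_265_509, 59_694_607, 19_289_656, 245_055, 50),
    (0, 0, 30, 50_725, 8_254_707, 35_908_516, 8_184_266, 3_747),
    (0, 0, 0, 11, 15_739, 3_231_110, 13_539_841, 702_925),
    (0, 0, 0, 0, 0, 577, 408_604, 1_074_525),
)

PD_TRANSITION_COUNTS: tuple[tuple[int, ...], ...] = (
    (53_560, 7_274, 0, 0, 0, 0, 0, 0),
    (6_062, 58_463, 4_277, 9, 2, 0, 0, 0),
    (3, 24_024, 85_156, 16_583, 314, 5, 1, 0),
    (9, 16_305, 484_685, 2_012_234, 1_168_009, 12_571, 33, 0),
    (6, 5_546, 393_274, 7_360_253, 29_846_001, 5_438_956, 33_073, 57),
    (0, 594, 73_877, 2_210_173, 29_393_376, 58_680_360, 5_410_454, 4_552),
    (0, 13, 1_807, 111_235, 2_805_248, 33_491_914, 40_651_108, 675_825),
    (0, 0, 2, 60, 3_064, 85_461, 2_828_820, 1_785_012),
)

#: First-row percentages as printed for each cohort's transition table
#: (bin 1 and bin 2 of the control [-1, -0.75) row).
RA_ROW1_PRINTED_PCT = (73.53091, 26.39126)
PD_ROW1_PRINTED_PCT = (88.04287, 11.95713)

#: The nine gene pairs reported as shared large-change pairs (distance >= 3
#: and |delta| > 0.8 in both diseases), with their published correlations.
SHARED_PAIRS = pd.DataFrame(
    [
        ("ARHGAP17", "TSHZ3", 0.382, -0.561, 0.384, -0.497),
        ("CDK20", "GRB2", 0.481, -0.484, 0.517, -0.492),
        ("CDK20", "PLEKHF2", 0.458, -0.342, 0.492, -0.408),
        ("CRY1", "GRB2", 0.599, -0.252, 0.552, -0.264),
        ("ETV1", "GRB2", 0.368, -0.473, 0.63, -0.237),
        ("GATA3", "GRB2", 0.279, -0.544, 0.59, -0.64),
        ("GRB2", "LCA5", 0.505, -0.36, 0.469, -0.41),
        ("GRB2", "PVR", 0.692, -0.32, 0.698, -0.114),
        ("GRB2", "TSHZ3", 0.441, -0.616, 0.397, -0.588),
    ],
    columns=[
        "gene1",
        "gene2",
        "ra_r_case",
        "ra_r_control",
        "pd_r_case",
        "pd_r_control",
    ],
)


def ra_transition_matrix() -> TransitionMatrix:
    """The RA cohort's published 8x8 transition counts as a TransitionMatrix."""
    return TransitionMatrix(
        counts=np.array(RA_TRANSITION_COUNTS, dtype=np.int64),
        n_excluded=0,
        scheme=DEFAULT_SCHEME,
    )


def pd_transition_matrix() -> TransitionMatrix:
    """The PD cohort's published 8x8 transition counts as a TransitionMatrix."""
    return TransitionMatrix(
        counts=np.array(PD_TRANSITION_COUNTS, dtype=np.int64),
        n_excluded=0,
        scheme=DEFAULT_SCHEME,
    )
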