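"""Bundled example data: the metastatic colorectal cancer (mCRC) case study.

The matching stage of the mCRC antiangiogenic-therapy case study produced
a distance matrix between 16 single-arm observational studies of
antiangiogenic treatment (rows) and 8 single-arm observational studies of
chemotherapy alone (columns), computed from five aggregate covariates
(treatment line, median age, performance score, colon-primary proportion,
female proportion) with the default weights of
:func:`surrobayes.matching.default_covariate_spec`. Distances are reported
to three decimals, the precision at which the matrix circulates.

Two matching thresholds accompany the matrix: the maximum between-arm
distance observed in the randomized trials of the same evidence base
(0.027, applied in practice as 0.030) and the maximum between-arm
distance in the comparative observational studies (0.055, used as a
sensitivity analysis).
"""

from __future__ import annotations

import numpy as np

from .matching import DistanceMatrix

__all__ = [
    "mcrc_distance_matrix",
    "MCRC_RCT_MAX_DISTANCE",
    "MCRC_APPLIED_THRESHOLD",
    "MCRC_CRWE_MAX_DISTANCE",
]

#: Maximum distance between arms of the included randomized trials.
MCRC_RCT_MAX_DISTANCE = 0.027
#: Threshold actually applied for primary matching (rounded up from 0.027).
MCRC_APPLIED_THRESHOLD = 0.030
#: Maximum distance between arms of the comparative observational studies
#: (sensitivity-analysis threshold).
MCRC_CRWE_MAX_DISTANCE = 0.055

_CONTROL_STUDIES = (
    "Dong 2015",
    "Matsumoto 2007",
    "Catalano 2009",
    "Fuse 2008",
    "Suenaga 2008",
    "Fuse 2007",
    "Hochster 2003",
    "Yoshino 2007",
)

_TREATMENT_STUDIES = (
    "Bendell 2012 (1)",
    "Bendell 2012 (2)",
    "Hurwitz 2014",
    "Van Cutsem 2009 (1)",
    "Van Cutsem 2009 (2)",
    "Van Cutsem 2009 (3)",
    "Van Cutsem 2009 (4)",
    "Bennouna 2017 (1)",
    "Bennouna 2017 (2)",
    "Buchler 2014 (1)",
    "Buchler 2014 (2)",
    "Ocvirk 2011 (1)",
    "Ocvirk 2011 (2)",
    "Moriwaki 2012 (1)",
    "Moriwaki 2012 (2)",
    "Kotaka 2016",
)

_DISTANCES = np.array(
    [
        [0.029, 0.273, 0.048, 0.134, 0.077, 0.126, 0.043, 0.057],
        [0.034, 0.273, 0.043, 0.139, 0.074, 0.131, 0.041, 0.062],
        [0.151, 0.156, 0.158, 0.211, 0.171, 0.248, 0.169, 0.179],
        [0.051, 0.234, 0.092, 0.093, 0.040, 0.085, 0.073, 0.018],
        [0.034, 0.232, 0.085, 0.082, 0.044, 0.074, 0.083, 0.018],
        [0.047, 0.221, 0.096, 0.072, 0.045, 0.064, 0.094, 0.013],
        [0.051, 0.224, 0.095, 0.079, 0.045, 0.071, 0.087, 0.017],
        [0.058, 0.227, 0.069, 0.110, 0.073, 0.102, 0.089, 0.041],
        [0.208, 0.115, 0.208, 0.175, 0.204, 0.212, 0.242, 0.191],
        [0.045, 0.233, 0.079, 0.094, 0.070, 0.086, 0.080, 0.025],
        [0.052, 0.213, 0.088, 0.082, 0.050, 0.072, 0.091, 0.014],
        [0.043, 0.260, 0.072, 0.100, 0.066, 0.094, 0.066, 0.065],
        [0.051, 0.226, 0.097, 0.080, 0.047, 0.062, 0.096, 0.044],
        [0.204, 0.062, 0.233, 0.121, 0.160, 0.148, 0.243, 0.165],
        [0.184, 0.099, 0.228, 0.132, 0.129, 0.169, 0.211, 0.150],
        [0.068, 0.200, 0.095, 0.072, 0.033, 0.064, 0.104, 0.034],
    ],
    dtype=float,
)


def mcrc_distance_matrix() -> DistanceMatrix:
    """The 16 x 8 mCRC single-arm study distance matrix.

    Rows are antiangiogenic (treatment-like) arms, columns chemotherapy
    (control-like) arms. Values are three-decimal transcriptions; matching
    decisions on this matrix compare the transcribed values directly.
    """
    return DistanceMatrix(
        row_ids=_TREATMENT_STUDIES, col_ids=_CONTROL_STUDIES, values=_DISTANCES.copy()
    )
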