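"""Reference outcome summaries from the original 63-knee CT cohort.

The simulation study this package re-implements reported per-angle tunnel
measurements on 63 adult knees (31 male, 32 female).  Its printed summary
tables are kept here as validation inputs: with one measurement per subject
at each angle the design is balanced, so the pooled OLS slope of TTL on TTA
equals the OLS slope of the five per-angle means — which lets the printed
prediction-equation slopes be re-derived from the tables alone, and the
pooled per-angle means be re-derived from the sex-stratified means by
sample-size weighting.  Lengths in mm, angles in degrees.
"""

from __future__ import annotations

import numpy as np

from .stats import fit_linear

ANGLES = (40.0, 45.0, 50.0, 55.0, 60.0)

N_MALE = 31
N_FEMALE = 32

# TTL mean +/- SD by sex and approach at each tunnel angle
TTL_BY_SEX = {
    ("male", "AM"): {"mean": (57.5, 61.1, 65.2, 71.2, 78.4), "sd": (4.6, 4.8, 4.6, 5.5, 6.5)},
    ("female", "AM"): {"mean": (52.3, 55.4, 59.2, 64.3, 70.9), "sd": (4.1, 4.3, 4.6, 5.2, 5.7)},
    ("male", "AL"): {"mean": (56.4, 59.0, 62.7, 68.2, 75.1), "sd": (4.5, 4.5, 4.9, 5.5, 6.9)},
    ("female", "AL"): {"mean": (49.2, 52.3, 56.1, 61.3, 68.1), "sd": (3.8, 4.6, 4.0, 5.4, 5.9)},
}

# pooled (both sexes) TTL and TTH means by approach
TTL_POOLED = {
    "AM": (54.9, 58.2, 62.2, 67.7, 74.6),
    "AL": (52.7, 55.6, 59.4, 64.7, 71.5),
}
TTH_POOLED = {
    "AM": (42.7, 48.7, 55.2, 62.7, 71.6),
    "AL": (41.8, 47.6, 53.0, 61.5, 70.3),
}

# printed best-fit TTL = a * TTA + b slopes per sex x approach stratum
PRINTED_SLOPES = {
    ("male", "AM"): 1.04,
    ("male", "AL"): 0.93,
    ("female", "AM"): 0.92,
    ("female", "AL"): 0.94,
}


def slope_from_angle_means(sex: str, approach: str) -> float:
    """OLS slope of TTL on TTA recomputed from the per-angle mean table.

    Balanced-design equivalence: every subject contributes one value per
    angle, so this equals the slope of the subject-level pooled regression.
    """
    means = TTL_BY_SEX[(sex, approach)]["mean"]
    return fit_linear(ANGLES, means, predictor="TTA", stratum=f"{sex}-{approach}").slope


def pooled_mean_from_sex_means(angle: float, approach: str) -> float:
    """Sample-size-weighted pooling of the sex-stratified TTL means."""
    i = ANGLES.index(angle)
    m = TTL_BY_SEX[("male", approach)]["mean"][i]
    f = TTL_BY_SEX[("female", approach)]["mean"][i]
    return (N_MALE * m + N_FEMALE * f) / (N_MALE + N_FEMALE)


def angle_means_table() -> "np.ndarray":
    """(angle, stratum) matrix of reported TTL means, mostly for inspection."""
    return np.array([TTL_BY_SEX[k]["mean"] for k in sorted(TTL_BY_SEX)])
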