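"""Named generative presets built from the study's published estimates.

The anthropometric twin study that motivates this package distributes its
raw data only on request, so the simulator ships the published summary
estimates as generating truths: per-trait descriptive statistics (mean,
SD), standardized variance components (a2, c2, e2) per sex and wave, and
cross-wave phenotypic/genetic/environmental correlations.  Cohorts drawn
from these presets have, in expectation, exactly the published moment
structure, which is what makes parameter-recovery testing meaningful.
"""

from __future__ import annotations

import numpy as np

from .truth import GenerativeTruth, truth_from_components

# (mean, SD) per wave, sex, trait -------------------------------------------
DESCRIPTIVES = {
    "initial": {
        "male": {
            "height": (149.0, 7.02), "sitting_height": (77.1, 3.48),
            "knee_height": (46.7, 2.84), "buttock_knee_length": (51.7, 3.23),
            "foot_length_left": (23.0, 1.42), "foot_length_right": (23.1, 1.38),
            "head_circumference": (54.1, 1.62), "head_breadth": (14.4, 0.48),
            "face_height": (20.7, 1.09), "head_length_1": (18.6, 0.70),
            "head_length_2": (16.8, 0.86), "weight": (41.3, 9.53),
            "bmi": (18.4, 3.22), "arm_circumference": (21.8, 2.88),
            "waist_circumference_relaxed": (65.7, 9.00),
            "waist_circumference_sucking": (60.6, 8.87),
        },
        "female": {
            "height": (151.0, 7.31), "sitting_height": (78.2, 4.12),
            "knee_height": (46.8, 2.77), "buttock_knee_length": (52.7, 3.44),
            "foot_length_left": (22.5, 1.31), "foot_length_right": (22.5, 1.32),
            "head_circumference": (54.1, 1.75), "head_breadth": (14.3, 0.50),
            "face_height": (20.0, 1.12), "head_length_1": (18.3, 0.81),
            "head_length_2": (16.4, 0.95), "weight": (44.5, 11.26),
            "bmi": (19.4, 3.73), "arm_circumference": (22.6, 3.24),
            "waist_circumference_relaxed": (67.2, 9.74),
            "waist_circumference_sucking": (62.6, 9.90),
        },
    },
    "followup": {
        "male": {
            "height": (170.0, 7.85), "sitting_height": (86.8, 4.47),
            "knee_height": (52.9, 2.85), "buttock_knee_length": (59.1, 3.34),
            "foot_length_left": (25.7, 1.38), "foot_length_right": (25.7, 1.37),
            "head_circumference": (55.9, 1.68), "head_breadth": (14.9, 0.53),
            "face_height": (21.8, 1.07), "head_length_1": (19.0, 0.84),
            "head_length_2": (17.3, 0.95), "weight": (61.7, 13.03),
            "bmi": (21.2, 3.58), "arm_circumference": (25.9, 3.29),
            "waist_circumference_relaxed": (76.2, 9.17),
            "waist_circumference_sucking": (71.1, 9.69),
            "shoulder_breadth": (33.8, 3.07), "wrist_breadth": (5.56, 0.33),
            "hip_breadth": (30.4, 3.03), "biceps_skinfold": (8.19, 5.93),
            "triceps_skinfold": (13.3, 8.30),
        },
        "female": {
            "height": (166.0, 6.40), "sitting_height": (87.1, 3.25),
            "knee_height": (50.5, 2.63), "buttock_knee_length": (58.4, 2.94),
            "foot_length_left": (23.5, 1.25), "foot_length_right": (23.6, 1.25),
            "head_circumference": (55.5, 1.75), "head_breadth": (14.6, 0.52),
            "face_height": (20.8, 1.03), "head_length_1": (18.8, 0.82),
            "head_length_2": (17.2, 0.84), "weight": (65.2, 14.73),
            "bmi": (23.7, 4.91), "arm_circumference": (26.6, 3.67),
            "waist_circumference_relaxed": (78.5, 11.28),
            "waist_circumference_sucking": (73.2, 11.31),
            "shoulder_breadth": (34.2, 2.88), "wrist_breadth": (5.18, 0.33),
            "hip_breadth": (34.3, 3.17), "biceps_skinfold": (11.73, 6.71),
            "triceps_skinfold": (20.1, 7.89),
        },
    },
}

# standardized (a2, c2, e2) per wave, sex, trait ----------------------------
VARIANCE_COMPONENTS = {
    "initial": {
        "male": {
            "height": (0.78, 0.15, 0.07), "sitting_height": (0.75, 0.11, 0.14),
            "knee_height": (0.81, 0.11, 0.07), "buttock_knee_length": (0.39, 0.44, 0.17),
            "foot_length_left": (0.82, 0.08, 0.09), "foot_length_right": (0.83, 0.09, 0.08),
            "head_circumference": (0.49, 0.35, 0.17), "head_breadth": (0.73, 0.08, 0.20),
            "head_length_1": (0.58, 0.19, 0.24), "head_length_2": (0.53, 0.26, 0.21),
            "face_height": (0.30, 0.37, 0.34), "weight": (0.79, 0.12, 0.09),
            "bmi": (0.79, 0.12, 0.09), "arm_circumference": (0.76, 0.11, 0.12),
            "waist_circumference_relaxed": (0.55, 0.30, 0.15),
            "waist_circumference_sucking": (0.68, 0.17, 0.15),
        },
        "female": {
            "height": (0.71, 0.22, 0.07), "sitting_height": (0.67, 0.23, 0.10),
            "knee_height": (0.73, 0.17, 0.10), "buttock_knee_length": (0.73, 0.14, 0.13),
            "foot_length_left": (0.66, 0.23, 0.11), "foot_length_right": (0.64, 0.23, 0.13),
            "head_circumference": (0.84, 0.01, 0.15), "head_breadth": (0.73, 0.14, 0.13),
            "head_length_1": (0.67, 0.11, 0.23), "head_length_2": (0.48, 0.34, 0.18),
            "face_height": (0.41, 0.17, 0.42), "weight": (0.78, 0.14, 0.08),
            "bmi": (0.82, 0.10, 0.08), "arm_circumference": (0.83, 0.07, 0.10),
            "waist_circumference_relaxed": (0.65, 0.19, 0.15),
            "waist_circumference_sucking": (0.68, 0.18, 0.14),
        },
    },
    "followup": {
        "male": {
            "height": (0.65, 0.24, 0.11), "sitting_height": (0.67, 0.18, 0.15),
            "knee_height": (0.62, 0.24, 0.13), "buttock_knee_length": (0.46, 0.37, 0.17),
            "foot_length_left": (0.69, 0.14, 0.17), "foot_length_right": (0.67, 0.17, 0.16),
            "head_circumference": (0.57, 0.25, 0.18), "head_breadth": (0.67, 0.15, 0.18),
            "head_length_1": (0.43, 0.35, 0.22), "head_length_2": (0.37, 0.43, 0.20),
            "face_height": (0.21, 0.42, 0.37), "shoulder_breadth": (0.27, 0.55, 0.19),
            "wrist_breadth": (0.64, 0.14, 0.22), "weight": (0.71, 0.19, 0.10),
            "bmi": (0.77, 0.12, 0.11), "arm_circumference": (0.79, 0.10, 0.12),
            "hip_breadth": (0.59, 0.31, 0.11),
            "waist_circumference_relaxed": (0.61, 0.22, 0.18),
            "waist_circumference_sucking": (0.49, 0.31, 0.20),
            "biceps_skinfold": (0.57, 0.26, 0.17), "triceps_skinfold": (0.42, 0.40, 0.18),
        },
        "female": {
            "height": (0.78, 0.17, 0.06), "sitting_height": (0.87, 0.00, 0.13),
            "knee_height": (0.70, 0.11, 0.19), "buttock_knee_length": (0.63, 0.18, 0.19),
            "foot_length_left": (0.90, 0.00, 0.10), "foot_length_right": (0.88, 0.00, 0.12),
            "head_circumference": (0.85, 0.00, 0.15), "head_breadth": (0.84, 0.00, 0.16),
            "head_length_1": (0.44, 0.23, 0.33), "head_length_2": (0.54, 0.12, 0.34),
            "face_height": (0.65, 0.01, 0.34), "shoulder_breadth": (0.23, 0.63, 0.14),
            "wrist_breadth": (0.61, 0.17, 0.22), "weight": (0.71, 0.18, 0.11),
            "bmi": (0.62, 0.26, 0.12), "arm_circumference": (0.67, 0.11, 0.22),
            "hip_breadth": (0.48, 0.36, 0.16),
            "waist_circumference_relaxed": (0.83, 0.00, 0.17),
            "waist_circumference_sucking": (0.45, 0.35, 0.20),
            "biceps_skinfold": (0.15, 0.60, 0.25), "triceps_skinfold": (0.24, 0.47, 0.30),
        },
    },
}

# cross-wave (phenotypic r, r_A, r_E) per sex, trait ------------------------
CROSS_WAVE = {
    "male": {
        "height": (0.87, 0.90, 0.56), "sitting_height": (0.79, 0.85, 0.41),
        "knee_height": (0.80, 0.85, 0.37), "buttock_knee_length": (0.79, 0.86, 0.36),
        "foot_length_left": (0.81, 0.87, 0.41), "foot_length_right": (0.82, 0.88, 0.35),
        "head_circumference": (0.75, 0.79, 0.60), "head_breadth": (0.87, 0.93, 0.60),
        "face_height": (0.48, 0.64, 0.12), "head_length_1": (0.65, 0.75, 0.30),
        "head_length_2": (0.45, 0.49, 0.27), "weight": (0.91, 0.94, 0.64),
        "bmi": (0.90, 0.95, 0.53), "arm_circumference": (0.82, 0.86, 0.52),
        "waist_circumference_relaxed": (0.80, 0.88, 0.41),
        "waist_circumference_sucking": (0.75, 0.84, 0.37),
    },
    "female": {
        "height": (0.71, 0.73, 0.49), "sitting_height": (0.68, 0.73, 0.29),
        "knee_height": (0.70, 0.78, 0.13), "buttock_knee_length": (0.66, 0.72, 0.34),
        "foot_length_left": (0.82, 0.83, 0.62), "foot_length_right": (0.81, 0.85, 0.46),
        "head_circumference": (0.72, 0.77, 0.40), "head_breadth": (0.83, 0.87, 0.61),
        "face_height": (0.49, 0.70, 0.06), "head_length_1": (0.51, 0.59, 0.29),
        "head_length_2": (0.34, 0.40, 0.23), "weight": (0.78, 0.80, 0.52),
        "bmi": (0.79, 0.82, 0.43), "arm_circumference": (0.70, 0.77, 0.30),
        "waist_circumference_relaxed": (0.66, 0.72, 0.22),
        "waist_circumference_sucking": (0.62, 0.68, 0.28),
    },
}

# traits the study models on the log scale (adiposity-type, right-skewed)
LOG_TRAITS = {
    "initial": frozenset({"weight", "bmi", "waist_circumference_relaxed",
                          "waist_circumference_sucking"}),
    "followup": frozenset({"weight", "bmi", "waist_circumference_relaxed",
                           "waist_circumference_sucking", "biceps_skinfold",
                           "triceps_skinfold"}),
}


def univariate_truth(
    trait: str, sex: str, wave: str = "initial", scaled: bool = False
) -> GenerativeTruth:
    """Single-trait truth with the published a2/c2/e2 for (trait, sex, wave).

    With ``scaled=True`` the total variance and mean follow the published
    descriptives (age slopes stay zero so the generating SD is the printed
    SD); otherwise the trait has unit variance and zero mean, which is all
    that standardized components can see.
    """
    a2, c2, e2 = VARIANCE_COMPONENTS[wave][sex][trait]
    total = 1.0
    means = {}
    if scaled:
        mean, sd = DESCRIPTIVES[wave][sex][trait]
        total = sd * sd
        means = {s: np.array([mean]) for s in ("male", "female")}
    return truth_from_components(
        (trait,), [a2], [c2], [e2], total_var=[total], means=means
    )


def solve_shared_env_correlation(
    comp1: tuple[float, float, float],
    comp2: tuple[float, float, float],
    r_p: float,
    r_a: float,
    r_e: float,
) -> float:
    """Shared-environmental correlation consistent with the published moments.

    Given the per-wave standardized components and the published phenotypic,
    genetic and unique-environmental correlations, the phenotypic identity
    r_P = sqrt(a2 a2') r_A + sqrt(c2 c2') r_C + sqrt(e2 e2') r_E
    pins down r_C; the result is clipped to [-1, 1] (0 when either c2 is 0).
    """
    a1, c1, e1 = comp1
    a2_, c2_, e2_ = comp2
    cc = np.sqrt(c1 * c2_)
    if cc < 1e-6:
        return 0.0
    resid = r_p - np.sqrt(a1 * a2_) * r_a - np.sqrt(e1 * e2_) * r_e
    return float(np.clip(resid / cc, -1.0, 1.0))


def cross_wave_truth(
    trait: str, sex: str, waves: tuple[str, str] = ("initial", "followup")
) -> GenerativeTruth:
    """Stacked bivariate truth for one trait across the two waves.

    Per-wave a2/c2/e2 come from the published univariate decomposition, r_A
    and r_E from the published cross-wave analysis, and r_C is solved so the
    implied phenotypic cross-wave correlation matches the published one.
    Unit phenotypic variance at both waves.
    """
    comp1 = VARIANCE_COMPONENTS[waves[0]][sex][trait]
    comp2 = VARIANCE_COMPONENTS[waves[1]][sex][trait]
    r_p, r_a, r_e = CROSS_WAVE[sex][trait]
    r_c = solve_shared_env_correlation(comp1, comp2, r_p, r_a, r_e)
    unit = np.array([[1.0, 0.0], [0.0, 1.0]])
    return truth_from_components(
        (trait, trait),
        [comp1[0], comp2[0]],
        [comp1[1], comp2[1]],
        [comp1[2], comp2[2]],
        r_A=unit + (1 - unit) * r_a,
        r_C=unit + (1 - unit) * r_c,
        r_E=unit + (1 - unit) * r_e,
        trait_waves=waves,
    )


def study_truth(
    sex: str,
    wave: str = "initial",
    traits=None,
    r_A=None,
    scaled: bool = True,
) -> GenerativeTruth:
    """Multi-trait truth for one sex and wave from the published components.

    Cross-trait component correlations default to the identity (the
    published matrices live in figures whose raw values are not embedded
    here); pass ``r_A``/``r_C``/``r_E`` matrices to plant structure.
    """
    comp = VARIANCE_COMPONENTS[wave][sex]
    if traits is None:
        traits = list(comp)
    a2 = [comp[t][0] for t in traits]
    c2 = [comp[t][1] for t in traits]
    e2 = [comp[t][2] for t in traits]
    total = [1.0] * len(traits)
    means = {}
    if scaled:
        desc = DESCRIPTIVES[wave][sex]
        total = [desc[t][1] ** 2 for t in traits]
        mvec = np.array([desc[t][0] for t in traits])
        means = {s: mvec for s in ("male", "female")}
    return truth_from_components(
        tuple(traits), a2, c2, e2, total_var=total, r_A=r_A, means=means
    )
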