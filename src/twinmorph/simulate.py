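"""Simulate twin cohorts with the exact covariance structure the twin model assumes.

Pairs are drawn from a zero-mean multivariate normal whose stacked
(twin1, twin2) covariance is the one implied by the generative A, C, E
matrices and the zygosity (cross-twin correlation 1 for A in MZ, 0.5 in DZ;
1 for C in both; 0 for E).  Per-sex means and linear age effects are added
afterwards, and log-normal traits are exponentiated last, so that the
modelled (log) scale carries the normal structure.

For multi-wave designs the latent vector for a family is drawn *once* over
all (trait, wave) combinations, so longitudinal (cross-wave) genetic
correlations are part of the same machinery; a truth without ``trait_waves``
treats waves as independent redraws.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import block_diag

from .design import CohortDesign
from .truth import GenerativeTruth, implied_pair_covariance

# fixed iteration order so a seed fully determines the output
_CELL_ORDER = (
    ("MZ", "male"),
    ("MZ", "female"),
    ("DZ", "male"),
    ("DZ", "female"),
)

COHORT_COLUMNS = ("family_id", "twin_index", "zygosity", "sex", "wave", "age")


def _stacked_truth(truth: GenerativeTruth, design: CohortDesign):
    """Expand a truth to (trait, wave) combos covering the design's waves."""
    if truth.trait_waves is not None:
        unknown = set(truth.trait_waves) - set(design.wave_labels)
        if unknown:
            raise ValueError(f"trait_waves not in design: {sorted(unknown)}")
        combos = list(zip(truth.traits, truth.trait_waves))
        return combos, truth.A, truth.C, truth.E, list(range(truth.n_traits))
    labels = design.wave_labels
    combos = [(t, w) for w in labels for t in truth.traits]
    reps = len(labels)
    A = block_diag(*([truth.A] * reps))
    C = block_diag(*([truth.C] * reps))
    E = block_diag(*([truth.E] * reps))
    idx = list(range(truth.n_traits)) * reps
    return combos, A, C, E, idx


def _normal_factor(cov: np.ndarray) -> np.ndarray:
    """Square root of a PSD covariance, tolerant of exact singularity."""
    w, v = np.linalg.eigh(0.5 * (cov + cov.T))
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("implied pair covariance is not PSD")
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_cohort(
    design: CohortDesign,
    truth: GenerativeTruth,
    seed: int,
    mcar_rate: float | dict[str, float] = 0.0,
) -> pd.DataFrame:
    """Simulate a twin cohort table.

    Parameters
    ----------
    design : CohortDesign
        Pair counts per (zygosity, sex) cell and wave, plus age laws.  With
        multiple waves, the first ``n_w`` families of a cell attend wave
        ``w``, so smaller follow-up waves are nested subsets of intake.
    truth : GenerativeTruth
        Generating A, C, E matrices, means and age slopes.
    seed : int
        Required; the same seed, design and truth give an identical table.
    mcar_rate : float or dict, optional
        Missing-completely-at-random probability per trait value (scalar or
        per-trait dict).  Off by default.

    Returns
    -------
    pandas.DataFrame
        One row per individual per attended wave with columns
        ``family_id, twin_index, zygosity, sex, wave, age, <trait...>``.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    rng = np.random.default_rng(int(seed))

    combos, A, C, E, trait_idx = _stacked_truth(truth, design)
    m = len(combos)
    base_names = list(dict.fromkeys(truth.traits))
    stacked = GenerativeTruth(
        traits=tuple(f"{t}@{w}" for t, w in combos), A=A, C=C, E=E
    )
    factors = {
        z: _normal_factor(implied_pair_covariance(stacked, z)) for z in ("MZ", "DZ")
    }
    if not isinstance(mcar_rate, dict):
        mcar_rate = {t: float(mcar_rate) for t in base_names}

    records: list[dict] = []
    for z, sex in _CELL_ORDER:
        n_fam = max((w.pair_counts.get((z, sex), 0) for w in design.waves), default=0)
        if n_fam == 0:
            continue
        # one joint latent draw per family over all (trait, wave) combos
        latent = rng.standard_normal((n_fam, 2 * m)) @ factors[z].T
        for wave in design.waves:
            n_att = wave.pair_counts.get((z, sex), 0)
            if n_att == 0:
                continue
            lo, hi = wave.age_range[sex]
            ages = np.clip(rng.uniform(lo, hi, n_att), lo, hi)
            in_wave = [j for j, (_, wl) in enumerate(combos) if wl == wave.label]
            for fam in range(n_att):
                fid = f"{z}-{sex[0].upper()}-{fam + 1:04d}"
                for twin in (1, 2):
                    row = {
                        "family_id": fid,
                        "twin_index": twin,
                        "zygosity": z,
                        "sex": sex,
                        "wave": wave.label,
                        "age": ages[fam],
                    }
                    for j in in_wave:
                        t = combos[j][0]
                        ti = trait_idx[j]
                        val = (
                            latent[fam, j + (twin - 1) * m]
                            + truth.means[sex][ti]
                            + truth.age_slopes[sex][ti] * ages[fam]
                        )
                        if t in truth.lognormal_traits:
                            val = np.exp(val)
                        if mcar_rate.get(t, 0.0) > 0 and rng.random() < mcar_rate[t]:
                            val = np.nan
                        row[t] = val
                    records.append(row)

    cols = list(COHORT_COLUMNS) + base_names
    table = pd.DataFrame.from_records(records)
    for c in cols:
        if c not in table.columns:
            table[c] = np.nan
    return table[cols]


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as UTF-8 CSV (missing values as empty cells)."""
    table.to_csv(path, index=False, float_format="%.10g", encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    table = pd.read_csv(path, encoding="utf-8")
    table["twin_index"] = table["twin_index"].astype(int)
    return table
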