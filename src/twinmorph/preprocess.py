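"""Trait derivation and adjustment: BMI, log transformation, age residualization.

The pipeline mirrors the standard anthropometric workflow: body-mass index
is computed from raw weight and height, right-skewed adiposity traits are
normalized with the (natural) logarithm, and every trait is then replaced by
the residuals of an ordinary least-squares regression on exact age, fitted
separately within each (sex, wave) stratum.  Log precedes residualization;
since the components reported downstream are standardized, the base of the
logarithm is immaterial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_MIN_STRATUM = 3  # below this an age slope is not meaningfully estimable


@dataclass
class PreprocessSpec:
    """What to derive and adjust.

    ``log_traits`` are replaced by their natural log; ``bmi_inputs`` names
    the weight (kg) and height (cm) columns used to derive BMI; residuals
    are always taken within sex x wave strata.
    """

    log_traits: frozenset[str] = frozenset()
    adjust_for_age: bool = True
    bmi_inputs: tuple[str, str] | None = None  # (weight_col, height_col)
    bmi_name: str = "bmi"
    trait_columns: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.log_traits = frozenset(self.log_traits)


def compute_bmi(weight_kg, height_cm):
    """Body-mass index: weight in kg divided by squared height in meters."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(weight_kg[~np.isnan(weight_kg)] <= 0):
        raise ValueError("weight must be strictly positive")
    if np.any(height_cm[~np.isnan(height_cm)] <= 0):
        raise ValueError("height must be strictly positive")
    out = weight_kg / (height_cm / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def _trait_columns(table: pd.DataFrame, spec: PreprocessSpec) -> list[str]:
    from .simulate import COHORT_COLUMNS

    if spec.trait_columns is not None:
        return list(spec.trait_columns)
    return [c for c in table.columns if c not in COHORT_COLUMNS]


def add_bmi(table: pd.DataFrame, spec: PreprocessSpec) -> pd.DataFrame:
    if spec.bmi_inputs is None:
        return table
    w_col, h_col = spec.bmi_inputs
    out = table.copy()
    out[spec.bmi_name] = compute_bmi(out[w_col].to_numpy(), out[h_col].to_numpy())
    return out


def log_transform(table: pd.DataFrame, spec: PreprocessSpec) -> pd.DataFrame:
    """Replace each trait in ``spec.log_traits`` by its natural log."""
    out = table.copy()
    for trait in sorted(spec.log_traits):
        if trait not in out.columns:
            raise KeyError(f"log trait {trait!r} not in table")
        vals = out[trait].to_numpy(dtype=float)
        bad = vals <= 0
        if np.any(bad & ~np.isnan(vals)):
            fam = out.loc[bad & ~np.isnan(vals), "family_id"].iloc[0]
            raise ValueError(
                f"non-positive value for log trait {trait!r} (e.g. family {fam})"
            )
        out[trait] = np.log(vals)
    return out


def residualize_age(table: pd.DataFrame, spec: PreprocessSpec) -> pd.DataFrame:
    """Replace traits by OLS residuals on intercept + exact age, per (sex, wave).

    Complete cases per trait per stratum; rows missing age are left missing
    for every trait.  Residuals have mean zero and zero sample covariance
    with age within each stratum.
    """
    traits = _trait_columns(table, spec)
    out = table.copy()
    for (sex, wave), idx in out.groupby(["sex", "wave"], sort=False).groups.items():
        sub = out.loc[idx]
        age = sub["age"].to_numpy(dtype=float)
        for trait in traits:
            y = sub[trait].to_numpy(dtype=float)
            ok = ~np.isnan(y) & ~np.isnan(age)
            if ok.sum() == 0:
                continue
            if ok.sum() < _MIN_STRATUM:
                raise ValueError(
                    f"stratum ({sex}, {wave}) has {ok.sum()} rows for {trait!r}; "
                    f"need at least {_MIN_STRATUM} to residualize on age"
                )
            X = np.column_stack([np.ones(ok.sum()), age[ok]])
            beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
            resid = np.full_like(y, np.nan)
            resid[ok] = y[ok] - X @ beta
            out.loc[idx, trait] = resid
    return out


def preprocess(table: pd.DataFrame, spec: PreprocessSpec) -> pd.DataFrame:
    """BMI derivation, then log transform, then per-stratum age residuals."""
    out = add_bmi(table, spec)
    out = log_transform(out, spec)
    if spec.adjust_for_age:
        out = residualize_age(out, spec)
    return out


def age_slopes(table: pd.DataFrame, spec: PreprocessSpec) -> pd.DataFrame:
    """Estimated per-stratum OLS age slopes (diagnostic companion to residuals)."""
    traits = _trait_columns(table, spec)
    rows = []
    for (sex, wave), sub in table.groupby(["sex", "wave"], sort=False):
        age = sub["age"].to_numpy(dtype=float)
        for trait in traits:
            y = sub[trait].to_numpy(dtype=float)
            ok = ~np.isnan(y) & ~np.isnan(age)
            if ok.sum() < _MIN_STRATUM:
                continue
            X = np.column_stack([np.ones(ok.sum()), age[ok]])
            beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
            rows.append(
                {"sex": sex, "wave": wave, "trait": trait, "slope": beta[1], "n": int(ok.sum())}
            )
    return pd.DataFrame(rows)


def descriptive_stats(table: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Sample mean and SD (n-1 denominator) per (trait, sex, wave).

    Cells with no data are omitted with a warning; single-observation cells
    get an undefined (NaN) SD and a flag.
    """
    from .simulate import COHORT_COLUMNS

    if traits is None:
        traits = [c for c in table.columns if c not in COHORT_COLUMNS]
    rows = []
    for (sex, wave), sub in table.groupby(["sex", "wave"], sort=False):
        for trait in traits:
            vals = sub[trait].dropna()
            if len(vals) == 0:
                warnings.warn(
                    f"no observations for {trait!r} in ({sex}, {wave}); cell omitted",
                    stacklevel=2,
                )
                continue
            rows.append(
                {
                    "trait": trait,
                    "sex": sex,
                    "wave": wave,
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "sd_defined": len(vals) > 1,
                }
            )
    return pd.DataFrame(rows)
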