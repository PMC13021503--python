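"""BMI, log transformation and age residualization."""

import numpy as np
import pandas as pd
import pytest

from twinmorph.preprocess import (
    PreprocessSpec,
    compute_bmi,
    descriptive_stats,
    log_transform,
    residualize_age,
)
from twinmorph.simulate import simulate_cohort
from twinmorph.design import single_wave_design
from twinmorph.truth import truth_from_components


@pytest.mark.parametrize(
    "weight, height, expected",
    [(41.3, 149.0, 18.60), (65.2, 166.0, 23.66), (70.0, 100.0, 70.0)],
)
def test_bmi_examples(weight, height, expected):
    assert compute_bmi(weight, height) == pytest.approx(expected, abs=0.005)


def test_bmi_scaling_laws():
    b = compute_bmi(60.0, 170.0)
    assert compute_bmi(120.0, 170.0) == pytest.approx(2 * b)
    assert compute_bmi(60.0, 2 * 170.0) == pytest.approx(b / 4)


def test_bmi_rejects_nonpositive():
    with pytest.raises(ValueError):
        compute_bmi(-1.0, 170.0)
    with pytest.raises(ValueError):
        compute_bmi(60.0, 0.0)


def _table(values, ages=None, sex="male", wave="initial"):
    n = len(values)
    return pd.DataFrame(
        {
            "family_id": [f"f{i // 2}" for i in range(n)],
            "twin_index": [1 + i % 2 for i in range(n)],
            "zygosity": "MZ",
            "sex": sex,
            "wave": wave,
            "age": ages if ages is not None else np.linspace(10, 13, n),
            "x": values,
        }
    )


def test_log_transform_identities():
    table = _table([1.0, np.e, np.e**2, 1.0])
    out = log_transform(table, PreprocessSpec(log_traits={"x"}))
    assert np.allclose(out["x"], [0.0, 1.0, 2.0, 0.0])


def test_log_transform_rejects_nonpositive_with_context():
    table = _table([1.0, -2.0, 3.0, 4.0])
    with pytest.raises(ValueError, match="x"):
        log_transform(table, PreprocessSpec(log_traits={"x"}))


def test_log_normalizes_lognormal_skew():
    truth = truth_from_components(("x",), [0.5], [0.2], [0.3],
                                  lognormal_traits={"x"})
    table = simulate_cohort(single_wave_design({("MZ", "male"): 5000}), truth, seed=0)
    from scipy.stats import skew

    out = log_transform(table, PreprocessSpec(log_traits={"x"}))
    assert abs(skew(out["x"])) < 0.1


class TestResidualizeAge:
    spec = PreprocessSpec(trait_columns=("x",))

    def test_recovers_slope_and_kills_age_correlation(self, rng):
        ages = rng.uniform(10, 14, 2000)
        y = 2.0 * ages + rng.normal(scale=0.5, size=2000)
        table = _table(y, ages=ages)
        out = residualize_age(table, self.spec)
        # slope is removed: residuals uncorrelated with age
        assert abs(np.corrcoef(out["x"], out["age"])[0, 1]) < 1e-12
        assert abs(out["x"].mean()) < 1e-10
        fitted_slope = np.polyfit(ages, y, 1)[0]
        assert fitted_slope == pytest.approx(2.0, abs=0.05)

    def test_uncorrelated_trait_reduces_to_centering(self, rng):
        y = rng.normal(size=500)
        ages = np.full(500, 12.0) + np.concatenate([np.zeros(250), np.zeros(250)])
        # constant age: slope indeterminate but lstsq residuals = centred values
        table = _table(y, ages=ages)
        out = residualize_age(table, self.spec)
        assert np.allclose(out["x"], y - y.mean(), atol=1e-10)

    def test_constant_trait_gives_zero_residuals(self):
        table = _table(np.full(100, 7.0))
        out = residualize_age(table, self.spec)
        assert np.allclose(out["x"], 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        ages = rng.uniform(10, 14, 400)
        table = _table(3 * ages + rng.normal(size=400), ages=ages)
        once = residualize_age(table, self.spec)
        twice = residualize_age(once, self.spec)
        assert np.allclose(once["x"], twice["x"], atol=1e-10)

    def test_log_then_residualize_commutes_with_prelogged(self, rng):
        ages = rng.uniform(10, 14, 400)
        vals = np.exp(0.1 * ages + rng.normal(scale=0.2, size=400))
        table = _table(vals, ages=ages)
        spec = PreprocessSpec(log_traits={"x"}, trait_columns=("x",))
        a = residualize_age(log_transform(table, spec), spec)
        prelogged = table.assign(x=np.log(table["x"]))
        b = residualize_age(prelogged, spec)
        assert np.allclose(a["x"], b["x"], atol=1e-12)

    def test_tiny_stratum_rejected(self):
        table = _table([1.0, 2.0])
        with pytest.raises(ValueError, match="stratum"):
            residualize_age(table, self.spec)

    def test_strata_are_sex_by_wave(self, rng):
        """Residualization is fitted separately per (sex, wave) cell."""
        parts = []
        for sex, slope in (("male", 1.0), ("female", 3.0)):
            ages = rng.uniform(10, 14, 300)
            t = _table(slope * ages + rng.normal(scale=0.1, size=300), ages=ages, sex=sex)
            t["family_id"] = sex + t["family_id"]
            parts.append(t)
        table = pd.concat(parts, ignore_index=True)
        out = residualize_age(table, self.spec)
        for sex in ("male", "female"):
            sub = out[out["sex"] == sex]
            assert abs(np.corrcoef(sub["x"], sub["age"])[0, 1]) < 1e-10


class TestDescriptiveStats:
    def test_hand_example(self):
        table = _table([1.0, 2.0, 3.0, 4.0])
        out = descriptive_stats(table, traits=["x"])
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(2.5)
        assert row["sd"] == pytest.approx(np.std([1, 2, 3, 4], ddof=1))

    def test_single_value_sd_flagged(self):
        table = _table([5.0])
        out = descriptive_stats(table, traits=["x"])
        assert not out.iloc[0]["sd_defined"]
        assert np.isnan(out.iloc[0]["sd"])

    def test_empty_cell_warns_and_omits(self):
        table = _table([np.nan, np.nan])
        with pytest.warns(UserWarning, match="omitted"):
            out = descriptive_stats(table, traits=["x"])
        assert len(out) == 0

    def test_recovers_published_intake_height_moments(self):
        """A cohort generated with intake-male height mean 149, SD 7.02 shows
        those descriptives at the study's intake n."""
        from twinmorph.presets import univariate_truth
        from twinmorph.design import mtfs_design

        truth = univariate_truth("height", "male", "initial", scaled=True)
        means, sds = [], []
        for seed in range(21, 26):  # replicate cohorts at the design's n
            table = simulate_cohort(mtfs_design(), truth, seed=seed)
            out = descriptive_stats(table, traits=["height"])
            row = out[(out["sex"] == "male") & (out["wave"] == "initial")].iloc[0]
            means.append(row["mean"])
            sds.append(row["sd"])
        assert np.mean(means) == pytest.approx(149.0, abs=0.3)
        assert np.mean(sds) == pytest.approx(7.02, abs=0.3)
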