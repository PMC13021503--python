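"""Univariate twin models: saturated, ACE family, LRTs, profile CIs."""

import numpy as np
import pytest

from conftest import exact_moment_pairs, simulated_pairs
from twinmorph.pairs import PairData
from twinmorph.univariate import (
    UnivariateTwinModel,
    bonferroni_threshold,
    cotwin_correlations,
    fit_saturated,
    lrt,
    moment_estimate,
)


class TestSaturated:
    def test_parameter_count_univariate_two_group(self):
        pairs = simulated_pairs([[0.6]], [[0.2]], [[0.2]], 50, 50)
        sat = fit_saturated(pairs)
        assert sat.n_params == 10

    def test_moment_matching(self):
        pairs = simulated_pairs([[0.6]], [[0.2]], [[0.2]], 80, 60, seed=4)
        sat = fit_saturated(pairs)
        arr = pairs.groups["MZ"]
        emp = np.cov(arr, rowvar=False, ddof=0)
        assert np.allclose(sat.group_covs["MZ"], emp, atol=1e-6)
        assert np.allclose(sat.group_means["MZ"], arr.mean(axis=0), atol=1e-10)

    def test_saturated_bounds_structured_models(self):
        pairs = simulated_pairs([[0.5]], [[0.3]], [[0.2]], 120, 120, seed=9)
        sat = fit_saturated(pairs)
        for model in ("ACE", "AE", "CE", "E"):
            res = UnivariateTwinModel(pairs, model=model).fit(starts=2)
            assert sat.minus2ll <= res.minus2ll + 1e-6


class TestAceFit:
    def test_self_consistency_at_matched_moments(self):
        pairs = exact_moment_pairs([[0.6]], [[0.2]], [[0.2]], 300, 300)
        res = UnivariateTwinModel(pairs).fit()
        assert res.a2 == pytest.approx(0.6, abs=1e-4)
        assert res.c2 == pytest.approx(0.2, abs=1e-4)
        assert res.e2 == pytest.approx(0.2, abs=1e-4)
        assert res.converged

    def test_pure_e_data(self):
        pairs = simulated_pairs([[0.0]], [[0.0]], [[1.0]], 800, 800, seed=2)
        res = UnivariateTwinModel(pairs).fit()
        assert res.a2 < 0.06
        assert res.c2 < 0.06
        assert res.e2 > 0.9

    def test_moment_oracle_equivalence(self):
        """At data whose group moments equal the implied ones exactly, the ML
        fit agrees with the closed-form moment estimator a2 = 2(r_MZ - r_DZ),
        c2 = 2 r_DZ - r_MZ."""
        for seed, (a2, c2, e2) in enumerate(
            [(0.2, 0.2, 0.6), (0.5, 0.3, 0.2), (0.6, 0.2, 0.2)]
        ):
            pairs = exact_moment_pairs([[a2]], [[c2]], [[e2]], 200, 200, seed=seed)
            res = UnivariateTwinModel(pairs).fit()
            mom = moment_estimate(pairs)
            assert res.a2 == pytest.approx(mom["a2"], abs=1e-3)
            assert res.c2 == pytest.approx(mom["c2"], abs=1e-3)

    def test_estimator_consistency_grid(self):
        """Mean absolute error of the standardized components < 0.02 at
        20,000 pairs per zygosity over a grid of truths."""
        grid = [(0.2, 0.2, 0.6), (0.5, 0.3, 0.2), (0.8, 0.0, 0.2)]
        errs = []
        for seed, (a2, c2, e2) in enumerate(grid):
            pairs = simulated_pairs([[a2]], [[c2]], [[e2]], 20_000, 20_000, seed=seed)
            res = UnivariateTwinModel(pairs).fit(starts=2)
            errs += [abs(res.a2 - a2), abs(res.c2 - c2), abs(res.e2 - e2)]
        assert np.mean(errs) < 0.02

    def test_scale_invariance_of_standardized_components(self):
        pairs = simulated_pairs([[0.5]], [[0.3]], [[0.2]], 500, 500, seed=6)
        res = UnivariateTwinModel(pairs).fit(starts=2)
        scaled = PairData(
            pairs.trait_labels, {z: 10.0 * a for z, a in pairs.groups.items()}
        )
        res10 = UnivariateTwinModel(scaled).fit(starts=2)
        assert res10.a2 == pytest.approx(res.a2, abs=1e-8)
        assert res10.c2 == pytest.approx(res.c2, abs=1e-8)
        assert res10.e2 == pytest.approx(res.e2, abs=1e-8)

    def test_components_sum_to_one(self):
        pairs = simulated_pairs([[0.4]], [[0.2]], [[0.4]], 100, 100, seed=8)
        res = UnivariateTwinModel(pairs).fit(starts=2)
        assert res.a2 + res.c2 + res.e2 == pytest.approx(1.0, abs=1e-8)
        assert res.e2 > 0

    def test_nesting_monotonicity(self):
        pairs = simulated_pairs([[0.5]], [[0.2]], [[0.3]], 150, 150, seed=5)
        m2 = {m: UnivariateTwinModel(pairs, model=m).fit(starts=2).minus2ll
              for m in ("ACE", "AE", "CE", "E")}
        sat = fit_saturated(pairs).minus2ll
        assert sat <= m2["ACE"] + 1e-6
        assert m2["ACE"] <= m2["AE"] + 1e-6
        assert m2["ACE"] <= m2["CE"] + 1e-6
        assert m2["AE"] <= m2["E"] + 1e-6

    def test_inadmissible_correlations_warn(self):
        # r_DZ > r_MZ cannot arise from non-negative A with the 1/0.5 structure
        rng = np.random.default_rng(0)
        base = rng.normal(size=(200, 2))
        shared = rng.normal(size=(200, 1))
        groups = {
            "MZ": base.copy(),
            "DZ": 0.3 * rng.normal(size=(200, 2)) + shared,
        }
        with pytest.warns(UserWarning, match="boundary"):
            UnivariateTwinModel(PairData(("x",), groups)).fit(starts=2)

    def test_fiml_uses_incomplete_pairs(self):
        pairs = simulated_pairs([[0.6]], [[0.2]], [[0.2]], 600, 600, seed=10)
        arr = pairs.groups["MZ"].copy()
        arr[:100, 1] = np.nan  # drop one co-twin in 100 pairs
        damaged = PairData(("x",), {"MZ": arr, "DZ": pairs.groups["DZ"]})
        res_cp = UnivariateTwinModel(damaged).fit(starts=2)
        res_fiml = UnivariateTwinModel(damaged, fiml=True).fit(starts=2)
        assert res_cp.n_pairs["MZ"] == 500
        assert res_fiml.n_pairs["MZ"] == 600
        assert res_fiml.a2 == pytest.approx(res_cp.a2, abs=0.1)


class TestProfileCI:
    def test_interval_contains_point_estimate(self):
        pairs = simulated_pairs([[0.6]], [[0.2]], [[0.2]], 252, 124, seed=1)
        res = UnivariateTwinModel(pairs).fit(starts=2)
        for comp in ("a2", "c2", "e2"):
            lo, hi = res.conf_int(comp)
            assert lo <= res.components[comp] <= hi

    def test_boundary_component_reports_zero_lower_limit(self):
        pairs = simulated_pairs([[0.7]], [[0.0]], [[0.3]], 252, 124, seed=3)
        res = UnivariateTwinModel(pairs).fit(starts=2)
        lo, hi = res.conf_int("c2")
        assert lo == 0.0

    def test_bootstrap_fallback_produces_interval(self):
        pairs = simulated_pairs([[0.5]], [[0.2]], [[0.3]], 100, 100, seed=7)
        res = UnivariateTwinModel(pairs).fit(starts=2)
        lo, hi = res.conf_int("a2", method="bootstrap", n_boot=40, seed=0)
        assert 0.0 <= lo < hi <= 1.0


class TestLrt:
    def test_identical_fits_give_zero(self):
        pairs = simulated_pairs([[0.5]], [[0.2]], [[0.3]], 100, 100, seed=2)
        res = UnivariateTwinModel(pairs).fit(starts=2)
        out = lrt(res, res)
        assert out.chi2 == pytest.approx(0.0, abs=1e-10)
        assert out.p == 1.0

    def test_degrees_of_freedom(self):
        pairs = simulated_pairs([[0.5]], [[0.2]], [[0.3]], 100, 100, seed=2)
        ace = UnivariateTwinModel(pairs).fit(starts=2)
        ae = UnivariateTwinModel(pairs, model="AE").fit(starts=2)
        sat = fit_saturated(pairs)
        assert lrt(ace, sat).df == 6
        assert lrt(ae, ace).df == 1
        assert lrt(ae, ace).p_mixture is not None


class TestCotwinCorrelations:
    def test_identical_values_give_unit_correlation(self):
        vals = np.arange(10.0)
        groups = {"MZ": np.column_stack([vals, vals])}
        out = cotwin_correlations(PairData(("x",), groups))
        assert out["MZ"]["r"] == pytest.approx(1.0)

    def test_double_entry_is_swap_invariant(self, rng):
        pairs = simulated_pairs([[0.6]], [[0.2]], [[0.2]], 100, 100, seed=4)
        a = cotwin_correlations(pairs)
        b = cotwin_correlations(pairs.swapped())
        assert a["MZ"]["r"] == pytest.approx(b["MZ"]["r"], abs=1e-12)
        assert a["DZ"]["r"] == pytest.approx(b["DZ"]["r"], abs=1e-12)

    def test_converges_to_implied_mz_correlation(self):
        pairs = simulated_pairs([[0.6]], [[0.2]], [[0.2]], 10_000, 100, seed=5)
        out = cotwin_correlations(pairs)
        assert out["MZ"]["r"] == pytest.approx(0.80, abs=0.02)
        lo, hi = out["MZ"]["ci"]
        assert lo < out["MZ"]["r"] < hi

    def test_zero_variance_flagged(self):
        groups = {"MZ": np.ones((5, 2))}
        out = cotwin_correlations(PairData(("x",), groups))
        assert not out["MZ"]["defined"]


@pytest.mark.parametrize(
    "alpha, m, expected",
    [(0.05, 37, 0.05 / 37), (0.05, 1, 0.05), (0.05, 5, 0.01)],
)
def test_bonferroni_threshold(alpha, m, expected):
    assert bonferroni_threshold(alpha, m) == pytest.approx(expected)
    assert bonferroni_threshold(0.05, 37) == pytest.approx(0.00135, abs=2e-5)


def test_bonferroni_rejects_bad_m():
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)
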