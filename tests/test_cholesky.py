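"""Multivariate Cholesky fits and component correlations."""

import numpy as np
import pandas as pd
import pytest

from conftest import exact_moment_pairs, simulated_pairs
from twinmorph.cholesky import (
    CholeskyTwinModel,
    correlation_matrix_pipeline,
    cross_wave_correlations,
)
from twinmorph.design import CohortDesign, WaveDesign, single_wave_design
from twinmorph.pairs import PairData
from twinmorph.simulate import simulate_cohort
from twinmorph.truth import truth_from_components
from twinmorph.univariate import UnivariateTwinModel


def _corrmat(r):
    return np.array([[1.0, r], [r, 1.0]])


class TestCholeskyFit:
    def test_loading_product_identity(self):
        X = np.array([[1.0, 0.0], [0.5, np.sqrt(0.75)]])
        assert np.allclose(X @ X.T, [[1.0, 0.5], [0.5, 1.0]])

    def test_self_consistency_at_matched_moments(self):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        E = np.eye(2)
        pairs = exact_moment_pairs(A, np.zeros((2, 2)), E, 400, 400)
        res = CholeskyTwinModel(pairs, model="AE").fit()
        assert np.allclose(res.A, A, atol=1e-3)
        assert np.allclose(res.E, E, atol=1e-3)

    def test_implied_components_psd(self):
        pairs = simulated_pairs(
            0.6 * _corrmat(0.4), 0.1 * _corrmat(0.2), 0.3 * _corrmat(0.1),
            300, 300, seed=3,
        )
        res = CholeskyTwinModel(pairs).fit(starts=2)
        for m in (res.A, res.C, res.E):
            assert np.linalg.eigvalsh(m).min() >= -1e-10
        assert np.allclose(res.phenotypic, res.A + res.C + res.E)

    def test_order_invariance(self):
        """Permuting trait order changes the factors but not the implied
        component matrices or correlations."""
        A = np.array([[0.7, 0.3], [0.3, 0.5]])
        C = np.array([[0.1, 0.05], [0.05, 0.2]])
        E = np.array([[0.2, 0.02], [0.02, 0.3]])
        pairs = exact_moment_pairs(A, C, E, 500, 500, seed=1)
        res_ab = CholeskyTwinModel(pairs).fit()
        res_ba = CholeskyTwinModel(pairs.select([1, 0])).fit()
        P = np.array([[0, 1.0], [1.0, 0]])
        for m_ab, m_ba in ((res_ab.A, res_ba.A), (res_ab.C, res_ba.C), (res_ab.E, res_ba.E)):
            assert np.allclose(P @ m_ab @ P, m_ba, atol=1e-4)
        ra_ab = res_ab.component_correlations().corr["A"][0, 1]
        ra_ba = res_ba.component_correlations().corr["A"][0, 1]
        assert ra_ab == pytest.approx(ra_ba, abs=1e-4)

    def test_univariate_reduction_oracle(self):
        """The k=1 Cholesky ACE fit reproduces the univariate module."""
        pairs = simulated_pairs([[0.55]], [[0.25]], [[0.2]], 250, 250, seed=7)
        uni = UnivariateTwinModel(pairs).fit(starts=2)
        chol = CholeskyTwinModel(pairs).fit(starts=2)
        comps = chol.standardized_components()
        assert comps["a2"].iloc[0] == pytest.approx(uni.a2, abs=1e-4)
        assert comps["c2"].iloc[0] == pytest.approx(uni.c2, abs=1e-4)
        assert chol.minus2ll == pytest.approx(uni.minus2ll, abs=1e-6)

    def test_parameter_recovery_over_ra_grid(self):
        """Bias and RMSE of the recovered genetic correlation stay small over
        a grid of true r_A (a2 = 0.7, e2 = 0.3 both traits)."""
        errors = []
        for seed, ra in enumerate((0.0, 0.3, 0.6, 0.9)):
            pairs = simulated_pairs(
                0.7 * _corrmat(ra), np.zeros((2, 2)), 0.3 * _corrmat(0.0),
                5000, 5000, seed=seed,
            )
            res = CholeskyTwinModel(pairs, model="AE").fit(starts=2)
            errors.append(res.component_correlations().corr["A"][0, 1] - ra)
        assert abs(np.mean(errors)) < 0.02
        assert np.sqrt(np.mean(np.square(errors))) < 0.05

    def test_ill_conditioned_rejected(self, rng):
        base = rng.normal(size=(50, 2))
        arr = np.column_stack([base[:, 0], base[:, 0], base[:, 1], base[:, 1]])
        pairs = PairData(("x", "y"), {"MZ": arr, "DZ": arr.copy()})
        with pytest.raises(ValueError, match="ill-conditioned"):
            CholeskyTwinModel(pairs)


class TestComponentCorrelations:
    def test_standardization_examples(self):
        pairs = exact_moment_pairs(
            np.array([[2.0, 1.0], [1.0, 2.0]]), np.zeros((2, 2)), np.eye(2),
            400, 400,
        )
        res = CholeskyTwinModel(pairs, model="AE").fit()
        cc = res.component_correlations()
        assert cc.corr["A"][0, 1] == pytest.approx(0.5, abs=5e-3)
        for name in cc.corr:
            r = cc.corr[name]
            assert np.allclose(r, r.T, equal_nan=True)
            assert np.allclose(np.diag(r), 1.0)
            assert np.nanmax(np.abs(r)) <= 1.0

    def test_diagonal_component_gives_identity(self):
        pairs = exact_moment_pairs(
            0.6 * np.eye(2), np.zeros((2, 2)), 0.4 * np.eye(2), 500, 500, seed=2
        )
        res = CholeskyTwinModel(pairs, model="AE").fit()
        assert abs(res.component_correlations().corr["A"][0, 1]) < 0.02

    def test_zero_variance_component_flagged_undefined(self):
        pairs = simulated_pairs(
            0.7 * _corrmat(0.5), np.zeros((2, 2)), 0.3 * _corrmat(0.1),
            400, 400, seed=5,
        )
        res = CholeskyTwinModel(pairs).fit(starts=2)
        cc = res.component_correlations()
        if res.C[0, 0] < 1e-10:  # C collapses to the boundary on AE-truth data
            assert not cc.defined["C"][0, 1]
            assert np.isnan(cc.corr["C"][0, 1])

    def test_profile_ci_brackets_estimate(self):
        pairs = simulated_pairs(
            0.6 * _corrmat(0.6), np.zeros((2, 2)), 0.4 * _corrmat(0.2),
            500, 500, seed=9,
        )
        res = CholeskyTwinModel(pairs, model="AE").fit(starts=2)
        ra = res.component_correlations().corr["A"][0, 1]
        lo, hi = res.corr_conf_int("A")
        assert lo <= ra <= hi
        assert -1.0 <= lo < hi <= 1.0


class TestPipelines:
    def _cohort(self, seed=0, n=600):
        blocks = _corrmat(0.9)
        truth = truth_from_components(
            ("w", "x", "y"),
            [0.7, 0.7, 0.7], [0.0, 0.0, 0.0], [0.3, 0.3, 0.3],
            r_A=np.block([[blocks, np.zeros((2, 1))], [np.zeros((1, 2)), np.eye(1)]]),
        )
        design = single_wave_design({("MZ", "male"): n, ("DZ", "male"): n})
        return simulate_cohort(design, truth, seed=seed)

    def test_pairwise_count_and_block_structure(self):
        table = self._cohort()
        out = correlation_matrix_pipeline(table, ["w", "x", "y"], sex="male",
                                          wave="initial")
        rec = out["records"]
        assert len(rec) == 3  # k(k-1)/2
        assert (rec["status"] == "ok").all()
        mats = out["matrices"]
        assert mats["r_A_AE"].loc["w", "x"] > 0.7
        assert abs(mats["r_A_AE"].loc["w", "y"]) < 0.25
        # AE and ACE estimates agree when shared environment is absent
        assert np.allclose(
            mats["r_A_AE"].to_numpy(), mats["r_A_ACE"].to_numpy(), atol=0.1
        )

    def test_pairwise_failure_isolated(self):
        table = self._cohort()
        table["z"] = table["w"]  # perfectly collinear: pairwise fits must fail
        out = correlation_matrix_pipeline(table, ["w", "x", "z"], sex="male",
                                          wave="initial")
        rec = out["records"]
        assert (rec["status"] != "ok").any()
        assert (rec["status"] == "ok").any()

    def test_cross_wave_degenerate_perfect_stability(self, rng):
        rows = []
        for i in range(30):
            v1, v2 = rng.normal(size=2)
            for wave in ("initial", "followup"):
                for t, v in zip((1, 2), (v1, v2)):
                    rows.append(
                        {"family_id": f"f{i}", "twin_index": t, "zygosity": "MZ",
                         "sex": "male", "wave": wave, "age": 12.0, "x": v}
                    )
        table = pd.DataFrame(rows)
        sub = table.pivot_table(index=["family_id", "twin_index"],
                                columns="wave", values="x")
        assert np.corrcoef(sub["initial"], sub["followup"])[0, 1] == pytest.approx(1.0)
        # the bivariate twin fit cannot proceed on an exactly singular
        # phenotypic covariance; the degenerate case is surfaced, not fudged
        with pytest.raises(ValueError):
            cross_wave_correlations(table, "x", sex="male")

    def test_cross_wave_too_few_individuals(self):
        rows = [
            {"family_id": "f0", "twin_index": 1, "zygosity": "MZ", "sex": "male",
             "wave": w, "age": 12.0, "x": v}
            for w, v in (("initial", 1.0), ("followup", 2.0))
        ]
        with pytest.raises(ValueError, match="3 individuals"):
            cross_wave_correlations(pd.DataFrame(rows), "x", sex="male")

    def test_cross_wave_recovery(self):
        unit = np.eye(2)
        truth = truth_from_components(
            ("x", "x"), [0.7, 0.6], [0.15, 0.2], [0.15, 0.2],
            r_A=unit + (1 - unit) * 0.9,
            r_C=unit + (1 - unit) * 0.9,
            r_E=unit + (1 - unit) * 0.4,
            trait_waves=("initial", "followup"),
        )
        counts = {("MZ", "male"): 2000, ("DZ", "male"): 2000}
        waves = tuple(
            WaveDesign(label=lbl, pair_counts=counts,
                       mean_age={"male": 12.0, "female": 12.0},
                       age_sd={"male": 0.4, "female": 0.4},
                       age_range={"male": (11, 13), "female": (11, 13)})
            for lbl in ("initial", "followup")
        )
        table = simulate_cohort(CohortDesign(waves=waves), truth, seed=13)
        cw = cross_wave_correlations(table, "x", sex="male")
        assert cw["r_A"] == pytest.approx(0.9, abs=0.05)
        assert cw["r_E"] == pytest.approx(0.4, abs=0.07)
        implied_rp = np.sqrt(0.7 * 0.6) * 0.9 + np.sqrt(0.15 * 0.2) * 0.9 \
            + np.sqrt(0.15 * 0.2) * 0.4
        assert cw["r_phenotypic"] == pytest.approx(implied_rp, abs=0.03)
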