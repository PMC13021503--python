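"""Multivariate Cholesky twin models and component correlations.

The Cholesky ACE (or AE) model decomposes the joint covariation of k traits
into additive-genetic, shared-environmental and unique-environmental
covariance matrices, each parameterized through a lower-triangular factor
(A = X Xt etc.) so the components are positive semidefinite by
construction.  Standardizing the off-diagonals of the fitted component
matrices yields the additive-genetic (r_A), shared-environmental (r_C) and
unique-environmental (r_E) cross-trait correlations.

The factorization is a parameterization, not a causal ordering: permuting
the traits changes the factors but not the implied component matrices or
any correlation derived from them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .likelihood import PairLikelihood, pair_sigma
from .pairs import PairData, cross_wave_pairs, to_pairs

_COMPONENT_OF = {"A": "X", "C": "Y", "E": "Z"}
_VAR_EPS = 1e-10  # below this a component variance cannot support a correlation
_CORR_CAP = 1.0 - 1e-6


def _vech_indices(k: int):
    return [(i, j) for i in range(k) for j in range(i + 1)]


def _to_lower(theta_part, k):
    L = np.zeros((k, k))
    for val, (i, j) in zip(theta_part, _vech_indices(k)):
        L[i, j] = val
    return L


def _nearest_psd_chol(m: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Cholesky factor of the PSD projection of a symmetric matrix."""
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    m = (v * np.clip(w, floor, None)) @ v.T
    return np.linalg.cholesky(m)


class CholeskyTwinModel:
    """k-trait Cholesky ACE/AE twin model (k = 1 reduces to the univariate model).

    Parameters
    ----------
    pairs : PairData
        Pair data over k traits (both zygosity groups required).
    model : {"ACE", "AE"}
        Whether a shared-environmental component is estimated.
    fiml : bool
        Full-information likelihood over incomplete pairs.
    """

    def __init__(self, pairs: PairData, model: str = "ACE", fiml: bool = False):
        if model not in ("ACE", "AE"):
            raise ValueError("model must be 'ACE' or 'AE'")
        self.model = model
        self.pairs = pairs
        self.k = pairs.n_traits
        self.lik = PairLikelihood(pairs, fiml=fiml)
        if set(self.lik.zygosities) != {"MZ", "DZ"}:
            raise ValueError("Cholesky twin models need both MZ and DZ groups")
        need = self.k + 2
        for z in self.lik.zygosities:
            if self.lik.n_pairs(z) < need:
                raise ValueError(f"need >= {need} pairs in group {z}, got {self.lik.n_pairs(z)}")
        # reject ill-conditioned phenotypic covariance up front
        within, _ = self.lik.moment_blocks("MZ")
        if np.linalg.cond(within) > 1e8:
            raise ValueError("phenotypic covariance is ill-conditioned for these traits")
        self._ntri = self.k * (self.k + 1) // 2
        self._has_c = model == "ACE"

    @classmethod
    def from_table(cls, table, traits, sex=None, wave=None, model="ACE", fiml=False):
        pairs = to_pairs(table, traits, sex=sex, wave=wave, include_incomplete=fiml)
        return cls(pairs, model=model, fiml=fiml)

    @property
    def n_params(self) -> int:
        return self.k + self._ntri * (3 if self._has_c else 2)

    # -- theta = [mu(k), vech(X), (vech(Y)), vech(Z)] --------------------
    def _unpack(self, theta):
        k = self.k
        mu = theta[:k]
        pos = k
        X = _to_lower(theta[pos : pos + self._ntri], k)
        pos += self._ntri
        Y = np.zeros((k, k))
        if self._has_c:
            Y = _to_lower(theta[pos : pos + self._ntri], k)
            pos += self._ntri
        Z = _to_lower(theta[pos : pos + self._ntri], k)
        return mu, X, Y, Z

    def _neg2ll(self, theta) -> float:
        mu, X, Y, Z = self._unpack(theta)
        return self.lik.neg2ll_model(mu, X @ X.T, Y @ Y.T, Z @ Z.T)

    def _bounds(self):
        k = self.k
        diag = {idx for idx, (i, j) in enumerate(_vech_indices(k)) if i == j}
        b = [(None, None)] * k
        for block, floor in (("X", 0.0), ("Y", 0.0), ("Z", 1e-4)):
            if block == "Y" and not self._has_c:
                continue
            for idx in range(self._ntri):
                b.append((floor, None) if idx in diag else (None, None))
        return b

    def _moment_components(self):
        """Method-of-moments A, C, E from double-entered blocks (scaled space)."""
        w_mz, x_mz = self.lik.moment_blocks("MZ")
        w_dz, x_dz = self.lik.moment_blocks("DZ")
        P = 0.5 * (w_mz + w_dz)
        A0 = 2.0 * (x_mz - x_dz)
        C0 = 2.0 * x_dz - x_mz
        E0 = P - x_mz
        if not self._has_c:
            A0 = A0 + np.clip(C0, 0, None) * 0  # AE start folds nothing in; C dropped
            C0 = np.zeros_like(C0)
        return A0, C0, E0

    def _starts(self, n_extra: int, seed: int):
        A0, C0, E0 = self._moment_components()
        parts = [np.zeros(self.k)]
        for m, is_c in ((A0, False), (C0, True), (E0, False)):
            if is_c and not self._has_c:
                continue
            L = _nearest_psd_chol(m, floor=1e-3)
            parts.append(np.array([L[i, j] for i, j in _vech_indices(self.k)]))
        base = np.concatenate(parts)
        starts = [base]
        rng = np.random.default_rng(seed)
        for _ in range(n_extra):
            starts.append(base + rng.normal(scale=0.05, size=base.size))
        return starts

    def fit(self, starts: int = 3, seed: int = 0, extra_start=None) -> "CholeskyResults":
        best = None
        cands = self._starts(starts - 1, seed)
        if extra_start is not None:
            cands.insert(0, np.asarray(extra_start, float))
        for x0 in cands:
            x0 = np.clip(x0, [b[0] if b[0] is not None else -np.inf for b in self._bounds()], None)
            res = optimize.minimize(
                self._neg2ll,
                x0,
                method="L-BFGS-B",
                bounds=self._bounds(),
                options={"ftol": 1e-13, "gtol": 1e-8, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        if not best.success:
            warnings.warn(
                f"Cholesky {self.model} fit convergence flag not met ({best.message})",
                stacklevel=2,
            )
        return CholeskyResults(self, best.x, float(best.fun), bool(best.success))

    # -- profile likelihood over a component correlation (bivariate) -----
    def profile_neg2ll_corr(self, component: str, t: float) -> float:
        """Profiled -2lnL with the cross-trait correlation of one component
        fixed at ``t`` (bivariate models only).

        The profiled component is reparameterized as two SDs and the fixed
        correlation; every other parameter is re-optimized.
        """
        if self.k != 2:
            raise ValueError("correlation profiling is implemented for bivariate fits")
        if component not in ("A", "C", "E"):
            raise ValueError("component must be 'A', 'C' or 'E'")
        if component == "C" and not self._has_c:
            raise ValueError("no C component under the AE model")
        if not -1.0 <= t <= 1.0:
            raise ValueError("a correlation must lie in [-1, 1]")

        others = [c for c in ("A", "C", "E") if c != component and (c != "C" or self._has_c)]
        floor = {"A": 0.0, "C": 0.0, "E": 1e-4}

        def build(theta):
            mu = theta[:2]
            pos = 2
            s1, s2 = theta[pos], theta[pos + 1]
            pos += 2
            fixed = np.array([[s1 * s1, t * s1 * s2], [t * s1 * s2, s2 * s2]])
            mats = {component: fixed}
            for name in others:
                L = _to_lower(theta[pos : pos + 3], 2)
                mats[name] = L @ L.T
                pos += 3
            return mu, mats.get("A", np.zeros((2, 2))), mats.get("C", np.zeros((2, 2))), mats["E"]

        def obj(theta):
            mu, A, C, E = build(theta)
            return self.lik.neg2ll_model(mu, A, C, E)

        bounds = [(None, None)] * 2 + [(floor[component], None)] * 2
        for name in others:
            f = floor[name]
            bounds += [(f, None), (None, None), (f, None)]

        # warm starts from the moment solution
        A0, C0, E0 = self._moment_components()
        moments = {"A": A0, "C": C0, "E": E0}
        prof = moments[component]
        s0 = np.sqrt(np.clip(np.diag(prof), 1e-3, None))
        x0 = [0.0, 0.0, s0[0], s0[1]]
        for name in others:
            L = _nearest_psd_chol(moments[name], floor=1e-3)
            x0 += [L[0, 0], L[1, 0], L[1, 1]]
        x0 = np.asarray(x0)
        best = None
        for start in (x0, x0 * 0.7 + 0.1):
            res = optimize.minimize(
                obj, np.clip(start, [b[0] if b[0] is not None else -np.inf for b in bounds], None),
                method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-13, "gtol": 1e-8, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        return float(best.fun)


@dataclass
class ComponentCorrelations:
    """Standardized cross-trait correlations of the fitted components.

    ``corr[comp][i, j]`` is undefined (NaN, ``defined`` False) when a
    corresponding diagonal component variance is numerically zero; values
    that hit |r| = 1 are capped and flagged in ``boundary``.
    """

    traits: tuple[str, ...]
    corr: dict[str, np.ndarray]
    defined: dict[str, np.ndarray]
    boundary: dict[str, np.ndarray]
    ci: dict[str, dict[tuple[int, int], tuple[float, float]]] = field(default_factory=dict)

    def matrix(self, component: str) -> pd.DataFrame:
        return pd.DataFrame(self.corr[component], index=self.traits, columns=self.traits)


class CholeskyResults:
    """Fitted Cholesky twin model: loadings, implied components, correlations."""

    def __init__(self, model: CholeskyTwinModel, theta, minus2ll: float, converged: bool):
        self._model = model
        self._theta = np.asarray(theta, float)
        self.minus2ll = float(minus2ll)
        self.converged = converged
        self.model = model.model
        self.traits = model.pairs.trait_labels
        mu, Xs, Ys, Zs = model._unpack(self._theta)
        S = np.diag(model.lik.scale)
        self.X, self.Y, self.Z = S @ Xs, S @ Ys, S @ Zs
        self.A = self.X @ self.X.T
        self.C = self.Y @ self.Y.T
        self.E = self.Z @ self.Z.T
        self.means = model.lik.unscale_mu(mu)
        self.n_params = model.n_params
        self.n_pairs = {z: model.lik.n_pairs(z) for z in model.lik.zygosities}

    @property
    def phenotypic(self) -> np.ndarray:
        """Implied within-twin phenotypic covariance A + C + E."""
        return self.A + self.C + self.E

    def standardized_components(self) -> pd.DataFrame:
        p = np.diag(self.phenotypic)
        return pd.DataFrame(
            {
                "a2": np.diag(self.A) / p,
                "c2": np.diag(self.C) / p,
                "e2": np.diag(self.E) / p,
            },
            index=list(self.traits),
        )

    def refit_from(self, restricted) -> "CholeskyResults":
        return self._model.fit(extra_start=self._theta)

    def component_correlations(self, ci: bool = False, level: float = 0.95) -> ComponentCorrelations:
        """Standardize the fitted component covariances into correlations."""
        k = len(self.traits)
        comps = {"A": self.A, "E": self.E}
        if self.model == "ACE":
            comps["C"] = self.C
        corr, defined, boundary = {}, {}, {}
        cis: dict[str, dict] = {}
        for name, m in comps.items():
            d = np.diag(m)
            ok = d > _VAR_EPS
            r = np.full((k, k), np.nan)
            bnd = np.zeros((k, k), dtype=bool)
            for i in range(k):
                for j in range(k):
                    if i == j:
                        r[i, j] = 1.0 if ok[i] else np.nan
                    elif ok[i] and ok[j]:
                        val = m[i, j] / np.sqrt(d[i] * d[j])
                        if abs(val) > 1.0 - 1e-9:
                            bnd[i, j] = True
                            val = np.sign(val) * 1.0
                        r[i, j] = val
            corr[name] = r
            defined[name] = np.outer(ok, ok)
            boundary[name] = bnd
            if ci and k == 2 and ok.all():
                cis[name] = {(0, 1): self.corr_conf_int(name, level=level)}
        return ComponentCorrelations(
            traits=self.traits, corr=corr, defined=defined, boundary=boundary, ci=cis
        )

    def corr_conf_int(
        self, component: str, level: float = 0.95, n_boot: int = 1000, seed: int = 0
    ) -> tuple[float, float]:
        """Profile-likelihood CI for the bivariate component correlation.

        Bounds stuck at the boundary are reported as exactly -1 or 1; if the
        profile fails to bracket, a parametric-bootstrap percentile interval
        is used instead.
        """
        model = self._model
        if model.k != 2:
            raise ValueError("correlation CIs are implemented for bivariate fits")
        comps = {"A": self.A, "C": self.C, "E": self.E}
        d = np.diag(comps[component])
        if np.any(d <= _VAR_EPS):
            raise ValueError(f"r_{component} undefined: component variance is zero")
        est = float(np.clip(comps[component][0, 1] / np.sqrt(d[0] * d[1]), -1.0, 1.0))
        q = float(stats.chi2.ppf(level, 1))
        ref = self.minus2ll

        def f(t):
            return model.profile_neg2ll_corr(component, t) - (ref + q)

        try:
            if est <= -_CORR_CAP or f(-_CORR_CAP) <= 0.0:
                lo = -1.0
            else:
                lo = float(optimize.brentq(f, -_CORR_CAP, min(est, _CORR_CAP), xtol=1e-4))
            if est >= _CORR_CAP or f(_CORR_CAP) <= 0.0:
                hi = 1.0
            else:
                hi = float(optimize.brentq(f, max(est, -_CORR_CAP), _CORR_CAP, xtol=1e-4))
        except ValueError:
            warnings.warn(
                "profile CI failed to bracket; falling back to parametric bootstrap",
                stacklevel=2,
            )
            return self._bootstrap_corr_ci(component, level, n_boot, seed)
        return (lo, hi)

    def _bootstrap_corr_ci(self, component, level, n_boot, seed):
        rng = np.random.default_rng(seed)
        model = self._model
        S = np.diag(1.0 / model.lik.scale)
        A, C, E = S @ self.A @ S, S @ self.C @ S, S @ self.E @ S
        mu, *_ = model._unpack(self._theta)
        vals = []
        for _ in range(n_boot):
            groups = {}
            for z in model.lik.zygosities:
                n = model.lik.n_pairs(z)
                sig = pair_sigma(A, C, E, z)
                groups[z] = rng.multivariate_normal(np.concatenate([mu, mu]), sig, size=n)
            rep = CholeskyTwinModel(
                PairData(trait_labels=model.pairs.trait_labels, groups=groups),
                model=model.model,
            ).fit(starts=1, seed=int(rng.integers(2**31)))
            m = {"A": rep.A, "C": rep.C, "E": rep.E}[component]
            dd = np.diag(m)
            if np.all(dd > _VAR_EPS):
                vals.append(float(np.clip(m[0, 1] / np.sqrt(dd[0] * dd[1]), -1, 1)))
        alpha = 1.0 - level
        lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
        return (float(lo), float(hi))

    def summary(self) -> str:
        cc = self.component_correlations()
        lines = [
            f"Cholesky twin model: {self.model} over {len(self.traits)} trait(s)",
            "traits: " + ", ".join(self.traits),
            "pairs: " + ", ".join(f"{z}={n}" for z, n in sorted(self.n_pairs.items())),
            f"-2lnL = {self.minus2ll:.4f}   parameters = {self.n_params}   "
            f"converged = {self.converged}",
            "standardized components:",
            self.standardized_components().round(3).to_string(),
        ]
        for name in cc.corr:
            lines.append(f"r_{name}:")
            lines.append(cc.matrix(name).round(3).to_string())
        return "\n".join(lines)

    def __repr__(self) -> str:
        return f"<CholeskyResults {self.model} k={len(self.traits)} -2lnL={self.minus2ll:.2f}>"


def fit_cholesky(pairs: PairData, model: str = "ACE", **kwargs) -> CholeskyResults:
    """Functional wrapper: fit a Cholesky twin model on pair data."""
    return CholeskyTwinModel(pairs, model=model).fit(**kwargs)


def component_correlations(fit: CholeskyResults, **kwargs) -> ComponentCorrelations:
    """Functional wrapper over :meth:`CholeskyResults.component_correlations`."""
    return fit.component_correlations(**kwargs)


def correlation_matrix_pipeline(
    table: pd.DataFrame,
    traits,
    sex=None,
    wave=None,
    ci: bool = False,
    starts: int = 2,
) -> dict:
    """All-pairs bivariate genetic/environmental correlation matrices.

    For every unordered trait pair (ordered alphabetically inside the fit,
    which is immaterial by order invariance), fit the AE model first, then
    confirm with the ACE model; the AE estimate is the headline r_A because
    small shared-environmental variances leave r_C unidentified at twin-study
    sample sizes.  Pairwise failures are recorded and skipped, never
    aborting the rest of the matrix.

    Returns a dict with per-component DataFrame matrices and a tidy record
    table (including the AE-vs-ACE difference in r_A per pair).
    """
    traits = list(traits)
    k = len(traits)
    mats = {
        name: pd.DataFrame(np.eye(k), index=traits, columns=traits)
        for name in ("r_A_AE", "r_A_ACE", "r_E", "r_C")
    }
    mats["r_C"].values[:] = np.where(np.eye(k), 1.0, np.nan)
    records = []
    for i in range(k):
        for j in range(i + 1, k):
            pair = tuple(sorted((traits[i], traits[j])))
            rec = {"trait_1": traits[i], "trait_2": traits[j], "sex": sex, "wave": wave}
            try:
                res_ae = CholeskyTwinModel.from_table(
                    table, list(pair), sex=sex, wave=wave, model="AE"
                ).fit(starts=starts)
                res_ace = CholeskyTwinModel.from_table(
                    table, list(pair), sex=sex, wave=wave, model="ACE"
                ).fit(starts=starts)
            except Exception as exc:  # isolate pairwise failures
                rec.update({"status": f"failed: {exc}"})
                records.append(rec)
                continue
            cc_ae = res_ae.component_correlations(ci=ci)
            cc_ace = res_ace.component_correlations(ci=ci)
            ra_ae = float(cc_ae.corr["A"][0, 1])
            ra_ace = float(cc_ace.corr["A"][0, 1])
            re_ = float(cc_ae.corr["E"][0, 1])
            rc = float(cc_ace.corr["C"][0, 1])
            rec.update(
                {
                    "status": "ok",
                    "r_A_AE": ra_ae,
                    "r_A_ACE": ra_ace,
                    "delta_r_A": ra_ace - ra_ae,
                    "r_E": re_,
                    "r_C": rc,
                    "converged_AE": res_ae.converged,
                    "converged_ACE": res_ace.converged,
                }
            )
            if ci:
                rec["r_A_AE_ci"] = cc_ae.ci.get("A", {}).get((0, 1))
                rec["r_C_ci"] = cc_ace.ci.get("C", {}).get((0, 1))
            for name, val in (
                ("r_A_AE", ra_ae),
                ("r_A_ACE", ra_ace),
                ("r_E", re_),
                ("r_C", rc),
            ):
                mats[name].iloc[i, j] = mats[name].iloc[j, i] = val
            records.append(rec)
    return {"matrices": mats, "records": pd.DataFrame(records)}


def cross_wave_correlations(
    table: pd.DataFrame,
    trait: str,
    sex=None,
    waves=("initial", "followup"),
    model: str = "ACE",
    ci: bool = False,
    level: float = 0.95,
) -> dict:
    """Stability of one trait across two waves: phenotypic r, r_A and r_E.

    The phenotypic cross-wave correlation is computed on individuals (one
    entry per person with both waves observed); r_A and r_E come from a
    bivariate Cholesky fit treating the wave-1 and wave-2 measurements as
    two traits.
    """
    sub = table if sex is None else table[table["sex"] == sex]
    wide = sub.pivot_table(
        index=["family_id", "twin_index"], columns="wave", values=trait, aggfunc="first"
    )
    if waves[0] not in wide.columns or waves[1] not in wide.columns:
        raise ValueError(f"trait {trait!r} not measured at both waves {waves}")
    wide = wide[[waves[0], waves[1]]].dropna()
    n_ind = len(wide)
    if n_ind < 3:
        raise ValueError("need at least 3 individuals with both waves observed")
    x, y = wide.iloc[:, 0].to_numpy(), wide.iloc[:, 1].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        r_p, ci_p = 1.0, (1.0, 1.0)  # degenerate perfect stability
    else:
        r_p = float(np.corrcoef(x, y)[0, 1])
        zcrit = stats.norm.ppf(0.5 + level / 2.0)
        if abs(r_p) < 1 and n_ind > 3:
            lohi = np.tanh(np.arctanh(r_p) + np.array([-1, 1]) * zcrit / np.sqrt(n_ind - 3))
            ci_p = (float(lohi[0]), float(lohi[1]))
        else:
            ci_p = (r_p, r_p)

    pairs = cross_wave_pairs(table, trait, sex=sex, waves=waves)
    res = CholeskyTwinModel(pairs, model=model).fit()
    cc = res.component_correlations(ci=ci, level=level)
    out = {
        "trait": trait,
        "sex": sex,
        "r_phenotypic": r_p,
        "r_phenotypic_ci": ci_p,
        "n_individuals": n_ind,
        "r_A": float(cc.corr["A"][0, 1]),
        "r_E": float(cc.corr["E"][0, 1]),
        "fit": res,
    }
    if ci:
        out["r_A_ci"] = cc.ci.get("A", {}).get((0, 1))
        out["r_E_ci"] = cc.ci.get("E", {}).get((0, 1))
    return out
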