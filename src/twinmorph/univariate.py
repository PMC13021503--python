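"""Univariate twin models: saturated and ACE-family maximum likelihood.

The ACE model decomposes one trait's variance into additive-genetic (A),
shared-environmental (C) and unique-environmental (E) parts using the
different cross-twin covariance they imply: within-twin variance
a2 + c2 + e2, MZ cross-twin covariance a2 + c2, DZ cross-twin covariance
0.5 a2 + c2.  Fitting maximizes the two-group normal likelihood with a
single grand mean per trait; path coefficients are constrained non-negative
(parameterized through component variances >= 0), and the unique
environment, which absorbs measurement error, is kept strictly positive.

The entry points follow the Model -> Results convention:

>>> model = UnivariateTwinModel.from_table(table, "height", sex="male",
...                                        wave="initial", model="ACE")
>>> res = model.fit()
>>> res.a2, res.conf_int("a2")
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .likelihood import PairLikelihood
from .pairs import PairData, to_pairs

MODELS = ("ACE", "AE", "CE", "E")
_E_FLOOR = 1e-8  # scaled space; unique environment stays strictly positive
_PROFILE_CAP = 1.0 - 1e-6


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni-corrected per-test significance level alpha / m."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    return float(alpha) / int(m)


def cotwin_correlations(pairs: PairData, level: float = 0.95) -> dict:
    """Per-zygosity co-twin correlations by double entry, with Fisher-z CIs.

    Each pair contributes both orderings (equivalent to an intraclass
    formulation), removing the arbitrary twin labelling; the Fisher-z CI
    uses the number of *pairs* as effective n, not the doubled count.
    """
    out = {}
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    for z, arr in pairs.complete().groups.items():
        n = arr.shape[0]
        if n < 3:
            raise ValueError(f"need >= 3 complete pairs in {z}, got {n}")
        k = arr.shape[1] // 2
        if k != 1:
            raise ValueError("co-twin correlations are defined per single trait")
        x = np.concatenate([arr[:, 0], arr[:, 1]])
        y = np.concatenate([arr[:, 1], arr[:, 0]])
        if np.std(x) == 0:
            out[z] = {"r": np.nan, "ci": (np.nan, np.nan), "n_pairs": n, "defined": False}
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if n > 3 and abs(r) < 1:
            se = 1.0 / np.sqrt(n - 3)
            lo, hi = np.tanh(np.arctanh(r) + np.array([-1, 1]) * zcrit * se)
        else:
            lo = hi = np.nan
        out[z] = {"r": r, "ci": (float(lo), float(hi)), "n_pairs": n, "defined": True}
    return out


def moment_estimate(pairs: PairData) -> dict:
    """Closed-form moment (Falconer-style) ACE estimator from co-twin correlations.

    a2 = 2 (r_MZ - r_DZ), c2 = 2 r_DZ - r_MZ, e2 = 1 - r_MZ.  Valid as a
    point estimator when the solution is interior; used as an independent
    oracle for the ML fit and as its starting value.
    """
    cc = cotwin_correlations(pairs)
    if "MZ" not in cc or "DZ" not in cc:
        raise ValueError("moment estimator needs both zygosity groups")
    r_mz, r_dz = cc["MZ"]["r"], cc["DZ"]["r"]
    return {
        "a2": 2.0 * (r_mz - r_dz),
        "c2": 2.0 * r_dz - r_mz,
        "e2": 1.0 - r_mz,
        "r_MZ": r_mz,
        "r_DZ": r_dz,
    }


@dataclass
class SaturatedResults:
    """Closed-form saturated (unstructured) two-group fit."""

    minus2ll: float
    n_params: int
    group_means: dict[str, np.ndarray]
    group_covs: dict[str, np.ndarray]
    converged: bool = True
    model: str = "SAT"


def fit_saturated(pairs: PairData) -> SaturatedResults:
    """Fit the saturated model: free means/variances/covariances per group.

    The MLE matches the sample moments, so no iteration is needed; for the
    univariate two-group complete-pairs case this has 10 parameters.
    """
    lik = PairLikelihood(pairs, fiml=False)
    for z, arr in lik.groups.items():
        if arr.shape[0] < 2:
            raise ValueError(f"need >= 2 complete pairs in group {z}")
    m2ll, n_params = lik.saturated()
    scale2 = np.concatenate([lik.scale, lik.scale])
    shift2 = np.concatenate([lik.shift, lik.shift])
    means = {z: shift2 + scale2 * st.mean for z, st in lik.stats.items()}
    covs = {z: st.cov * np.outer(scale2, scale2) for z, st in lik.stats.items()}
    return SaturatedResults(minus2ll=m2ll, n_params=n_params, group_means=means, group_covs=covs)


class UnivariateTwinModel:
    """One-trait ACE-family twin model fitted by maximum likelihood.

    Parameters
    ----------
    pairs : PairData
        Univariate pair data (both zygosity groups for ACE/AE/CE).
    model : {"ACE", "AE", "CE", "E"}
        Which component variances are free; dropped components are fixed at
        zero.
    fiml : bool
        Include incomplete pairs through the full-information likelihood.
    """

    def __init__(self, pairs: PairData, model: str = "ACE", fiml: bool = False):
        if model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if pairs.n_traits != 1:
            raise ValueError("UnivariateTwinModel expects exactly one trait")
        self.model = model
        self.pairs = pairs
        self.lik = PairLikelihood(pairs, fiml=fiml)
        if model in ("ACE", "AE", "CE") and set(self.lik.zygosities) != {"MZ", "DZ"}:
            raise ValueError(f"{model} needs both MZ and DZ groups")
        for z in self.lik.zygosities:
            if self.lik.n_pairs(z) < 2:
                raise ValueError(f"need >= 2 pairs in group {z}")
        self._free_a = "A" in model
        self._free_c = "C" in model

    @classmethod
    def from_table(cls, table, trait, sex=None, wave=None, model="ACE", fiml=False):
        pairs = to_pairs(table, trait, sex=sex, wave=wave, include_incomplete=fiml)
        return cls(pairs, model=model, fiml=fiml)

    # -- parameter vector: (mu, [va], [vc], ve) in scaled space ----------
    def _unpack(self, theta):
        i = 1
        va = vc = 0.0
        if self._free_a:
            va = theta[i]
            i += 1
        if self._free_c:
            vc = theta[i]
            i += 1
        return theta[0], va, vc, theta[i]

    def _neg2ll(self, theta) -> float:
        mu, va, vc, ve = self._unpack(theta)
        return self.lik.neg2ll_model(
            np.array([mu]), np.array([[va]]), np.array([[vc]]), np.array([[ve]])
        )

    def _neg2ll_jac(self, theta):
        """Objective with analytic gradient (complete-pairs fast path)."""
        mu, va, vc, ve = self._unpack(theta)
        f, g4 = self.lik.neg2ll_grad_univariate(mu, va, vc, ve)
        idx = [0]
        if self._free_a:
            idx.append(1)
        if self._free_c:
            idx.append(2)
        idx.append(3)
        return f, g4[idx]

    @property
    def n_params(self) -> int:
        return 2 + self._free_a + self._free_c

    def _starts(self, n_extra: int, seed: int):
        """Moment-estimator start plus jittered copies."""
        within_mz, cross_mz = self.lik.moment_blocks("MZ") if "MZ" in self.lik.zygosities else (None, None)
        v = 1.0
        r_mz = r_dz = 0.0
        if within_mz is not None:
            r_mz = float(cross_mz[0, 0] / within_mz[0, 0])
        if "DZ" in self.lik.zygosities:
            w_dz, c_dz = self.lik.moment_blocks("DZ")
            r_dz = float(c_dz[0, 0] / w_dz[0, 0])
        if r_dz > r_mz or r_dz < 0.5 * r_mz - 0.05:
            warnings.warn(
                "co-twin correlations outside the admissible ACE region "
                f"(r_MZ={r_mz:.3f}, r_DZ={r_dz:.3f}); a boundary solution is likely",
                stacklevel=3,
            )
        a20 = float(np.clip(2 * (r_mz - r_dz), 0.02, 0.95))
        c20 = float(np.clip(2 * r_dz - r_mz, 0.02, 0.95))
        e20 = max(1.0 - a20 - c20, 0.03)
        base = [0.0]
        if self._free_a:
            base.append(a20 * v)
        if self._free_c:
            base.append(c20 * v)
        base.append(e20 * v)
        starts = [np.array(base)]
        rng = np.random.default_rng(seed)
        for _ in range(n_extra):
            jit = starts[0].copy()
            jit[1:] = np.clip(jit[1:] * rng.uniform(0.3, 3.0, size=jit.size - 1), 1e-4, None)
            jit[0] += rng.normal(scale=0.1)
            starts.append(jit)
        return starts

    def _bounds(self):
        b = [(None, None)]
        if self._free_a:
            b.append((0.0, None))
        if self._free_c:
            b.append((0.0, None))
        b.append((_E_FLOOR, None))
        return b

    def fit(self, starts: int = 5, seed: int = 0, extra_start=None) -> "UnivariateTwinResults":
        """Maximize the likelihood from multiple starting values."""
        best = None
        cands = self._starts(starts - 1, seed)
        if extra_start is not None:
            cands.insert(0, np.asarray(extra_start, float))
        analytic = not self.lik.fiml
        for x0 in cands:
            res = optimize.minimize(
                self._neg2ll_jac if analytic else self._neg2ll,
                x0,
                jac=analytic,
                method="L-BFGS-B",
                bounds=self._bounds(),
                options={"ftol": 1e-15, "gtol": 1e-9, "maxiter": 1000},
            )
            if best is None or res.fun < best.fun:
                best = res
        if analytic:
            best = self._newton_polish(best)
        if not best.success and np.max(np.abs(np.atleast_1d(best.jac))) < 1e-4:
            best.success = True  # tolerance-level stall at a stationary point
        if not best.success:
            warnings.warn(
                f"{self.model} fit did not satisfy the convergence criterion "
                f"({best.message}); returning best point found",
                stacklevel=2,
            )
        return UnivariateTwinResults(self, best.x, float(best.fun), bool(best.success))

    def _newton_polish(self, res, max_steps: int = 8):
        """Damped Newton steps on the interior coordinates.

        L-BFGS-B stops on relative-f tolerance; a couple of Newton steps with
        the exact gradient (and a finite-difference Hessian of it) pin the
        optimum tightly enough that standardized components are reproducible
        to ~1e-10 across affine rescalings of the data.
        """
        lo = np.array([b[0] if b[0] is not None else -np.inf for b in self._bounds()])
        x = res.x.copy()
        f, g = self._neg2ll_jac(x)
        for _ in range(max_steps):
            free = (x > lo + 1e-9) | (g < 0)
            if np.max(np.abs(g[free])) < 1e-10:
                break
            h = 1e-6 * np.maximum(np.abs(x), 1e-3)
            H = np.zeros((x.size, x.size))
            for j in range(x.size):
                xp = x.copy()
                xp[j] += h[j]
                H[:, j] = (self._neg2ll_jac(xp)[1] - g) / h[j]
            H = 0.5 * (H + H.T)
            idx = np.where(free)[0]
            try:
                step = np.linalg.solve(
                    H[np.ix_(idx, idx)] + 1e-10 * np.eye(idx.size), -g[idx]
                )
            except np.linalg.LinAlgError:
                break
            x_new = x.copy()
            x_new[idx] += step
            x_new = np.maximum(x_new, lo)
            f_new, g_new = self._neg2ll_jac(x_new)
            if not np.isfinite(f_new) or f_new > f + 1e-9:
                break
            x, f, g = x_new, f_new, g_new
        res.x, res.fun, res.jac = x, f, g
        return res

    # -- profiling -------------------------------------------------------
    def profile_neg2ll(self, component: str, t: float, x0=None) -> float:
        """Profiled -2lnL with the standardized component fixed at ``t``.

        The constraint fixes e.g. a2 = va/(va+vc+ve) = t by expressing va
        through the remaining free variances; the grand mean and the other
        variances are re-optimized.
        """
        if component not in ("a2", "c2", "e2"):
            raise ValueError("component must be a2, c2 or e2")
        if not 0.0 <= t <= _PROFILE_CAP:
            raise ValueError("component value must lie in [0, 1)")
        comp_free = {"a2": self._free_a, "c2": self._free_c, "e2": True}[component]
        if not comp_free:
            raise ValueError(f"{component} is fixed at 0 under the {self.model} model")

        others = [c for c in ("a2", "c2", "e2") if c != component and
                  {"a2": self._free_a, "c2": self._free_c, "e2": True}[c]]
        ratio = 0.0 if t == 0.0 else t / (1.0 - t)
        comp_idx = {"a2": 1, "c2": 2, "e2": 3}
        analytic = not self.lik.fiml

        def _values(theta):
            vals = {component: ratio * max(sum(theta[1:]), 1e-12)}
            if t == 0.0:
                vals[component] = 0.0
            for name, val in zip(others, theta[1:]):
                vals[name] = val
            return vals.get("a2", 0.0), vals.get("c2", 0.0), vals.get("e2", _E_FLOOR)

        def full(theta):
            va, vc, ve = _values(theta)
            if analytic:
                f, g4 = self.lik.neg2ll_grad_univariate(theta[0], va, vc, ve)
                grad = np.empty(len(theta))
                grad[0] = g4[0]
                for j, name in enumerate(others, start=1):
                    grad[j] = g4[comp_idx[name]] + ratio * g4[comp_idx[component]]
                return f, grad
            return self.lik.neg2ll_model(
                np.array([theta[0]]), np.array([[va]]), np.array([[vc]]),
                np.array([[ve]]),
            )

        bounds = [(None, None)] + [
            ((_E_FLOOR, None) if name == "e2" else (0.0, None)) for name in others
        ]
        starts = [np.array([0.0] + [0.3] * len(others))]
        if x0 is not None:
            starts.insert(0, np.asarray(x0, float))
        best = None
        for i, start in enumerate(starts):
            res = optimize.minimize(
                full, start, jac=analytic, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-15, "gtol": 1e-9, "maxiter": 1000},
            )
            if best is None or res.fun < best.fun:
                best = res
            # warm start succeeded: skip the generic fallback
            if i == 0 and x0 is not None and res.success and np.isfinite(res.fun):
                break
        return float(best.fun)


@dataclass
class LrtResult:
    """Likelihood-ratio test of a restricted against a full model."""

    chi2: float
    df: int
    p: float
    p_mixture: float | None = None  # 50:50 chi2(0)/chi2(1) boundary reference

    def __str__(self) -> str:
        s = f"chi2({self.df}) = {self.chi2:.4f}, p = {self.p:.4g}"
        if self.p_mixture is not None:
            s += f" (boundary-mixture p = {self.p_mixture:.4g})"
        return s


def lrt(restricted, full) -> LrtResult:
    """Likelihood-ratio test: chi2 = Delta(-2lnL), df = Delta(n params).

    If the "full" model lands above the restricted one by more than
    numerical tolerance (a failed optimization), the full model is refitted
    starting from the restricted solution.
    """
    chi2 = restricted.minus2ll - full.minus2ll
    if chi2 < -1e-6 and hasattr(full, "refit_from"):
        full = full.refit_from(restricted)
        chi2 = restricted.minus2ll - full.minus2ll
    chi2 = max(float(chi2), 0.0)
    df = full.n_params - restricted.n_params
    if df < 0:
        raise ValueError("restricted model has more parameters than the full model")
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    if chi2 <= 1e-12:
        p = 1.0
    p_mix = None
    if df == 1:
        p_mix = 0.5 * float(stats.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
    return LrtResult(chi2=chi2, df=df, p=p, p_mixture=p_mix)


class UnivariateTwinResults:
    """Estimates, uncertainty and diagnostics of a univariate twin fit."""

    def __init__(self, model: UnivariateTwinModel, theta: np.ndarray, minus2ll: float, converged: bool):
        self._model = model
        self._theta = np.asarray(theta, float)
        self.minus2ll = minus2ll
        self.converged = converged
        self.model = model.model
        self.trait = model.pairs.trait_labels[0]
        mu, va, vc, ve = model._unpack(self._theta)
        s2 = float(model.lik.scale[0]) ** 2
        self.variances = {"a2": va * s2, "c2": vc * s2, "e2": ve * s2}
        total = va + vc + ve
        self.a2 = float(va / total)
        self.c2 = float(vc / total)
        self.e2 = float(ve / total)
        self.paths = {k: float(np.sqrt(v)) for k, v in self.variances.items()}
        self.mean = float(model.lik.unscale_mu(np.array([mu]))[0])
        self.n_params = model.n_params
        self.n_pairs = {z: model.lik.n_pairs(z) for z in model.lik.zygosities}

    @property
    def components(self) -> dict[str, float]:
        return {"a2": self.a2, "c2": self.c2, "e2": self.e2}

    def refit_from(self, restricted) -> "UnivariateTwinResults":
        """Refit this results' model warm-started at another solution."""
        start = self._theta.copy()
        return self._model.fit(extra_start=start)

    def conf_int(
        self,
        component: str = "a2",
        level: float = 0.95,
        method: str = "profile",
        n_boot: int = 1000,
        seed: int = 0,
    ) -> tuple[float, float]:
        """Confidence interval for a standardized component in [0, 1].

        ``profile`` inverts the likelihood-ratio statistic against the
        chi-square(1) quantile (3.84 at 95%); a bound stuck at the parameter
        boundary is reported as exactly 0 or 1.  ``bootstrap`` is the
        parametric-bootstrap percentile fallback.
        """
        if method == "bootstrap":
            return self._bootstrap_ci(component, level, n_boot, seed)
        if not self.converged:
            warnings.warn("profiling a non-converged fit", stacklevel=2)
        q = float(stats.chi2.ppf(level, 1))
        est = self.components[component]
        ref = self.minus2ll

        # warm start: grand mean plus the other fitted variances (scaled space)
        model = self._model
        mu, va, vc, ve = model._unpack(self._theta)
        fitted = {"a2": va, "c2": vc, "e2": ve}
        others = [
            c for c in ("a2", "c2", "e2")
            if c != component and {"a2": model._free_a, "c2": model._free_c, "e2": True}[c]
        ]
        warm = np.array([mu] + [max(fitted[c], 1e-4) for c in others])

        def f(t):
            return self._model.profile_neg2ll(component, t, x0=warm) - (ref + q)

        try:
            if est <= 1e-6 or f(0.0) <= 0.0:
                lo = 0.0
            else:
                lo = float(optimize.brentq(f, 0.0, est, xtol=5e-5))
            if est >= _PROFILE_CAP or f(_PROFILE_CAP) <= 0.0:
                hi = 1.0
            else:
                hi = float(optimize.brentq(f, est, _PROFILE_CAP, xtol=5e-5))
        except ValueError:
            warnings.warn(
                "profile CI failed to bracket; falling back to parametric bootstrap",
                stacklevel=2,
            )
            return self._bootstrap_ci(component, level, n_boot, seed)
        return (max(lo, 0.0), min(hi, 1.0))

    def _bootstrap_ci(self, component, level, n_boot, seed):
        from .likelihood import pair_sigma

        rng = np.random.default_rng(seed)
        model = self._model
        mu, va, vc, ve = model._unpack(self._theta)
        vals = []
        for _ in range(n_boot):
            groups = {}
            for z in model.lik.zygosities:
                n = model.lik.n_pairs(z)
                sig = pair_sigma(np.array([[va]]), np.array([[vc]]), np.array([[ve]]), z)
                groups[z] = rng.multivariate_normal(np.full(2, mu), sig, size=n)
            rep = UnivariateTwinModel(
                PairData(trait_labels=model.pairs.trait_labels, groups=groups),
                model=model.model,
            ).fit(starts=2, seed=int(rng.integers(2**31)))
            vals.append(rep.components[component])
        alpha = 1.0 - level
        lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
        return (float(lo), float(hi))

    def summary(self) -> str:
        lines = [
            f"Univariate twin model: {self.model}  (trait: {self.trait})",
            f"pairs: " + ", ".join(f"{z}={n}" for z, n in sorted(self.n_pairs.items())),
            f"-2lnL = {self.minus2ll:.4f}   parameters = {self.n_params}   "
            f"converged = {self.converged}",
            f"mean = {self.mean:.4f}",
            "component   share   path (trait units)",
        ]
        for comp in ("a2", "c2", "e2"):
            path = {"a2": "a", "c2": "c", "e2": "e"}[comp]
            lines.append(
                f"   {comp}      {self.components[comp]:6.3f}   {path} = {self.paths[comp]:.4f}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<UnivariateTwinResults {self.model} {self.trait} "
            f"a2={self.a2:.3f} c2={self.c2:.3f} e2={self.e2:.3f}>"
        )
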