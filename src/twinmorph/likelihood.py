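"""Two-group multivariate-normal likelihood for twin pair data.

The classical twin likelihood treats each zygosity group as a sample of iid
2k-vectors (both twins' k traits stacked) from a multivariate normal whose
covariance is structured by the model (saturated, ACE, AE, ... or a
Cholesky-parameterized multivariate model) and whose mean repeats one grand
mean per trait across twins and groups.

For complete pairs the -2 log-likelihood depends on the data only through
per-group sufficient statistics (n, mean vector, MLE covariance), which is
what makes profile confidence intervals and large simulation studies cheap.
Incomplete pairs are supported through a full-information (FIML) path that
groups pairs by missingness pattern and marginalizes the unobserved
elements.

Traits are internally centred and scaled to unit pooled SD before
optimization; the Jacobian constant is added back so reported -2lnL values
refer to the original scale and are comparable across models and with the
saturated fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pairs import PairData

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class GroupStats:
    """Sufficient statistics of one zygosity group (complete pairs)."""

    n: int
    mean: np.ndarray  # (2k,)
    cov: np.ndarray  # (2k, 2k), MLE (divisor n)


def pair_sigma(A: np.ndarray, C: np.ndarray, E: np.ndarray, zygosity: str) -> np.ndarray:
    """Implied stacked-pair covariance for a zygosity group."""
    within = A + C + E
    alpha = 1.0 if zygosity == "MZ" else 0.5
    cross = alpha * A + C
    return np.block([[within, cross], [cross.T, within]])


def _mvn_neg2ll(stats: GroupStats, mu: np.ndarray, sigma: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    d = stats.mean - mu
    try:
        sinv_s = np.linalg.solve(sigma, stats.cov)
        quad = d @ np.linalg.solve(sigma, d)
    except np.linalg.LinAlgError:
        return np.inf
    p = sigma.shape[0]
    return stats.n * (p * _LOG2PI + logdet + np.trace(sinv_s) + quad)


class PairLikelihood:
    """-2lnL evaluator for a :class:`PairData` set under any pair covariance.

    Parameters
    ----------
    pairs : PairData
        Observations; pairs with missing elements are used only when
        ``fiml=True``, otherwise silently dropped.
    fiml : bool
        Use the full-information path (missingness-pattern marginalization).
    """

    def __init__(self, pairs: PairData, fiml: bool = False):
        self.traits = pairs.trait_labels
        self.k = pairs.n_traits
        self.fiml = bool(fiml)
        data = pairs if fiml else pairs.complete()
        self.groups = {z: a for z, a in data.groups.items() if a.shape[0] > 0}
        if not self.groups:
            raise ValueError("no usable pairs")

        # pooled per-trait centring/scaling over both twins and groups
        k = self.k
        allvals = np.concatenate(
            [np.concatenate([a[:, :k], a[:, k:]], axis=0) for a in self.groups.values()]
        )
        self.shift = np.nanmean(allvals, axis=0)
        sd = np.nanstd(allvals, axis=0)
        sd[~np.isfinite(sd) | (sd <= 0)] = 1.0
        self.scale = sd

        shift2 = np.concatenate([self.shift, self.shift])
        scale2 = np.concatenate([self.scale, self.scale])
        self._scaled = {z: (a - shift2) / scale2 for z, a in self.groups.items()}

        # Jacobian constant: -2 sum over observed coords of log density scale
        logs2 = np.log(scale2)
        self._const = 2.0 * sum(
            float(np.sum(~np.isnan(a) * logs2)) for a in self.groups.values()
        )

        if not self.fiml:
            self.stats: dict[str, GroupStats] = {}
            for z, a in self._scaled.items():
                xbar = a.mean(axis=0)
                d = a - xbar
                self.stats[z] = GroupStats(n=a.shape[0], mean=xbar, cov=(d.T @ d) / a.shape[0])
        else:
            self._patterns: dict[str, list[tuple[np.ndarray, GroupStats]]] = {}
            for z, a in self._scaled.items():
                mask = ~np.isnan(a)
                pats: dict[bytes, list[int]] = {}
                for i, row in enumerate(mask):
                    pats.setdefault(row.tobytes(), []).append(i)
                entries = []
                for key, idx in pats.items():
                    obs = np.frombuffer(key, dtype=bool)
                    sub = a[np.ix_(idx, np.where(obs)[0])]
                    xbar = sub.mean(axis=0)
                    d = sub - xbar
                    entries.append(
                        (obs, GroupStats(n=sub.shape[0], mean=xbar, cov=(d.T @ d) / sub.shape[0]))
                    )
                self._patterns[z] = entries

    @property
    def zygosities(self) -> tuple[str, ...]:
        return tuple(self.groups)

    def n_pairs(self, z: str) -> int:
        return int(self.groups[z].shape[0])

    # ------------------------------------------------------------------
    def neg2ll(self, mu_traits: np.ndarray, sigmas: dict[str, np.ndarray]) -> float:
        """-2lnL on the original scale.

        ``mu_traits`` is the length-k grand mean and ``sigmas`` maps each
        zygosity to its 2k x 2k pair covariance, both on the *scaled* space
        (use :meth:`scale_mu` / :meth:`scale_cov` to convert).
        """
        mu2 = np.concatenate([mu_traits, mu_traits])
        total = self._const
        if not self.fiml:
            for z, st in self.stats.items():
                total += _mvn_neg2ll(st, mu2, sigmas[z])
        else:
            for z, entries in self._patterns.items():
                sig = sigmas[z]
                for obs, st in entries:
                    ix = np.where(obs)[0]
                    total += _mvn_neg2ll(st, mu2[ix], sig[np.ix_(ix, ix)])
        return float(total)

    def neg2ll_model(self, mu_traits, A, C, E) -> float:
        """-2lnL for component matrices A, C, E given on the scaled space."""
        sig = {z: pair_sigma(A, C, E, z) for z in self.groups}
        return self.neg2ll(np.asarray(mu_traits, float), sig)

    # -- scale conversions ---------------------------------------------
    def scale_cov(self, m: np.ndarray) -> np.ndarray:
        """Original-scale k x k covariance -> scaled space."""
        return m / np.outer(self.scale, self.scale)

    def unscale_cov(self, m: np.ndarray) -> np.ndarray:
        return m * np.outer(self.scale, self.scale)

    def unscale_mu(self, mu: np.ndarray) -> np.ndarray:
        return self.shift + self.scale * np.asarray(mu, float)

    # -- moment summaries (complete pairs, double entry) ----------------
    def moment_blocks(self, z: str) -> tuple[np.ndarray, np.ndarray]:
        """Double-entered (within, cross) k x k moment blocks, scaled space."""
        if self.fiml:
            a = self._scaled[z]
            a = a[~np.isnan(a).any(axis=1)]
        else:
            a = self._scaled[z]
        k = self.k
        both = np.concatenate([a, np.concatenate([a[:, k:], a[:, :k]], axis=1)], axis=0)
        xbar = both.mean(axis=0)
        d = both - xbar
        S = (d.T @ d) / both.shape[0]
        within = 0.5 * (S[:k, :k] + S[k:, k:])
        cross = 0.5 * (S[:k, k:] + S[k:, :k])
        return within, cross

    def neg2ll_grad_univariate(self, mu: float, va: float, vc: float, ve: float):
        """Value and analytic gradient of -2lnL for the univariate ACE family.

        Complete-pairs fast path (k = 1).  Returns the -2lnL on the original
        scale and its gradient with respect to (mu, va, vc, ve) on the
        scaled space.  Exact gradients let the optimizer converge far past
        what numerical differencing allows, which the scale-invariance
        contract on the standardized components relies on.
        """
        if self.fiml or self.k != 1:
            raise NotImplementedError("analytic gradient: complete pairs, one trait")
        total = self._const
        grad = np.zeros(4)
        for z, st in self.stats.items():
            alpha = 1.0 if z == "MZ" else 0.5
            v = va + vc + ve
            c = alpha * va + vc
            det = v * v - c * c
            if det <= 0.0 or v <= 0.0:
                return np.inf, np.full(4, np.nan)
            inv = np.array([[v, -c], [-c, v]]) / det
            d = st.mean - mu
            M = st.cov + np.outer(d, d)
            G = inv - inv @ M @ inv  # d(-2lnL)/dSigma up to the n factor
            grad[0] += -2.0 * st.n * float((inv @ d).sum())
            tr_g = G[0, 0] + G[1, 1]
            grad[1] += st.n * (tr_g + 2.0 * alpha * G[0, 1])
            grad[2] += st.n * (tr_g + 2.0 * G[0, 1])
            grad[3] += st.n * tr_g
            total += st.n * (2.0 * _LOG2PI + np.log(det) + float(np.sum(inv * M)))
        return float(total), grad

    def saturated(self) -> tuple[float, int]:
        """Closed-form saturated fit: (-2lnL, n_params).

        Per group: free mean per twin-trait coordinate plus an unconstrained
        2k x 2k covariance; the MLE matches the sample moments exactly.
        Complete-pairs only.
        """
        if self.fiml:
            raise NotImplementedError("saturated model is defined for complete pairs")
        total = self._const
        n_params = 0
        p = 2 * self.k
        for st in self.stats.values():
            sign, logdet = np.linalg.slogdet(st.cov)
            if sign <= 0:
                raise np.linalg.LinAlgError("singular sample covariance in saturated fit")
            total += st.n * (p * _LOG2PI + logdet + p)
            n_params += p + p * (p + 1) // 2
        return float(total), n_params
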