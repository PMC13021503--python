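"""Principal-factor analysis with varimax rotation.

Iterated principal-axis factoring of a trait correlation matrix:
communalities start at the squared multiple correlations, the diagonal of
the correlation matrix is replaced by the current communalities, loadings
are taken from the top eigenpairs, and the cycle repeats until the
communalities stabilize.  An orthogonal Kaiser-normalized varimax rotation
then moves the loadings toward simple structure without changing the
communalities or the reproduced correlation matrix.

Applied to anthropometric trait batteries this typically recovers the
familiar three-factor structure: a linear (skeletal length) factor, a
volume (adiposity) factor and a craniofacial factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FactorSolution:
    """Loadings and communalities of a (possibly rotated) factor solution."""

    loadings: np.ndarray  # traits x factors
    communalities: np.ndarray
    n_factors: int
    rotation: str  # "none" or "varimax"
    iterations: int
    converged: bool
    heywood: bool = False
    traits: tuple[str, ...] | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = list(self.traits) if self.traits else list(range(self.loadings.shape[0]))
        df = pd.DataFrame(
            self.loadings, index=idx,
            columns=[f"factor_{i + 1}" for i in range(self.n_factors)],
        )
        df["communality"] = self.communalities
        return df


def _check_corr(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-6):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh(corr).min() < -1e-6:
        raise ValueError("correlation matrix is not PSD within tolerance")
    return 0.5 * (corr + corr.T)


def smc(corr: np.ndarray) -> np.ndarray:
    """Squared multiple correlations of each variable with all others."""
    corr = _check_corr(corr)
    # ridge keeps the inverse defined for singular (perfectly collinear) inputs
    inv = np.linalg.inv(corr + 1e-10 * np.eye(corr.shape[0]))
    return np.clip(1.0 - 1.0 / np.diag(inv), 0.0, 1.0)


def principal_factor(
    corr: np.ndarray,
    n_factors: int,
    traits=None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> FactorSolution:
    """Iterated principal-axis factoring of a correlation matrix.

    Heywood cases (communalities exceeding 1) are clipped and flagged
    rather than aborting the solution.
    """
    corr = _check_corr(corr)
    p = corr.shape[0]
    if not 1 <= n_factors < p:
        raise ValueError("need 1 <= n_factors < number of traits")

    h = smc(corr)
    heywood = False
    loadings = np.zeros((p, n_factors))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        reduced = corr.copy()
        np.fill_diagonal(reduced, h)
        w, v = np.linalg.eigh(reduced)
        order = np.argsort(w)[::-1][:n_factors]
        lam = np.clip(w[order], 0.0, None)
        loadings = v[:, order] * np.sqrt(lam)
        h_new = np.sum(loadings**2, axis=1)
        if np.any(h_new > 1.0 + 1e-8):
            heywood = True
            h_new = np.minimum(h_new, 1.0)
        if np.max(np.abs(h_new - h)) < tol:
            h = h_new
            converged = True
            break
        h = h_new
    if not converged:
        warnings.warn(
            f"principal-axis iteration did not converge in {max_iter} steps", stacklevel=2
        )
    if heywood:
        warnings.warn("Heywood case: a communality was clipped at 1", stacklevel=2)
    loadings = _canonical_columns(loadings)
    return FactorSolution(
        loadings=loadings,
        communalities=np.sum(loadings**2, axis=1),
        n_factors=n_factors,
        rotation="none",
        iterations=it,
        converged=converged,
        heywood=heywood,
        traits=tuple(traits) if traits is not None else None,
    )


def varimax_criterion(loadings: np.ndarray) -> float:
    """The raw varimax objective: summed variance of squared loadings per factor."""
    L2 = loadings**2
    return float(np.sum(L2.var(axis=0)))


def _canonical_columns(L: np.ndarray) -> np.ndarray:
    """Sign each column so its largest-|loading| is positive; order columns
    by explained sum of squares, descending."""
    L = L.copy()
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    order = np.argsort(-np.sum(L**2, axis=0), kind="stable")
    return L[:, order]


def varimax(solution: FactorSolution, tol: float = 1e-10, max_iter: int = 500) -> FactorSolution:
    """Orthogonal Kaiser-normalized varimax rotation of a factor solution.

    Rows are normalized to unit communality before rotation and scaled back
    after, so communalities (and the reproduced correlation matrix) are
    untouched; the rotation only redistributes variance across factors.
    """
    L = solution.loadings
    p, q = L.shape
    if q < 2:
        raise ValueError("varimax needs at least 2 factors")
    h = np.sqrt(np.sum(L**2, axis=1))
    safe = np.where(h > 1e-12, h, 1.0)
    A = L / safe[:, None]

    R = np.eye(q)
    d_old = 0.0
    it = 0
    converged = True
    for it in range(1, max_iter + 1):
        B = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (B**3 - B @ np.diag(np.sum(B**2, axis=0)) / p)
        )
        R = u @ vt
        d = np.sum(s)
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    else:
        converged = False
    rotated = (A @ R) * safe[:, None]
    rotated = _canonical_columns(rotated)
    return FactorSolution(
        loadings=rotated,
        communalities=np.sum(rotated**2, axis=1),
        n_factors=q,
        rotation="varimax",
        iterations=it,
        converged=converged,
        heywood=solution.heywood,
        traits=solution.traits,
    )


class PrincipalFactorModel:
    """Model wrapper: principal-axis factoring of a correlation matrix.

    >>> res = PrincipalFactorModel.from_table(table, traits, sex="male",
    ...                                       wave="initial", n_factors=3).fit()
    >>> res.to_frame()
    """

    def __init__(self, corr: np.ndarray, n_factors: int = 3, traits=None):
        self.corr = _check_corr(corr)
        self.n_factors = n_factors
        self.traits = tuple(traits) if traits is not None else None

    @classmethod
    def from_table(cls, table: pd.DataFrame, traits, sex=None, wave=None, n_factors: int = 3):
        """Correlation matrix from individual-level rows of one stratum.

        Twin clustering inflates the effective sample size of this
        correlation matrix; loadings are unbiased but their sampling error
        is understated.
        """
        sub = table
        if sex is not None:
            sub = sub[sub["sex"] == sex]
        if wave is not None:
            sub = sub[sub["wave"] == wave]
        traits = list(traits)
        corr = sub[traits].corr().to_numpy()
        return cls(corr, n_factors=n_factors, traits=traits)

    def fit(self, rotation: str = "varimax") -> FactorSolution:
        sol = principal_factor(self.corr, self.n_factors, traits=self.traits)
        if rotation == "varimax" and self.n_factors >= 2:
            sol = varimax(sol)
        elif rotation not in ("none", "varimax"):
            raise ValueError("rotation must be 'none' or 'varimax'")
        return sol
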