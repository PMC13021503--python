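"""Generative truths for twin simulation: A, C, E covariance matrices.

The classical twin model decomposes the phenotypic covariance of a set of
traits into additive-genetic (A), shared-environmental (C) and
unique-environmental (E) components.  Within a pair, additive-genetic values
correlate 1 in MZ twins and 0.5 in DZ twins, shared environment correlates 1
in both zygosities, and unique environment is uncorrelated.  A
:class:`GenerativeTruth` holds the three component matrices together with
per-sex means and linear age slopes, and is both the input to the simulator
and the recovery target for the estimators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .design import SEXES, ZYGOSITIES

_PSD_TOL = 1e-8


def _check_psd(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(m)
    if w.min() < -_PSD_TOL * max(1.0, w.max()):
        raise ValueError(f"{name} is not positive semidefinite (min eig {w.min():.3g})")
    return 0.5 * (m + m.T)


@dataclass
class GenerativeTruth:
    """A, C, E component covariances plus mean/age structure.

    Parameters
    ----------
    traits : sequence of str
        Ordered trait names.  For longitudinal (stacked) truths, each trait
        is tied to one wave through ``trait_waves``.
    A, C, E : (k, k) arrays
        Symmetric PSD component covariance matrices on the modelled
        (possibly log) scale, in trait units squared.
    means : dict, optional
        ``sex -> length-k array`` of intercepts; default zeros.
    age_slopes : dict, optional
        ``sex -> length-k array`` of linear age coefficients (units/year);
        default zeros.
    lognormal_traits : set of str, optional
        Traits generated on the log scale and exponentiated after the linear
        stage (adiposity-type traits).
    trait_waves : sequence of str, optional
        Parallel to ``traits``; wave label at which each trait is measured.
        When absent, every trait is measured at every wave of the design
        (independently redrawn per wave).
    """

    traits: tuple[str, ...]
    A: np.ndarray
    C: np.ndarray
    E: np.ndarray
    means: dict[str, np.ndarray] = field(default_factory=dict)
    age_slopes: dict[str, np.ndarray] = field(default_factory=dict)
    lognormal_traits: frozenset[str] = frozenset()
    trait_waves: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        k = len(self.traits)
        self.A = _check_psd(self.A, "A")
        self.C = _check_psd(self.C, "C")
        self.E = _check_psd(self.E, "E")
        for m, name in ((self.A, "A"), (self.C, "C"), (self.E, "E")):
            if m.shape != (k, k):
                raise ValueError(f"{name} has shape {m.shape}, expected ({k}, {k})")
        if np.any(np.diag(self.phenotypic) <= 0):
            raise ValueError("total phenotypic variance must be strictly positive")
        self.lognormal_traits = frozenset(self.lognormal_traits)
        unknown = self.lognormal_traits - set(self.traits)
        if unknown:
            raise ValueError(f"lognormal_traits not in traits: {sorted(unknown)}")
        for d, name in ((self.means, "means"), (self.age_slopes, "age_slopes")):
            for sex in SEXES:
                d[sex] = np.asarray(d.get(sex, np.zeros(k)), dtype=float)
                if d[sex].shape != (k,):
                    raise ValueError(f"{name}[{sex!r}] must have length {k}")
        if self.trait_waves is not None:
            self.trait_waves = tuple(self.trait_waves)
            if len(self.trait_waves) != k:
                raise ValueError("trait_waves must be parallel to traits")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def phenotypic(self) -> np.ndarray:
        """Total within-person phenotypic covariance P = A + C + E."""
        return self.A + self.C + self.E

    def standardized_components(self) -> dict[str, np.ndarray]:
        """Per-trait a², c², e² (diagonal ratios against P)."""
        p = np.diag(self.phenotypic)
        return {
            "a2": np.diag(self.A) / p,
            "c2": np.diag(self.C) / p,
            "e2": np.diag(self.E) / p,
        }

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "traits": list(self.traits),
            "A": self.A.tolist(),
            "C": self.C.tolist(),
            "E": self.E.tolist(),
            "means": {s: v.tolist() for s, v in self.means.items()},
            "age_slopes": {s: v.tolist() for s, v in self.age_slopes.items()},
            "lognormal_traits": sorted(self.lognormal_traits),
        }
        if self.trait_waves is not None:
            d["trait_waves"] = list(self.trait_waves)
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeTruth":
        return cls(
            traits=tuple(d["traits"]),
            A=np.asarray(d["A"], dtype=float),
            C=np.asarray(d["C"], dtype=float),
            E=np.asarray(d["E"], dtype=float),
            means={s: np.asarray(v, float) for s, v in d.get("means", {}).items()},
            age_slopes={s: np.asarray(v, float) for s, v in d.get("age_slopes", {}).items()},
            lognormal_traits=frozenset(d.get("lognormal_traits", ())),
            trait_waves=tuple(d["trait_waves"]) if "trait_waves" in d else None,
        )

    @classmethod
    def from_json(cls, path) -> "GenerativeTruth":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def truth_from_components(
    traits,
    a2,
    c2,
    e2,
    total_var=None,
    r_A=None,
    r_C=None,
    r_E=None,
    **kwargs,
) -> GenerativeTruth:
    """Build a truth from standardized components and component correlations.

    ``a2``, ``c2``, ``e2`` are per-trait standardized shares (summing to ~1);
    ``total_var`` the per-trait phenotypic variances (default 1).  ``r_A``
    etc. are full correlation matrices for the off-diagonal structure of each
    component (default identity: component effects uncorrelated across
    traits).
    """
    traits = tuple(traits)
    k = len(traits)
    a2, c2, e2 = (np.broadcast_to(np.asarray(v, float), (k,)) for v in (a2, c2, e2))
    tv = np.ones(k) if total_var is None else np.broadcast_to(np.asarray(total_var, float), (k,))

    def build(share, r):
        sd = np.sqrt(share * tv)
        rr = np.eye(k) if r is None else np.asarray(r, float)
        return np.outer(sd, sd) * rr

    return GenerativeTruth(
        traits=traits,
        A=build(a2, r_A),
        C=build(c2, r_C),
        E=build(e2, r_E),
        **kwargs,
    )


def implied_pair_covariance(truth: GenerativeTruth, zygosity: str) -> np.ndarray:
    """Implied 2k x 2k covariance of the stacked (twin1, twin2) trait vector.

    Within-twin block A + C + E; cross-twin block A + C for MZ pairs and
    0.5 A + C for DZ pairs.
    """
    if zygosity not in ZYGOSITIES:
        raise ValueError(f"zygosity must be one of {ZYGOSITIES}, got {zygosity!r}")
    within = truth.phenotypic
    alpha = 1.0 if zygosity == "MZ" else 0.5
    cross = alpha * truth.A + truth.C
    return np.block([[within, cross], [cross.T, within]])
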