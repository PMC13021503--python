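"""Per-pair (wide) arrangement of cohort tables for twin likelihoods.

A :class:`PairData` holds, per zygosity group, an ``(n_pairs, 2k)`` array of
stacked observation vectors ``(twin1 traits..., twin2 traits...)`` with NaN
marking missing elements.  Twin ordering within a pair follows the stored
``twin_index`` and is never sorted by value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ZYGOSITIES


@dataclass
class PairData:
    """Zygosity-grouped stacked pair observations over k trait columns."""

    trait_labels: tuple[str, ...]
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trait_labels = tuple(self.trait_labels)
        k2 = 2 * self.n_traits
        for z, arr in self.groups.items():
            if z not in ZYGOSITIES:
                raise ValueError(f"unknown zygosity {z!r}")
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != k2:
                raise ValueError(f"group {z} must be (n, {k2})")
            if arr.shape[0] and np.any(np.all(np.isnan(arr), axis=1)):
                raise ValueError("every pair must have at least one observed element")
            self.groups[z] = arr

    @property
    def n_traits(self) -> int:
        return len(self.trait_labels)

    def n_pairs(self, zygosity: str | None = None) -> int:
        if zygosity is not None:
            return int(self.groups.get(zygosity, np.empty((0, 0))).shape[0])
        return sum(int(a.shape[0]) for a in self.groups.values())

    def complete(self) -> "PairData":
        """Keep only pairs with every element observed."""
        return PairData(
            trait_labels=self.trait_labels,
            groups={
                z: arr[~np.isnan(arr).any(axis=1)] for z, arr in self.groups.items()
            },
        )

    @property
    def is_complete(self) -> bool:
        return all(not np.isnan(a).any() for a in self.groups.values())

    def select(self, indices) -> "PairData":
        """Restrict to a subset of traits (by index), keeping both twins."""
        indices = list(indices)
        k = self.n_traits
        cols = indices + [i + k for i in indices]
        return PairData(
            trait_labels=tuple(self.trait_labels[i] for i in indices),
            groups={z: arr[:, cols] for z, arr in self.groups.items()},
        )

    def swapped(self) -> "PairData":
        """Exchange twin 1 and twin 2 (a relabelling the model must ignore)."""
        k = self.n_traits
        return PairData(
            trait_labels=self.trait_labels,
            groups={
                z: np.concatenate([arr[:, k:], arr[:, :k]], axis=1)
                for z, arr in self.groups.items()
            },
        )


def _wide_one_wave(table: pd.DataFrame, trait: str, sex, wave) -> pd.DataFrame:
    sub = table
    if sex is not None:
        sub = sub[sub["sex"] == sex]
    if wave is not None:
        sub = sub[sub["wave"] == wave]
    wide = sub.pivot_table(
        index=["family_id", "zygosity"],
        columns="twin_index",
        values=trait,
        aggfunc="first",
        dropna=False,
    )
    wide = wide.reindex(columns=[1, 2])
    wide.columns = [f"{trait}:1", f"{trait}:2"]
    return wide


def to_pairs(
    table: pd.DataFrame,
    traits,
    sex=None,
    wave=None,
    include_incomplete: bool = False,
) -> PairData:
    """Extract per-pair observation vectors for one stratum.

    Parameters
    ----------
    traits : str or sequence
        Trait column(s); for multivariate models pass k names.  Each may
        optionally be a ``(trait, wave)`` tuple for cross-wave analyses, in
        which case the ``wave`` argument is ignored for that trait.
    sex, wave : optional
        Stratum selectors; ``None`` pools.
    include_incomplete : bool
        Keep pairs with missing elements (for full-information likelihoods);
        default drops them (complete-pairs analysis).
    """
    if isinstance(traits, str):
        traits = [traits]
    blocks = []
    labels = []
    for t in traits:
        if isinstance(t, tuple):
            name, w = t
            labels.append(f"{name}@{w}")
            blocks.append(_wide_one_wave(table, name, sex, w))
        else:
            labels.append(t if wave is None else f"{t}@{wave}")
            blocks.append(_wide_one_wave(table, t, sex, wave))
    wide = pd.concat(blocks, axis=1, join="outer")
    k = len(labels)
    twin1 = wide.iloc[:, [2 * i for i in range(k)]].to_numpy(dtype=float)
    twin2 = wide.iloc[:, [2 * i + 1 for i in range(k)]].to_numpy(dtype=float)
    stacked = np.concatenate([twin1, twin2], axis=1)

    zyg = wide.index.get_level_values("zygosity").to_numpy()
    groups = {}
    for z in ZYGOSITIES:
        arr = stacked[zyg == z]
        arr = arr[~np.all(np.isnan(arr), axis=1)]
        if not include_incomplete:
            arr = arr[~np.isnan(arr).any(axis=1)]
        if arr.shape[0]:
            groups[z] = arr
    if not groups:
        raise ValueError(
            f"no pairs for traits {labels} in stratum (sex={sex!r}, wave={wave!r})"
        )
    return PairData(trait_labels=tuple(labels), groups=groups)


def cross_wave_pairs(
    table: pd.DataFrame,
    trait: str,
    sex=None,
    waves=("initial", "followup"),
    include_incomplete: bool = False,
) -> PairData:
    """Bivariate pair data treating one trait at two waves as two traits."""
    return to_pairs(
        table,
        [(trait, waves[0]), (trait, waves[1])],
        sex=sex,
        include_incomplete=include_incomplete,
    )
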