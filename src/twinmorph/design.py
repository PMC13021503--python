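"""Twin cohort designs: zygosity-by-sex pair counts and assessment waves.

A :class:`CohortDesign` describes *who* is measured: how many complete
monozygotic (MZ) and dizygotic (DZ) same-sex pairs of each sex attend each
assessment wave, and the age distribution at each wave.  The built-in
:func:`mtfs_design` reproduces the Minnesota Twin Family Study layout: a
two-wave longitudinal design with an early-adolescent intake and a follow-up
in mid (males) or late (females) adolescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ZYGOSITIES = ("MZ", "DZ")
SEXES = ("male", "female")


@dataclass(frozen=True)
class WaveDesign:
    """One assessment wave.

    Parameters
    ----------
    label : str
        Wave identifier (e.g. ``"initial"``, ``"followup"``).
    pair_counts : dict
        ``(zygosity, sex) -> number of complete pairs`` attending this wave.
    mean_age, age_sd : dict
        Per-sex mean and SD of exact age in years.
    age_range : dict
        Per-sex ``(lo, hi)`` bounds of exact age in years.
    """

    label: str
    pair_counts: dict[tuple[str, str], int]
    mean_age: dict[str, float]
    age_sd: dict[str, float]
    age_range: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for cell, n in self.pair_counts.items():
            if cell[0] not in ZYGOSITIES or cell[1] not in SEXES:
                raise ValueError(f"unknown (zygosity, sex) cell {cell!r}")
            if n < 0:
                raise ValueError(f"negative pair count for {cell!r}")
        for sex in self.mean_age:
            lo, hi = self.age_range[sex]
            if not lo <= self.mean_age[sex] <= hi:
                raise ValueError(
                    f"wave {self.label!r}: mean age {self.mean_age[sex]} for "
                    f"{sex} outside range [{lo}, {hi}]"
                )
            if self.age_sd[sex] < 0:
                raise ValueError("age SD must be non-negative")

    @property
    def n_pairs(self) -> int:
        return sum(self.pair_counts.values())

    @property
    def n_individuals(self) -> int:
        return 2 * self.n_pairs


@dataclass(frozen=True)
class CohortDesign:
    """A multi-wave twin cohort design (same-sex MZ/DZ pairs only)."""

    waves: tuple[WaveDesign, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.waves:
            raise ValueError("a design needs at least one wave")
        if not any(n > 0 for w in self.waves for n in w.pair_counts.values()):
            raise ValueError("at least one (zygosity, sex) cell must be non-empty")
        labels = [w.label for w in self.waves]
        if len(set(labels)) != len(labels):
            raise ValueError("wave labels must be unique")

    def wave(self, label: str) -> WaveDesign:
        for w in self.waves:
            if w.label == label:
                return w
        raise KeyError(label)

    @property
    def wave_labels(self) -> tuple[str, ...]:
        return tuple(w.label for w in self.waves)

    def to_dict(self) -> dict:
        return {
            "waves": [
                {
                    "label": w.label,
                    "pair_counts": {f"{z}:{s}": n for (z, s), n in w.pair_counts.items()},
                    "mean_age": dict(w.mean_age),
                    "age_sd": dict(w.age_sd),
                    "age_range": {s: list(r) for s, r in w.age_range.items()},
                }
                for w in self.waves
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortDesign":
        waves = []
        for wd in d["waves"]:
            counts = {}
            for key, n in wd["pair_counts"].items():
                z, s = key.split(":")
                counts[(z, s)] = int(n)
            waves.append(
                WaveDesign(
                    label=wd["label"],
                    pair_counts=counts,
                    mean_age={s: float(v) for s, v in wd["mean_age"].items()},
                    age_sd={s: float(v) for s, v in wd["age_sd"].items()},
                    age_range={s: (float(r[0]), float(r[1])) for s, r in wd["age_range"].items()},
                )
            )
        return cls(waves=tuple(waves))


def single_wave_design(
    pair_counts: dict[tuple[str, str], int],
    label: str = "initial",
    mean_age: float = 11.7,
    age_sd: float = 0.4,
    age_range: tuple[float, float] = (10.7, 12.8),
) -> CohortDesign:
    """Convenience constructor for a one-wave design with a common age law."""
    return CohortDesign(
        waves=(
            WaveDesign(
                label=label,
                pair_counts=dict(pair_counts),
                mean_age={s: mean_age for s in SEXES},
                age_sd={s: age_sd for s in SEXES},
                age_range={s: age_range for s in SEXES},
            ),
        )
    )


def mtfs_design() -> CohortDesign:
    """The built-in Minnesota Twin Family Study two-wave design.

    Intake at mean age 11.7 (range 10.7-12.8, both sexes) with 252 male MZ,
    233 female MZ, 124 male DZ and 147 female DZ complete pairs
    (2 x 756 = 1512 children); follow-up with 207/161/104/93 complete pairs
    at mean age 14.8 (13.6-16.9) for males and 18.1 (16.6-20.3) for females.
    Follow-up pairs are a subset of the intake pairs (per cell, the first
    ``n`` families), so longitudinal analyses have within-family linkage.
    """
    intake = WaveDesign(
        label="initial",
        pair_counts={
            ("MZ", "male"): 252,
            ("MZ", "female"): 233,
            ("DZ", "male"): 124,
            ("DZ", "female"): 147,
        },
        mean_age={"male": 11.7, "female": 11.7},
        age_sd={"male": 0.39, "female": 0.46},
        age_range={"male": (10.7, 12.8), "female": (10.7, 12.8)},
    )
    followup = WaveDesign(
        label="followup",
        pair_counts={
            ("MZ", "male"): 207,
            ("MZ", "female"): 161,
            ("DZ", "male"): 104,
            ("DZ", "female"): 93,
        },
        mean_age={"male": 14.8, "female": 18.1},
        age_sd={"male": 0.49, "female": 0.71},
        age_range={"male": (13.6, 16.9), "female": (16.6, 20.3)},
    )
    return CohortDesign(waves=(intake, followup))
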