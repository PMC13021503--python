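"""End-to-end study pipeline: simulate -> preprocess -> tables -> factors.

One seeded configuration produces the full set of study-style outputs:
descriptive statistics, the univariate variance-component table with CIs
and model-comparison tests, per-wave additive-genetic correlation matrices
(males in the upper triangle, females in the lower), the cross-wave
stability table, and factor loadings per stratum -- plus a manifest
recording seeds, convergence and failures.  Identical configuration and
seed give a byte-identical output bundle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cholesky import correlation_matrix_pipeline, cross_wave_correlations
from .design import SEXES, CohortDesign, mtfs_design
from .factor import PrincipalFactorModel
from .pairs import to_pairs
from .preprocess import PreprocessSpec, descriptive_stats, preprocess
from .simulate import simulate_cohort, write_cohort
from .truth import GenerativeTruth
from .univariate import UnivariateTwinModel, bonferroni_threshold, fit_saturated, lrt

_FLOAT_FMT = "%.6g"  # pinned so identical runs give byte-identical CSVs


@dataclass
class StudyConfig:
    """Configuration of a full simulated-study run.

    ``truths`` maps sex to a :class:`GenerativeTruth` (a single truth may be
    shared); ``design`` is a :class:`CohortDesign` or the string ``"mtfs"``.
    """

    truths: dict[str, GenerativeTruth]
    design: CohortDesign | str = "mtfs"
    seed: int = 0
    sexes: tuple[str, ...] = SEXES
    traits: tuple[str, ...] | None = None
    log_traits: frozenset[str] = frozenset()
    ci: bool = True
    ci_method: str = "profile"
    model_policy: str = "AE-then-ACE"
    n_factors: int = 3
    out_dir: str | Path = "results"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required")
        if isinstance(self.truths, GenerativeTruth):
            self.truths = {s: self.truths for s in self.sexes}
        for s in self.sexes:
            if s not in self.truths:
                raise ValueError(f"no truth for sex {s!r}")
        if self.traits is not None:
            for s in self.sexes:
                missing = set(self.traits) - set(self.truths[s].traits)
                if missing:
                    raise ValueError(f"traits not in truth[{s!r}]: {sorted(missing)}")

    @property
    def resolved_design(self) -> CohortDesign:
        if isinstance(self.design, str):
            if self.design != "mtfs":
                return CohortDesign.from_dict(json.loads(Path(self.design).read_text()))
            return mtfs_design()
        return self.design

    @classmethod
    def from_json(cls, path, out_dir=None, seed=None) -> "StudyConfig":
        d = json.loads(Path(path).read_text())
        truths = d["truth"]
        if isinstance(truths, str):
            truths = {s: truths for s in SEXES}
        truths = {s: GenerativeTruth.from_json(p) for s, p in truths.items()}
        return cls(
            truths=truths,
            design=d.get("design", "mtfs"),
            seed=int(seed if seed is not None else d.get("seed", 0)),
            sexes=tuple(d.get("sexes", SEXES)),
            traits=tuple(d["traits"]) if "traits" in d else None,
            log_traits=frozenset(d.get("log_traits", ())),
            ci=bool(d.get("ci", True)),
            n_factors=int(d.get("n_factors", 3)),
            out_dir=out_dir if out_dir is not None else d.get("out_dir", "results"),
        )


def _sub_design(design: CohortDesign, sex: str) -> CohortDesign:
    from .design import WaveDesign

    waves = tuple(
        WaveDesign(
            label=w.label,
            pair_counts={c: n for c, n in w.pair_counts.items() if c[1] == sex},
            mean_age=w.mean_age,
            age_sd=w.age_sd,
            age_range=w.age_range,
        )
        for w in design.waves
    )
    return CohortDesign(waves=waves)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")


def run_study(config: StudyConfig) -> dict:
    """Run the whole pipeline; returns the bundle (paths + in-memory tables).

    Per-stratum analysis failures are recorded in the manifest and do not
    abort independent strata.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.resolved_design
    manifest: dict = {
        "seed": int(config.seed),
        "twinmorph_version": __version__,
        "stages": {},
        "fits": [],
    }
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    # -- simulate (per sex, spawned deterministic seeds) -----------------
    ss = np.random.SeedSequence(config.seed)
    sex_seeds = {s: int(c.generate_state(1)[0] % (2**31)) for s, c in
                 zip(config.sexes, ss.spawn(len(config.sexes)))}
    tables = []
    for sex in config.sexes:
        tables.append(simulate_cohort(_sub_design(design, sex), config.truths[sex],
                                      seed=sex_seeds[sex]))
    cohort = pd.concat(tables, ignore_index=True)
    write_cohort(cohort, out / "cohort.csv")
    manifest["stages"]["simulate"] = {"status": "done", "rows": int(len(cohort)),
                                      "seeds": sex_seeds}
    log(f"simulated {len(cohort)} rows")

    traits = list(config.traits) if config.traits is not None else [
        t for t in cohort.columns if t not in
        ("family_id", "twin_index", "zygosity", "sex", "wave", "age")
    ]
    waves = list(design.wave_labels)

    # -- preprocess ------------------------------------------------------
    spec = PreprocessSpec(log_traits=config.log_traits, trait_columns=tuple(traits))
    desc = descriptive_stats(cohort, traits=traits)
    _write_csv(desc, out / "table1_descriptives.csv")
    adjusted = preprocess(cohort, spec)
    write_cohort(adjusted, out / "adjusted.csv")
    manifest["stages"]["preprocess"] = {"status": "done", "log_traits": sorted(config.log_traits)}

    # -- univariate components table ------------------------------------
    rows = []
    sidecar = []
    for sex in config.sexes:
        for wave in waves:
            for trait in traits:
                rec = {"sex": sex, "wave": wave, "trait": trait}
                try:
                    pairs = to_pairs(adjusted, trait, sex=sex, wave=wave)
                    res = UnivariateTwinModel(pairs, model="ACE").fit()
                    sat = fit_saturated(pairs)
                    res_ae = UnivariateTwinModel(pairs, model="AE").fit()
                    t_sat = lrt(res, sat)
                    t_c = lrt(res_ae, res)
                    rec.update(
                        a2=res.a2, c2=res.c2, e2=res.e2,
                        minus2ll=res.minus2ll, converged=res.converged,
                        lrt_sat_chi2=t_sat.chi2, lrt_sat_df=t_sat.df, lrt_sat_p=t_sat.p,
                        lrt_c_chi2=t_c.chi2, lrt_c_df=t_c.df, lrt_c_p=t_c.p,
                        status="done",
                    )
                    if config.ci:
                        for comp in ("a2", "c2", "e2"):
                            lo, hi = res.conf_int(comp, method=config.ci_method)
                            rec[f"{comp}_lo"], rec[f"{comp}_hi"] = lo, hi
                    sidecar.append(dict(rec))
                    manifest["fits"].append(
                        {"kind": "univariate", "sex": sex, "wave": wave, "trait": trait,
                         "converged": bool(res.converged)}
                    )
                except Exception as exc:
                    rec["status"] = f"failed: {exc}"
                    manifest["fits"].append(
                        {"kind": "univariate", "sex": sex, "wave": wave, "trait": trait,
                         "converged": False, "error": str(exc)}
                    )
                    log(f"univariate {sex}/{wave}/{trait} failed: {exc}")
                rows.append(rec)
    table2 = pd.DataFrame(rows)
    _write_csv(table2.round(6), out / "table2_components.csv")
    manifest["stages"]["univariate"] = {
        "status": "done",
        "n_done": int((table2["status"] == "done").sum()),
        "n_failed": int((table2["status"] != "done").sum()),
    }

    # -- per-wave r_A matrices (males upper / females lower triangle) ----
    for wave in waves:
        k = len(traits)
        mat = pd.DataFrame(np.full((k, k), np.nan), index=traits, columns=traits)
        np.fill_diagonal(mat.values, 1.0)
        status = "done"
        for sex, upper in (("male", True), ("female", False)):
            if sex not in config.sexes:
                continue
            try:
                res = correlation_matrix_pipeline(adjusted, traits, sex=sex, wave=wave)
                ra = res["matrices"]["r_A_AE"]
                for i in range(k):
                    for j in range(i + 1, k):
                        if upper:
                            mat.iloc[i, j] = ra.iloc[i, j]
                        else:
                            mat.iloc[j, i] = ra.iloc[j, i]
                (out / f"pairwise_{sex}_{wave}.csv").write_text(
                    res["records"].to_csv(index=False, float_format=_FLOAT_FMT)
                )
            except Exception as exc:
                status = f"failed for {sex}: {exc}"
                log(f"corrmatrix {sex}/{wave} failed: {exc}")
        mat.round(6).to_csv(out / f"fig_rA_matrix_{wave}.csv", float_format=_FLOAT_FMT)
        manifest["stages"][f"rA_matrix_{wave}"] = {"status": status}

    # -- cross-wave table ------------------------------------------------
    rows = []
    if len(waves) >= 2:
        for sex in config.sexes:
            for trait in traits:
                rec = {"sex": sex, "trait": trait}
                try:
                    cw = cross_wave_correlations(
                        adjusted, trait, sex=sex, waves=(waves[0], waves[1]),
                        ci=config.ci,
                    )
                    rec.update(
                        r=cw["r_phenotypic"], r_lo=cw["r_phenotypic_ci"][0],
                        r_hi=cw["r_phenotypic_ci"][1], r_A=cw["r_A"], r_E=cw["r_E"],
                        status="done",
                    )
                    if config.ci and cw.get("r_A_ci"):
                        rec["r_A_lo"], rec["r_A_hi"] = cw["r_A_ci"]
                        rec["r_E_lo"], rec["r_E_hi"] = cw["r_E_ci"]
                except Exception as exc:
                    rec["status"] = f"failed: {exc}"
                    log(f"crosswave {sex}/{trait} failed: {exc}")
                rows.append(rec)
    table3 = pd.DataFrame(rows)
    _write_csv(table3.round(6) if len(table3) else table3, out / "table3_crosswave.csv")
    manifest["stages"]["crosswave"] = {"status": "done", "n": len(rows)}

    # -- factor loadings per stratum ------------------------------------
    for sex in config.sexes:
        for wave in waves:
            try:
                if len(traits) <= config.n_factors:
                    raise ValueError("need more traits than factors")
                sol = PrincipalFactorModel.from_table(
                    adjusted, traits, sex=sex, wave=wave, n_factors=config.n_factors
                ).fit()
                sol.to_frame().round(6).to_csv(
                    out / f"loadings_{sex}_{wave}.csv", float_format=_FLOAT_FMT
                )
                manifest["stages"][f"factors_{sex}_{wave}"] = {
                    "status": "done", "converged": bool(sol.converged),
                    "heywood": bool(sol.heywood),
                }
            except Exception as exc:
                manifest["stages"][f"factors_{sex}_{wave}"] = {"status": f"failed: {exc}"}
                log(f"factors {sex}/{wave} failed: {exc}")

    with open(out / "results_full.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True, default=float)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")

    return {
        "out_dir": out,
        "cohort": cohort,
        "adjusted": adjusted,
        "table1": desc,
        "table2": table2,
        "table3": table3,
        "manifest": manifest,
    }


def significance_summary(bundle: dict, alpha: float = 0.05, m: int | None = None) -> dict:
    """Count traits whose shared-environmental variance is significant.

    Uses the AE-vs-ACE likelihood-ratio p-values from the univariate table,
    at the nominal level and at the Bonferroni-corrected level alpha/m
    (m defaults to the number of tests performed).
    """
    table2 = bundle["table2"] if isinstance(bundle, dict) else bundle
    if "lrt_c_p" not in getattr(table2, "columns", ()):
        warnings.warn("bundle contains no likelihood-ratio tests", stacklevel=2)
        return {"n_tests": 0, "n_sig_nominal": 0, "n_sig_bonferroni": 0,
                "threshold_bonferroni": None}
    ok = table2[table2["status"] == "done"]
    pvals = ok["lrt_c_p"].to_numpy(dtype=float)
    m = len(pvals) if m is None else m
    thr = bonferroni_threshold(alpha, max(m, 1)) if m else None
    return {
        "n_tests": int(len(pvals)),
        "n_sig_nominal": int((pvals < alpha).sum()),
        "n_sig_bonferroni": int((pvals < thr).sum()) if thr else 0,
        "threshold_bonferroni": thr,
    }
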