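"""End-to-end study orchestration.

`run_study` ties the stages together for a whole cohort: read trials
(and optionally incremental-test summaries), fit the six-cell battery
per participant, attach quality metrics, run the mixed-model
family/procedure comparison per outcome, map CS onto the incremental
physiology, and correlate CS with the aerobic fitness parameters.  The
result is a bundle of tidy CSVs plus a run log capturing the analysis
conventions (seed, weighting, tolerances, CI level, AIC convention) and
every excluded fit.

Serialization precision: speeds 0.01 m/s, distances 0.1 m, percents and
dimensionless quality metrics 0.1; values are kept at full precision in
memory and rounded only when written.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aerobic import relative_cs, vo2_at_cs
from .cohort import (
    assemble_long_table,
    log_scale_association,
    mixed_model_effects,
)
from .estimator import FitResult, fit_battery
from .io import read_incremental, read_trials
from .models import PARAM_NAMES
from .quality import (
    combined_percent_see,
    information_criterion,
    parameter_intervals,
    residual_heteroscedasticity,
)

__all__ = ["StudyConfig", "StudyReport", "run_study", "load_config"]

_SPEED_COLS = ("cs", "s_max", "cs_ci90", "s_max_ci90", "cs_se", "s_max_se")
_DIST_COLS = ("d_prime", "d_prime_ci90", "d_prime_se")


@dataclass
class StudyConfig:
    trials_path: str | Path
    incremental_path: str | Path | None = None
    out_dir: str | Path = "study_out"
    ci_level: float = 0.90
    weighting: str = "inverse_dependent"
    tol: float = 1e-10
    max_iterations: int = 500
    seed: int = 0
    write_residual_profiles: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")


def load_config(path) -> StudyConfig:
    """Study configuration from a plain-text key: value (YAML) file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected key: value pairs")
    return StudyConfig(**raw)


@dataclass
class StudyReport:
    fits: pd.DataFrame
    mixed_models: pd.DataFrame
    physiology: pd.DataFrame | None
    correlations: pd.DataFrame | None
    exclusions: list[tuple[str, str, str]]
    paths: dict[str, Path] = field(default_factory=dict)


def _fit_row(fit: FitResult, ci_level: float) -> dict:
    row = dict(
        participant_id=fit.participant_id,
        family=fit.spec.family.value,
        formulation=fit.spec.formulation.value,
        n_obs=fit.n_obs,
        df=fit.df,
        converged=fit.converged,
        flags=";".join(fit.flags),
    )
    for name in ("cs", "d_prime", "s_max", "tau"):
        row[name] = getattr(fit.params, name, None) if fit.params else None
    if fit.standard_errors is not None and fit.df >= 1:
        ints = parameter_intervals(fit, ci_level)
        for name in fit.param_names:
            row[f"{name}_se"] = fit.standard_errors[name]
            row[f"{name}_ci90"] = ints[name].half_width
        row["percent_see"] = combined_percent_see(fit)
    if fit.params is not None:
        row["aic"] = information_criterion(fit)
        row["het_index"] = residual_heteroscedasticity(fit).index
    return row


def _round_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        if col in _SPEED_COLS:
            out[col] = out[col].round(2)
        elif col in _DIST_COLS or col == "tau" or col == "tau_se" or col == "tau_ci90":
            out[col] = out[col].round(1)
        else:
            out[col] = out[col].round(4)
    return out


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full analysis; deterministic for fixed inputs and seed."""
    trialsets = read_trials(config.trials_path)
    if not trialsets:
        raise ValueError("empty cohort")
    profiles = (
        read_incremental(config.incremental_path) if config.incremental_path else None
    )

    batteries = {
        t.participant_id: fit_battery(
            t,
            weighting=config.weighting,
            tol=config.tol,
            max_iterations=config.max_iterations,
            random_state=config.seed,
        )
        for t in trialsets
    }
    fit_rows = [
        _fit_row(fit, config.ci_level) for battery in batteries.values() for fit in battery
    ]
    fits = pd.DataFrame(fit_rows)

    table = assemble_long_table(batteries)
    mixed_rows = []
    for outcome in ("cs", "d_prime", "s_max"):
        sub = table[table["outcome"] == outcome]
        if sub.empty or sub["family"].nunique() < 2:
            continue
        mm = mixed_model_effects(table, outcome)
        mixed_rows.append(
            dict(
                outcome=outcome,
                p_family=mm.fixed_effect_p.get("family"),
                p_formulation=mm.fixed_effect_p.get("formulation"),
                p_interaction=mm.fixed_effect_p.get("interaction"),
                r2_marginal=mm.r2_marginal,
                r2_conditional=mm.r2_conditional,
                icc=mm.icc,
                var_fixed=mm.var_fixed,
                var_random=mm.var_random,
                var_resid=mm.var_resid,
                posthoc=";".join(f"{pair}:p={p:.4g}" for pair, p in mm.posthoc),
                flags=";".join(mm.flags),
            )
        )
    mixed = pd.DataFrame(mixed_rows)

    physiology = correlations = None
    if profiles:
        cs_table = table[table["outcome"] == "cs"]
        phys_rows, corr_rows = [], []
        for (fam, form), grp in cs_table.groupby(["family", "formulation"], sort=False):
            pct_vo2, pct_svo2 = [], []
            merged = []
            for _, rec in grp.iterrows():
                prof = profiles.get(rec["participant_id"])
                if prof is None:
                    continue
                if prof.vo2_intercept is not None:
                    pct_vo2.append(vo2_at_cs(prof, rec["value"]).percent_vo2max)
                pct_svo2.append(relative_cs(rec["value"], prof.s_vo2max))
                merged.append((rec["value"], prof))
            phys_rows.append(
                dict(
                    family=fam,
                    formulation=form,
                    n=len(pct_svo2),
                    vo2_percent_vo2max=float(np.mean(pct_vo2)) if pct_vo2 else None,
                    cs_percent_s_vo2max=float(np.mean(pct_svo2)) if pct_svo2 else None,
                )
            )
            for ref_name in ("vt", "rcp", "vo2max"):
                pairs = [
                    (getattr(prof, ref_name), cs)
                    for cs, prof in merged
                    if getattr(prof, ref_name) is not None
                ]
                if len(pairs) < 3:
                    continue
                x, y = zip(*pairs)
                assoc = log_scale_association(x, y)
                corr_rows.append(
                    dict(
                        family=fam,
                        formulation=form,
                        reference=ref_name,
                        r=assoc.r,
                        ci90_low=assoc.ci90[0],
                        ci90_high=assoc.ci90[1],
                        p=assoc.p,
                        see_percent=assoc.see_percent,
                        delta_percent=assoc.delta_percent,
                        n=assoc.n,
                    )
                )
        physiology = pd.DataFrame(phys_rows)
        correlations = pd.DataFrame(corr_rows) if corr_rows else None

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame | None) -> None:
        if frame is None or frame.empty:
            return
        p = out_dir / f"{name}.csv"
        _round_columns(frame).to_csv(p, index=False)
        paths[name] = p

    emit("fits", fits)
    emit("mixed_models", mixed)
    emit("physiology", physiology)
    emit("correlations", correlations)

    log = dict(
        package=f"critspeed {__version__}",
        seed=config.seed,
        ci_level=config.ci_level,
        weighting=config.weighting,
        tol=config.tol,
        max_iterations=config.max_iterations,
        ci_convention="t-quantile x asymptotic SE, df = n - p",
        aic_convention="n ln(weighted RSS / n) + 2p; within-formulation comparisons only",
        n_participants=len(trialsets),
        n_excluded_fits=table.attrs["n_excluded"],
        excluded=[list(e) for e in table.attrs["exclusions"]],
    )
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2) + "\n")
    paths["run_log"] = log_path

    return StudyReport(
        fits=fits,
        mixed_models=mixed,
        physiology=physiology,
        correlations=correlations,
        exclusions=table.attrs["exclusions"],
        paths=paths,
    )
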