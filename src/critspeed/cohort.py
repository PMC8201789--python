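"""Cohort-level inference on battery estimates.

Two questions drive the cohort analysis: does the choice of model
family or of fitting procedure (t(s) vs d(s)) shift the estimates, and
how tightly does CS track aerobic fitness?

* A random-intercept linear mixed model (REML) with fixed effects for
  family, formulation and their interaction, and a random intercept per
  participant, answers the first.  Variance is decomposed into
  fixed-effect, random-intercept and residual parts, yielding
  R2_marginal = var_fixed / total, R2_conditional =
  (var_fixed + var_random) / total and ICC = var_random /
  (var_random + var_resid).  Pairwise family contrasts use Holm-adjusted
  paired t-tests when the family effect is significant.
* Log-scale Pearson correlations (natural logs, Fisher-z 90 % CI)
  answer the second, with SEE% = 100 (e^{s_res} - 1) from the residual
  SD of the log-log regression and a systematic difference
  Delta% = 100 (e^{mean leave-one-out log error} - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .estimator import FitResult
from .models import Formulation, ModelFamily, dprime_max_exp

__all__ = [
    "MixedModelResult",
    "CorrelationResult",
    "assemble_long_table",
    "mixed_model_effects",
    "variance_explained",
    "log_scale_association",
    "percent_difference",
    "holm_adjust",
    "icc_label",
    "correlation_label",
]

_OUTCOMES = ("cs", "d_prime", "s_max")


def assemble_long_table(batteries: dict[str, list[FitResult]]) -> pd.DataFrame:
    """Long table of (participant, family, formulation, outcome, value).

    d' for the exponential family is its derived d'_max; s_max is absent
    for the two-parameter family.  Flagged (non-usable) fits are dropped
    and counted in the frame's ``attrs["n_excluded"]`` /
    ``attrs["exclusions"]``.
    """
    if not batteries:
        raise ValueError("empty cohort")
    rows: list[dict] = []
    exclusions: list[tuple[str, str, str]] = []
    for pid, battery in batteries.items():
        for fit in battery:
            fam, form = fit.spec.family, fit.spec.formulation
            if not fit.ok:
                exclusions.append((pid, fam.value, form.value))
                continue
            p = fit.params
            values = {"cs": p.cs}
            if fam is ModelFamily.THREE_PARAM_EXP:
                values["d_prime"] = dprime_max_exp(p)
                values["s_max"] = p.s_max
            else:
                values["d_prime"] = p.d_prime
                if p.s_max is not None:
                    values["s_max"] = p.s_max
            for outcome, value in values.items():
                rows.append(
                    dict(
                        participant_id=pid,
                        family=fam.value,
                        formulation=form.value,
                        outcome=outcome,
                        value=float(value),
                    )
                )
    table = pd.DataFrame(rows, columns=["participant_id", "family", "formulation", "outcome", "value"])
    dup = table.duplicated(["participant_id", "family", "formulation", "outcome"])
    if dup.any():
        raise ValueError("duplicate participant x family x formulation x outcome cell")
    table.attrs["n_excluded"] = len(exclusions)
    table.attrs["exclusions"] = exclusions
    return table


def variance_explained(
    var_fixed: float, var_random: float, var_resid: float
) -> tuple[float, float, float]:
    """(R2_marginal, R2_conditional, ICC) from the three variance parts."""
    total = var_fixed + var_random + var_resid
    if not total > 0:
        return 0.0, 0.0, 0.0
    r2m = var_fixed / total
    r2c = (var_fixed + var_random) / total
    denom = var_random + var_resid
    icc = var_random / denom if denom > 0 else 0.0
    return float(r2m), float(r2c), float(icc)


@dataclass
class MixedModelResult:
    outcome: str
    fixed_effect_p: dict[str, float]  # keys: family, formulation, interaction
    var_fixed: float
    var_random: float
    var_resid: float
    r2_marginal: float
    r2_conditional: float
    icc: float
    posthoc: list[tuple[str, float]] = field(default_factory=list)  # (pair, holm p)
    converged: bool = True
    flags: tuple[str, ...] = ()
    method: str = "REML random-intercept; Wald chi-square fixed-effect tests"


def _wald_term_p(fe: np.ndarray, cov: np.ndarray, idx: list[int]) -> float:
    beta = fe[idx]
    V = cov[np.ix_(idx, idx)]
    stat = float(beta @ np.linalg.pinv(V) @ beta)
    return float(stats.chi2.sf(stat, len(idx)))


def mixed_model_effects(table: pd.DataFrame, outcome: str = "cs") -> MixedModelResult:
    """Random-intercept mixed model of one outcome on family x formulation.

    ``value ~ C(family) * C(formulation) + (1 | participant)`` fitted by
    REML.  Fixed-effect p values are Wald chi-square tests on the term's
    coefficient block; pairwise family contrasts (Holm-adjusted paired t
    tests on per-participant family means) are reported when the family
    term is significant at 0.05.
    """
    if outcome not in _OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    df = table[table["outcome"] == outcome].copy()
    families = sorted(df["family"].unique())
    if len(families) < 2:
        raise ValueError("need at least two model families")
    n_cells = len(families) * df["formulation"].nunique() * df["participant_id"].nunique()
    flags: list[str] = []
    if len(df) < 0.8 * n_cells:
        flags.append("unbalanced")
        warnings.warn("more than 20% of cohort cells are missing", stacklevel=2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            "value ~ C(family) * C(formulation)", groups="participant_id", data=df
        )
        fitted = model.fit(reml=True)

    k = len(fitted.fe_params)
    fe = np.asarray(fitted.fe_params)
    cov_fe = np.asarray(fitted.cov_params())[:k, :k]
    design_info = model.data.design_info
    term_idx: dict[str, list[int]] = {}
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        key = (
            "interaction"
            if ":" in term
            else "family"
            if "family" in term
            else "formulation"
        )
        term_idx[key] = list(range(sl.start, sl.stop))
    fixed_p = {key: _wald_term_p(fe, cov_fe, idx) for key, idx in term_idx.items()}

    var_random = float(np.asarray(fitted.cov_re)[0, 0])
    var_resid = float(fitted.scale)
    var_fixed = float(np.var(model.exog @ fe, ddof=1))
    r2m, r2c, icc = variance_explained(var_fixed, var_random, var_resid)
    if var_random <= 1e-10 * max(var_resid, 1e-12):
        flags.append("boundary_variance")
    if not fitted.converged:
        flags.append("not_converged")

    posthoc: list[tuple[str, float]] = []
    if fixed_p.get("family", 1.0) <= 0.05 and len(families) >= 2:
        wide = (
            df.groupby(["participant_id", "family"])["value"].mean().unstack("family")
        )
        pairs = [
            (families[i], families[j])
            for i in range(len(families))
            for j in range(i + 1, len(families))
        ]
        raw = []
        for a, b in pairs:
            paired = wide[[a, b]].dropna()
            raw.append(float(stats.ttest_rel(paired[a], paired[b]).pvalue))
        adjusted = holm_adjust(raw)
        posthoc = [(f"{a} vs {b}", p) for (a, b), p in zip(pairs, adjusted)]

    return MixedModelResult(
        outcome=outcome,
        fixed_effect_p=fixed_p,
        var_fixed=var_fixed,
        var_random=var_random,
        var_resid=var_resid,
        r2_marginal=r2m,
        r2_conditional=r2c,
        icc=icc,
        posthoc=posthoc,
        converged=bool(fitted.converged),
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci90: tuple[float, float]
    p: float
    see_percent: float
    delta_percent: float
    n: int


def log_scale_association(x, y, level: float = 0.90) -> CorrelationResult:
    """Pearson correlation of ln(y) on ln(x) with SEE% and Delta%.

    SEE% back-transforms the residual SD of the log-log regression
    (df = n - 2) to percent units; Delta% back-transforms the mean
    leave-one-out log prediction error (in-sample residuals average to
    exactly zero, so a held-out definition is used for the systematic
    difference).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        lx = np.log(np.asarray(x, dtype=float))
        ly = np.log(np.asarray(y, dtype=float))
    if np.any(~np.isfinite(lx)) or np.any(~np.isfinite(ly)):
        raise ValueError("values must be strictly positive and finite")
    n = lx.size
    if n < 3 or ly.size != n:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(lx) == 0:
        raise ValueError("zero variance in x")

    r, p = stats.pearsonr(lx, ly)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) < 1.0 and n > 3:
        z = np.arctanh(r)
        zq = stats.norm.ppf(1 - (1 - level) / 2)
        ci = (float(np.tanh(z - zq / np.sqrt(n - 3))), float(np.tanh(z + zq / np.sqrt(n - 3))))
    else:
        ci = (r, r)

    # log-log OLS and hat-matrix leave-one-out residuals
    xc = lx - lx.mean()
    sxx = float(xc @ xc)
    beta = float(xc @ ly) / sxx
    alpha = float(ly.mean() - beta * lx.mean())
    resid = ly - (alpha + beta * lx)
    s_res = float(np.sqrt((resid @ resid) / (n - 2)))
    h = 1.0 / n + xc**2 / sxx
    loo = resid / (1.0 - h)
    return CorrelationResult(
        r=r,
        ci90=ci,
        p=float(p),
        see_percent=100.0 * float(np.expm1(s_res)),
        delta_percent=100.0 * float(np.expm1(loo.mean())),
        n=n,
    )


def percent_difference(smaller: float, larger: float) -> float:
    """How much smaller ``smaller`` is than ``larger``: 100 (larger - smaller)/larger."""
    if not larger > 0:
        raise ValueError("reference (larger) value must be positive")
    return 100.0 * (larger - smaller) / larger


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p values (never below the raw p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def icc_label(icc: float) -> str:
    """Reliability label: poor < 0.5 <= moderate < 0.75 <= good < 0.9 <= excellent."""
    if not 0 <= icc <= 1:
        raise ValueError("ICC must lie in [0, 1]")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def correlation_label(r: float) -> str:
    """|r| label: negligible < 0.3 <= low < 0.5 <= moderate < 0.7 <= high < 0.9 <= very high."""
    a = abs(r)
    if a > 1:
        raise ValueError("|r| must not exceed 1")
    if a < 0.3:
        return "negligible"
    if a < 0.5:
        return "low"
    if a < 0.7:
        return "moderate"
    if a < 0.9:
        return "high"
    return "very high"
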