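"""Fit-quality metrics: confidence intervals, combined %SEE, AIC, and
residual heteroscedasticity diagnostics.

Conventions
-----------
* Confidence intervals are t-quantile x asymptotic SE with df = n - p
  (default level 90 %).
* The combined %SEE is the sum over fitted parameters of the SE
  expressed as a percent of the absolute estimate.  For the exponential
  family the fitted parameters are (CS, tau, s_max); a variant that
  replaces tau by the derived d'_max (delta-method SE) is available for
  cross-family comparisons.
* AIC = n ln(weighted RSS / n) + 2p.  The weighted RSS carries the
  squared units of the formulation's dependent variable, so AIC is
  comparable across families only within one formulation, never across
  formulations.  No small-sample correction is applied.
* The heteroscedasticity profile pairs predicted values with absolute
  weighted residuals; the Spearman rank correlation between the two is
  reported as a scalar index (0 under homoscedasticity-after-weighting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimator import FitResult
from .models import ModelFamily, dprime_max_exp

__all__ = [
    "ParamInterval",
    "IntervalSet",
    "HeteroscedasticityProfile",
    "QualityReport",
    "parameter_intervals",
    "combined_percent_see",
    "information_criterion",
    "residual_heteroscedasticity",
    "percent_excess",
    "quality_report",
]


@dataclass(frozen=True)
class ParamInterval:
    estimate: float
    half_width: float

    @property
    def lower(self) -> float:
        return self.estimate - self.half_width

    @property
    def upper(self) -> float:
        return self.estimate + self.half_width


@dataclass(frozen=True)
class IntervalSet:
    level: float
    intervals: dict[str, ParamInterval]

    def __getitem__(self, name: str) -> ParamInterval:
        return self.intervals[name]


@dataclass(frozen=True)
class HeteroscedasticityProfile:
    """(predicted value, |weighted residual|) pairs plus a rank index."""

    predicted: np.ndarray
    abs_weighted_residuals: np.ndarray
    index: float  # Spearman rho; 0 when undefined (constant inputs)


@dataclass(frozen=True)
class QualityReport:
    intervals: IntervalSet | None
    percent_see: float | None
    aic: float | None
    residual_profile: HeteroscedasticityProfile


def _require_se(fit: FitResult) -> dict[str, float]:
    if fit.params is None:
        raise ValueError("fit carries no estimates")
    if fit.standard_errors is None:
        raise ValueError("standard errors unavailable (df = 0)")
    return fit.standard_errors


def parameter_intervals(fit: FitResult, level: float = 0.90) -> IntervalSet:
    """Per-parameter confidence intervals, half-width = t(1-(1-level)/2, df) x SE."""
    if not 0 <= level < 1:
        raise ValueError("level must lie in [0, 1)")
    se = _require_se(fit)
    if fit.df < 1:
        raise ValueError("df must be >= 1 for confidence intervals")
    tq = float(stats.t.ppf(1 - (1 - level) / 2, fit.df))
    return IntervalSet(
        level=level,
        intervals={
            name: ParamInterval(float(getattr(fit.params, name)), tq * se[name])
            for name in fit.param_names
        },
    )


def combined_percent_see(fit: FitResult, dprime_max_variant: bool = False) -> float:
    """Sum of per-parameter SEs as percent of their absolute estimates.

    With ``dprime_max_variant=True`` (exponential family only), tau is
    replaced by the derived d'_max with its delta-method SE.
    """
    se = _require_se(fit)
    names = list(fit.param_names)
    estimates = {n: float(getattr(fit.params, n)) for n in names}
    ses = dict(se)
    if dprime_max_variant:
        if fit.spec.family is not ModelFamily.THREE_PARAM_EXP:
            raise ValueError("d'_max variant applies to the exponential family only")
        if fit.covariance is None:
            raise ValueError("covariance unavailable")
        p = fit.params
        dmax = dprime_max_exp(p)
        # gradient of tau (s_max - cs)/e in fit order (cs, tau, s_max)
        g = np.array([-p.tau / math.e, (p.s_max - p.cs) / math.e, p.tau / math.e])
        var = float(g @ fit.covariance @ g)
        names[names.index("tau")] = "d_prime_max"
        estimates["d_prime_max"] = dmax
        ses["d_prime_max"] = math.sqrt(max(var, 0.0))
    total = 0.0
    for n in names:
        if estimates[n] == 0:
            raise ValueError(f"zero estimate for {n}; %SEE undefined")
        total += 100.0 * ses[n] / abs(estimates[n])
    return total


def information_criterion(fit: FitResult) -> float | None:
    """AIC = n ln(weighted RSS / n) + 2p; ``None`` for a perfect fit.

    Comparable across model families only within one formulation.
    """
    if fit.params is None:
        raise ValueError("fit carries no estimates")
    if not fit.weighted_rss > 0:
        return None  # zero residual: criterion degenerates to -inf
    return float(fit.n_obs * math.log(fit.weighted_rss / fit.n_obs) + 2 * fit.n_params)


def residual_heteroscedasticity(fit: FitResult) -> HeteroscedasticityProfile:
    """Absolute weighted residuals against predicted values.

    A positive Spearman index means residual spread still grows with the
    predicted value, i.e. the weighting did not remove the
    heteroscedasticity.
    """
    pred = np.asarray(fit.fitted_values, dtype=float)
    absres = np.abs(np.asarray(fit.weighted_residuals, dtype=float))
    if pred.size < 2 or np.allclose(absres, absres[0] if absres.size else 0.0):
        index = 0.0
    else:
        rho = stats.spearmanr(pred, absres).statistic
        index = float(rho) if np.isfinite(rho) else 0.0
    return HeteroscedasticityProfile(pred, absres, index)


def percent_excess(a: float, b: float) -> float:
    """How much larger ``a`` is than the reference ``b``: 100 (a - b)/b."""
    if not b > 0:
        raise ValueError("reference value must be positive")
    return 100.0 * (a - b) / b


def quality_report(fit: FitResult, level: float = 0.90) -> QualityReport:
    """Bundle intervals, %SEE and AIC; metrics missing when df = 0."""
    profile = residual_heteroscedasticity(fit)
    if fit.standard_errors is None or fit.df < 1:
        return QualityReport(None, None, information_criterion(fit), profile)
    return QualityReport(
        intervals=parameter_intervals(fit, level),
        percent_see=combined_percent_see(fit),
        aic=information_criterion(fit),
        residual_profile=profile,
    )
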