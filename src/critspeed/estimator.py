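"""Weighted least-squares estimation of power-duration parameters.

The estimator follows the statistically appropriate fitting procedures
for the treadmill critical-speed test: speed is the error-free
controlled variable, so the loss is minimised along the dependent
variable only — time to exhaustion for the t(s) formulation, distance
for d(s).  Time-to-exhaustion data are heteroscedastic, with variance
roughly proportional to the dependent variable itself, so observations
are weighted by the inverse of the dependent value (inverse-variance
weighting under that law), normalised to sum to n so the objective is
scale-free.

Minimisation uses a bounded trust-region Levenberg-Marquardt variant
(`scipy.optimize.least_squares`, method ``"trf"``) inside the box
cs in (0, min speed), d' > 0, s_max > max speed, tau > 0; the box keeps
every data point inside the model's speed domain during iteration.
Standard errors come from the weighted Gauss-Newton covariance
s^2 (J'WJ)^-1 with s^2 = weighted RSS / (n - p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data import TrialSet
from .models import (
    PARAM_NAMES,
    BATTERY,
    Formulation,
    ModelFamily,
    ModelSpec,
    Params,
    predict,
    predict_time,
)

__all__ = [
    "CriticalSpeedRegressor",
    "FitResult",
    "observation_weights",
    "initial_params",
    "fit_trialset",
    "fit_battery",
]

# distance kept between cs and the slowest trial speed (and s_max and the
# fastest) so the model stays defined at every data point during iteration
_EDGE = 1e-6


def observation_weights(dependent_values) -> np.ndarray:
    """WLS weights proportional to 1/y, normalised to sum to n.

    Under the assumed error law Var[y_i] proportional to y_i, weights
    proportional to the inverse variance are proportional to 1/y_i.
    The normalisation makes the weighted objective invariant to the
    unit (scale) of the dependent variable.
    """
    y = np.asarray(dependent_values, dtype=float)
    if np.any(y <= 0):
        raise ValueError("dependent values must be strictly positive to form 1/y weights")
    w = 1.0 / y
    return w * (y.size / w.sum())


def initial_params(trials: TrialSet, family: ModelFamily) -> Params:
    """Starting values from the linear distance-time regression.

    For the two-parameter family d = d' + CS*t exactly, so the ordinary
    regression of distance on time yields the starts (slope -> CS,
    intercept -> d').  Three-parameter families add s_max = 1.5x the
    fastest trial speed (1.4x for the exponential family, whose s_max
    estimates run lower) and tau = the observed time at the
    second-fastest speed.  Starts are clipped into the fitting box.
    """
    family = ModelFamily(family)
    if trials.n_obs < 2:
        raise ValueError("at least two observations are needed for starting values")
    t, d = trials.times, trials.distances
    slope, intercept = np.polyfit(t, d, 1)
    if not np.isfinite(slope) or not np.isfinite(intercept):
        raise ValueError("degenerate distance-time regression")
    cs0 = float(np.clip(slope, 0.25 * trials.min_speed, (1.0 - 1e-3) * trials.min_speed))
    dp0 = float(max(intercept, 1.0))
    if family is ModelFamily.TWO_PARAM:
        return Params(cs=cs0, d_prime=dp0)
    if family is ModelFamily.THREE_PARAM:
        return Params(cs=cs0, d_prime=dp0, s_max=1.5 * trials.max_speed)
    order = np.argsort(trials.speeds)[::-1]
    tau0 = float(trials.times[order[1]]) if trials.n_obs >= 2 else float(trials.times[order[0]])
    return Params(cs=cs0, tau=tau0, s_max=1.4 * trials.max_speed)


@dataclass
class FitResult:
    """Outcome of one (family, formulation) fit.

    ``standard_errors`` / ``covariance`` are ``None`` when df = 0, and
    the whole parameter block is ``None`` for a fit that could not be
    attempted (see ``flags``).  ``weighted_rss`` is in the squared units
    of the formulation's dependent variable, so it is comparable across
    families only within one formulation.
    """

    spec: ModelSpec
    params: Params | None
    standard_errors: dict[str, float] | None
    covariance: np.ndarray | None
    weighted_rss: float
    n_obs: int
    df: int
    residuals: np.ndarray
    weighted_residuals: np.ndarray
    weights: np.ndarray
    fitted_values: np.ndarray
    converged: bool
    iterations: int
    flags: tuple[str, ...] = ()
    participant_id: str | None = None

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.spec.family]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def ok(self) -> bool:
        """Converged, in-bounds fit usable for cohort summaries."""
        return self.converged and self.params is not None and "active_bound" not in self.flags


def _bounds(family: ModelFamily, trials: TrialSet) -> tuple[np.ndarray, np.ndarray]:
    lo_s, hi_s = trials.min_speed, trials.max_speed
    box = {
        "cs": (1e-8, lo_s - _EDGE * max(1.0, lo_s)),
        "d_prime": (1e-8, np.inf),
        "s_max": (hi_s + _EDGE * max(1.0, hi_s), np.inf),
        "tau": (1e-8, np.inf),
    }
    names = PARAM_NAMES[family]
    lo = np.array([box[n][0] for n in names])
    hi = np.array([box[n][1] for n in names])
    return lo, hi


class CriticalSpeedRegressor(RegressorMixin, BaseEstimator):
    """Power-duration model fitted by weighted least squares.

    Parameters
    ----------
    family : {"2p", "3p", "3pexp"} or ModelFamily, default "2p"
        Model family: two-parameter hyperbola, three-parameter
        hyperbola, or three-parameter exponential.
    formulation : {"ts", "ds"} or Formulation, default "ts"
        Dependent variable of the WLS objective: time t(s) or distance
        d(s).  ``y`` passed to :meth:`fit` is always the measured time
        to exhaustion in seconds; for ``"ds"`` the distance y*X is
        formed internally.
    weighting : {"inverse_dependent", "none", "iterative_fitted"}
        Weight source.  ``"inverse_dependent"`` (default) computes 1/y
        weights from the observed dependent values; ``"iterative_fitted"``
        re-derives them from fitted values over a few reweighting
        passes; ``"none"`` is ordinary least squares.
    max_iterations : int, default 500
        Cap on objective evaluations per start.
    tol : float, default 1e-10
        Relative step/gradient/cost convergence tolerance.
    n_restarts : int, default 5
        Jittered restarts (+-20 % on each start value) tried when the
        default start fails to converge cleanly.
    random_state : int, default 0
        Seed for the restart jitter.

    Attributes
    ----------
    params_ : Params
        Point estimates (also exposed as ``cs_``, ``d_prime_``,
        ``s_max_``, ``tau_`` where applicable).
    standard_errors_ : dict or None
        Asymptotic SEs per parameter; ``None`` when df = 0.
    result_ : FitResult
        Full record (residuals, weights, convergence, flags).

    Examples
    --------
    >>> reg = CriticalSpeedRegressor(family="2p", formulation="ts")
    >>> reg.fit([[4.5], [5.0], [5.5], [6.0]], [400.0, 200.0, 400/3, 100.0])
    ... # doctest: +ELLIPSIS
    CriticalSpeedRegressor(...)
    >>> round(reg.cs_, 6), round(reg.d_prime_, 4)
    (4.0, 200.0)
    """

    def __init__(
        self,
        family: str | ModelFamily = "2p",
        formulation: str | Formulation = "ts",
        weighting: str = "inverse_dependent",
        max_iterations: int = 500,
        tol: float = 1e-10,
        n_restarts: int = 5,
        random_state: int = 0,
    ) -> None:
        self.family = family
        self.formulation = formulation
        self.weighting = weighting
        self.max_iterations = max_iterations
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _spec(self) -> ModelSpec:
        return ModelSpec(ModelFamily(self.family), Formulation(self.formulation))

    def fit(self, X, y, participant_id: str | None = None):
        """Fit to trial speeds ``X`` (m/s) and times to exhaustion ``y`` (s)."""
        speeds = np.asarray(X, dtype=float)
        if speeds.ndim == 2:
            if speeds.shape[1] != 1:
                raise ValueError("X must be a single column of trial speeds (m/s)")
            speeds = speeds[:, 0]
        times = np.asarray(y, dtype=float)
        trials = TrialSet(participant_id or "anonymous", speeds, times)
        self.result_ = _fit_trials(trials, self._spec(), self._options())
        if self.result_.params is None:
            raise ValueError(
                f"fit not possible: {', '.join(self.result_.flags) or 'unknown failure'}"
            )
        self.params_ = self.result_.params
        self.standard_errors_ = self.result_.standard_errors
        self.weighted_rss_ = self.result_.weighted_rss
        self.weights_ = self.result_.weights
        self.residuals_ = self.result_.residuals
        self.df_ = self.result_.df
        self.converged_ = self.result_.converged
        self.n_features_in_ = 1
        for name in PARAM_NAMES[self._spec().family]:
            setattr(self, f"{name}_", getattr(self.params_, name))
        return self

    def _options(self) -> dict:
        if self.weighting not in ("inverse_dependent", "none", "iterative_fitted"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        return dict(
            weighting=self.weighting,
            max_iterations=int(self.max_iterations),
            tol=float(self.tol),
            n_restarts=int(self.n_restarts),
            random_state=int(self.random_state),
        )

    def predict(self, X):
        """Predicted time to exhaustion (s) at speeds ``X`` (m/s)."""
        check_is_fitted(self, "params_")
        speeds = np.asarray(X, dtype=float)
        if speeds.ndim == 2:
            speeds = speeds[:, 0]
        return np.asarray(predict_time(ModelFamily(self.family), self.params_, speeds))


# ----------------------------------------------------------------------
# functional layer


def _fit_trials(trials: TrialSet, spec: ModelSpec, opts: dict) -> FitResult:
    family = spec.family
    p = len(PARAM_NAMES[family])
    n = trials.n_obs
    speeds = trials.speeds
    dep = trials.times if spec.formulation is Formulation.TIME_OF_SPEED else trials.distances

    empty = np.zeros(0)
    if n < p:
        return FitResult(
            spec, None, None, None, np.nan, n, n - p, empty, empty, empty, empty,
            converged=False, iterations=0, flags=("insufficient_observations",),
            participant_id=trials.participant_id,
        )

    if opts["weighting"] == "none":
        w = np.ones(n)
    else:
        w = observation_weights(dep)
    sqrt_w = np.sqrt(w)
    lo, hi = _bounds(family, trials)

    def residual(theta: np.ndarray) -> np.ndarray:
        params = Params.from_array(family, theta)
        return sqrt_w * (dep - np.asarray(predict(spec, params, speeds)))

    theta0 = initial_params(trials, family).as_array(family)
    theta0 = np.clip(theta0, lo * (1 + 1e-9) + 1e-12, np.where(np.isfinite(hi), hi * (1 - 1e-9), np.inf))

    def solve(theta_start):
        return least_squares(
            residual,
            theta_start,
            bounds=(lo, hi),
            method="trf",
            xtol=opts["tol"],
            ftol=opts["tol"],
            gtol=opts["tol"],
            max_nfev=opts["max_iterations"],
        )

    best = solve(theta0)
    total_nfev = best.nfev
    if not best.success or not np.isfinite(best.cost):
        rng = np.random.default_rng(opts["random_state"])
        for _ in range(opts["n_restarts"]):
            jitter = 1.0 + rng.uniform(-0.2, 0.2, size=theta0.size)
            start = np.clip(theta0 * jitter, lo * (1 + 1e-9) + 1e-12,
                            np.where(np.isfinite(hi), hi * (1 - 1e-9), np.inf))
            cand = solve(start)
            total_nfev += cand.nfev
            if cand.success and (not best.success or cand.cost < best.cost):
                best = cand
        # a converged restart replaces a failed default start entirely

    if opts["weighting"] == "iterative_fitted":
        # a few reweighting passes: weights from current fitted values
        for _ in range(3):
            fitted = np.asarray(predict(spec, Params.from_array(family, best.x), speeds))
            if np.any(fitted <= 0):
                break
            w = observation_weights(fitted)
            sqrt_w = np.sqrt(w)
            best = solve(best.x)
            total_nfev += best.nfev

    theta = best.x
    params = Params.from_array(family, theta)
    fitted = np.asarray(predict(spec, params, speeds))
    raw = dep - fitted
    weighted = sqrt_w * raw
    wrss = float(np.sum(weighted**2))
    df = n - p

    flags: list[str] = []
    if not best.success:
        flags.append("not_converged")
    at_bound = (theta - lo <= 1e-7 * (np.abs(lo) + 1.0)) | (
        np.isfinite(hi) & (hi - theta <= 1e-7 * (np.abs(hi) + 1.0))
    )
    if np.any(at_bound):
        flags.append("active_bound")

    se: dict[str, float] | None = None
    cov: np.ndarray | None = None
    if df >= 1:
        J = best.jac  # jacobian of the weighted residuals
        JTJ = J.T @ J
        try:
            cov = float(wrss / df) * np.linalg.pinv(JTJ)
            se = {
                name: float(np.sqrt(max(cov[i, i], 0.0)))
                for i, name in enumerate(PARAM_NAMES[family])
            }
        except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
            flags.append("singular_covariance")
    else:
        flags.append("no_dof")

    return FitResult(
        spec=spec,
        params=params,
        standard_errors=se,
        covariance=cov,
        weighted_rss=wrss,
        n_obs=n,
        df=df,
        residuals=raw,
        weighted_residuals=weighted,
        weights=w,
        fitted_values=fitted,
        converged=best.success,
        iterations=int(total_nfev),
        flags=tuple(flags),
        participant_id=trials.participant_id,
    )


def fit_trialset(
    trials: TrialSet,
    family: str | ModelFamily = "2p",
    formulation: str | Formulation = "ts",
    **options,
) -> FitResult:
    """Fit one (family, formulation) cell of the battery to a TrialSet."""
    reg = CriticalSpeedRegressor(family=family, formulation=formulation, **options)
    spec = reg._spec()
    return _fit_trials(trials, spec, reg._options())


def fit_battery(trials: TrialSet, **options) -> list[FitResult]:
    """All six (family, formulation) fits in fixed battery order.

    Order: two-parameter, three-parameter, three-parameter exponential,
    each t(s) then d(s).  A cell that cannot be fitted (e.g. too few
    observations for a three-parameter family) is carried as a flagged
    entry rather than aborting the battery.
    """
    reg = CriticalSpeedRegressor(**options)
    opts = reg._options()
    return [_fit_trials(trials, spec, opts) for spec in BATTERY]
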