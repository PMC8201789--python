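"""Published group-level summaries of the treadmill cohort this package
emulates.

The reference study cohort is sixteen trained male runners who each
completed a maximal incremental treadmill test (2.78 m/s warm-up,
+0.28 m/s every 2 min) and four randomized exhaustive constant-speed
runs at 90, 100, 110 and 120 % of the incremental test's peak speed
(PS).  Only group-level summaries were published — no per-participant
raw trials — so these numbers serve two roles here: as the targets the
synthetic-cohort generator is centred on, and as inputs to the
reporting arithmetic (between-model percent comparisons) that the
acceptance checks recompute.

All values are group means; speeds m/s, distances m, times of the trial
table minutes (converted to seconds by `reference_group_trials`),
oxygen uptake ml/min/kg.
"""

from __future__ import annotations

import numpy as np

from .data import TrialSet

__all__ = [
    "TRIAL_PERCENTS",
    "TRIAL_MEAN_MINUTES",
    "INCREMENTAL_SUMMARY",
    "GROUP_FITS",
    "reference_group_trials",
]

#: Exhaustive-run intensities, % of incremental peak speed.
TRIAL_PERCENTS = (90.0, 100.0, 110.0, 120.0)

#: Group-mean time to exhaustion at each intensity, minutes.
TRIAL_MEAN_MINUTES = (14.8, 5.94, 2.78, 1.68)

#: Group means of the incremental test.
INCREMENTAL_SUMMARY = {
    "s_vo2max": 5.05,  # m/s
    "peak_speed": 5.16,  # m/s
    "vo2max": 63.0,  # ml/min/kg
    "vt": 47.1,  # ml/min/kg
    "rcp": 56.3,  # ml/min/kg
    "vt_percent_vo2max": 74.8,
    "rcp_percent_vo2max": 89.3,
}

#: Group-mean battery results, keyed by (family value, formulation value).
#: cs m/s, d_prime m (d'_max for the exponential family), s_max m/s,
#: percent_see %, aic unitless (comparable within one formulation only).
GROUP_FITS = {
    ("2p", "ts"): dict(cs=4.39, d_prime=226.0, s_max=None, percent_see=9.8, aic=32.3),
    ("2p", "ds"): dict(cs=4.39, d_prime=222.3, s_max=None, percent_see=9.7, aic=45.8),
    ("3p", "ts"): dict(cs=4.12, d_prime=556.9, s_max=7.72, percent_see=24.8, aic=24.1),
    ("3p", "ds"): dict(cs=4.12, d_prime=546.6, s_max=7.76, percent_see=25.2, aic=37.8),
    ("3pexp", "ts"): dict(cs=4.55, d_prime=219.5, s_max=6.96, percent_see=23.9, aic=24.4),
    ("3pexp", "ds"): dict(cs=4.56, d_prime=217.7, s_max=6.98, percent_see=24.1, aic=38.2),
}


def reference_group_trials() -> TrialSet:
    """Group-mean pseudo-participant built from the published summaries.

    Speeds are 90-120 % of the mean peak speed (5.16 m/s); times are the
    group-mean times to exhaustion converted to seconds.  Useful as a
    download-free fixture for end-to-end fitting checks; note it is a
    mean profile, not an individual, so refits bracket rather than
    reproduce the published individual-level means.
    """
    ps = INCREMENTAL_SUMMARY["peak_speed"]
    speeds = np.asarray(TRIAL_PERCENTS) / 100.0 * ps
    times = np.asarray(TRIAL_MEAN_MINUTES) * 60.0
    return TrialSet("group_mean", speeds, times, peak_speed=ps)
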