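"""CSV readers and writers for trial and incremental-test data.

Trial CSV (long format, header required)::

    participant_id,speed_mps,time_s

One row per exhaustive run.  Two documented variants are accepted:
``time_min`` instead of ``time_s`` (converted by x60), and percent-of-PS
speed coding via ``percent_ps`` plus ``peak_speed_mps`` instead of
``speed_mps`` (speed = percent_ps/100 x peak_speed_mps).

Incremental CSV::

    participant_id,s_vo2max_mps,alpha,vo2max,vt,rcp,vo2_intercept,vo2_slope,r2
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .aerobic import IncrementalProfile
from .data import TrialSet
from .simulate import SyntheticCohort

__all__ = [
    "read_trials",
    "write_trials",
    "read_incremental",
    "write_incremental",
    "write_truth",
]


class TrialParseError(ValueError):
    """The trial CSV does not match any accepted dialect."""


def _trial_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    cols = set(df.columns)
    if "participant_id" not in cols:
        raise TrialParseError(f"{path}: missing required column participant_id")
    if "speed_mps" in cols:
        speed = df["speed_mps"].astype(float)
    elif {"percent_ps", "peak_speed_mps"} <= cols:
        speed = df["percent_ps"].astype(float) / 100.0 * df["peak_speed_mps"].astype(float)
    else:
        raise TrialParseError(
            f"{path}: need speed_mps, or percent_ps with peak_speed_mps"
        )
    if "time_s" in cols:
        time = df["time_s"].astype(float)
    elif "time_min" in cols:
        time = df["time_min"].astype(float) * 60.0
    else:
        raise TrialParseError(f"{path}: need time_s or time_min")
    out = pd.DataFrame(
        {"participant_id": df["participant_id"].astype(str), "speed": speed, "time": time}
    )
    if "peak_speed_mps" in cols:
        out["peak_speed"] = df["peak_speed_mps"].astype(float)
    return out


def read_trials(path) -> list[TrialSet]:
    """Read one TrialSet per participant, in file order of first appearance."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - normalise parser failures
        raise TrialParseError(f"{path}: {exc}") from exc
    frame = _trial_frame(df, path)
    out = []
    for pid, grp in frame.groupby("participant_id", sort=False):
        ps = float(grp["peak_speed"].iloc[0]) if "peak_speed" in grp else None
        try:
            out.append(TrialSet(str(pid), grp["speed"].to_numpy(), grp["time"].to_numpy(), ps))
        except ValueError as exc:
            raise TrialParseError(f"{path}: participant {pid}: {exc}") from exc
    if not out:
        raise TrialParseError(f"{path}: no trial rows")
    return out


def write_trials(trialsets: list[TrialSet], path) -> None:
    rows = [
        dict(participant_id=t.participant_id, speed_mps=s, time_s=tt)
        for t in trialsets
        for s, tt in zip(t.speeds, t.times)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_incremental(path) -> dict[str, IncrementalProfile]:
    df = pd.read_csv(path)
    profiles = {}
    for _, row in df.iterrows():
        pid = str(row["participant_id"])
        profiles[pid] = IncrementalProfile(
            participant_id=pid,
            s_vo2max=float(row["s_vo2max_mps"]),
            alpha=float(row["alpha"]),
            vo2max=float(row["vo2max"]),
            vt=float(row["vt"]) if "vt" in row and pd.notna(row["vt"]) else None,
            rcp=float(row["rcp"]) if "rcp" in row and pd.notna(row["rcp"]) else None,
            vo2_intercept=float(row["vo2_intercept"]),
            vo2_slope=float(row["vo2_slope"]),
            r_squared=float(row["r2"]) if "r2" in row and pd.notna(row["r2"]) else None,
        )
    if not profiles:
        raise TrialParseError(f"{path}: no incremental rows")
    return profiles


def write_incremental(profiles: dict[str, IncrementalProfile], path) -> None:
    rows = [
        dict(
            participant_id=p.participant_id,
            s_vo2max_mps=p.s_vo2max,
            alpha=p.alpha,
            vo2max=p.vo2max,
            vt=p.vt,
            rcp=p.rcp,
            vo2_intercept=p.vo2_intercept,
            vo2_slope=p.vo2_slope,
            r2=p.r_squared,
        )
        for p in profiles.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_truth(cohort: SyntheticCohort, path) -> None:
    cohort.truth_frame().to_csv(path, index=False)
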