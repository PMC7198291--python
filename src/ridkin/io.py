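"""Readers and writers for the package's plain-text formats.

Units are fixed package-wide: times in decimal days, specific activity as
fraction of dose per µmol plasma retinol.  Observation files using a
percent-of-dose dialect must be converted explicitly at the boundary
(``sa_unit="percent"``); units are never guessed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import SACurves, SteadyStateMasses, TracerTrajectory
from .parameters import KineticParameters, read_params, write_params  # noqa: F401

__all__ = [
    "read_observations",
    "write_observations",
    "read_params",
    "write_params",
    "trajectory_frame",
    "write_trajectory",
    "config_hash",
]

OBSERVATION_HEADER = ["subject_id", "time_d", "sa_fod_per_umol"]

TRAJECTORY_HEADER = [
    "time_d",
    "f_delay",
    "f_4",
    "f_5",
    "f_6",
    "f_7",
    "f_out_8",
    "f_out_6",
    "sa_plasma",
    "sa_stores",
]


def read_observations(path: str | Path, *, sa_unit: str = "fraction") -> pd.DataFrame:
    """Read pooled plasma SA observations from CSV.

    The file must carry the header ``subject_id,time_d,sa_fod_per_umol``.
    Malformed, blank or negative rows and duplicate (subject, time) pairs
    are rejected with the offending line number (header = line 1).
    """
    path = Path(path)
    if sa_unit not in ("fraction", "percent"):
        raise ValueError(f"sa_unit must be 'fraction' or 'percent', got {sa_unit!r}")
    frame = pd.read_csv(
        path,
        dtype={"subject_id": str},
        skip_blank_lines=False,
        float_precision="round_trip",
    )
    if list(frame.columns) != OBSERVATION_HEADER:
        raise ValueError(
            f"{path}: expected header {','.join(OBSERVATION_HEADER)}, "
            f"got {','.join(map(str, frame.columns))}"
        )
    for col in ("time_d", "sa_fod_per_umol"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() | frame["subject_id"].isna()]
        if len(bad):
            raise ValueError(
                f"{path}: malformed or blank value in column {col!r} "
                f"at line {int(bad[0]) + 2}"
            )
        frame[col] = coerced
    negative = frame.index[(frame["time_d"] < 0) | (frame["sa_fod_per_umol"] < 0)]
    if len(negative):
        raise ValueError(
            f"{path}: negative time or SA at line {int(negative[0]) + 2}"
        )
    duplicated = frame.index[frame.duplicated(["subject_id", "time_d"])]
    if len(duplicated):
        raise ValueError(
            f"{path}: duplicate (subject_id, time_d) pair at line "
            f"{int(duplicated[0]) + 2}"
        )
    if sa_unit == "percent":
        frame["sa_fod_per_umol"] = frame["sa_fod_per_umol"] / 100.0
    return frame


def write_observations(frame: pd.DataFrame, path: str | Path) -> None:
    frame.loc[:, OBSERVATION_HEADER].to_csv(path, index=False)


def trajectory_frame(
    traj: TracerTrajectory, sa: SACurves | None = None
) -> pd.DataFrame:
    """Tabulate a tracer trajectory (and SA curves) for CSV export."""
    data = {
        "time_d": traj.times,
        "f_delay": traj.f_delay,
        "f_4": traj.f_4,
        "f_5": traj.f_5,
        "f_6": traj.f_6,
        "f_7": traj.f_7,
        "f_out_8": traj.f_out_8,
        "f_out_6": traj.f_out_6,
    }
    if sa is not None:
        data["sa_plasma"] = sa.sa_plasma
        data["sa_stores"] = sa.sa_stores
    else:
        data["sa_plasma"] = np.full(traj.times.size, np.nan)
        data["sa_stores"] = np.full(traj.times.size, np.nan)
    return pd.DataFrame(data, columns=TRAJECTORY_HEADER)


def write_trajectory(
    traj: TracerTrajectory,
    path: str | Path,
    *,
    masses: SteadyStateMasses | None = None,
    sa: SACurves | None = None,
) -> None:
    if sa is None and masses is not None:
        from .kinetics import specific_activity

        sa = specific_activity(traj, masses)
    trajectory_frame(traj, sa).to_csv(path, index=False)


def config_hash(config: dict) -> str:
    """Short stable hash of a config mapping, for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
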