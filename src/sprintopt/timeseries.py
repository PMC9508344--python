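"""Tabular time-series I/O and the experiment-data container.

Two dialects are supported: plain CSV and an OpenSim-style STO/MOT text
format (tab-separated, a small ``key=value`` header terminated by
``endheader``, time in the first column). An :class:`ExperimentData`
bundle holds the coordinate, ground-reaction-force and net-joint-moment
tables for one two-step trial together with body mass and stance-window
metadata, and round-trips to a directory of STO files plus a JSON sidecar.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_timeseries", "write_timeseries", "ExperimentData"]


def write_timeseries(path, df: pd.DataFrame, dialect: str | None = None, name: str | None = None):
    """Write a time-series table (first column must be ``time``).

    ``dialect`` is ``"csv"`` or ``"sto"``; inferred from the suffix when
    omitted (.sto/.mot -> sto, otherwise csv).
    """
    path = Path(path)
    if df.columns[0] != "time":
        raise ValueError("first column must be 'time'")
    if dialect is None:
        dialect = "sto" if path.suffix.lower() in (".sto", ".mot") else "csv"
    if dialect == "csv":
        df.to_csv(path, index=False, float_format="%.17g")
    elif dialect == "sto":
        with open(path, "w") as fh:
            fh.write(f"{name or path.stem}\n")
            fh.write("version=1\n")
            fh.write(f"nRows={len(df)}\n")
            fh.write(f"nColumns={df.shape[1]}\n")
            fh.write("inDegrees=no\n")
            fh.write("endheader\n")
            fh.write("\t".join(df.columns) + "\n")
            np.savetxt(fh, df.to_numpy(), fmt="%.17g", delimiter="\t")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_timeseries(path, dialect: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if dialect is None:
        dialect = "sto" if path.suffix.lower() in (".sto", ".mot") else "csv"
    if dialect == "csv":
        return pd.read_csv(path)
    if dialect != "sto":
        raise ValueError(f"unknown dialect {dialect!r}")
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    end = None
    for i, line in enumerate(lines):
        s = line.strip()
        if s == "endheader":
            end = i
            break
        if "=" in s:
            k, _, v = s.partition("=")
            header[k.strip()] = v.strip()
    if end is None:
        raise ValueError(f"{path}: malformed STO header, no 'endheader' line")
    cols = lines[end + 1].rstrip("\n").split("\t")
    body = [ln for ln in lines[end + 2 :] if ln.strip()]
    try:
        data = np.array([[float(x) for x in ln.split()] for ln in body])
    except ValueError as e:
        raise ValueError(f"{path}: malformed data row near line {end + 3}: {e}") from None
    df = pd.DataFrame(data.reshape(-1, len(cols)), columns=cols)
    for key, expect in (("nRows", len(df)), ("nColumns", df.shape[1])):
        if key in header and int(header[key]) != expect:
            raise ValueError(
                f"{path}: header {key}={header[key]} inconsistent with body ({expect})"
            )
    return df


@dataclass
class ExperimentData:
    """One two-step sprint trial: kinematics, GRF and net joint moments.

    All tables share ``time``. ``coords`` has one column per generalized
    coordinate, ``grf`` columns ``<foot>_x`` / ``<foot>_y`` per foot, and
    ``moments`` one column per internal DOF. ``stance_windows`` maps foot
    segment names to (touchdown, takeoff) times.
    """

    time: np.ndarray
    coords: pd.DataFrame
    grf: pd.DataFrame
    moments: pd.DataFrame
    body_mass: float
    stance_windows: dict[str, tuple[float, float]] = field(default_factory=dict)
    trial_id: str = "synthetic"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for name in ("coords", "grf", "moments"):
            df = getattr(self, name)
            if len(df) != len(self.time):
                raise ValueError(f"{name} table length does not match time grid")
        for foot, (td, to) in self.stance_windows.items():
            if not (self.time[0] - 1e-9 <= td < to <= self.time[-1] + 1e-9):
                raise ValueError(f"stance window for {foot} outside the horizon")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def grf_bw(self) -> pd.DataFrame:
        """GRF normalized to body weight (for reporting)."""
        g = 9.80665
        out = self.grf / (self.body_mass * g)
        return out

    def _with_time(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out.insert(0, "time", self.time)
        return out

    def save(self, directory):
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_timeseries(d / "coordinates.sto", self._with_time(self.coords))
        write_timeseries(d / "grf.sto", self._with_time(self.grf))
        write_timeseries(d / "moments.sto", self._with_time(self.moments))
        meta = {
            "body_mass": self.body_mass,
            "stance_windows": {k: list(v) for k, v in self.stance_windows.items()},
            "trial_id": self.trial_id,
            "metadata": self.metadata,
        }
        with open(d / "experiment.json", "w") as fh:
            json.dump(meta, fh, indent=2, default=_jsonable)

    @classmethod
    def load(cls, directory) -> "ExperimentData":
        d = Path(directory)
        coords = read_timeseries(d / "coordinates.sto")
        grf = read_timeseries(d / "grf.sto")
        moments = read_timeseries(d / "moments.sto")
        with open(d / "experiment.json") as fh:
            meta = json.load(fh)
        time = coords["time"].to_numpy()
        return cls(
            time=time,
            coords=coords.drop(columns="time"),
            grf=grf.drop(columns="time"),
            moments=moments.drop(columns="time"),
            body_mass=meta["body_mass"],
            stance_windows={k: tuple(v) for k, v in meta["stance_windows"].items()},
            trial_id=meta.get("trial_id", "unknown"),
            metadata=meta.get("metadata", {}),
        )


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
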