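"""Trajectory container and plain-text I/O.

A :class:`Trajectory` is the ordered ``(t, x, y)`` record of one granule in
physical units (seconds, micrometres).  It is produced by the simulator
(``source="ground_truth"``), by the spot linker (``source="linked"``), or read
from a CSV exported by other tracking software (``source="csv"``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: motion-regime labels used by the simulator's ground truth
REGIME_FREE = "free"
REGIME_CORRALLED = "corralled"
REGIME_TRANSPORT = "transport"


@dataclass
class Trajectory:
    """Ordered positions of a single granule.

    Parameters
    ----------
    times:
        Strictly increasing observation times in seconds, shape ``(n,)``.
    xy:
        Positions in micrometres, shape ``(n, 2)`` as ``(x, y)``.
    frames:
        Acquisition frame index per point; defaults to ``0..n-1``.
    track_id:
        Integer identity of the track within its dataset.
    source:
        One of ``{"linked", "ground_truth", "csv"}``.
    regimes:
        Optional per-point motion-regime label (ground truth only).  Point
        ``i`` is labelled with the regime that generated the step from point
        ``i`` to ``i + 1``; the final point repeats the previous label.
    """

    times: np.ndarray
    xy: np.ndarray
    frames: np.ndarray | None = None
    track_id: int = 0
    source: str = "linked"
    regimes: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError(f"xy must have shape (n, 2), got {self.xy.shape}")
        if self.times.shape[0] != self.xy.shape[0]:
            raise ValueError("times and xy length mismatch")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.frames is None:
            self.frames = np.arange(self.times.size)
        else:
            self.frames = np.asarray(self.frames, dtype=int)
        if self.regimes is not None and len(self.regimes) != self.times.size:
            raise ValueError("regimes length mismatch")

    @property
    def n(self) -> int:
        return int(self.times.size)

    def is_uniform_dt(self, rtol: float = 1e-6) -> bool:
        if self.n < 2:
            return True
        d = np.diff(self.times)
        return bool(np.allclose(d, d[0], rtol=rtol, atol=0.0))

    @property
    def dt(self) -> float:
        """Uniform frame interval in seconds; raises on irregular sampling."""
        if self.n < 2:
            raise ValueError("dt undefined for a track with < 2 points")
        if not self.is_uniform_dt():
            raise ValueError("trajectory is not uniformly sampled")
        return float(self.times[1] - self.times[0])

    def subwindow(self, t0: float, t1: float) -> "Trajectory":
        """Points with ``t0 <= t < t1`` as a new trajectory (views copied)."""
        mask = (self.times >= t0) & (self.times < t1)
        return Trajectory(
            times=self.times[mask].copy(),
            xy=self.xy[mask].copy(),
            frames=self.frames[mask].copy(),
            track_id=self.track_id,
            source=self.source,
            regimes=[r for r, m in zip(self.regimes, mask) if m]
            if self.regimes is not None
            else None,
        )


def trajectories_to_dataframe(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Long-format table: track_id, frame, t_s, x_um, y_um[, regime]."""
    rows = []
    for tr in trajectories:
        df = pd.DataFrame(
            {
                "track_id": tr.track_id,
                "frame": tr.frames,
                "t_s": tr.times,
                "x_um": tr.xy[:, 0],
                "y_um": tr.xy[:, 1],
            }
        )
        df["regime"] = tr.regimes if tr.regimes is not None else ""
        rows.append(df)
    if not rows:
        return pd.DataFrame(
            columns=["track_id", "frame", "t_s", "x_um", "y_um", "regime"]
        )
    return pd.concat(rows, ignore_index=True)


def write_tracks_csv(trajectories: list[Trajectory], path) -> None:
    trajectories_to_dataframe(trajectories).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_tracks_csv(path, source: str = "csv") -> list[Trajectory]:
    """Read trajectories from a long-format CSV (see writer for columns)."""
    df = pd.read_csv(path)
    out = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("t_s")
        regimes = None
        if "regime" in g.columns and g["regime"].notna().all():
            vals = g["regime"].astype(str).tolist()
            if any(v for v in vals):
                regimes = vals
        out.append(
            Trajectory(
                times=g["t_s"].to_numpy(),
                xy=g[["x_um", "y_um"]].to_numpy(),
                frames=g["frame"].to_numpy(),
                track_id=int(tid),
                source=source,
                regimes=regimes,
            )
        )
    return out
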