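"""Small plotting helpers mirroring the standard views of this analysis:
a time-coloured trajectory, the cluster-affiliation series, and MSD curves."""
from __future__ import annotations

import numpy as np

from .motion import ClusterResult, MSDCurve
from .tracks import Trajectory


def plot_trajectory(traj: Trajectory, ax=None, cmap: str = "viridis"):
    """x-y path coloured by observation time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sc = ax.scatter(traj.xy[:, 0], traj.xy[:, 1], c=traj.times / 60.0,
                    cmap=cmap, s=8)
    ax.plot(traj.xy[:, 0], traj.xy[:, 1], lw=0.3, color="0.6", zorder=0)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    ax.figure.colorbar(sc, ax=ax, label="time (min)")
    return ax


def plot_affiliation(traj: Trajectory, result: ClusterResult, ax=None):
    """Cluster membership (1 = earlier-occupied cluster) over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.step(traj.times / 60.0, result.labels, where="post")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("cluster")
    ax.set_yticks(np.unique(result.labels))
    ax.set_title(f"τ = {result.tau}, R_rev = {result.r_rev:.3f}")
    return ax


def plot_msd(curve: MSDCurve, ax=None, label=None):
    """MSD versus lag time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.lags_s, curve.msd, "o-", ms=3, label=label)
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("MSD (µm²)")
    if label:
        ax.legend()
    return ax
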