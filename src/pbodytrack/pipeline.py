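"""End-to-end orchestration: simulate -> detect -> segment -> link -> motion.

Each stage reads and writes plain files under the output directory, so a
later stage can be re-run from cached earlier outputs and produce identical
results.  A provenance record (config, seed, library versions) is written
alongside.
"""
from __future__ import annotations

import dataclasses
import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .detect import (
    DetectionParams,
    detect_movie,
    spots_from_dataframe,
    spots_to_dataframe,
)
from .motion import (
    cluster_positions,
    detect_hovering,
    link_spots,
    msd,
    diffusion_coefficient,
    steps_and_velocities,
    windowed_diffusion,
)
from .segment import (
    SegmentationParams,
    pb_fraction_timecourse,
    per_cell_spot_counts,
    segment_frame,
)
from .simulate import SimConfig, generate_dataset
from .tracks import read_tracks_csv, write_tracks_csv


@dataclass
class PipelineConfig:
    """Everything one run needs; serializable to/from JSON."""

    out_dir: str
    seed: int = 0
    frame_interval_s: float = 60.0  # 60 s (two-channel) or 10 s (fluorescence only)
    sim: SimConfig = field(default_factory=SimConfig)
    n_cells: int = 4
    detection: DetectionParams = field(
        default_factory=lambda: DetectionParams(binary_threshold=6.0)
    )
    segmentation: SegmentationParams = field(
        default_factory=lambda: SegmentationParams(cell_threshold=60.0)
    )
    max_disp_um: float = 4.0  # linking gate per frame
    during_window_s: float = 900.0  # half-width of the budding window
    #: path to a bud-annotation CSV (cell_id, bud_time_frame, bud_x_um,
    #: bud_y_um, track_id); None = use synthetic ground truth if present
    bud_annotations: str | None = None

    def validate(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        self.sim.validate()
        self.detection.validate()
        self.segmentation.validate()

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["sim"]["image_shape"] = list(self.sim.image_shape)
        d["segmentation"]["focus_frames"] = list(self.segmentation.focus_frames)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        if "sim" in d:
            d["sim"]["image_shape"] = tuple(d["sim"].get("image_shape", (256, 256)))
            d["sim"] = SimConfig(**d["sim"])
        if "detection" in d:
            d["detection"] = DetectionParams(**d["detection"])
        if "segmentation" in d:
            d["segmentation"]["focus_frames"] = tuple(
                d["segmentation"].get("focus_frames", (0, 1))
            )
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tagged for the user
                raise StageError(f"[{name}] {exc}") from exc

        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped

    return deco


@_stage("simulate")
def stage_simulate(cfg: PipelineConfig) -> Path:
    """Generate a synthetic dataset under ``out_dir/data``."""
    out = Path(cfg.out_dir) / "data"
    sim = dataclasses.replace(cfg.sim, rng_seed=cfg.seed, dt=cfg.frame_interval_s)
    generate_dataset(sim, out, n_cells=cfg.n_cells)
    return out


@_stage("detect")
def stage_detect(cfg: PipelineConfig, movie_path) -> Path:
    """Detect granules in every frame; writes ``spots.csv``."""
    frames = tifffile.imread(movie_path)
    if frames.ndim == 2:
        frames = frames[None]
    spots = detect_movie(frames, cfg.detection, pixel_size=cfg.sim.pixel_size)
    out = Path(cfg.out_dir) / "spots.csv"
    spots_to_dataframe(spots).to_csv(out, index=False, float_format="%.6f")
    return out


@_stage("segment")
def stage_segment(cfg: PipelineConfig, stack_path, spots_csv) -> Path:
    """Segment cells per frame, assign spots, write labels and fractions."""
    stacks = tifffile.imread(stack_path)
    if stacks.ndim == 3:  # single time point
        stacks = stacks[None]
    spots_by_frame = spots_from_dataframe(pd.read_csv(spots_csv))
    out_dir = Path(cfg.out_dir)
    labels_out = np.zeros((stacks.shape[0], *stacks.shape[-2:]), dtype=np.uint16)
    cell_rows = []
    for f in range(stacks.shape[0]):
        li = segment_frame(stacks[f], cfg.segmentation)
        labels_out[f] = li.labels.astype(np.uint16)
        spots = spots_by_frame[f] if f < len(spots_by_frame) else []
        counts = per_cell_spot_counts(li, spots)
        counts.insert(0, "frame", f)
        cell_rows.append(counts)
    cells = (
        pd.concat(cell_rows, ignore_index=True)
        if cell_rows
        else pd.DataFrame(columns=["frame", "cell_id", "area_px",
                                   "centroid_row", "centroid_col", "n_spots"])
    )
    tifffile.imwrite(out_dir / "labels.tif", labels_out)
    cells.to_csv(out_dir / "cells.csv", index=False, float_format="%.6f")
    frac = pb_fraction_timecourse(cells, dt_s=cfg.frame_interval_s)
    frac.to_csv(out_dir / "pb_fraction.csv", index=False, float_format="%.6f")
    return out_dir / "cells.csv"


@_stage("link")
def stage_link(cfg: PipelineConfig, spots_csv) -> Path:
    """Link per-frame spots into trajectories; writes ``tracks.csv``."""
    spots_by_frame = spots_from_dataframe(pd.read_csv(spots_csv))
    tracks = link_spots(spots_by_frame, cfg.max_disp_um, cfg.frame_interval_s)
    out = Path(cfg.out_dir) / "tracks.csv"
    write_tracks_csv(tracks, out)
    return out


def _load_bud_annotations(cfg: PipelineConfig, data_dir: Path | None) -> dict | None:
    """track_id -> (bud_time_s, bud_site or None); from CSV or ground truth."""
    if cfg.bud_annotations is not None:
        df = pd.read_csv(cfg.bud_annotations)
        return {
            int(r.track_id): (
                float(r.bud_time_frame) * cfg.frame_interval_s,
                (float(r.bud_x_um), float(r.bud_y_um)),
            )
            for r in df.itertuples(index=False)
        }
    meta_path = (data_dir / "truth_meta.json") if data_dir is not None else None
    if meta_path is not None and meta_path.exists():
        meta = json.loads(meta_path.read_text())
        by_cell = {c["cell_id"]: c for c in meta["cells"]}
        out = {}
        for track_id, home in meta["track_home"].items():
            if int(home) > 0:  # track starts in this mother
                c = by_cell[int(home)]
                out[int(track_id)] = (
                    c["bud_time"] * cfg.frame_interval_s,
                    tuple(c["bud_site"]),
                )
        return out
    return None


@_stage("motion")
def stage_motion(cfg: PipelineConfig, tracks_csv, data_dir=None) -> Path:
    """Per-track motion report; hover/bud statistics need bud annotations."""
    tracks = read_tracks_csv(tracks_csv, source="linked")
    buds = _load_bud_annotations(
        cfg, Path(data_dir) if data_dir is not None else None
    )
    if buds is None:
        warnings.warn(
            "no bud annotations: hover and bud-distance sections omitted",
            stacklevel=2,
        )
    rows = []
    for tr in tracks:
        row = {"track_id": tr.track_id, "n_points": tr.n,
               "t_start_s": float(tr.times[0]), "t_end_s": float(tr.times[-1])}
        # cluster over the division window when budding is annotated,
        # mirroring manual selection of one cell division per track
        cl_tr = tr
        if buds is not None and tr.track_id in buds:
            bud_t, _ = buds[tr.track_id]
            sub = tr.subwindow(bud_t - 1800.0, bud_t + 5400.0)
            if sub.n >= 4:
                cl_tr = sub
        if cl_tr.n >= 4:
            cl = cluster_positions(cl_tr, seed=cfg.seed)
            row.update(tau=cl.tau, r_rev=cl.r_rev, j4=cl.j4,
                       degenerate_clusters=cl.degenerate)
            steps, vel = steps_and_velocities(tr)
            row.update(mean_step_um=float(steps.mean()),
                       mean_velocity_um_s=float(vel.mean()))
            curve = msd(tr, max_lag=min(4, tr.n - 3))
            row["D_um2_s"] = diffusion_coefficient(curve).D
        if buds is not None and tr.track_id in buds and tr.n >= 61:
            bud_t, bud_site = buds[tr.track_id]
            try:
                wd = windowed_diffusion(tr, bud_t, cfg.during_window_s)
                row.update(D_before=wd.D_before, D_during=wd.D_during,
                           D_after=wd.D_after)
            except ValueError:
                pass
            try:
                hv = detect_hovering(tr, bud_t)
                row.update(hovering=hv.hovering, H_start_s=hv.H_start,
                           H_stop_s=hv.H_stop, T_hov_s=hv.T_hov)
            except ValueError:
                pass
        rows.append(row)
    report = pd.DataFrame(rows)
    out = Path(cfg.out_dir) / "motion_report.csv"
    report.to_csv(out, index=False, float_format="%.6f")
    num = report.select_dtypes("number")
    num.agg(["mean", "median"]).to_csv(
        Path(cfg.out_dir) / "summary.csv", float_format="%.6f"
    )
    return out


def write_provenance(cfg: PipelineConfig) -> None:
    rec = {
        "pbodytrack": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config": json.loads(cfg.to_json()),
    }
    (Path(cfg.out_dir) / "provenance.json").write_text(json.dumps(rec, indent=1))


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage on a synthetic dataset; returns the report directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = stage_simulate(cfg)
    spots = stage_detect(cfg, data / "fluorescence.tif")
    stage_segment(cfg, data / "brightfield.tif", spots)
    tracks = stage_link(cfg, spots)
    stage_motion(cfg, tracks, data_dir=data)
    write_provenance(cfg)
    return out
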