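"""Synthetic time-lapse data with known ground truth.

Emulates the experimental regime the analysis is built for: budding-yeast
cells growing as a monolayer, a diffraction-limited fluorescent granule
(P-body) per mother cell, and three classes of granule motion —

* free diffusion inside the mother,
* corralled (confined) motion near the future bud site, modelled as a
  discrete-time mean-reverting (Ornstein–Uhlenbeck) process,
* a single directed mother-to-daughter translocation at division.

Each generated dataset carries its full ground truth (subpixel positions,
per-frame regime labels, cell outlines, bud/division times), so every
downstream stage — spot detection, segmentation, linking, motion statistics —
has an exact oracle.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .tracks import (
    REGIME_CORRALLED,
    REGIME_FREE,
    REGIME_TRANSPORT,
    Trajectory,
    trajectories_to_dataframe,
)

FATE_TRANSPORTED = "transported"
FATE_DE_NOVO = "de_novo"
FATE_NONE = "none"


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Durations are seconds, lengths micrometres unless noted.  Defaults follow
    the acquisition regime the analysis targets: 60-s frame interval, a free
    diffusion coefficient of 0.01 µm²/s, confinement of 0.2 µm (per-axis
    stationary std) with a 20-s relaxation time, hovering starting 0.5 h
    before budding and lasting 0.75 h, and a 0.2 µm/px camera scale.
    """

    n_frames: int = 240
    dt: float = 60.0  # s per frame
    pixel_size: float = 0.2  # µm / pixel
    image_shape: tuple[int, int] = (256, 256)  # (rows, cols) pixels
    D_free: float = 0.01  # µm²/s
    corral_sigma: float = 0.2  # µm, stationary per-axis std of confined motion
    corral_tau: float = 20.0  # s, relaxation time of confined motion
    hover_start_offset: float = -1800.0  # s relative to budding (negative = before)
    hover_duration: float = 2700.0  # s
    transport_speed: float = 0.3  # µm/s, directed mother->daughter segment
    spot_sigma: float = 2.0  # px, granule PSF width
    spot_amplitude: float = 3000.0  # integrated photons per granule
    background: float = 100.0  # photons per pixel
    noise_model: str = "poisson"  # "poisson" | "gaussian:<sigma>" | "none"
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name in ("dt", "pixel_size", "corral_sigma", "corral_tau",
                     "hover_duration", "transport_speed", "spot_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.D_free < 0:
            raise ValueError("D_free must be >= 0")
        if self.spot_amplitude <= 0:
            raise ValueError("spot_amplitude must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if len(self.image_shape) != 2 or min(self.image_shape) < 16:
            raise ValueError("image_shape must be 2D and at least 16x16")
        self._parse_noise()

    def _parse_noise(self) -> tuple[str, float]:
        m = self.noise_model
        if m == "poisson" or m == "none":
            return m, 0.0
        if m.startswith("gaussian:"):
            sigma = float(m.split(":", 1)[1])
            if sigma < 0:
                raise ValueError("gaussian noise sigma must be >= 0")
            return "gaussian", sigma
        raise ValueError(f"unknown noise_model {m!r}")

    @property
    def field_um(self) -> tuple[float, float]:
        """Physical field of view (width, height) in µm."""
        return (
            self.image_shape[1] * self.pixel_size,
            self.image_shape[0] * self.pixel_size,
        )


def _reflect_into_circle(p: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Radial reflection of a point into a disk (billiard-style boundary)."""
    d = p - center
    r = float(np.hypot(*d))
    if r <= radius or r == 0.0:
        return p
    r_new = 2.0 * radius - r
    if r_new < 0:  # jump longer than the diameter: clamp just inside
        r_new = 0.99 * radius
    return center + d * (r_new / r)


def simulate_trajectory(
    config: SimConfig,
    bud_time: int,
    bud_site,
    *,
    start=None,
    mother: tuple | None = ((0.0, 0.0), 2.5),
    division_time: int | None = None,
    daughter: tuple | None = None,
    transport_target=None,
    boundary_margin: float = 0.4,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Simulate one granule trajectory with per-frame regime labels.

    The granule diffuses freely (per-axis Gaussian increments of variance
    ``2 * D_free * dt``) except during the hover window
    ``[bud_time*dt + hover_start_offset, + hover_duration)``, where it follows
    the exact one-step update of a mean-reverting process around ``bud_site``
    with autocorrelation ``exp(-dt / corral_tau)`` and stationary per-axis std
    ``corral_sigma``.  From ``division_time`` on it moves deterministically at
    ``transport_speed`` toward ``transport_target`` (default: the daughter
    centre) and, once arrived, diffuses freely inside the daughter.

    A reflecting boundary keeps the granule inside the current cell outline,
    shrunk by ``boundary_margin`` (granules stay in the cytoplasm, clear of
    the cell wall).

    Parameters
    ----------
    bud_time:
        Frame index of bud emergence; must lie in ``[0, n_frames)``.
    mother, daughter:
        ``((cx, cy), radius)`` outlines in µm; ``mother=None`` disables the
        boundary.
    """
    config.validate()
    n, dt = config.n_frames, config.dt
    if not (0 <= bud_time < n):
        raise ValueError("bud_time must lie within [0, n_frames)")
    if division_time is not None and daughter is None and transport_target is None:
        raise ValueError("transport requires a daughter outline or target")
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng

    bud_site = np.asarray(bud_site, dtype=float)
    h_on = bud_time * dt + config.hover_start_offset
    h_off = h_on + config.hover_duration
    t_end = (n - 1) * dt
    if h_off > t_end and h_on <= t_end:
        warnings.warn(
            "hover window extends past the end of the trajectory; truncated",
            stacklevel=2,
        )
        h_off = t_end + dt  # hover until the last step

    if daughter is not None:
        d_center = np.asarray(daughter[0], dtype=float)
        d_radius = float(daughter[1])
    if transport_target is None and daughter is not None:
        transport_target = d_center
    if transport_target is not None:
        transport_target = np.asarray(transport_target, dtype=float)

    if start is None:
        start = np.asarray(mother[0], dtype=float) if mother is not None else bud_site
    xy = np.empty((n, 2))
    xy[0] = np.asarray(start, dtype=float)
    regimes: list[str] = []

    step_sd = np.sqrt(2.0 * config.D_free * dt)
    rho = np.exp(-dt / config.corral_tau)
    ou_sd = config.corral_sigma * np.sqrt(1.0 - rho**2)
    arrived = False

    for i in range(n - 1):
        t = i * dt
        transporting = (
            division_time is not None and i >= division_time and not arrived
        )
        if transporting:
            regime = REGIME_TRANSPORT
            d = transport_target - xy[i]
            dist = float(np.hypot(*d))
            step = config.transport_speed * dt
            if step >= dist or dist == 0.0:
                xy[i + 1] = transport_target
                arrived = True
            else:
                xy[i + 1] = xy[i] + d * (step / dist)
        elif h_on <= t < h_off and not arrived:
            regime = REGIME_CORRALLED
            xy[i + 1] = bud_site + rho * (xy[i] - bud_site) + ou_sd * rng.standard_normal(2)
        else:
            regime = REGIME_FREE
            xy[i + 1] = xy[i] + step_sd * rng.standard_normal(2)

        if regime != REGIME_TRANSPORT:
            if arrived and daughter is not None:
                xy[i + 1] = _reflect_into_circle(
                    xy[i + 1], d_center, max(d_radius - boundary_margin, 0.2)
                )
            elif mother is not None and not arrived:
                xy[i + 1] = _reflect_into_circle(
                    xy[i + 1],
                    np.asarray(mother[0], dtype=float),
                    max(float(mother[1]) - boundary_margin, 0.2),
                )
        regimes.append(regime)

    regimes.append(regimes[-1] if regimes else REGIME_FREE)
    return Trajectory(
        times=np.arange(n) * dt,
        xy=xy,
        frames=np.arange(n),
        source="ground_truth",
        regimes=regimes,
    )


def render_fluorescence_frame(
    positions_um,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one fluorescence frame: background plus Gaussian spots plus noise.

    Each granule is an isotropic 2D Gaussian of width ``spot_sigma`` pixels
    whose *integrated* intensity is ``spot_amplitude`` photons; the peak pixel
    value is therefore ``spot_amplitude / (2 pi spot_sigma**2)``.  Positions
    are ``(x, y)`` in µm with x along columns, y along rows, origin at the
    centre of pixel (0, 0).
    """
    config.validate()
    kind, gsigma = config._parse_noise()
    h, w = config.image_shape
    positions_um = np.asarray(positions_um, dtype=float).reshape(-1, 2)
    img = np.full((h, w), float(config.background))

    for x_um, y_um in positions_um:
        cx = x_um / config.pixel_size
        cy = y_um / config.pixel_size
        if not (-0.5 <= cx < w - 0.5 and -0.5 <= cy < h - 0.5):
            raise ValueError(f"spot position ({x_um}, {y_um}) µm outside image")
        s = config.spot_sigma
        peak = config.spot_amplitude / (2.0 * np.pi * s**2)
        r0 = max(int(np.floor(cy - 5 * s)), 0)
        r1 = min(int(np.ceil(cy + 5 * s)) + 1, h)
        c0 = max(int(np.floor(cx - 5 * s)), 0)
        c1 = min(int(np.ceil(cx + 5 * s)) + 1, w)
        rr = np.arange(r0, r1)[:, None]
        cc = np.arange(c0, c1)[None, :]
        img[r0:r1, c0:c1] += peak * np.exp(
            -((cc - cx) ** 2 + (rr - cy) ** 2) / (2.0 * s**2)
        )

    if kind == "none":
        return img
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    if kind == "poisson":
        return rng.poisson(img).astype(float)
    return img + rng.normal(0.0, gsigma, size=img.shape)


def render_brightfield_stack(
    cell_outlines,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    interior_contrast: float = 60.0,
    rim_contrast: float = 5.0,
    rim_width_um: float = 0.2,
    texture_sigma: float = 2.0,
    read_noise_sigma: float = 0.0,
) -> np.ndarray:
    """Render a two-frame bright-field focus stack, shape ``(2, h, w)``.

    Models the defocus behaviour of yeast in transmitted light: above focus a
    cell appears bright inside with a bright rim, below focus dark inside with
    a dark rim.  The difference of the two frames therefore peaks inside cell
    bodies, which is what the focus-differential detection step exploits.
    The interior profile is a parabolic dome ``1 - (r/R)^2``, so touching
    cells still produce separable maxima.

    ``texture_sigma`` adds a common background texture identical in both
    frames (cancels exactly in the difference); ``read_noise_sigma`` adds
    independent per-frame noise.  Overlapping outlines are allowed (touching
    cells) but flagged with a warning.
    """
    config.validate()
    h, w = config.image_shape
    outlines = [(np.asarray(c, dtype=float), float(r)) for c, r in cell_outlines]
    for i in range(len(outlines)):
        for j in range(i + 1, len(outlines)):
            gap = np.hypot(*(outlines[i][0] - outlines[j][0]))
            if gap < outlines[i][1] + outlines[j][1] + 1e-6:  # touching counts
                warnings.warn("overlapping cell outlines in bright-field render",
                              stacklevel=2)

    yy = (np.arange(h)[:, None] + 0.0) * config.pixel_size
    xx = (np.arange(w)[None, :] + 0.0) * config.pixel_size
    relief = np.zeros((h, w))
    for (cx, cy), R in outlines:
        d = np.hypot(xx - cx, yy - cy)
        dome = np.clip(1.0 - (d / R) ** 2, 0.0, None)
        ring = np.exp(-((d - R) ** 2) / (2.0 * rim_width_um**2))
        relief += interior_contrast * dome + rim_contrast * ring

    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    texture = (
        rng.normal(0.0, texture_sigma, size=(h, w)) if texture_sigma > 0 else 0.0
    )
    above = config.background + texture + relief
    below = config.background + texture - relief
    stack = np.stack([above, below])
    if read_noise_sigma > 0:
        stack = stack + rng.normal(0.0, read_noise_sigma, size=stack.shape)
    return stack


@dataclass
class CellRecord:
    """Ground-truth bookkeeping for one mother/daughter pair."""

    cell_id: int
    center: np.ndarray  # mother centre, µm
    radius: float  # mother radius, µm
    bud_time: int  # frame index of bud emergence
    division_time: int  # frame index of cytokinesis / transport
    bud_site: np.ndarray  # µm, on the mother cortex
    daughter_center: np.ndarray
    daughter_radius_final: float
    pb_fate: str  # transported | de_novo | none

    def daughter_radius(self, frame: int, initial: float = 1.0) -> float:
        """Linear bud growth from ``initial`` to the final radius."""
        if frame < self.bud_time:
            return 0.0
        if frame >= self.division_time:
            return self.daughter_radius_final
        f = (frame - self.bud_time) / max(self.division_time - self.bud_time, 1)
        return initial + f * (self.daughter_radius_final - initial)


@dataclass
class GroundTruth:
    """Everything the generator knows about a synthetic dataset."""

    trajectories: list[Trajectory]
    cells: list[CellRecord]
    config: SimConfig
    #: track_id -> cell_id of the mother the track starts in (or daughter for
    #: de-novo tracks, negated: -cell_id)
    track_home: dict = field(default_factory=dict)

    def cell_outline_table(self) -> pd.DataFrame:
        """Per-frame outlines of mothers and (once budded) daughters."""
        rows = []
        for frame in range(self.config.n_frames):
            for c in self.cells:
                rows.append(
                    dict(frame=frame, cell_id=c.cell_id, role="mother",
                         x_um=c.center[0], y_um=c.center[1], radius_um=c.radius)
                )
                rd = c.daughter_radius(frame)
                if rd > 0:
                    rows.append(
                        dict(frame=frame, cell_id=-c.cell_id, role="daughter",
                             x_um=c.daughter_center[0], y_um=c.daughter_center[1],
                             radius_um=rd)
                    )
        return pd.DataFrame(rows)

    def meta(self) -> dict:
        return {
            "cells": [
                {
                    "cell_id": c.cell_id,
                    "bud_time": c.bud_time,
                    "division_time": c.division_time,
                    "bud_site": list(map(float, c.bud_site)),
                    "pb_fate": c.pb_fate,
                }
                for c in self.cells
            ],
            "track_home": {str(k): int(v) for k, v in self.track_home.items()},
        }


def _layout_cells(config: SimConfig, n_cells: int, rng: np.random.Generator,
                  mother_radius: float, daughter_radius: float) -> list[dict]:
    """Place mothers on a jittered grid with room for each daughter."""
    fw, fh = config.field_um
    pitch = 2.0 * (mother_radius + daughter_radius) + 1.5
    cols = max(int((fw - 2 * mother_radius) // pitch), 1)
    rows_needed = int(np.ceil(n_cells / cols))
    if rows_needed * pitch + 2 * mother_radius > fh:
        raise ValueError(
            f"image_shape too small for {n_cells} cells at pitch {pitch:.1f} µm"
        )
    placements = []
    for k in range(n_cells):
        r, c = divmod(k, cols)
        center = np.array(
            [
                mother_radius + pitch / 2 + c * pitch,
                mother_radius + pitch / 2 + r * pitch,
            ]
        ) + rng.uniform(-0.4, 0.4, size=2)
        theta = rng.uniform(0, 2 * np.pi)
        placements.append({"center": center, "theta": theta})
    return placements


def build_scene(
    config: SimConfig,
    n_cells: int = 4,
    fates=None,
    mother_radius: float = 2.5,
    daughter_radius: float = 1.8,
    division_delay_s: float = 2700.0,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Construct cells, fates and granule trajectories for one dataset.

    Each mother carries one granule.  ``fates`` cycles through
    ``(transported, de_novo, none)`` by default: *transported* granules hover
    at the bud site and translocate at division; *de_novo* mothers keep a
    freely diffusing granule while a new one assembles in the daughter after
    division; *none* daughters never get a granule.  Mothers of non-transported
    granules skip the hover phase, emulating transport-machinery mutants.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    if fates is None:
        cycle = [FATE_TRANSPORTED, FATE_DE_NOVO, FATE_NONE]
        fates = [cycle[i % 3] for i in range(n_cells)]
    if len(fates) != n_cells:
        raise ValueError("fates length must equal n_cells")

    placements = _layout_cells(config, n_cells, rng, mother_radius, daughter_radius)
    n = config.n_frames
    div_delay = max(int(round(division_delay_s / config.dt)), 1)

    cells, trajectories, track_home = [], [], {}
    next_track = 0
    for idx, (place, fate) in enumerate(zip(placements, fates)):
        center, theta = place["center"], place["theta"]
        u = np.array([np.cos(theta), np.sin(theta)])
        bud_site = center + (mother_radius - 0.3) * u
        d_center = center + (mother_radius + daughter_radius) * u
        if n > 2:
            lo, hi = max(1, n // 4), max(2, n // 2)
            bud_time = int(rng.integers(lo, hi))
            division_time = min(bud_time + div_delay, n - 2)
        else:
            bud_time, division_time = 0, max(n - 1, 1)
        rec = CellRecord(
            cell_id=idx + 1,
            center=center,
            radius=mother_radius,
            bud_time=bud_time,
            division_time=division_time,
            bud_site=bud_site,
            daughter_center=d_center,
            daughter_radius_final=daughter_radius,
            pb_fate=fate,
        )
        cells.append(rec)

        if fate == FATE_TRANSPORTED:
            tr = simulate_trajectory(
                config, bud_time, bud_site,
                mother=(center, mother_radius),
                division_time=division_time,
                daughter=(d_center, daughter_radius),
                rng=rng,
            )
        else:
            # mutant-like: dynamic movement but neither hovering nor transport
            quiet = SimConfig(**{**asdict(config),
                                 "hover_start_offset": -1e12})
            tr = simulate_trajectory(
                quiet, bud_time, bud_site,
                mother=(center, mother_radius), rng=rng,
            )
        tr.track_id = next_track
        track_home[next_track] = rec.cell_id
        trajectories.append(tr)
        next_track += 1

        if fate == FATE_DE_NOVO and division_time < n - 1:
            m = n - division_time
            quiet = SimConfig(**{**asdict(config),
                                 "n_frames": m, "hover_start_offset": -1e12})
            tr_d = simulate_trajectory(
                quiet, 0, d_center,
                start=d_center, mother=(d_center, daughter_radius), rng=rng,
            )
            tr_d.times = tr_d.times + division_time * config.dt
            tr_d.frames = tr_d.frames + division_time
            tr_d.track_id = next_track
            track_home[next_track] = -rec.cell_id
            trajectories.append(tr_d)
            next_track += 1

    return GroundTruth(trajectories=trajectories, cells=cells, config=config,
                       track_home=track_home)


def render_dataset(truth: GroundTruth, rng: np.random.Generator | None = None):
    """Render fluorescence frames and bright-field stacks for a scene.

    Returns ``(fluor, brightfield)`` with shapes ``(n, h, w)`` and
    ``(n, 2, h, w)``.
    """
    config = truth.config
    rng = np.random.default_rng(config.rng_seed + 1) if rng is None else rng
    n = config.n_frames
    fluor = np.empty((n, *config.image_shape), dtype=np.float32)
    bf = np.empty((n, 2, *config.image_shape), dtype=np.float32)
    for frame in range(n):
        pos = []
        for tr in truth.trajectories:  # track frames are contiguous ranges
            off = frame - int(tr.frames[0])
            if 0 <= off < tr.n:
                pos.append(tr.xy[off])
        fluor[frame] = render_fluorescence_frame(
            np.array(pos).reshape(-1, 2), config, rng=rng
        )
        outlines = []
        for c in truth.cells:
            outlines.append((c.center, c.radius))
            rd = c.daughter_radius(frame)
            if rd > 0:
                outlines.append((c.daughter_center, rd))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # touching outlines are intended
            bf[frame] = render_brightfield_stack(outlines, config, rng=rng)
    return fluor, bf


def generate_dataset(
    config: SimConfig,
    out_dir,
    n_cells: int = 4,
    fates=None,
) -> GroundTruth:
    """Simulate, render and write a complete dataset to ``out_dir``.

    Writes ``fluorescence.tif`` (n, h, w), ``brightfield.tif`` (n, 2, h, w),
    ``truth_tracks.csv``, ``truth_cells.csv``, ``truth_meta.json`` and
    ``config.json``.  Fully reproducible from ``config.rng_seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    truth = build_scene(config, n_cells=n_cells, fates=fates, rng=rng)
    fluor, bf = render_dataset(truth, rng=rng)
    tifffile.imwrite(out / "fluorescence.tif", fluor)
    tifffile.imwrite(out / "brightfield.tif", bf)
    trajectories_to_dataframe(truth.trajectories).to_csv(
        out / "truth_tracks.csv", index=False, float_format="%.6f"
    )
    truth.cell_outline_table().to_csv(
        out / "truth_cells.csv", index=False, float_format="%.6f"
    )
    (out / "truth_meta.json").write_text(json.dumps(truth.meta(), indent=1))
    cfg = asdict(config)
    cfg["image_shape"] = list(config.image_shape)
    (out / "config.json").write_text(json.dumps(cfg, indent=1))
    return truth


def config_from_json(path) -> SimConfig:
    data = json.loads(Path(path).read_text())
    if "image_shape" in data:
        data["image_shape"] = tuple(data["image_shape"])
    cfg = SimConfig(**data)
    cfg.validate()
    return cfg
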