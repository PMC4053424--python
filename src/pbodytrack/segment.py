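"""Cell detection from bright-field focus stacks and spot-to-cell assignment.

Cells are found from the differential image of two focus frames (cell bodies
change contrast with defocus while the background does not), thresholded with
size constraints to reject debris, and used as markers for a standard
watershed segmentation so that touching cells in the crowded monolayer are
split.  Detected granules are then assigned to the cell whose label contains
them, yielding the fraction of cells with at least one P-body over time.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, segmentation


@dataclass
class SegmentationParams:
    """Cell-detection settings.

    ``cell_threshold`` applies to the smoothed magnitude of the focus
    differential and, like the spot threshold, is dataset specific.
    ``mask_frac`` sets the watershed foreground mask at
    ``mask_frac * cell_threshold``, extending labels from the marker cores
    out to the (weaker) cell periphery.
    """

    cell_threshold: float
    focus_frames: tuple[int, int] = (0, 1)
    min_cell_area: int = 30
    max_cell_area: int = 20000
    smoothing_sigma: float = 2.0
    mask_frac: float = 0.125

    def validate(self) -> None:
        if self.focus_frames[0] == self.focus_frames[1]:
            raise ValueError("focus_frames must be distinct")
        if not 0 < self.min_cell_area < self.max_cell_area:
            raise ValueError("require 0 < min_cell_area < max_cell_area")
        if self.cell_threshold <= 0:
            raise ValueError("cell_threshold must be > 0")
        if not 0 < self.mask_frac <= 1:
            raise ValueError("mask_frac must be in (0, 1]")


@dataclass
class LabelImage:
    """Integer-labelled segmentation (0 = background, k > 0 = cell k)."""

    labels: np.ndarray
    table: pd.DataFrame  # cell_id, area_px, centroid_row, centroid_col

    @property
    def n_cells(self) -> int:
        return int(len(self.table))


def differential_focus_image(stack: np.ndarray, focus_frames=(0, 1)) -> np.ndarray:
    """Signed difference of two focus frames of a bright-field stack."""
    a, b = focus_frames
    fa, fb = np.asarray(stack[a], dtype=float), np.asarray(stack[b], dtype=float)
    if fa.shape != fb.shape:
        raise ValueError("focus frames have mismatched shapes")
    return fa - fb


def detect_cell_markers(diff: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Marker label image from the focus differential.

    Connected components of ``smoothed |diff| > cell_threshold``, with small
    (noise/debris) and large (chamber borders) components removed.
    """
    params.validate()
    mag = ndimage.gaussian_filter(np.abs(diff), params.smoothing_sigma)
    labels = measure.label(mag > params.cell_threshold, connectivity=2)
    markers = np.zeros_like(labels)
    k = 0
    for rp in measure.regionprops(labels):
        if params.min_cell_area <= rp.area <= params.max_cell_area:
            k += 1
            markers[labels == rp.label] = k
    return markers


def watershed_cells(
    diff: np.ndarray, markers: np.ndarray, params: SegmentationParams
) -> LabelImage:
    """Marker-based watershed on the negated focus-differential magnitude.

    Cell interiors have a strong differential response, so ``-|diff|``
    (lightly smoothed) makes each cell a basin; labels are restricted to a
    foreground mask at ``mask_frac * cell_threshold``.
    """
    params.validate()
    if markers.max() == 0:
        empty = pd.DataFrame(columns=["cell_id", "area_px", "centroid_row",
                                      "centroid_col"])
        return LabelImage(labels=np.zeros_like(markers), table=empty)
    mag = ndimage.gaussian_filter(np.abs(diff), params.smoothing_sigma)
    mask = mag > params.mask_frac * params.cell_threshold
    mask |= markers > 0
    labels = segmentation.watershed(-mag, markers=markers, mask=mask)
    rows = [
        dict(cell_id=int(rp.label), area_px=int(rp.area),
             centroid_row=float(rp.centroid[0]), centroid_col=float(rp.centroid[1]))
        for rp in measure.regionprops(labels)
    ]
    return LabelImage(labels=labels, table=pd.DataFrame(rows))


def segment_frame(stack: np.ndarray, params: SegmentationParams) -> LabelImage:
    """Differential image, markers and watershed for one focus stack."""
    diff = differential_focus_image(stack, params.focus_frames)
    markers = detect_cell_markers(diff, params)
    return watershed_cells(diff, markers, params)


def assign_spots_to_cells(label_image: LabelImage, spots) -> pd.DataFrame:
    """Assign each spot the label under its rounded centre.

    Spots falling on background get ``cell_id`` 0 and the flag
    ``"background"``.  Returns one row per spot plus the containing cell.
    """
    labels = label_image.labels
    h, w = labels.shape
    rows = []
    for s in spots:
        r = int(np.clip(round(s.y_px), 0, h - 1))
        c = int(np.clip(round(s.x_px), 0, w - 1))
        cell = int(labels[r, c])
        rows.append(
            dict(frame=s.frame, x_px=s.x_px, y_px=s.y_px, cell_id=cell,
                 flag="" if cell > 0 else "background")
        )
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "cell_id", "flag"])


def per_cell_spot_counts(label_image: LabelImage, spots) -> pd.DataFrame:
    """Spot count per segmented cell (cells without spots get 0)."""
    assigned = assign_spots_to_cells(label_image, spots)
    counts = assigned[assigned.cell_id > 0].groupby("cell_id").size()
    table = label_image.table.copy()
    table["n_spots"] = table["cell_id"].map(counts).fillna(0).astype(int)
    return table


def pb_fraction_timecourse(
    per_frame_counts: pd.DataFrame,
    dt_s: float,
    window_min: float = 20.0,
) -> pd.DataFrame:
    """Fraction of cells containing >= 1 granule, window-averaged in time.

    ``per_frame_counts`` needs columns ``frame`` and ``n_spots`` with one row
    per cell per frame.  Per-frame fractions are averaged over non-overlapping
    windows of ``window_min`` minutes (default 20) to filter detection noise;
    frames with zero segmented cells are skipped with a warning.
    """
    frac_rows = []
    for frame, g in per_frame_counts.groupby("frame", sort=True):
        frac_rows.append(
            dict(frame=int(frame), t_s=frame * dt_s,
                 fraction=float((g["n_spots"] >= 1).mean()))
        )
    per_frame = pd.DataFrame(frac_rows, columns=["frame", "t_s", "fraction"])
    if len(per_frame):
        span = range(int(per_frame.frame.min()), int(per_frame.frame.max()) + 1)
        missing = sorted(set(span) - set(per_frame.frame))
        if missing:
            warnings.warn(
                f"{len(missing)} frame(s) with no segmented cells skipped: "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}",
                stacklevel=2,
            )
    if per_frame.empty:
        return pd.DataFrame(columns=["t_center_s", "fraction"])
    win_s = window_min * 60.0
    bins = (per_frame["t_s"] // win_s).astype(int)
    agg = per_frame.groupby(bins).agg(
        t_center_s=("t_s", "mean"), fraction=("fraction", "mean")
    )
    return agg.reset_index(drop=True)
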