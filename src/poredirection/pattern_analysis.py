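"""Electrode-aligned regional photometry of tracked cells.

The central computation: each cell mask is divided into 1-pixel rows
parallel to the electrodes (i.e. perpendicular to the field axis), the rows
are grouped into anode-facing, middle and cathode-facing thirds, and the
value reported for a group is the average of the mean intensities of its
rows — deliberately *not* the pooled pixel mean, which would weight long
rows more heavily.

Remainder rule: with R rows, the anode and cathode groups each get
floor(R/3) rows and the middle group takes the remainder, keeping the two
polar groups the same size so anode-cathode differences are not biased by
group size (e.g. 50 rows -> 16/18/16).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .calibration import CalibrationCurve
from .errors import ConfigurationError, DegenerateROIError
from .image_io import ImageStack

logger = logging.getLogger(__name__)

__all__ = [
    "CellROI",
    "CellTrack",
    "RegionalTrace",
    "RowGroups",
    "partition_rows",
    "region_intensity",
    "track_cells",
    "extract_traces",
    "smooth_trace",
    "traces_from_dataframe",
]


@dataclass
class CellROI:
    """Binary pixel mask of one cell on one frame."""

    cell_id: int
    frame_index: int
    mask: np.ndarray  # full-frame boolean array

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise DegenerateROIError(f"cell {self.cell_id}: empty mask")

    @property
    def centroid(self) -> tuple[float, float]:
        """(y, x) centroid of the mask in pixel coordinates."""
        ys, xs = np.nonzero(self.mask)
        return float(ys.mean()), float(xs.mean())

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class CellTrack:
    """One cell's ROI on every frame, with tracking QC flags."""

    cell_id: int
    rois: list[CellROI]
    flagged_frames: list[int] = field(default_factory=list)

    def centroids(self) -> np.ndarray:
        return np.array([roi.centroid for roi in self.rois])


@dataclass
class RegionalTrace:
    """Per-cell time series of anode/middle/cathode regional values."""

    cell_id: int | str
    times: np.ndarray  # s, strictly increasing, uniform step
    anode: np.ndarray
    middle: np.ndarray
    cathode: np.ndarray
    units: str = "intensity"  # "intensity" | "uM"
    baseline_window: int = 0  # number of pre-pulse frames averaged out

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.anode = np.asarray(self.anode, dtype=float)
        self.middle = np.asarray(self.middle, dtype=float)
        self.cathode = np.asarray(self.cathode, dtype=float)
        n = len(self.times)
        if not (len(self.anode) == len(self.middle) == len(self.cathode) == n):
            raise ConfigurationError("trace arrays must share one length")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("times must be strictly increasing")

    def region(self, name: str) -> np.ndarray:
        return {"anode": self.anode, "middle": self.middle, "cathode": self.cathode}[name]


@dataclass(frozen=True)
class RowGroups:
    """Row coordinates of the three groups, ordered anode -> cathode."""

    field_axis: str  # "x": rows share a column index; "y": a row index
    anode: tuple[int, ...]
    middle: tuple[int, ...]
    cathode: tuple[int, ...]

    @property
    def all_rows(self) -> tuple[int, ...]:
        return self.anode + self.middle + self.cathode


def partition_rows(roi: CellROI | np.ndarray, field_axis: str, anode_side: str) -> RowGroups:
    """Split a cell mask into anode/middle/cathode row groups.

    A "row" is the set of in-mask pixels sharing one coordinate along the
    field axis; rows are ordered from the anode end to the cathode end and
    split floor(R/3) / remainder / floor(R/3).
    """
    mask = roi.mask if isinstance(roi, CellROI) else np.asarray(roi, dtype=bool)
    if field_axis not in ("x", "y"):
        raise ConfigurationError(f"field_axis must be 'x' or 'y', got {field_axis!r}")
    if anode_side not in ("low", "high"):
        raise ConfigurationError(f"anode_side must be 'low' or 'high', got {anode_side!r}")
    axis = 1 if field_axis == "x" else 0  # array axis whose index varies along the field
    occupied = np.nonzero(mask.any(axis=1 - axis))[0]
    coords = [int(c) for c in occupied]
    if anode_side == "high":
        coords = coords[::-1]
    n_rows = len(coords)
    if n_rows < 3:
        raise DegenerateROIError(
            f"mask spans only {n_rows} row(s) along the field axis; need >= 3"
        )
    n_polar = n_rows // 3
    return RowGroups(
        field_axis=field_axis,
        anode=tuple(coords[:n_polar]),
        middle=tuple(coords[n_polar : n_rows - n_polar]),
        cathode=tuple(coords[n_rows - n_polar :]),
    )


def region_intensity(
    frame: np.ndarray,
    mask: np.ndarray,
    groups: RowGroups,
) -> tuple[float, float, float]:
    """(anode, middle, cathode) values as row-mean-of-means over the mask.

    Each row's in-mask pixel intensities are averaged first, then the row
    means within a group are averaged with equal weight per row.
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    axis = 1 if groups.field_axis == "x" else 0

    def group_value(coords: tuple[int, ...]) -> float:
        row_means = []
        for c in coords:
            row_mask = mask[:, c] if axis == 1 else mask[c, :]
            row_vals = (frame[:, c] if axis == 1 else frame[c, :])[row_mask]
            if row_vals.size == 0:
                logger.warning("empty row at coordinate %d excluded from group", c)
                continue
            row_means.append(row_vals.mean())
        return float(np.mean(row_means)) if row_means else np.nan

    return group_value(groups.anode), group_value(groups.middle), group_value(groups.cathode)


def _segment_near(
    frame: np.ndarray,
    prev_centroid: tuple[float, float],
    prev_area: int,
    search_radius: float,
) -> np.ndarray | None:
    """Otsu-threshold a window around the predicted centroid and return the
    connected component nearest to it, or None if segmentation fails."""
    h, w = frame.shape
    cy, cx = prev_centroid
    half = int(round(search_radius + np.sqrt(prev_area / np.pi) + 2))
    y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    window = frame[y0:y1, x0:x1]
    if window.size == 0 or window.max() - window.min() < 1e-9:
        return None
    try:
        thr = threshold_otsu(window)
    except ValueError:
        return None
    binary = window > thr
    if not binary.any():
        return None
    labels = label(binary)
    best, best_dist = None, np.inf
    for prop in regionprops(labels):
        if prop.area < max(4, 0.2 * prev_area):
            continue
        py, px = prop.centroid
        dist = np.hypot(py + y0 - cy, px + x0 - cx)
        if dist < best_dist:
            best, best_dist = prop.label, dist
    if best is None:
        return None
    mask = np.zeros(frame.shape, dtype=bool)
    mask[y0:y1, x0:x1] = labels == best
    return mask


def track_cells(
    stack: ImageStack,
    initial_rois: Sequence[CellROI],
    max_displacement: float = 5.0,
) -> list[CellTrack]:
    """Follow each seeded ROI through all frames by nearest-centroid linking.

    Per frame the cell is re-segmented (Otsu threshold in a search window
    around the predicted centroid); when segmentation fails or the centroid
    jumps farther than ``max_displacement`` pixels, the previous mask is
    carried forward and the frame is flagged.
    """
    tracks = []
    for seed in initial_rois:
        rois: list[CellROI] = []
        flagged: list[int] = []
        prev_mask = seed.mask
        prev_centroid = seed.centroid
        for idx in range(stack.n_frames):
            frame = stack.frames[idx]
            new_mask = _segment_near(
                frame, prev_centroid, int(prev_mask.sum()), max_displacement
            )
            if new_mask is not None:
                ys, xs = np.nonzero(new_mask)
                new_centroid = (float(ys.mean()), float(xs.mean()))
                jump = np.hypot(
                    new_centroid[0] - prev_centroid[0],
                    new_centroid[1] - prev_centroid[1],
                )
                if jump > max_displacement:
                    flagged.append(idx)
                    new_mask, new_centroid = prev_mask, prev_centroid
            else:
                new_mask, new_centroid = prev_mask, prev_centroid
            rois.append(CellROI(seed.cell_id, idx, new_mask))
            prev_mask, prev_centroid = new_mask, new_centroid
        tracks.append(CellTrack(seed.cell_id, rois, flagged))
    return tracks


def extract_traces(
    stack: ImageStack,
    tracks: Sequence[CellTrack],
    curve: CalibrationCurve | None = None,
    baseline: bool = True,
) -> list[RegionalTrace]:
    """Regional photometry of every track: partition rows, average, calibrate.

    Per frame: row partition of the frame's mask -> row-mean-of-means per
    group -> optional intensity-to-concentration conversion -> optional
    subtraction of the per-region mean over all pre-pulse frames. The time
    axis starts at 0 so the pulse lands at ``stack.pulse_time``.
    """
    if curve is not None and curve.dye_name and stack.dye_name:
        if curve.dye_name.lower() != stack.dye_name.lower():
            raise ConfigurationError(
                f"calibration is for {curve.dye_name!r} but stack was recorded "
                f"with {stack.dye_name!r}"
            )
    times = stack.times
    pre_pulse = times < stack.pulse_time
    traces = []
    for track in tracks:
        if len(track.rois) != stack.n_frames:
            raise ConfigurationError(
                f"track {track.cell_id} covers {len(track.rois)} frames, "
                f"stack has {stack.n_frames}"
            )
        values = np.empty((stack.n_frames, 3))
        for idx, roi in enumerate(track.rois):
            groups = partition_rows(roi, stack.field_axis, stack.anode_side)
            values[idx] = region_intensity(stack.frames[idx], roi.mask, groups)
        units = "intensity"
        if curve is not None:
            values = curve.to_concentration(values)
            units = "uM"
        n_baseline = 0
        if baseline and pre_pulse.any():
            values = values - values[pre_pulse].mean(axis=0, keepdims=True)
            n_baseline = int(pre_pulse.sum())
        traces.append(
            RegionalTrace(
                cell_id=track.cell_id,
                times=times,
                anode=values[:, 0],
                middle=values[:, 1],
                cathode=values[:, 2],
                units=units,
                baseline_window=n_baseline,
            )
        )
    return traces


def smooth_trace(values: np.ndarray, window: int) -> np.ndarray:
    """Second-order Savitzky-Golay smoothing, length-preserving.

    Edges use a polynomial fit on the truncated window (``mode='interp'``).
    ``window`` must be odd and 3 <= window <= len(values).
    """
    values = np.asarray(values, dtype=float)
    if window % 2 == 0 or window < 3 or window > len(values):
        raise ConfigurationError(
            f"window must be odd and within [3, {len(values)}], got {window}"
        )
    return savgol_filter(values, window_length=window, polyorder=2, mode="interp")


def traces_from_dataframe(df: pd.DataFrame) -> list[RegionalTrace]:
    """Rebuild RegionalTrace objects from a long-format traces DataFrame."""
    traces = []
    for cell_id, sub in df.groupby("cell_id"):
        use_conc = sub["concentration_uM"].notna().any()
        col = "concentration_uM" if use_conc else "intensity"
        wide = sub.pivot_table(index="time_s", columns="region", values=col)
        traces.append(
            RegionalTrace(
                cell_id=cell_id,
                times=wide.index.to_numpy(),
                anode=wide["anode"].to_numpy(),
                middle=wide["middle"].to_numpy(),
                cathode=wide["cathode"].to_numpy(),
                units="uM" if use_conc else "intensity",
            )
        )
    return traces
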