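"""Image-stack and trace I/O plus the coordinate conventions used package-wide.

Coordinate convention (fixed, relied on by every other module):

* pixel indices are 0-based; frame arrays are indexed ``[i, j]`` = (y, x);
* ``field_axis`` names the image axis the electric field runs along
  ("x" = array columns, "y" = array rows);
* a "row" of the regional partition is the set of in-mask pixels sharing one
  coordinate along ``field_axis`` — rows are parallel to the electrodes and
  perpendicular to the field axis;
* ``anode_side`` says which end of ``field_axis`` faces the anode: "low"
  means index 0, "high" means index n-1. Anode-facing rows are the rows
  nearest that end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, MetadataError

if TYPE_CHECKING:  # pragma: no cover
    from .pattern_analysis import RegionalTrace

__all__ = ["ImageStack", "read_stack", "write_stack", "write_traces", "read_traces"]

REQUIRED_METADATA_KEYS = (
    "frame_interval_s",
    "pixel_size_um",
    "field_axis",
    "anode_side",
    "pulse_time_s",
)

TRACE_COLUMNS = ["cell_id", "time_s", "region", "intensity", "concentration_uM"]


@dataclass
class ImageStack:
    """Time-ordered single-channel frames plus acquisition metadata."""

    frames: np.ndarray  # (n_frames, height, width), float internally
    frame_interval: float  # s
    pixel_size: float  # um
    field_axis: str  # "x" | "y"
    anode_side: str  # "low" | "high"
    pulse_time: float  # s
    dye_name: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] == 0:
            raise FormatError(
                f"frames must be a non-empty (n, h, w) array, got shape "
                f"{self.frames.shape}"
            )
        if self.frame_interval <= 0:
            raise MetadataError("frame_interval_s must be positive")
        if self.field_axis not in ("x", "y"):
            raise MetadataError(f"field_axis must be 'x' or 'y', got {self.field_axis!r}")
        if self.anode_side not in ("low", "high"):
            raise MetadataError(
                f"anode_side must be 'low' or 'high', got {self.anode_side!r}"
            )
        if np.nanmin(self.frames) < 0:
            raise FormatError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Recording duration in seconds (frame count x frame interval)."""
        return self.n_frames * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame, frame 0 at t = 0."""
        return np.arange(self.n_frames) * self.frame_interval


def _validate_metadata(meta: dict, path) -> dict:
    for key in REQUIRED_METADATA_KEYS:
        if key not in meta:
            raise MetadataError(f"metadata file {path} is missing required key {key!r}")
    return meta


def read_stack(path: str | Path, metadata_path: str | Path) -> ImageStack:
    """Read a multi-page TIFF and its YAML/JSON metadata sidecar.

    An optional metadata key ``rotation_deg`` pre-rotates every frame
    (nearest-neighbor) so the field axis aligns with an image axis.
    """
    with open(metadata_path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict):
        raise MetadataError(f"metadata file {metadata_path} did not parse to a mapping")
    _validate_metadata(meta, metadata_path)

    frames = tifffile.imread(path)
    frames = np.asarray(frames)
    if frames.size == 0:
        raise FormatError(f"{path} contains no image data")
    if frames.ndim == 2:
        frames = frames[None, :, :]
    if frames.ndim != 3:
        raise FormatError(f"{path} is not a single-channel 2-D stack: shape {frames.shape}")

    rotation = float(meta.get("rotation_deg", 0.0))
    if rotation != 0.0:
        from scipy import ndimage

        frames = np.stack(
            [ndimage.rotate(f, rotation, reshape=False, order=0, mode="nearest")
             for f in frames]
        )

    return ImageStack(
        frames=frames.astype(float),
        frame_interval=float(meta["frame_interval_s"]),
        pixel_size=float(meta["pixel_size_um"]),
        field_axis=str(meta["field_axis"]),
        anode_side=str(meta["anode_side"]),
        pulse_time=float(meta["pulse_time_s"]),
        dye_name=str(meta.get("dye", "")),
        extra={k: v for k, v in meta.items() if k not in REQUIRED_METADATA_KEYS},
    )


def write_stack(stack: ImageStack, path: str | Path, metadata_path: str | Path) -> None:
    """Write frames as 16-bit multi-page TIFF plus a YAML metadata sidecar."""
    data = np.clip(np.round(stack.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data)
    meta = {
        "frame_interval_s": float(stack.frame_interval),
        "pixel_size_um": float(stack.pixel_size),
        "field_axis": stack.field_axis,
        "anode_side": stack.anode_side,
        "pulse_time_s": float(stack.pulse_time),
        "dye": stack.dye_name,
    }
    meta.update(stack.extra)
    with open(metadata_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def write_traces(traces: Iterable["RegionalTrace"], path: str | Path) -> None:
    """Write regional traces as long-format CSV.

    Columns: cell_id, time_s, region in {anode, middle, cathode}, intensity,
    concentration_uM. Whichever of intensity/concentration a trace does not
    carry is written as NaN; round-trips losslessly at float precision.
    """
    records = []
    for trace in traces:
        for region in ("anode", "middle", "cathode"):
            values = getattr(trace, region)
            for t, v in zip(trace.times, values):
                is_conc = trace.units == "uM"
                records.append(
                    {
                        "cell_id": trace.cell_id,
                        "time_s": float(t),
                        "region": region,
                        "intensity": np.nan if is_conc else float(v),
                        "concentration_uM": float(v) if is_conc else np.nan,
                    }
                )
    df = pd.DataFrame.from_records(records, columns=TRACE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_traces(path: str | Path) -> pd.DataFrame:
    """Read a traces CSV back into a long-format DataFrame."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"traces file {path} is missing columns {missing}")
    return df
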