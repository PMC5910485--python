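"""Fluorescence-to-concentration standard curves.

A curve is an ordinary-least-squares line through the per-concentration
replicate means, mirroring a lysate-based calibration: known dye
concentrations are spiked into cell lysate, imaged with the experiment's
settings, and the mean intensity at each concentration defines the line.
For natively fluorescent dyes the top point can instead be anchored to the
known extracellular concentration measured in cell-free regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationQualityError, DegenerateDesignError

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "fit_calibration",
    "anchor_calcein",
    "to_concentration",
    "read_points_csv",
]


@dataclass(frozen=True)
class CalibrationPoint:
    concentration: float  # uM
    mean_intensity: float
    sd: float
    n: int


@dataclass
class CalibrationCurve:
    """Monotone linear intensity <-> concentration mapping for one dye."""

    dye_name: str
    slope: float  # intensity per uM, > 0
    intercept: float  # intensity at zero concentration
    points: list[CalibrationPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope <= 0:
            raise CalibrationQualityError(
                f"calibration slope must be positive, got {self.slope!r}"
            )

    def forward(self, concentration):
        """Predicted intensity for a concentration (vectorized)."""
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept

    def to_concentration(self, intensity):
        """Invert the line; negative inferred concentrations clamp to 0."""
        conc = (np.asarray(intensity, dtype=float) - self.intercept) / self.slope
        return np.clip(conc, 0.0, None)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "dye_name": self.dye_name,
                "slope": self.slope,
                "intercept": self.intercept,
                "concentration_uM": p.concentration,
                "mean_intensity": p.mean_intensity,
                "sd": p.sd,
                "n": p.n,
            }
            for p in (self.points or [CalibrationPoint(np.nan, np.nan, np.nan, 0)])
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationCurve":
        df = pd.read_csv(path)
        points = [
            CalibrationPoint(r.concentration_uM, r.mean_intensity, r.sd, int(r.n))
            for r in df.itertuples()
            if np.isfinite(r.concentration_uM)
        ]
        return cls(
            dye_name=str(df["dye_name"].iloc[0]),
            slope=float(df["slope"].iloc[0]),
            intercept=float(df["intercept"].iloc[0]),
            points=points,
        )


def _ols_line(conc: np.ndarray, intensity: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(conc, intensity, 1)
    return float(slope), float(intercept)


def fit_calibration(
    points: Sequence[tuple[float, Sequence[float]]],
    dye_name: str = "",
) -> CalibrationCurve:
    """Fit an OLS line through replicate means of (concentration, intensities).

    Parameters
    ----------
    points
        Sequence of ``(concentration_uM, replicate_intensities)`` pairs; each
        concentration needs at least one replicate.

    Raises
    ------
    DegenerateDesignError
        Fewer than two distinct concentrations.
    CalibrationQualityError
        Fitted slope is not positive.
    """
    if not points:
        raise DegenerateDesignError("no calibration points provided")
    concs, means, sds, ns = [], [], [], []
    for conc, reps in points:
        reps = np.asarray(list(np.atleast_1d(reps)), dtype=float)
        if reps.size == 0:
            raise DegenerateDesignError(f"concentration {conc} has no replicates")
        concs.append(float(conc))
        means.append(float(reps.mean()))
        sds.append(float(reps.std(ddof=1)) if reps.size > 1 else 0.0)
        ns.append(int(reps.size))
    if len(set(concs)) < 2:
        raise DegenerateDesignError(
            "need at least two distinct concentrations to fit a line"
        )
    slope, intercept = _ols_line(np.array(concs), np.array(means))
    if slope <= 0:
        raise CalibrationQualityError(
            f"fitted slope {slope:g} is not positive; intensity must increase "
            "with concentration"
        )
    curve_points = [
        CalibrationPoint(c, m, s, n) for c, m, s, n in zip(concs, means, sds, ns)
    ]
    return CalibrationCurve(dye_name, slope, intercept, curve_points)


def anchor_calcein(
    cell_free_intensities: Iterable[float],
    known_conc: float = 200.0,
    lower_points: Sequence[tuple[float, Sequence[float]]] | None = None,
    dye_name: str = "calcein",
) -> CalibrationCurve:
    """Calibration anchored at the measured extracellular concentration.

    The mean of the cell-free intensity measurements defines the top point at
    ``known_conc``; ``lower_points`` (cell-free preparations at lower
    concentrations) fill in the rest of the line. With no lower points the
    line is anchored through the origin.
    """
    intensities = np.asarray(list(cell_free_intensities), dtype=float)
    if intensities.size == 0:
        raise DegenerateDesignError("need at least one cell-free measurement")
    if known_conc <= 0:
        raise ValueError("known_conc must be positive")
    anchor = (known_conc, intensities)
    all_points = list(lower_points or [(0.0, [0.0])]) + [anchor]
    return fit_calibration(all_points, dye_name=dye_name)


def to_concentration(curve: CalibrationCurve, intensity):
    """Module-level alias for :meth:`CalibrationCurve.to_concentration`."""
    if curve is None:
        raise CalibrationQualityError("no fitted calibration curve supplied")
    return curve.to_concentration(intensity)


def read_points_csv(path: str | Path) -> list[tuple[float, list[float]]]:
    """Read a replicate table (columns concentration_uM, intensity) into
    the ``fit_calibration`` input format."""
    df = pd.read_csv(path)
    grouped = df.groupby("concentration_uM")["intensity"].apply(list)
    return [(float(c), list(v)) for c, v in grouped.items()]
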