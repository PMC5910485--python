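"""Asymmetry difference traces, exponential-decay fits, crossover times."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConfigurationError
from .pattern_analysis import RegionalTrace

logger = logging.getLogger(__name__)

__all__ = [
    "DIFFERENCE_KINDS",
    "DifferenceTrace",
    "DecayFit",
    "difference_trace",
    "fit_decay",
    "crossover_times",
]

DIFFERENCE_KINDS = ("anode_minus_cathode", "anode_minus_middle", "cathode_minus_middle")

_KIND_PAIRS = {
    "anode_minus_cathode": ("anode", "cathode"),
    "anode_minus_middle": ("anode", "middle"),
    "cathode_minus_middle": ("cathode", "middle"),
}


@dataclass
class DifferenceTrace:
    """Per-frame regional difference; positive anode_minus_cathode means
    anode-dominant uptake."""

    cell_id: int | str  # "population-mean" for the across-cell average
    times: np.ndarray
    delta: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if len(self.times) != len(self.delta):
            raise ConfigurationError("times and delta must share one length")
        if self.kind not in DIFFERENCE_KINDS:
            raise ConfigurationError(
                f"kind must be one of {DIFFERENCE_KINDS}, got {self.kind!r}"
            )


@dataclass
class DecayFit:
    """Result of fitting delta(t) = A exp(-(t - t_start)/tau)."""

    amplitude: float  # uM (or intensity units), signed
    tau: float  # s; NaN when undefined
    t_start: float  # s, fit-window start
    rss: float  # residual sum of squares over the fit window
    n_points: int
    converged: bool
    method: str = "nls"  # "nls" | "loglinear" | "degenerate"


def difference_trace(
    traces: Sequence[RegionalTrace], kind: str = "anode_minus_cathode"
) -> DifferenceTrace:
    """Population-mean difference trace: per-cell subtraction, then the
    per-frame mean across cells."""
    if not traces:
        raise ConfigurationError("need at least one regional trace")
    if kind not in _KIND_PAIRS:
        raise ConfigurationError(f"unknown difference kind {kind!r}")
    times = traces[0].times
    for t in traces[1:]:
        if len(t.times) != len(times) or not np.allclose(t.times, times):
            raise ConfigurationError("traces must share one time base")
    a, b = _KIND_PAIRS[kind]
    deltas = np.stack([t.region(a) - t.region(b) for t in traces])
    return DifferenceTrace(
        cell_id="population-mean" if len(traces) > 1 else traces[0].cell_id,
        times=times,
        delta=deltas.mean(axis=0),
        kind=kind,
    )


def _exp_model(t, A, tau):
    return A * np.exp(-t / tau)


def _loglinear_tau(t: np.ndarray, y: np.ndarray, sign: float) -> tuple[float, float]:
    """Fallback estimate: linear regression of log|delta| where the sign is
    right. Returns (amplitude, tau); NaNs when even that is impossible."""
    keep = sign * y > 0
    if keep.sum() < 2:
        return np.nan, np.nan
    coeffs = np.polyfit(t[keep], np.log(sign * y[keep]), 1)
    if coeffs[0] >= 0:
        return np.nan, np.nan
    return sign * float(np.exp(coeffs[1])), float(-1.0 / coeffs[0])


def fit_decay(trace: DifferenceTrace, pulse_time: float) -> DecayFit:
    """Nonlinear least-squares fit of a decaying exponential to the post-pulse
    difference trace.

    The fit window starts at the post-pulse extremum of the dominant-sign
    delta: the dominant sign is the sign of the post-pulse integral of the
    trace, which excludes a brief opposite-sign transient (such as the early
    anode-positive spike under cathode-dominant influx) from setting the
    window. Initial guesses are A = delta(t_start) and tau = time for the
    trace to fall to A/e. On non-convergence a log-linear regression
    fallback is reported with ``converged=False``.
    """
    post = trace.times >= pulse_time
    if post.sum() < 3:
        raise ConfigurationError("fewer than 3 post-pulse samples")
    t_post = trace.times[post]
    y_post = trace.delta[post]

    if np.allclose(y_post, 0.0):
        return DecayFit(0.0, np.nan, float(t_post[0]), 0.0, int(post.sum()),
                        False, "degenerate")

    sign = 1.0 if y_post.sum() >= 0 else -1.0
    # leave at least 3 samples after the window start
    i_start = int(np.argmax(sign * y_post[: max(1, len(y_post) - 2)]))
    t_start = float(t_post[i_start])
    t_fit = t_post[i_start:] - t_start
    y_fit = y_post[i_start:]
    if len(t_fit) < 3:
        raise ConfigurationError("fit window has fewer than 3 samples")

    A0 = float(y_fit[0])
    below = np.nonzero(sign * y_fit <= sign * A0 / np.e)[0]
    tau0 = float(t_fit[below[0]]) if below.size else float(t_fit[-1] / 3.0)
    tau0 = max(tau0, float(t_fit[1] - t_fit[0]))

    try:
        popt, _ = curve_fit(
            _exp_model, t_fit, y_fit, p0=(A0, tau0),
            bounds=([-np.inf, 1e-9], [np.inf, np.inf]), maxfev=10000,
        )
        A_hat, tau_hat = float(popt[0]), float(popt[1])
        resid = y_fit - _exp_model(t_fit, A_hat, tau_hat)
        return DecayFit(A_hat, tau_hat, t_start, float(resid @ resid),
                        len(t_fit), True, "nls")
    except (RuntimeError, ValueError):
        logger.warning("decay fit did not converge; using log-linear fallback")
        A_hat, tau_hat = _loglinear_tau(t_fit, y_fit, sign)
        rss = np.nan
        if np.isfinite(tau_hat):
            resid = y_fit - _exp_model(t_fit, A_hat, tau_hat)
            rss = float(resid @ resid)
        return DecayFit(A_hat, tau_hat, t_start, rss, len(t_fit), False, "loglinear")


def crossover_times(
    traces: Sequence[RegionalTrace],
    pulse_time: float,
    persistence: int = 5,
) -> dict[str, float | None]:
    """First post-pulse times at which the middle region overtakes each polar
    region and stays above it for ``persistence`` consecutive frames.

    Returns ``{"middle_minus_anode": t or None, "middle_minus_cathode": ...}``.
    """
    if not traces:
        raise ConfigurationError("need at least one regional trace")
    out: dict[str, float | None] = {}
    times = traces[0].times
    post = times >= pulse_time
    for region in ("anode", "cathode"):
        stacked = np.stack([t.middle - t.region(region) for t in traces])
        delta = stacked.mean(axis=0)
        positive = (delta > 0) & post
        run = 0
        found = None
        for i, p in enumerate(positive):
            run = run + 1 if p else 0
            if run >= persistence:
                found = float(times[i - persistence + 1])
                break
        out[f"middle_minus_{region}"] = found
    return out


def fits_to_dataframe(fits: dict[str, DecayFit]) -> pd.DataFrame:
    """Flatten a {kind: DecayFit} mapping into a tidy table."""
    return pd.DataFrame(
        [
            {
                "kind": kind,
                "amplitude": f.amplitude,
                "tau_s": f.tau,
                "t_start_s": f.t_start,
                "rss": f.rss,
                "n_points": f.n_points,
                "converged": f.converged,
                "method": f.method,
            }
            for kind, f in fits.items()
        ]
    )
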