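"""Phase diagrams and fold-change sensitivity analysis.

A phase diagram classifies the loop's long-run output (peak and average
free p53, spikyness, oscillatory or not) on a 2-D parameter grid, and
extracts the contour where spikyness (amplitude/average) equals 2 — the
boundary between smooth and spiky oscillations.

A sensitivity curve varies one parameter over folds 1/5 .. 5 of its
default and reports the fold change of the settled average free-p53
level; the maximum log-log slope summarizes how sensitive the p53 level
is to that parameter.  beta and k_tl are excluded: rescaling time and
mRNA-concentration units maps any (beta, k_tl) onto the default pair, so
their variations are mimicked by the remaining parameters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .dynamics import (
    SPIKYNESS_THRESHOLD,
    UnsettledError,
    IntegrationError,
    oscillation_metrics,
    standard_run,
)
from .params import ModelParameters
from .stress import StressScenario, apply

__all__ = [
    "AxisSpec",
    "PhaseDiagram",
    "SensitivityCurve",
    "phase_diagram",
    "sensitivity_curve",
    "SENSITIVITY_PARAMETERS",
]

logger = logging.getLogger(__name__)

#: parameters admissible in sensitivity_curve.
SENSITIVITY_PARAMETERS = ("sigma", "alpha", "delta", "k_t", "gamma", "k_D")


@dataclass(frozen=True)
class AxisSpec:
    """One scan axis: parameter name and a (log-spaced) value grid."""

    name: str
    lo: float
    hi: float
    n: int
    log: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("axis needs at least one point")
        if not (0 < self.lo <= self.hi):
            raise ValueError("axis bounds must be positive with lo <= hi")

    def grid(self) -> np.ndarray:
        if self.n == 1:
            return np.array([self.lo])
        if self.log:
            return np.geomspace(self.lo, self.hi, self.n)
        return np.linspace(self.lo, self.hi, self.n)


@dataclass
class PhaseDiagram:
    """Grid of per-cell oscillation metrics plus the spikyness=2 contour.

    2-D arrays are indexed [i_x, i_y].  ``contours`` is a list of
    polylines in (x_value, y_value) coordinates where interpolated
    spikyness equals :data:`SPIKYNESS_THRESHOLD`.
    """

    axis_x: AxisSpec
    axis_y: AxisSpec
    peak_p53: np.ndarray
    avg_p53: np.ndarray
    spikyness: np.ndarray
    oscillatory: np.ndarray
    contours: list[np.ndarray] = field(default_factory=list)
    errors: list[tuple[int, int, str]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        gx, gy = self.axis_x.grid(), self.axis_y.grid()
        rows = []
        for (i, x), (j, y) in itertools.product(enumerate(gx), enumerate(gy)):
            rows.append(
                {
                    "axis1_value": x,
                    "axis2_value": y,
                    "peak_p53_nM": self.peak_p53[i, j],
                    "avg_p53_nM": self.avg_p53[i, j],
                    "spikyness": self.spikyness[i, j],
                    "oscillatory": bool(self.oscillatory[i, j]),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SensitivityCurve:
    """Average-free-p53 response to fold changes of one parameter.

    Two slope summaries are provided.  ``max_abs_slope`` is the largest
    local log-log finite difference; near a Hopf onset it measures how
    the oscillation waveform reshapes the average rather than how the
    level responds, so it is kept for diagnostics (it reproduces the
    flat stretch of the gamma curve at 1-2 fold).  ``overall_slope`` is
    the log-log chord across the whole fold range — the slope of the
    curve as a whole — and is the summary used to rank parameters by
    sensitivity.
    """

    parameter: str
    folds: np.ndarray
    response: np.ndarray  # fold change in settled average free p53
    max_abs_slope: float  # max |d log response / d log fold|, local
    overall_slope: float  # |log response ratio| / |log fold ratio|, chord


def _cell_params(params: ModelParameters, name: str, value: float) -> ModelParameters:
    if name == "k_D":
        return params.with_updates(k_D=value)
    return params.with_updates(**{name: value})


def _cell_metrics(params: ModelParameters, duration: float):
    traj = standard_run(params, duration=duration)
    return oscillation_metrics(traj, species="free_p53", settle_fraction=0.5)


def phase_diagram(
    params: ModelParameters,
    axis_x: AxisSpec,
    axis_y: AxisSpec,
    *,
    duration: float = 200.0,
) -> PhaseDiagram:
    """Evaluate the standardized run on every cell of a 2-D grid.

    Integrator or classification failures are recorded per cell (NaN
    metrics) and never abort the scan.  Contours are extracted from the
    spikyness field by linear interpolation on grid edges; disconnected
    pieces are kept separate.
    """
    if axis_x.name == axis_y.name:
        raise ValueError("axes must name distinct parameters")
    gx, gy = axis_x.grid(), axis_y.grid()
    shape = (gx.size, gy.size)
    peak = np.full(shape, np.nan)
    avg = np.full(shape, np.nan)
    spiky = np.full(shape, np.nan)
    osc = np.zeros(shape, dtype=bool)
    errors: list[tuple[int, int, str]] = []
    for (i, x), (j, y) in itertools.product(enumerate(gx), enumerate(gy)):
        try:
            cell = _cell_params(_cell_params(params, axis_x.name, x), axis_y.name, y)
            met = _cell_metrics(cell, duration)
        except (IntegrationError, UnsettledError, ValueError) as exc:
            errors.append((i, j, str(exc)))
            logger.warning("cell (%d, %d) failed: %s", i, j, exc)
            continue
        peak[i, j] = met.peak_level
        avg[i, j] = met.average
        spiky[i, j] = met.spikyness
        osc[i, j] = met.oscillatory

    contours = _spikyness_contours(gx, gy, spiky, axis_x.log, axis_y.log)
    return PhaseDiagram(
        axis_x=axis_x,
        axis_y=axis_y,
        peak_p53=peak,
        avg_p53=avg,
        spikyness=spiky,
        oscillatory=osc,
        contours=contours,
        errors=errors,
    )


def _spikyness_contours(gx, gy, spiky, log_x: bool, log_y: bool) -> list[np.ndarray]:
    """Spikyness=2 level set in parameter coordinates.

    Fractional grid indices from marching squares are mapped through the
    axis spacing (linear in log space for log axes).
    """
    if spiky.shape[0] < 2 or spiky.shape[1] < 2 or not np.isfinite(spiky).any():
        return []
    field = np.where(np.isfinite(spiky), spiky, -1.0)
    tx = np.log(gx) if log_x else gx
    ty = np.log(gy) if log_y else gy
    out = []
    for seg in measure.find_contours(field, SPIKYNESS_THRESHOLD):
        xs = np.interp(seg[:, 0], np.arange(tx.size), tx)
        ys = np.interp(seg[:, 1], np.arange(ty.size), ty)
        if log_x:
            xs = np.exp(xs)
        if log_y:
            ys = np.exp(ys)
        out.append(np.column_stack([xs, ys]))
    return out


def sensitivity_curve(
    params: ModelParameters,
    name: str,
    n_points: int = 21,
    *,
    duration: float = 200.0,
) -> SensitivityCurve:
    """Fold-response curve of the settled average free-p53 level.

    Folds are log-spaced over exactly [1/5, 5] with fold 1 included
    (``n_points`` is made odd), so the normalization response(1) = 1
    holds identically.
    """
    if name in ("beta", "k_tl"):
        raise ValueError(
            f"{name} is excluded from sensitivity analysis: time and mRNA "
            "units can be rescaled so that beta = k_tl = 1, hence its "
            "variations are equivalent to changes in the other parameters"
        )
    if name not in SENSITIVITY_PARAMETERS:
        raise ValueError(
            f"unknown parameter {name!r}; choose from {SENSITIVITY_PARAMETERS}"
        )
    if n_points < 3:
        raise ValueError("n_points must be at least 3")
    if n_points % 2 == 0:
        n_points += 1
    folds = np.geomspace(0.2, 5.0, n_points)
    folds[n_points // 2] = 1.0

    base_value = params.k_D if name == "k_D" else getattr(params, name)
    averages = np.empty_like(folds)
    for i, f in enumerate(folds):
        met = _cell_metrics(_cell_params(params, name, base_value * f), duration)
        averages[i] = met.average
    ref = averages[n_points // 2]
    response = averages / ref
    with np.errstate(divide="ignore"):
        slopes = np.diff(np.log(response)) / np.diff(np.log(folds))
    chord = abs(np.log(response[-1]) - np.log(response[0])) / abs(
        np.log(folds[-1]) - np.log(folds[0])
    )
    return SensitivityCurve(
        parameter=name,
        folds=folds,
        response=response,
        max_abs_slope=float(np.max(np.abs(slopes))),
        overall_slope=float(chord),
    )
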