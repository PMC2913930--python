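"""Deterministic time courses, peak detection and oscillation metrics.

Simulations use a stiff implicit integrator (BDF with the analytic
Jacobian); complex formation/dissociation (k_b = 7200/h) is orders of
magnitude faster than transcription/translation, which makes the system
stiff.  Stress events are parameter switches applied exactly at their
event times by restarting the integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .model import SystemState, steady_states
from .params import ModelParameters

__all__ = [
    "Trajectory",
    "OscillationMetrics",
    "ResponseClass",
    "IntegrationError",
    "UnsettledError",
    "NoRestingStateError",
    "simulate",
    "resting_state",
    "oscillation_metrics",
    "classify_response",
]

logger = logging.getLogger(__name__)

#: spikyness (amplitude/average) at and above which oscillations are
#: called "spiky"; the boundary itself is spiky (closed threshold).
SPIKYNESS_THRESHOLD = 2.0

#: amplitude below this multiple of the average is treated as numerically
#: flat (no oscillation).
OSCILLATION_FLOOR = 1e-3

#: minimum separation between detected peaks, hours.
PEAK_MIN_SEPARATION_H = 0.25

#: prominence floor for peak detection, as a fraction of the window range.
PEAK_PROMINENCE_FRACTION = 0.01


class IntegrationError(RuntimeError):
    """The ODE integrator failed on some interval."""


class UnsettledError(RuntimeError):
    """The trajectory window is too short to classify the settled regime."""


class NoRestingStateError(RuntimeError):
    """The parameter set has no stable equilibrium to rest at."""


@dataclass
class Trajectory:
    """A simulated time course on a uniform grid.

    ``states`` has one row per time point with columns (p, m_m, m, c) in
    nM (deterministic runs) or molecules (stochastic runs, see
    ``meta['omega']``).
    """

    times: np.ndarray
    states: np.ndarray
    params_timeline: list[tuple[float, ModelParameters]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 4):
            raise ValueError("states must be (n_times, 4)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def p(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def m_m(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def m(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def c(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def total_p53(self) -> np.ndarray:
        return self.states[:, 0] + self.states[:, 3]

    @property
    def total_mdm2(self) -> np.ndarray:
        return self.states[:, 2] + self.states[:, 3]

    def species(self, name: str) -> np.ndarray:
        try:
            return {
                "free_p53": self.p,
                "total_p53": self.total_p53,
                "mdm2": self.m,
                "total_mdm2": self.total_mdm2,
                "mrna": self.m_m,
                "complex": self.c,
            }[name]
        except KeyError:
            raise ValueError(f"unknown species {name!r}") from None

    def final_state(self) -> SystemState:
        return SystemState.from_array(np.clip(self.states[-1], 0.0, None))


@dataclass(frozen=True)
class OscillationMetrics:
    """Summary of the settled regime of one species' time course."""

    average: float
    amplitude: float
    peak_level: float
    period: float | None
    spikyness: float
    peaks: tuple[tuple[float, float], ...]
    oscillatory: bool
    free_to_bound_ratio: float


@dataclass(frozen=True)
class ResponseClass:
    """Deterministic classification of a parameter set's long-run output."""

    kind: str  # "steady" | "oscillatory"
    shape: str  # "smooth" | "spiky"
    peak_free_p53: float
    metrics: OscillationMetrics


def _compiled_system(params: ModelParameters, variant: str):
    """Closure pair (rhs, jac) with rate constants bound as locals.

    Equivalent to :func:`p53loop.model.rhs`/``jacobian`` but without
    per-call validation; negative excursions from the solver are clamped
    to zero.  This is the hot path of every simulation.
    """
    sigma, alpha, delta = params.sigma, params.alpha, params.delta
    k_t, k_tl, beta = params.k_t, params.k_tl, params.beta
    gamma, k_b, k_f, hill = params.gamma, params.k_b, params.k_f, params.hill
    gamma_on_p = gamma if variant == "release" else 0.0
    square = hill == 2.0

    def f(t, y):
        p, mm, m, c = y
        if p < 0.0:
            p = 0.0
        if mm < 0.0:
            mm = 0.0
        if m < 0.0:
            m = 0.0
        if c < 0.0:
            c = 0.0
        form = k_f * p * m
        trans = k_t * (p * p if square else p**hill)
        return (
            sigma - alpha * p - form + (k_b + gamma_on_p) * c,
            trans - beta * mm,
            k_tl * mm - gamma * m - form + (k_b + delta) * c,
            form - (k_b + delta + gamma) * c,
        )

    def jac(t, y):
        p, mm, m, c = (max(v, 0.0) for v in y)
        dtrans = hill * k_t * (p if square else p ** (hill - 1.0))
        return np.array(
            [
                [-alpha - k_f * m, 0.0, -k_f * p, k_b + gamma_on_p],
                [dtrans, -beta, 0.0, 0.0],
                [-k_f * m, k_tl, -gamma - k_f * p, k_b + delta],
                [k_f * m, 0.0, k_f * p, -(k_b + delta + gamma)],
            ]
        )

    return f, jac


def simulate(
    params: ModelParameters,
    init: SystemState | np.ndarray,
    duration: float,
    events: list[tuple[float, "StressScenario"]] | None = None,
    *,
    dt: float = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    method: str = "LSODA",
    variant: str = "release",
) -> Trajectory:
    """Integrate the loop for ``duration`` hours with optional stress events.

    Each event is ``(time, scenario)``; the scenario's fold changes are
    applied to the currently active parameters at exactly that time and
    the integration restarts from the interface state.

    Parameters
    ----------
    dt : float
        Output grid spacing, hours.  Peaks are later refined below the
        grid by quadratic interpolation, so 0.01 h suffices.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    init_arr = init.as_array() if isinstance(init, SystemState) else np.asarray(init, float)
    if np.any(init_arr < 0) or not np.all(np.isfinite(init_arr)):
        raise ValueError(f"initial state must be non-negative and finite: {init_arr}")

    events = sorted(events or [], key=lambda ev: ev[0])
    for t_ev, _ in events:
        if not (0.0 <= t_ev <= duration):
            raise ValueError(f"event time {t_ev} outside [0, {duration}]")

    # breakpoints partition [0, duration] into constant-parameter intervals
    breakpoints = [0.0] + [t for t, _ in events if t > 0.0] + [duration]
    # events at t=0 modify the starting parameters
    current = params
    from .stress import apply as apply_scenario  # local import, avoids cycle

    ev_iter = iter(events)
    pending = next(ev_iter, None)
    while pending is not None and pending[0] == 0.0:
        current = apply_scenario(pending[1], current)
        pending = next(ev_iter, None)

    n_out = max(int(round(duration / dt)), 2)
    times = np.linspace(0.0, duration, n_out + 1)
    states = np.empty((times.size, 4))
    states[0] = init_arr
    timeline: list[tuple[float, ModelParameters]] = [(0.0, current)]

    y = init_arr.copy()
    for t_lo, t_hi in zip(breakpoints[:-1], breakpoints[1:]):
        if t_hi <= t_lo:
            continue
        mask = (times > t_lo) & (times <= t_hi)
        t_eval = times[mask]
        f, jac = _compiled_system(current, variant)
        sol = solve_ivp(
            f,
            (t_lo, t_hi),
            y,
            method=method,
            jac=jac,
            t_eval=t_eval if t_eval.size else None,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed on [{t_lo:g}, {t_hi:g}] h: {sol.message}"
            )
        if t_eval.size:
            states[mask] = sol.y.T
        y = np.clip(sol.y[:, -1] if sol.y.size else y, 0.0, None)
        # apply all events scheduled at t_hi
        while pending is not None and pending[0] == t_hi:
            current = apply_scenario(pending[1], current)
            timeline.append((t_hi, current))
            pending = next(ev_iter, None)

    states = np.clip(states, 0.0, None)
    return Trajectory(times=times, states=states, params_timeline=timeline)


def resting_state(params: ModelParameters, variant: str = "release") -> SystemState:
    """The stable equilibrium used as initial condition for stress runs.

    Raises
    ------
    NoRestingStateError
        If the admissible equilibrium is unstable (oscillatory regime);
        use a long pre-equilibration run instead.
    """
    eq = steady_states(params, variant=variant)[0]
    if not eq.stable:
        raise NoRestingStateError(
            "the equilibrium is unstable for this parameter set; "
            "pre-equilibrate with a long simulation instead of resting_state"
        )
    return eq.state


def _refine_peak(t: np.ndarray, x: np.ndarray, i: int) -> tuple[float, float]:
    """Quadratic (3-point) refinement of a grid peak at index i."""
    if i == 0 or i == len(x) - 1:
        return float(t[i]), float(x[i])
    y0, y1, y2 = x[i - 1], x[i], x[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(t[i]), float(x[i])
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    dt = t[i] - t[i - 1] if shift < 0 else t[min(i + 1, len(t) - 1)] - t[i]
    t_peak = float(t[i] + shift * abs(dt))
    h_peak = float(y1 - 0.25 * (y0 - y2) * shift)
    return t_peak, h_peak


def detect_peaks(
    times: np.ndarray,
    series: np.ndarray,
    *,
    min_separation: float = PEAK_MIN_SEPARATION_H,
    prominence_fraction: float = PEAK_PROMINENCE_FRACTION,
) -> list[tuple[float, float]]:
    """Local maxima of ``series`` with sub-grid quadratic refinement.

    A prominence floor of ``prominence_fraction`` of the window's range
    and a minimum separation suppress solver ripple; ties keep the
    earliest sample.
    """
    rng = float(np.max(series) - np.min(series))
    if rng == 0.0:
        return []
    dt = float(np.median(np.diff(times)))
    distance = max(int(round(min_separation / dt)), 1)
    idx, _ = find_peaks(series, prominence=prominence_fraction * rng, distance=distance)
    return [_refine_peak(times, series, int(i)) for i in idx]


def oscillation_metrics(
    traj: Trajectory,
    species: str = "free_p53",
    settle_fraction: float = 0.5,
) -> OscillationMetrics:
    """Settled-regime summary of one species.

    Metrics are computed over the trailing ``settle_fraction`` of the
    span.  A window whose amplitude is below ``OSCILLATION_FLOOR`` times
    its average is reported as non-oscillatory with peak_level equal to
    the average.  An oscillating window containing fewer than two peaks
    raises :class:`UnsettledError`.
    """
    if not (0 < settle_fraction <= 1):
        raise ValueError("settle_fraction must be in (0, 1]")
    x_full = traj.species(species)
    t = traj.times
    t_start = t[-1] - settle_fraction * (t[-1] - t[0])
    win = t >= t_start
    if win.sum() < 16:
        raise UnsettledError("settled window has too few samples to classify")
    tw, xw = t[win], x_full[win]

    average = float(np.trapezoid(xw, tw) / (tw[-1] - tw[0]))
    amplitude = float(np.max(xw) - np.min(xw))
    p_win, c_win = traj.p[win], traj.c[win]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(c_win > 0, p_win / np.maximum(c_win, 1e-300), np.inf)
    free_to_bound = float(np.mean(ratio)) if np.all(np.isfinite(ratio)) else float("inf")

    floor = OSCILLATION_FLOOR * max(average, 1e-12)
    if amplitude < floor:
        return OscillationMetrics(
            average=average,
            amplitude=amplitude,
            peak_level=average,
            period=None,
            spikyness=0.0,
            peaks=(),
            oscillatory=False,
            free_to_bound_ratio=free_to_bound,
        )

    peaks = detect_peaks(tw, xw)
    if len(peaks) < 2:
        raise UnsettledError(
            f"window oscillates (amplitude {amplitude:.3g}) but contains "
            f"{len(peaks)} peak(s); lengthen the trajectory"
        )
    peak_times = np.array([pt for pt, _ in peaks])
    period = float(np.mean(np.diff(peak_times)))
    spikyness = amplitude / average if average > 0 else float("inf")
    return OscillationMetrics(
        average=average,
        amplitude=amplitude,
        peak_level=float(np.max(xw)),
        period=period,
        spikyness=spikyness,
        peaks=tuple(peaks),
        oscillatory=True,
        free_to_bound_ratio=free_to_bound,
    )


def standard_run(
    params: ModelParameters,
    *,
    duration: float = 200.0,
    variant: str = "release",
    fallback_init: SystemState | None = None,
) -> Trajectory:
    """The standardized protocol behind classification and scans.

    Start from the parameter set's own resting state when a stable
    equilibrium exists; otherwise pre-equilibrate for ``duration`` hours
    (from ``fallback_init`` or a unit state) and continue from where
    that run ends.  Integrate ``duration`` hours for analysis.
    """
    try:
        init: SystemState | np.ndarray = resting_state(params, variant=variant)
    except NoRestingStateError:
        start = fallback_init if fallback_init is not None else SystemState(1.0, 1.0, 1.0, 1.0)
        warmup = simulate(params, start, duration, dt=0.05, variant=variant)
        init = warmup.final_state()
    return simulate(params, init, duration, variant=variant)


def classify_response(
    params: ModelParameters,
    *,
    species: str = "free_p53",
    variant: str = "release",
) -> ResponseClass:
    """Label a parameter set as steady/oscillatory and smooth/spiky.

    Uses the standardized run (resting start or pre-equilibration,
    200 h, settle fraction 0.5).  "Spiky" means spikyness >= 2, the
    boundary included.
    """
    traj = standard_run(params, variant=variant)
    metrics = oscillation_metrics(traj, species=species, settle_fraction=0.5)
    kind = "oscillatory" if metrics.oscillatory else "steady"
    shape = "spiky" if metrics.spikyness >= SPIKYNESS_THRESHOLD else "smooth"
    return ResponseClass(
        kind=kind, shape=shape, peak_free_p53=metrics.peak_level, metrics=metrics
    )
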