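"""Exact stochastic counterpart of the loop (Gillespie direct method).

The four concentrations become integer copy numbers through the cell
volume: omega = V * N_A * 1e-9 molecules per nM.  The reference volume
is a sphere of radius 6 um (9.05e-13 L, omega ~ 545), at which the
resting ~100 nM of total p53 corresponds to ~54,500 molecules — large
enough that intrinsic noise is nearly invisible.  A volume reduction
(e.g. 500-fold) shrinks all copy numbers proportionally and exposes the
noise.

The ten reaction channels are the term-by-term translation of the
deterministic rate equations; summed mean-field rates reproduce the ODE
right-hand side exactly in the large-omega limit.  Transcription uses
the combinatorial pair count n_p*(n_p-1) (Hill-2 activation is dimer
occupancy), which differs from n_p**2 by O(1/omega).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
from numba import njit
from scipy.constants import Avogadro

from .dynamics import Trajectory, detect_peaks, resting_state
from .model import SystemState
from .params import ModelParameters

__all__ = [
    "REFERENCE_VOLUME_L",
    "VolumeContext",
    "StochasticState",
    "ReactionChannel",
    "ReactionNetwork",
    "PeakTimeStats",
    "build_reactions",
    "ssa_run",
    "peak_time_variability",
]

#: Volume of a sphere of radius 6 um, in liters.
REFERENCE_VOLUME_L = 4.0 / 3.0 * math.pi * (6e-6) ** 3 * 1e3

#: moving-average pre-smoother window for peak detection on counts, h.
#: Chosen well below the ~5.5 h inter-peak interval but wide enough to
#: suppress shot noise at a few tens of molecules.
SMOOTH_WINDOW_H = 0.5

#: peak-detector settings for stochastic ensembles: genuine response
#: peaks are hours apart and an order of magnitude above residual
#: smoothed noise, so a coarse separation and a 10% prominence floor
#: isolate them.
ENSEMBLE_MIN_SEPARATION_H = 2.0
ENSEMBLE_PROMINENCE_FRACTION = 0.1


@dataclass(frozen=True)
class VolumeContext:
    """Cell volume and the concentration <-> copy-number conversion."""

    volume: float  # liters
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (self.volume > 0):
            raise ValueError(f"volume must be positive, got {self.volume}")

    @classmethod
    def reference(cls, scale_factor: float = 1.0) -> "VolumeContext":
        """The 6-um-sphere reference volume divided by ``scale_factor``."""
        if not (scale_factor > 0):
            raise ValueError("scale_factor must be positive")
        return cls(volume=REFERENCE_VOLUME_L / scale_factor, scale_factor=scale_factor)

    @property
    def omega(self) -> float:
        """Molecules per nM."""
        return self.volume * Avogadro * 1e-9

    def to_counts(self, state: SystemState | np.ndarray) -> "StochasticState":
        arr = state.as_array() if isinstance(state, SystemState) else np.asarray(state)
        n = np.rint(arr * self.omega).astype(np.int64)
        return StochasticState(*map(int, n))

    def to_concentrations(self, counts: np.ndarray) -> np.ndarray:
        return np.asarray(counts, dtype=float) / self.omega


@dataclass(frozen=True)
class StochasticState:
    """Integer copy numbers (n_p, n_mm, n_m, n_c)."""

    n_p: int
    n_mm: int
    n_m: int
    n_c: int

    def __post_init__(self) -> None:
        for name in ("n_p", "n_mm", "n_m", "n_c"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.n_p, self.n_mm, self.n_m, self.n_c], dtype=np.int64)


@dataclass(frozen=True)
class ReactionChannel:
    """One reaction: stoichiometry change per firing and propensity rule."""

    label: str
    stoichiometry: tuple[int, int, int, int]
    propensity: Callable[[np.ndarray], float]


@dataclass(frozen=True)
class ReactionNetwork(Sequence):
    """The model's channel list plus the context needed by the SSA core."""

    channels: tuple[ReactionChannel, ...]
    params: ModelParameters
    volume: VolumeContext
    variant: str = "release"

    def __len__(self) -> int:
        return len(self.channels)

    def __getitem__(self, i):
        return self.channels[i]

    def __iter__(self) -> Iterator[ReactionChannel]:
        return iter(self.channels)

    def propensities(self, counts: StochasticState | np.ndarray) -> np.ndarray:
        n = counts.as_array() if isinstance(counts, StochasticState) else np.asarray(counts)
        return np.array([ch.propensity(n) for ch in self.channels])

    def stoichiometry_matrix(self) -> np.ndarray:
        return np.array([ch.stoichiometry for ch in self.channels], dtype=np.int64)


def build_reactions(
    params: ModelParameters, vol: VolumeContext, variant: str = "release"
) -> ReactionNetwork:
    """The ten channels of the loop at volume ``vol``.

    Propensities are in events per hour; counts are molecules.  The
    gamma event on the complex releases p53 in the default variant and
    destroys the whole complex in the "codegradation" variant.
    """
    if variant not in ("release", "codegradation"):
        raise ValueError(f"unknown variant {variant!r}")
    om = vol.omega
    pr = params
    gamma_c_stoich = (1, 0, 0, -1) if variant == "release" else (0, 0, 0, -1)
    channels = (
        ReactionChannel("p53_production", (1, 0, 0, 0), lambda n: pr.sigma * om),
        ReactionChannel("p53_removal", (-1, 0, 0, 0), lambda n: pr.alpha * n[0]),
        ReactionChannel(
            "complex_formation", (-1, 0, -1, 1), lambda n: pr.k_f / om * n[0] * n[2]
        ),
        ReactionChannel("complex_dissociation", (1, 0, 1, -1), lambda n: pr.k_b * n[3]),
        ReactionChannel(
            "p53_degradation_in_complex", (0, 0, 1, -1), lambda n: pr.delta * n[3]
        ),
        ReactionChannel(
            "mdm2_degradation_in_complex", gamma_c_stoich, lambda n: pr.gamma * n[3]
        ),
        ReactionChannel(
            "transcription", (0, 1, 0, 0), lambda n: pr.k_t / om * n[0] * (n[0] - 1)
        ),
        ReactionChannel("mrna_decay", (0, -1, 0, 0), lambda n: pr.beta * n[1]),
        ReactionChannel("translation", (0, 0, 1, 0), lambda n: pr.k_tl * n[1]),
        ReactionChannel("mdm2_removal", (0, 0, -1, 0), lambda n: pr.gamma * n[2]),
    )
    return ReactionNetwork(channels=channels, params=params, volume=vol, variant=variant)


@njit(cache=True)
def _ssa_core(rates, release_variant, n0, record_times, seed):  # pragma: no cover
    """Direct-method inner loop specialized to the ten channels.

    rates = (sigma*omega, alpha, k_f/omega, k_b, delta, gamma,
    k_t/omega, beta, k_tl).  Returns counts at ``record_times``
    (piecewise-constant sampling) and an exhaustion flag.
    """
    np.random.seed(seed)
    c_prod, alpha, kf_om, kb, delta, gamma, kt_om, beta, ktl = rates
    n_p, n_mm, n_m, n_c = n0[0], n0[1], n0[2], n0[3]
    n_rec = record_times.shape[0]
    out = np.empty((n_rec, 4), dtype=np.int64)
    a = np.empty(10)
    t = 0.0
    i_rec = 0
    exhausted = False
    t_end = record_times[n_rec - 1]
    while i_rec < n_rec:
        a[0] = c_prod
        a[1] = alpha * n_p
        a[2] = kf_om * n_p * n_m
        a[3] = kb * n_c
        a[4] = delta * n_c
        a[5] = gamma * n_c
        a[6] = kt_om * n_p * (n_p - 1)
        a[7] = beta * n_mm
        a[8] = ktl * n_mm
        a[9] = gamma * n_m
        a0 = a[0] + a[1] + a[2] + a[3] + a[4] + a[5] + a[6] + a[7] + a[8] + a[9]
        if a0 <= 0.0:
            exhausted = True
            t_next = t_end + 1.0
        else:
            t_next = t - math.log(np.random.random()) / a0
        while i_rec < n_rec and record_times[i_rec] < t_next:
            out[i_rec, 0] = n_p
            out[i_rec, 1] = n_mm
            out[i_rec, 2] = n_m
            out[i_rec, 3] = n_c
            i_rec += 1
        if exhausted or i_rec >= n_rec:
            break
        t = t_next
        r = np.random.random() * a0
        acc = a[0]
        j = 0
        while acc < r and j < 9:
            j += 1
            acc += a[j]
        if j == 0:
            n_p += 1
        elif j == 1:
            n_p -= 1
        elif j == 2:
            n_p -= 1
            n_m -= 1
            n_c += 1
        elif j == 3:
            n_p += 1
            n_m += 1
            n_c -= 1
        elif j == 4:
            n_m += 1
            n_c -= 1
        elif j == 5:
            n_c -= 1
            if release_variant:
                n_p += 1
        elif j == 6:
            n_mm += 1
        elif j == 7:
            n_mm -= 1
        elif j == 8:
            n_m += 1
        else:
            n_m -= 1
    return out, exhausted


def _ssa_python(network: ReactionNetwork, init, record_times, rng) -> tuple[np.ndarray, bool]:
    """Reference direct-method loop over generic channels (slow; used as
    an independent cross-check of the compiled core at tiny scale)."""
    n = init.as_array() if isinstance(init, StochasticState) else np.array(init, np.int64)
    stoich = network.stoichiometry_matrix()
    out = np.empty((len(record_times), 4), dtype=np.int64)
    t, i_rec, exhausted = 0.0, 0, False
    t_end = record_times[-1]
    while i_rec < len(record_times):
        a = network.propensities(n)
        a0 = float(a.sum())
        t_next = t + rng.exponential(1.0 / a0) if a0 > 0 else t_end + 1.0
        exhausted = a0 <= 0
        while i_rec < len(record_times) and record_times[i_rec] < t_next:
            out[i_rec] = n
            i_rec += 1
        if exhausted or i_rec >= len(record_times):
            break
        t = t_next
        j = int(np.searchsorted(np.cumsum(a), rng.random() * a0, side="right"))
        j = min(j, len(a) - 1)
        n = n + stoich[j]
    return out, exhausted


def ssa_run(
    network: ReactionNetwork,
    init: StochasticState,
    t_max: float,
    seed: int,
    *,
    record_dt: float = 0.01,
    engine: str = "compiled",
) -> Trajectory:
    """One exact SSA realization, sampled on a uniform grid.

    Exponential waiting times and propensity-weighted channel choice
    (direct method); reproducible for a fixed ``seed``.  States are
    recorded piecewise-constantly every ``record_dt`` hours; counts are
    stored in molecules with ``omega`` in ``Trajectory.meta``.  If every
    propensity vanishes before ``t_max`` the state is held constant and
    ``meta['exhausted']`` is set.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if seed < 0:
        raise ValueError("seed must be non-negative")
    n_rec = int(round(t_max / record_dt))
    times = np.linspace(0.0, t_max, n_rec + 1)
    if engine == "compiled":
        pr, om = network.params, network.volume.omega
        rates = np.array(
            [
                pr.sigma * om,
                pr.alpha,
                pr.k_f / om,
                pr.k_b,
                pr.delta,
                pr.gamma,
                pr.k_t / om,
                pr.beta,
                pr.k_tl,
            ]
        )
        counts, exhausted = _ssa_core(
            rates,
            network.variant == "release",
            init.as_array(),
            times,
            np.uint32(seed % 2**31),
        )
    elif engine == "python":
        counts, exhausted = _ssa_python(
            network, init, times, np.random.default_rng(seed)
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return Trajectory(
        times=times,
        states=counts.astype(float),
        meta={
            "omega": network.volume.omega,
            "seed": int(seed),
            "exhausted": bool(exhausted),
            "units": "molecules",
        },
    )


def smooth_counts(series: np.ndarray, dt: float, window_h: float = SMOOTH_WINDOW_H) -> np.ndarray:
    """Centered moving average used before peak detection on counts;
    shot noise otherwise produces spurious one-step maxima."""
    w = max(int(round(window_h / dt)), 1)
    if w <= 1:
        return np.asarray(series, dtype=float)
    kernel = np.ones(w) / w
    pad = w // 2
    padded = np.pad(np.asarray(series, dtype=float), pad, mode="edge")
    return np.convolve(padded, kernel, mode="same")[pad : pad + len(series)]


@dataclass(frozen=True)
class PeakTimeStats:
    """Per-peak-index timing statistics across an SSA ensemble."""

    mean_times: tuple[float, ...]
    sd_times: tuple[float, ...]
    n_runs: int
    n_excluded: int
    peak_times: tuple[tuple[float, ...], ...] = field(repr=False, default=())


def peak_time_variability(
    params: ModelParameters,
    scenario: "StressScenario",
    n_runs: int,
    vol: VolumeContext,
    seed: int,
    *,
    t_max: float = 16.0,
    n_peaks: int = 3,
    record_dt: float = 0.01,
) -> PeakTimeStats:
    """Timing statistics of the first ``n_peaks`` free-p53 peaks across runs.

    Each run starts from the resting-state copy numbers of ``params``
    with the stress applied at t=0.  Peaks are detected on smoothed
    count trajectories with the shared detector contract.  Runs with
    fewer than ``n_peaks`` detectable peaks are counted and excluded.
    """
    from .stress import apply as apply_scenario

    if n_runs < 2:
        raise ValueError("n_runs must be at least 2")
    rest_counts = vol.to_counts(resting_state(params))
    network = build_reactions(apply_scenario(scenario, params), vol)
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % np.uint32(2**31)

    per_run: list[tuple[float, ...]] = []
    n_excluded = 0
    for s in run_seeds:
        traj = ssa_run(network, rest_counts, t_max, int(s), record_dt=record_dt)
        smoothed = smooth_counts(traj.p, record_dt)
        peaks = detect_peaks(
            traj.times,
            smoothed,
            min_separation=ENSEMBLE_MIN_SEPARATION_H,
            prominence_fraction=ENSEMBLE_PROMINENCE_FRACTION,
        )
        if len(peaks) < n_peaks:
            n_excluded += 1
            continue
        per_run.append(tuple(t for t, _ in peaks[:n_peaks]))

    if len(per_run) < 2:
        raise RuntimeError(
            f"only {len(per_run)} of {n_runs} runs had {n_peaks} peaks; "
            "cannot form statistics"
        )
    arr = np.array(per_run)
    return PeakTimeStats(
        mean_times=tuple(arr.mean(axis=0)),
        sd_times=tuple(arr.std(axis=0, ddof=1)),
        n_runs=n_runs,
        n_excluded=n_excluded,
        peak_times=tuple(map(tuple, arr)),
    )
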