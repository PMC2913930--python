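"""Stochastic layer: volume scaling, channels and the direct method."""

import numpy as np
import pytest

from p53loop.dynamics import resting_state
from p53loop.gillespie import (
    ReactionChannel,
    ReactionNetwork,
    StochasticState,
    VolumeContext,
    build_reactions,
    peak_time_variability,
    smooth_counts,
    ssa_run,
)
from p53loop.model import rhs
from p53loop.params import ModelParameters


@pytest.fixture(scope="module")
def ref_volume():
    return VolumeContext.reference()


class TestVolumeContext:
    def test_reference_sphere_conversion(self, ref_volume):
        # sphere of radius 6 um: 100 nM ~ 5.45e4 molecules
        assert ref_volume.omega == pytest.approx(544.87, rel=1e-3)
        assert 100.0 * ref_volume.omega == pytest.approx(50_000.0, rel=0.15)

    def test_volume_reduction_scales_counts(self):
        small = VolumeContext.reference(500.0)
        assert small.omega == pytest.approx(VolumeContext.reference().omega / 500.0)

    def test_count_rounding(self, ref_volume):
        counts = ref_volume.to_counts(np.array([1.0, 0.0, 0.0, 0.0]))
        assert counts.n_p == round(ref_volume.omega)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            VolumeContext(volume=0.0)
        with pytest.raises(ValueError):
            VolumeContext.reference(-1.0)


class TestChannels:
    def test_ten_channels_with_integer_stoichiometry(self, defaults, ref_volume):
        net = build_reactions(defaults, ref_volume)
        assert len(net) == 10
        stoich = net.stoichiometry_matrix()
        assert stoich.dtype == np.int64
        assert set(np.abs(stoich).sum(axis=1)) <= {1, 2, 3}

    def test_empty_state_only_production_fires(self, defaults, ref_volume):
        net = build_reactions(defaults, ref_volume)
        a = net.propensities(StochasticState(0, 0, 0, 0))
        assert a[0] == pytest.approx(defaults.sigma * ref_volume.omega)
        assert np.all(a[1:] == 0.0)

    def test_single_p53_cannot_transcribe(self, defaults, ref_volume):
        # Hill-2 activation is pair occupancy: n_p*(n_p-1) vanishes at 1
        net = build_reactions(defaults, ref_volume)
        a = net.propensities(StochasticState(1, 0, 0, 0))
        transcription = next(i for i, ch in enumerate(net) if ch.label == "transcription")
        assert a[transcription] == 0.0

    def test_mean_field_limit_reproduces_rhs(self, defaults, ref_volume, rest):
        # propensity drift divided by omega equals the deterministic rates
        # up to the O(1/omega) combinatorial correction
        net = build_reactions(defaults, ref_volume)
        counts = rest.as_array() * ref_volume.omega  # keep fractional: exact
        channel_rates = np.array([ch.propensity(counts) for ch in net.channels])
        drift = net.stoichiometry_matrix().T @ channel_rates / ref_volume.omega
        expected = rhs(rest, defaults)
        correction = defaults.k_t * rest.p / ref_volume.omega  # n_p(n_p-1) vs p^2
        assert drift[0] == pytest.approx(expected[0], abs=1e-9)
        assert drift[1] == pytest.approx(expected[1] - correction, abs=1e-9)
        assert drift[2:] == pytest.approx(expected[2:], abs=1e-9)

    def test_codegradation_variant_changes_gamma_stoichiometry(self, defaults, ref_volume):
        rel = build_reactions(defaults, ref_volume, variant="release")
        cod = build_reactions(defaults, ref_volume, variant="codegradation")
        idx = next(
            i for i, ch in enumerate(rel) if ch.label == "mdm2_degradation_in_complex"
        )
        assert rel[idx].stoichiometry == (1, 0, 0, -1)
        assert cod[idx].stoichiometry == (0, 0, 0, -1)


class TestSsaRun:
    def test_no_production_from_empty_state_stays_empty(self, defaults, ref_volume):
        net = build_reactions(defaults.with_updates(sigma=0.0), ref_volume)
        traj = ssa_run(net, StochasticState(0, 0, 0, 0), 5.0, seed=1)
        assert np.all(traj.states == 0)
        assert traj.meta["exhausted"]

    def test_identical_seed_identical_trajectory(self, defaults):
        vol = VolumeContext.reference(500.0)
        net = build_reactions(defaults, vol)
        init = vol.to_counts(resting_state(defaults))
        a = ssa_run(net, init, 2.0, seed=123)
        b = ssa_run(net, init, 2.0, seed=123)
        assert np.array_equal(a.states, b.states)
        assert not np.array_equal(a.states, ssa_run(net, init, 2.0, seed=124).states)

    def test_production_only_counting_process_is_poisson(self, defaults):
        # a bare birth process: mean count at t equals rate * t; checked
        # against the closed form within 3 standard errors over 200 seeds
        rate = 25.0  # events per hour
        vol = VolumeContext(volume=1.0)
        channel = ReactionChannel("birth", (1, 0, 0, 0), lambda n: rate)
        net = ReactionNetwork(
            channels=(channel,), params=defaults, volume=vol, variant="release"
        )
        t = 2.0
        finals = [
            ssa_run(net, StochasticState(0, 0, 0, 0), t, seed=s, engine="python").p[-1]
            for s in range(200)
        ]
        expected = rate * t
        se = np.sqrt(expected / 200)
        assert abs(np.mean(finals) - expected) < 3 * se

    def test_compiled_and_python_engines_agree_in_distribution(self):
        # slowed-down rate constants keep the event count tiny so the
        # generic python direct method can serve as the oracle
        slow = ModelParameters(
            sigma=20.0, alpha=0.1, delta=1.0, k_t=0.003, k_tl=1.4,
            beta=0.6, gamma=0.2, k_b=7.2, k_f=5.0,
        )
        vol = VolumeContext(volume=1.0 / (6.02214076e23 * 1e-9))  # omega = 1
        net = build_reactions(slow, vol)
        init = StochasticState(10, 2, 3, 1)
        n_seeds = 150
        finals = {
            engine: np.array(
                [
                    ssa_run(net, init, 4.0, seed=s, engine=engine, record_dt=0.5).states[-1]
                    for s in range(n_seeds)
                ]
            )
            for engine in ("compiled", "python")
        }
        mean_c = finals["compiled"].mean(axis=0)
        mean_p = finals["python"].mean(axis=0)
        pooled_se = np.sqrt(
            (finals["compiled"].var(axis=0) + finals["python"].var(axis=0)) / n_seeds
        )
        assert np.all(np.abs(mean_c - mean_p) < 4 * np.maximum(pooled_se, 1e-9))

    def test_validation(self, defaults, ref_volume):
        net = build_reactions(defaults, ref_volume)
        with pytest.raises(ValueError):
            ssa_run(net, StochasticState(0, 0, 0, 0), -1.0, seed=1)
        with pytest.raises(ValueError):
            StochasticState(-1, 0, 0, 0)


class TestSmoothing:
    def test_moving_average_preserves_mean_and_reduces_variance(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(20, size=2000).astype(float)
        sm = smooth_counts(x, dt=0.01, window_h=0.5)
        assert sm.mean() == pytest.approx(x.mean(), rel=1e-2)
        assert sm.var() < 0.1 * x.var()
        assert len(sm) == len(x)


class TestPeakTimeVariability:
    def test_later_peaks_vary_more_at_reduced_volume(self, defaults, dna_damage):
        stats = peak_time_variability(
            defaults, dna_damage, n_runs=30, vol=VolumeContext.reference(500.0), seed=11
        )
        assert stats.sd_times[2] > stats.sd_times[0]
        # mean schedule still resembles the deterministic one
        assert stats.mean_times[0] == pytest.approx(0.5, abs=0.4)
        assert 4.0 < stats.mean_times[1] < 8.0

    def test_noise_grows_as_volume_shrinks(self, defaults, dna_damage):
        sds = {}
        for scale, n_runs in ((100.0, 12), (500.0, 12)):
            stats = peak_time_variability(
                defaults,
                dna_damage,
                n_runs=n_runs,
                vol=VolumeContext.reference(scale),
                seed=5,
                t_max=12.0,
                n_peaks=2,
            )
            sds[scale] = stats.sd_times[1]
        assert sds[500.0] >= sds[100.0]

    def test_statistics_are_reproducible_per_seed(self, defaults, dna_damage):
        kwargs = dict(
            n_runs=5, vol=VolumeContext.reference(500.0), seed=3, t_max=8.0, n_peaks=2
        )
        a = peak_time_variability(defaults, dna_damage, **kwargs)
        b = peak_time_variability(defaults, dna_damage, **kwargs)
        assert a.mean_times == b.mean_times
        assert a.sd_times == b.sd_times
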