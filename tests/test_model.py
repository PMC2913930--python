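"""Core model: parameter defaults, rates, Jacobian and equilibria."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from p53loop.model import (
    NoEquilibriumError,
    SystemState,
    jacobian,
    rhs,
    steady_states,
)
from p53loop.params import ModelParameters, default_parameters


class TestParameters:
    def test_default_rate_constants(self):
        pr = default_parameters()
        assert pr.sigma == 1000.0
        assert pr.alpha == 0.1
        assert pr.delta == 11.0
        assert pr.k_t == 0.03
        assert pr.k_tl == 1.4
        assert pr.beta == 0.6
        assert pr.gamma == 0.2
        assert pr.k_b == 7200.0
        assert pr.k_D == pytest.approx(1.44)
        # k_f forced by k_D = k_b / k_f
        assert pr.k_f == pytest.approx(7200.0 / 1.44) == 5000.0
        assert pr.hill == 2.0

    @pytest.mark.parametrize("field", ["alpha", "delta", "k_t", "gamma", "k_b", "k_f"])
    def test_nonpositive_rates_rejected(self, field):
        with pytest.raises(ValueError, match=field):
            default_parameters().with_updates(**{field: 0.0})

    def test_sigma_zero_allowed_but_not_negative(self):
        assert default_parameters().with_updates(sigma=0.0).sigma == 0.0
        with pytest.raises(ValueError):
            default_parameters().with_updates(sigma=-1.0)

    @given(k_D=st.floats(0.01, 100.0))
    def test_k_D_consistent_under_any_update_path(self, k_D):
        via_kd = default_parameters().with_updates(k_D=k_D)
        via_kf = default_parameters().with_updates(k_f=7200.0 / k_D)
        assert via_kd.k_f == pytest.approx(via_kf.k_f, rel=1e-12)
        assert via_kd.k_D == pytest.approx(k_D, rel=1e-12)

    def test_setting_both_kf_and_kd_rejected(self):
        with pytest.raises(ValueError):
            default_parameters().with_updates(k_f=1.0, k_D=1.0)


class TestRhs:
    def test_origin_only_production_survives(self, defaults):
        assert rhs([0, 0, 0, 0], defaults) == pytest.approx([1000.0, 0.0, 0.0, 0.0])

    def test_single_transcription_term(self, defaults):
        # only p present: dm_m/dt = k_t * p**2 = 0.03 * 100
        rates = rhs([10.0, 0.0, 0.0, 0.0], defaults)
        assert rates[1] == pytest.approx(3.0)

    def test_rejects_negative_and_nonfinite_states(self, defaults):
        with pytest.raises(ValueError):
            rhs([-1.0, 0, 0, 0], defaults)
        with pytest.raises(ValueError):
            rhs([np.nan, 0, 0, 0], defaults)
        with pytest.raises(ValueError):
            SystemState(1.0, 1.0, -0.5, 0.0)

    def test_vanishes_at_resting_equilibrium(self, defaults, rest):
        assert np.max(np.abs(rhs(rest, defaults))) < 1e-6

    @given(
        zero_axis=st.integers(0, 3),
        values=st.lists(st.floats(0.0, 1e3), min_size=4, max_size=4),
    )
    def test_boundary_of_positive_orthant_never_exits(self, defaults, zero_axis, values):
        # whenever a component is zero its rate must be non-negative
        state = np.array(values)
        state[zero_axis] = 0.0
        assert rhs(state, defaults)[zero_axis] >= 0.0

    def test_mass_bookkeeping_of_complex_degradation(self, defaults):
        # from a pure-complex state: delta removes p53 and returns Mdm2,
        # gamma removes Mdm2 and returns p53 (release convention)
        c0 = 5.0
        dp, _, dm, dc = rhs([0.0, 0.0, 0.0, c0], defaults)
        assert dp == pytest.approx(defaults.sigma + (defaults.k_b + defaults.gamma) * c0)
        assert dm == pytest.approx((defaults.k_b + defaults.delta) * c0)
        assert dc == pytest.approx(-(defaults.k_b + defaults.delta + defaults.gamma) * c0)

    def test_codegradation_variant_keeps_complex_p53(self, defaults):
        dp_rel = rhs([0.0, 0.0, 0.0, 5.0], defaults, variant="release")[0]
        dp_cod = rhs([0.0, 0.0, 0.0, 5.0], defaults, variant="codegradation")[0]
        assert dp_rel - dp_cod == pytest.approx(defaults.gamma * 5.0)


class TestJacobian:
    def test_matches_central_finite_differences(self, defaults, rest):
        x0 = rest.as_array()
        J = jacobian(x0, defaults)
        eps = 1e-6
        J_fd = np.empty_like(J)
        for j in range(4):
            dx = np.zeros(4)
            dx[j] = eps * max(x0[j], 1.0)
            J_fd[:, j] = (rhs(x0 + dx, defaults) - rhs(np.clip(x0 - dx, 0, None), defaults)) / (
                2 * dx[j]
            )
        assert np.max(np.abs(J - J_fd) / np.maximum(np.abs(J_fd), 1.0)) < 1e-4

    def test_transcription_derivative_vanishes_at_origin(self, defaults):
        assert jacobian([0, 0, 0, 0], defaults)[1, 0] == 0.0
        assert jacobian([10, 0, 0, 0], defaults)[1, 0] == pytest.approx(2 * 0.03 * 10)

    def test_complex_self_decay_entry(self, defaults):
        J = jacobian([1.0, 1.0, 1.0, 1.0], defaults)
        assert J[3, 3] == pytest.approx(-(7200.0 + 11.0 + 0.2)) == -7211.2


class TestSteadyStates:
    def test_resting_equilibrium_total_p53_near_100nM(self, defaults):
        (eq,) = steady_states(defaults)
        assert eq.stable
        assert eq.state.total_p53 == pytest.approx(100.0, rel=0.15)
        # values frozen from the bracketed-bisection oracle on the reduced
        # scalar equilibrium equation
        assert eq.state.p == pytest.approx(16.78066, rel=1e-4)
        assert eq.state.c == pytest.approx(90.75654, rel=1e-4)

    def test_equilibrium_identities(self, defaults):
        for params in (
            defaults,
            defaults.with_updates(sigma=300.0),
            defaults.with_updates(delta=3.0),
            defaults.with_updates(k_t=0.1),
        ):
            (eq,) = steady_states(params)
            s = eq.state
            lhs = s.m + s.c
            expected = params.k_tl * params.k_t / (params.gamma * params.beta) * s.p**2
            assert lhs == pytest.approx(expected, rel=1e-8)
            assert params.sigma == pytest.approx(
                params.alpha * s.p + params.delta * s.c, rel=1e-8
            )

    def test_no_production_gives_stable_origin(self, defaults):
        (eq,) = steady_states(defaults.with_updates(sigma=0.0))
        assert eq.state.as_array() == pytest.approx(np.zeros(4))
        assert eq.stable

    def test_gamma_doubling_destabilizes_with_complex_pair(self, defaults):
        (eq,) = steady_states(defaults.with_updates(gamma=0.4))
        assert not eq.stable
        lead = eq.leading_eigenvalues[0]
        assert lead.real > 0
        assert abs(lead.imag) > 0  # oscillation onset, not a saddle

    @pytest.mark.parametrize(
        "name,increasing", [("sigma", True), ("delta", False), ("k_t", False)]
    )
    def test_equilibrium_total_p53_monotone(self, defaults, name, increasing):
        folds = np.geomspace(1 / 5, 5, 7)
        base = getattr(defaults, name)
        totals = [
            steady_states(defaults.with_updates(**{name: base * f}))[0].state.total_p53
            for f in folds
        ]
        diffs = np.diff(totals)
        assert np.all(diffs > 0) if increasing else np.all(diffs < 0)

    def test_empty_bracket_raises_explicitly(self, defaults):
        with pytest.raises(NoEquilibriumError, match="no equilibrium"):
            steady_states(defaults, bracket=(1e-6, 1e-5))
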