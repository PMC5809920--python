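"""Analytic dimensionless diffusion solution: values, limits, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfc

from papdiff import (
    CANONICAL_TAUS,
    InvalidParameterError,
    phi,
    phi_series,
    phi_smalltau,
    profile,
    steady_state_tau,
    tau_to_time,
    time_to_tau,
)
from papdiff.diffusion import TAU_SWITCH


class TestPointValues:
    @pytest.mark.parametrize("tau", [0.05, 0.1, 0.5, 1.5])
    def test_source_face_is_pinned_at_one(self, tau):
        assert phi_series(tau, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_far_end_early_and_late(self):
        # frozen from two independent oracles (fine finite differences and
        # direct >=50-term summation)
        assert phi_series(0.1, 1.0) == pytest.approx(0.0507, abs=2e-4)
        assert phi_series(1.5, 1.0) == pytest.approx(0.9686, abs=2e-4)

    def test_smalltau_matches_similarity_solution(self):
        # erfc form at tau = 0.005: standard-function oracle
        assert phi_smalltau(0.005, 0.0) == pytest.approx(1.0)
        assert phi_smalltau(0.005, 0.1) == pytest.approx(erfc(0.1 / (2 * math.sqrt(0.005))), abs=1e-12)
        assert phi_smalltau(0.005, 0.1) == pytest.approx(0.317, abs=5e-4)
        assert phi_smalltau(0.005, 0.2) == pytest.approx(0.0455, abs=5e-4)
        assert phi_smalltau(0.005, 1.0) < 1e-10  # the far end is unreached

    def test_series_and_similarity_agree_at_the_switch(self):
        eta = np.linspace(0, 1, 101)
        gap = np.abs(phi_series(TAU_SWITCH, eta) - phi_smalltau(TAU_SWITCH, eta))
        assert gap.max() < 1e-6

    @pytest.mark.parametrize(
        "func,kwargs",
        [
            (phi_series, {"tau": -0.1, "eta": 0.5}),
            (phi_series, {"tau": 0.1, "eta": 0.5, "tol": 0.0}),
            (phi_series, {"tau": 0.1, "eta": 1.5}),
            (phi_smalltau, {"tau": 0.0, "eta": 0.5}),
        ],
    )
    def test_domain_errors(self, func, kwargs):
        with pytest.raises(InvalidParameterError):
            func(**kwargs)


class TestProfile:
    def test_initial_condition(self):
        prof = profile(0.0, 11)
        assert prof.phi[0] == 1.0
        assert np.all(prof.phi[1:] == 0.0)

    def test_monotone_decreasing_in_eta(self):
        prof = profile(0.1, 11)
        assert np.all(np.diff(prof.phi) <= 1e-12)
        assert prof.phi[0] == pytest.approx(1.0)
        assert prof.phi[-1] == pytest.approx(0.0507, abs=2e-4)

    def test_near_steady_state_profile_is_flat(self):
        prof = profile(1.5, 11)
        assert np.all(prof.phi >= 0.968)

    def test_no_flux_at_the_accumulating_face(self):
        # one-sided difference at eta = 1 vanishes once the front has arrived
        for tau in (0.05, 0.1, 0.3, 0.8, 1.5):
            d = 1e-4
            grad = (phi(tau, 1.0) - phi(tau, 1.0 - d)) / d
            assert abs(grad) < 1e-3

    def test_grid_size_validation(self):
        with pytest.raises(InvalidParameterError):
            profile(0.1, 1)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        tau=st.floats(min_value=1e-3, max_value=3.0),
        eta=st.floats(min_value=0.0, max_value=1.0),
        bump=st.floats(min_value=1e-3, max_value=1.0),
    )
    def test_monotone_in_tau_and_bounded(self, tau, eta, bump):
        lo, hi = phi(tau, eta), phi(tau + bump, eta)
        assert 0.0 <= lo <= 1.0
        assert hi >= lo - 1e-9


class TestTimeMapping:
    @pytest.mark.parametrize(
        "tau,expected_s",
        [
            (0.005, 16.7e-6),
            (0.1, 333e-6),
            (0.3, 1e-3),
            (0.8, 2.667e-3),
            (1.5, 5e-3),
        ],
    )
    def test_reference_time_list(self, tau, expected_s):
        assert tau_to_time(tau) == pytest.approx(expected_s, rel=2e-3)

    def test_slow_diffusion_coefficient(self):
        # Dab = 10 um^2/s stretches tau = 1.5 to 150 ms, still below the
        # 0.8 s degradation horizon
        assert tau_to_time(1.5, dab_um2_s=10.0) == pytest.approx(0.150, rel=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(tau=st.floats(min_value=1e-6, max_value=1e3))
    def test_round_trip(self, tau):
        assert time_to_tau(tau_to_time(tau)) == pytest.approx(tau, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            tau_to_time(0.0)
        with pytest.raises(InvalidParameterError):
            time_to_tau(1e-3, dab_um2_s=-1)


class TestSteadyState:
    def test_five_percent_deficit_is_near_tau_1p3(self):
        # leading-term closed form (4/pi^2) ln(4/(pi eps)) as oracle
        tau = steady_state_tau(0.05)
        closed = (4 / math.pi**2) * math.log(4 / (math.pi * 0.05))
        assert tau == pytest.approx(closed, abs=5e-3)
        assert 1.3 <= tau <= 1.4  # so tau = 1.5 qualifies as steady state

    def test_achieves_the_requested_deficit(self):
        tau = steady_state_tau(0.02)
        assert 1.0 - phi(tau, 1.0) == pytest.approx(0.02, abs=1e-8)

    def test_monotone_decreasing_in_epsilon(self):
        taus = [steady_state_tau(e) for e in (0.01, 0.05, 0.2, 0.9)]
        assert taus == sorted(taus, reverse=True)

    @pytest.mark.parametrize("eps", [0.0, 1.0, -0.5])
    def test_epsilon_domain(self, eps):
        with pytest.raises(InvalidParameterError):
            steady_state_tau(eps)
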