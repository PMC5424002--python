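"""NiAc disposition: pump input, baselines, Michaelis-Menten balances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from niacffa import (
    baseline_concentration,
    default_pk_parameters,
    plateau_concentration,
    pump_rate,
    simulate_pk,
)
from niacffa.parameters import PKParameters, replace_fields
from niacffa.pk import pk_initial_state, pk_rhs, rate_for_plateau
from niacffa.protocols import DosingProtocol, build_protocol, constant_iv, zero_protocol
from niacffa.simulate import Trajectory


def erf_series(x, terms=80):
    """Independent error-function oracle: Maclaurin series."""
    total = 0.0
    for n in range(terms):
        total += (-1) ** n * x ** (2 * n + 1) / (math.factorial(n) * (2 * n + 1))
    return 2.0 / math.sqrt(math.pi) * total


class TestPumpRate:
    def test_zero_at_activation(self):
        assert pump_rate(0.0, 10.2, 77.4) == 0.0

    def test_limit_is_programmed_rate(self):
        assert pump_rate(1e6, 10.2, 77.4) == pytest.approx(10.2, rel=1e-12)

    def test_against_series_oracle(self):
        # 10.2 * erf(0.1*77.4/sqrt(168)) with erf from an independent series
        x = 0.1 * 77.4 / math.sqrt(168.0)
        expected = 10.2 * erf_series(x)
        assert expected == pytest.approx(6.136440, abs=1e-5)
        assert pump_rate(0.1, 10.2, 77.4, 168.0) == pytest.approx(expected, rel=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            pump_rate(-0.1, 10.2, 77.4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.0, 50.0), st.floats(0.0, 50.0))
    def test_monotone_and_bounded(self, t1, t2):
        lo, hi = sorted((t1, t2))
        r_lo = pump_rate(lo, 10.2, 62.4)
        r_hi = pump_rate(hi, 10.2, 62.4)
        assert 0.0 <= r_lo <= r_hi <= 10.2


class TestBaseline:
    def test_obese_closed_form(self, obese_params):
        pk, _, _ = obese_params
        # single-pathway inversion: Cp0 = Synt*Km1/(Vmax1 - Synt)
        expected = 0.168 * 18.9 / (164.0 - 0.168)
        assert baseline_concentration(pk) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.019381, abs=1e-6)

    def test_lean_against_bisection_oracle(self, lean_params):
        pk, _, _ = lean_params

        def balance(c):
            return 2.64 * c / (0.235 + c) + 425.0 * c / (74.5 + c) - 0.213

        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if balance(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert baseline_concentration(pk) == pytest.approx(lo, abs=1e-12)
        assert baseline_concentration(pk) == pytest.approx(0.0130294, abs=1e-6)

    def test_zero_synthesis_gives_zero(self, obese_params):
        pk, _, _ = obese_params
        pk0 = replace_fields(pk, Synt=1e-300)
        assert baseline_concentration(pk0) < 1e-290

    def test_excess_synthesis_rejected(self, obese_params):
        pk, _, _ = obese_params
        with pytest.raises(ValueError):
            baseline_concentration(replace_fields(pk, Synt=200.0))


class TestRHS:
    def test_baseline_is_stationary(self, lean_params):
        pk, _, _ = lean_params
        state = pk_initial_state(pk)
        dydt = pk_rhs(0.0, state, pk, zero_protocol())
        assert np.allclose(dydt, 0.0, atol=1e-14)

    def test_obese_elimination_at_1uM(self, obese_params):
        pk, _, _ = obese_params
        expected = (0.168 - 164.0 * 1.0 / (18.9 + 1.0)) / 0.323  # scalar arithmetic
        state = np.array([0.0, 1.0])
        dydt = pk_rhs(0.0, state, pk, zero_protocol())
        assert dydt[1] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-24.99, abs=0.01)

    def test_lean_elimination_vanishes_at_zero(self, lean_params):
        pk, _, _ = lean_params
        state = np.array([0.0, 0.0, 0.5])
        dydt = pk_rhs(0.0, state, pk, zero_protocol())
        assert dydt[1] == pytest.approx((0.213 + 0.0511 * 0.5) / 0.393, rel=1e-12)


class TestSimulatePK:
    def test_zero_rate_constant_baseline(self, obese_params):
        pk, _, _ = obese_params
        traj = simulate_pk(zero_protocol(24.0), pk, t_grid=np.linspace(0, 24, 9))
        Cp0 = baseline_concentration(pk)
        assert np.allclose(traj["Cp"], Cp0, rtol=1e-9)

    def test_constant_iv_plateau_matches_mm_balance(self, obese_params):
        pk, _, _ = obese_params
        traj = simulate_pk(constant_iv(10.2, 48.0), pk, t_grid=np.array([0.0, 48.0]))
        expected = 18.9 * (10.2 + 0.168) / (164.0 - 10.2 - 0.168)  # algebraic oracle
        assert expected == pytest.approx(1.2755, abs=1e-3)
        assert traj["Cp"][-1] == pytest.approx(expected, rel=1e-3)
        assert plateau_concentration(pk, 10.2) == pytest.approx(expected, rel=1e-12)

    def test_rate_for_plateau_roundtrip(self, obese_params):
        pk, _, _ = obese_params
        rate = rate_for_plateau(pk, 1.0)
        assert plateau_concentration(pk, rate) == pytest.approx(1.0, rel=1e-10)

    def test_sc_mass_balance(self, obese_params):
        """Drug absorbed from the depot equals drug pumped minus what remains."""
        from niacffa.dosing import _integral

        pk, _, _ = obese_params
        prot = build_protocol("Off_12h")
        traj = simulate_pk(prot, pk)
        from scipy.integrate import quad

        pumped, _ = quad(lambda t: pump_rate(t, 10.2, pk.delta, pk.t0), 0.0, 12.0,
                         epsabs=1e-12, epsrel=1e-10)
        absorbed = pk.ka * _integral(traj, "Asc", 0.0, prot.end)
        asc_left = traj["Asc"][-1]
        assert absorbed == pytest.approx(pumped - asc_left, rel=1e-6)

    def test_instant_start_limit(self, obese_params):
        """A long-activated pump behaves like one with no start-up dilution."""
        pk, _, _ = obese_params
        fast_pump = replace_fields(pk, delta=1e9)
        prot = build_protocol("NiAc_Naive")
        prot_old = DosingProtocol(route="sc_pump", segments=prot.segments,
                                  pump_first_activation=-1e5,
                                  acute_window=prot.acute_window)
        grid = np.linspace(0.2, 5.0, 25)
        a = simulate_pk(prot, fast_pump, t_grid=grid)
        b = simulate_pk(prot_old, pk, t_grid=grid)
        assert np.allclose(a["Cp"], b["Cp"], rtol=1e-6)

    def test_lean_reduces_to_obese_structure(self):
        """The two-compartment model collapses onto the one-compartment one."""
        lean_like = PKParameters(species="lean", Vp=0.323, Vt=0.172, Cld=1e-12,
                                 Vmax1=164.0, Km1=18.9, Vmax2=1e-12, Km2=74.5,
                                 Synt=0.168, ka=5.54, delta=62.4)
        obese = default_pk_parameters("obese")
        grid = np.linspace(0.0, 6.0, 30)
        prot = build_protocol("Off_1h")
        a = simulate_pk(prot, lean_like, t_grid=grid)
        b = simulate_pk(prot, obese, t_grid=grid)
        assert np.allclose(a["Cp"], b["Cp"], rtol=1e-7, atol=1e-12)

    def test_washout_returns_to_baseline(self, obese_params):
        pk, _, _ = obese_params
        prot = constant_iv(10.2, 1.0, window=10.0)
        traj = simulate_pk(prot, pk, t_grid=np.array([0.0, 10.0]))
        Cp0 = baseline_concentration(pk)
        assert traj["Cp"][-1] == pytest.approx(Cp0, rel=1e-3)

    def test_cp_nonnegative(self, lean_params):
        pk, _, _ = lean_params
        traj = simulate_pk(build_protocol("StpDwn_12h"), pk,
                           t_grid=np.linspace(0, 17, 100))
        assert np.all(traj["Cp"] >= 0)
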