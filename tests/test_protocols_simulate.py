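"""Protocol encodings, coupled integration, periodic steady states."""

import numpy as np
import pytest

from niacffa import build_protocol, periodic_steady_state, simulate_individual
from niacffa.parameters import replace_fields
from niacffa.pk import baseline_concentration, rate_for_plateau
from niacffa.protocols import (
    BASE_RATE,
    DosingProtocol,
    STEP_DOWN_12H,
    STEP_DOWN_1H,
    constant_iv,
    zero_protocol,
)


class TestBuildProtocol:
    def test_off_1h(self):
        prot = build_protocol("Off_1h")
        assert prot.route == "iv"
        assert prot.segments == ((0.0, 1.0, 10.2),)

    def test_base_rate_unit_conversion(self):
        assert BASE_RATE == pytest.approx(10.2)  # 170 nmol/min/kg

    def test_stepdown_1h_ladder(self):
        prot = build_protocol("StpDwn_1h")
        assert len(prot.segments) == 8
        assert prot.segments[-1][1] == pytest.approx(4.5)  # final switch-off
        rates = [s[2] for s in prot.segments[1:]]
        assert rates == pytest.approx([r * 0.06 for r in STEP_DOWN_1H])
        durations = [s[1] - s[0] for s in prot.segments[1:]]
        assert durations == pytest.approx([0.5] * 7)

    def test_stepdown_12h_ladder(self):
        prot = build_protocol("StpDwn_12h")
        assert prot.segments[0] == (0.0, 12.0, 10.2)
        assert prot.segments[-1][1] == pytest.approx(15.5)
        assert [s[2] for s in prot.segments[1:]] == pytest.approx(
            [r * 0.06 for r in STEP_DOWN_12H])

    def test_pretreated_groups_carry_history(self):
        cont = build_protocol("Cont_NiAc")
        assert cont.pretreatment_duration == 120.0
        assert cont.segments[0][0] == -120.0
        inter = build_protocol("Inter_NiAc")
        on_time = sum(e - s for s, e, _ in inter.segments)
        assert on_time == pytest.approx(5 * 12 + 5)  # five 12 h cycles + acute phase

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            build_protocol("foo")

    def test_yaml_round_trip(self, tmp_path):
        prot = build_protocol("StpDwn_12h")
        path = tmp_path / "prot.yaml"
        prot.to_yaml(path)
        back = DosingProtocol.from_yaml(path)
        assert back == prot

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            DosingProtocol(route="iv", segments=((0, 2, 1.0), (1, 3, 1.0)))


class TestSimulateIndividual:
    def test_zero_protocol_flat(self, lean_params):
        pk, ins, ffa = lean_params
        traj = simulate_individual(zero_protocol(24.0), pk, ins, ffa,
                                   t_grid=np.linspace(0, 24, 10))
        Cp0 = baseline_concentration(pk)
        assert np.allclose(traj["Cp"], Cp0, rtol=1e-8)
        assert np.allclose(traj["I"], ins.I0, rtol=1e-8)
        assert np.allclose(traj["F"], ffa.F0, rtol=1e-8)

    def test_sequential_matches_coupled(self, obese_params):
        pk, ins, ffa = obese_params
        grid = np.linspace(0.25, 17.0, 60)
        prot = build_protocol("Off_12h")
        a = simulate_individual(prot, pk, ins, ffa, t_grid=grid, mode="coupled")
        b = simulate_individual(prot, pk, ins, ffa, t_grid=grid, mode="sequential")
        for col in ("Cp", "I", "F"):
            rel = np.abs(a[col] - b[col]) / np.maximum(np.abs(a[col]), 1e-9)
            assert rel.max() < 1e-3  # well under the 0.1 % contract

    def test_sequential_matches_coupled_lean(self, lean_params):
        pk, ins, ffa = lean_params
        grid = np.linspace(0.25, 6.0, 30)
        prot = build_protocol("Off_1h")
        a = simulate_individual(prot, pk, ins, ffa, t_grid=grid, mode="coupled")
        b = simulate_individual(prot, pk, ins, ffa, t_grid=grid, mode="sequential")
        for col in ("Cp", "I", "F"):
            rel = np.abs(a[col] - b[col]) / np.maximum(np.abs(a[col]), 1e-9)
            assert rel.max() < 1e-3

    def test_cont_pretreatment_reaches_adaptation(self, obese_params):
        """After 5 days of continuous dosing, FFA has fully adapted."""
        pk, ins, ffa = obese_params
        traj = simulate_individual(build_protocol("Cont_NiAc"), pk, ins, ffa,
                                   t_grid=np.array([0.0]), with_actions=False)
        assert traj["F"][-1] == pytest.approx(ffa.F0, rel=0.05)

    def test_species_mismatch_rejected(self, lean_params, obese_params):
        pk, ins, _ = lean_params
        _, _, ffa_o = obese_params
        with pytest.raises(ValueError):
            simulate_individual(zero_protocol(), pk, ins, ffa_o)


class TestPeriodicSteadyState:
    def test_zero_dose_converges_immediately(self, obese_params):
        pk, ins, ffa = obese_params
        cycle = DosingProtocol(route="iv", segments=(), acute_window=(0.0, 24.0))
        traj, n = periodic_steady_state(cycle, pk, ins, ffa)
        assert n == 1
        assert traj["F"][-1] == pytest.approx(ffa.F0, rel=1e-8)

    def test_constant_cycle_insulin_at_set_point(self, obese_params):
        pk, ins, ffa = obese_params
        rate = rate_for_plateau(pk, 1.0)
        cycle = DosingProtocol(route="iv", segments=((0.0, 24.0, rate),),
                               acute_window=(0.0, 24.0))
        traj, n = periodic_steady_state(cycle, pk, ins, ffa, insulin="dynamic",
                                        max_cycles=100)
        assert abs(traj["I"][-1] / ins.I0 - 1) < 0.005

    def test_faster_action_turnover_converges_in_fewer_cycles(self, obese_params):
        """Higher kNF means faster adaptation, hence fewer cycles to converge."""
        pk, ins, ffa = obese_params
        rate = rate_for_plateau(pk, 1.0)
        cycle = DosingProtocol(route="iv", segments=((0.0, 4.0, rate),),
                               acute_window=(0.0, 8.0))
        counts = []
        for knf in (0.02, 0.0377, 0.12):
            ffa_k = replace_fields(ffa, kNF=knf)
            _, n = periodic_steady_state(cycle, pk, ins, ffa_k, insulin="set_point",
                                         pin_nf=False, max_cycles=2000, tol=1e-6)
            counts.append(n)
        assert counts[0] >= counts[1] >= counts[2]

    def test_pinned_and_plain_iteration_agree(self, obese_params):
        pk, ins, ffa = obese_params
        rate = rate_for_plateau(pk, 1.0)
        cycle = DosingProtocol(route="iv", segments=((0.0, 4.0, rate),),
                               acute_window=(0.0, 8.0))
        a, _ = periodic_steady_state(cycle, pk, ins, ffa, insulin="set_point",
                                     pin_nf=True)
        b, _ = periodic_steady_state(cycle, pk, ins, ffa, insulin="set_point",
                                     pin_nf=False, max_cycles=2000)
        assert a["F"][-1] == pytest.approx(b["F"][-1], rel=1e-4)

    def test_misaligned_cycle_rejected(self, obese_params):
        pk, ins, ffa = obese_params
        cycle = DosingProtocol(route="iv", segments=((0.0, 30.0, 1.0),),
                               acute_window=(0.0, 24.0))
        with pytest.raises(ValueError):
            periodic_steady_state(cycle, pk, ins, ffa)
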