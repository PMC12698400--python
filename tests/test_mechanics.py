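"""Respiratory mechanics: obstruction law, two-lung split, RC network."""

import math

import numpy as np
import pytest

from crsim import Scenario, Schedule, run_scenario
from crsim.mechanics import (MechanicsParams, MechanicsState, ObstructionSpec,
                             branch_flows, cycle_ventilation,
                             derive_two_lung_params, obstructed_resistance,
                             step_mechanics)

DT = 4.17e-4


def make_params(**overrides) -> MechanicsParams:
    base = dict(R_ml0=0.0125, R_lt0=0.0041, R_tb0=0.0038,
                R_bll=0.00223, R_brl=0.00182,
                C_cw=0.332, C_ll=0.122, C_rl=0.150,
                V_llu=0.99, V_rlu=1.21)
    base.update(overrides)
    return MechanicsParams(**base)


class TestObstructedResistance:
    def test_no_obstruction_identity(self):
        assert obstructed_resistance(1.7, 0.0) == 1.7

    def test_half_obstruction_quadruples(self):
        assert obstructed_resistance(1.0, 0.5) == pytest.approx(4.0)

    def test_complete_obstruction_is_infinite(self):
        assert math.isinf(obstructed_resistance(1.0, 1.0))

    @pytest.mark.parametrize("fao", [-0.1, 1.5])
    def test_rejects_out_of_range(self, fao):
        with pytest.raises(ValueError):
            obstructed_resistance(1.0, fao)


class TestTwoLungSplit:
    def test_compliance_split(self):
        s = derive_two_lung_params(0.1, 2.0, 1.0)
        assert s.C_ll == pytest.approx(0.045)
        assert s.C_rl == pytest.approx(0.055)

    def test_unstressed_volume_split(self):
        s = derive_two_lung_params(0.1, 2.0, 1.0)
        assert s.V_llu == pytest.approx(0.9)
        assert s.V_rlu == pytest.approx(1.1)

    def test_resistances_recombine_in_parallel(self):
        s = derive_two_lung_params(0.1, 2.0, 1.0)
        assert s.R_bll == pytest.approx(1.0 / 0.45)   # 222% of original
        assert s.R_brl == pytest.approx(1.0 / 0.55)   # 181% of original
        parallel = 1.0 / (1.0 / s.R_bll + 1.0 / s.R_brl)
        assert parallel == pytest.approx(1.0, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            derive_two_lung_params(-1.0, 2.0, 1.0)


class TestStepMechanics:
    def test_equilibrium_is_fixed_point(self):
        p = make_params()
        s0 = MechanicsState.at_rest(p)
        s1 = step_mechanics(s0, p, P_mus=0.0, P_ao=0.0, obstruction=None,
                            dt=DT, P_mus_rate=0.0)
        assert s1.P_pl == s0.P_pl == 0.0
        assert s1.V_l == pytest.approx(s0.V_l)

    def test_complete_obstruction_blocks_inflow(self):
        p = make_params()
        s = MechanicsState.at_rest(p)
        blocked = ObstructionSpec(F_ao=1.0, location="lt")
        vl0 = s.V_l
        # drive hard with muscle pressure; total volume cannot change
        for k in range(500):
            rate = -300.0 * math.cos(2 * math.pi * k / 500)
            q_in, _, _ = branch_flows(s, p, 0.0, rate, blocked)
            assert q_in == 0.0
            s = step_mechanics(s, p, 0.0, 0.0, blocked, DT, P_mus_rate=rate)
        assert s.V_l == pytest.approx(vl0, abs=1e-12)

    def test_symmetric_network_stays_symmetric(self):
        p = make_params(C_ll=0.13, C_rl=0.13, R_bll=0.002, R_brl=0.002,
                        V_llu=1.0, V_rlu=1.0)
        s = MechanicsState.at_rest(p)
        for k in range(400):
            rate = -200.0 * math.sin(2 * math.pi * k / 400)
            s = step_mechanics(s, p, 0.0, 0.0, None, DT, P_mus_rate=rate)
        assert s.V_ll == pytest.approx(s.V_rl, rel=1e-12)

    def test_mass_conservation_at_bronchial_node(self, rng):
        """Serial inflow equals the sum of branch flows (algebraic balance)."""
        p = make_params()
        for _ in range(50):
            s = MechanicsState(P_pl=rng.normal(0, 3), P_ll=rng.normal(0, 3),
                               P_rl=rng.normal(0, 3))
            q_in, q_l, q_r = branch_flows(s, p, P_ao=rng.normal(0, 2),
                                          P_mus_rate=rng.normal(0, 100))
            scale = max(abs(q_in), abs(q_l), abs(q_r), 1e-3)
            assert abs(q_in - (q_l + q_r)) < 1e-9 * scale

    def test_rejects_nonfinite_and_bad_dt(self):
        p = make_params()
        s = MechanicsState(P_pl=float("nan"))
        with pytest.raises(ValueError):
            step_mechanics(s, p, 0.0, 0.0, None, DT)
        with pytest.raises(ValueError):
            step_mechanics(MechanicsState.at_rest(p), p, 0.0, 0.0, None, -DT)


class TestOneCompartmentOracle:
    def test_two_lung_matches_single_compartment(self):
        """With the 45/55 split, the two-lung network must reproduce an
        independently coded one-compartment RC model driven by the same
        sinusoidal muscle pressure, to within 0.5% on tidal volume."""
        C_lung, Vu, R_b = 0.27, 2.2, 0.001
        split = derive_two_lung_params(C_lung, Vu, R_b)
        p = make_params(C_ll=split.C_ll, C_rl=split.C_rl,
                        R_bll=split.R_bll, R_brl=split.R_brl,
                        V_llu=split.V_llu, V_rlu=split.V_rlu)
        freq = 12.0  # cycles/min
        amp = 4.0    # mmHg

        def pmus_rate(t):
            return -amp * 2 * math.pi * freq * math.cos(2 * math.pi * freq * t)

        # two-lung network via the package
        s = MechanicsState.at_rest(p)
        n = int(round(0.5 / DT))  # 6 cycles
        vl = np.empty(n)
        for k in range(n):
            s = step_mechanics(s, p, 0.0, 0.0, None, DT,
                               P_mus_rate=pmus_rate(k * DT))
            vl[k] = s.V_l
        tv_two, _ = cycle_ventilation(vl[-int(round(1 / freq / DT)):], freq)

        # independent one-compartment oracle (plain Euler, absolute form)
        R_aw = p.R_ml0 + p.R_lt0 + p.R_tb0
        ppl = pl = 0.0
        vl1 = np.empty(n)
        for k in range(n):
            g_aw, g_b = 1.0 / R_aw, 1.0 / R_b
            pb = (0.0 * g_aw + pl * g_b) / (g_aw + g_b)
            q_in = (0.0 - pb) * g_aw
            dppl = pmus_rate(k * DT) + q_in / p.C_cw
            dpl = dppl + (pb - pl) * g_b / C_lung
            ppl += DT * dppl
            pl += DT * dpl
            vl1[k] = C_lung * (pl - ppl) + Vu
        tv_one, _ = cycle_ventilation(vl1[-int(round(1 / freq / DT)):], freq)
        assert tv_two == pytest.approx(tv_one, rel=0.005)


class TestCycleVentilation:
    def test_constant_trace_gives_zero(self):
        assert cycle_ventilation([2.2] * 10, 12.0) == (0.0, 0.0)

    def test_product_identity(self):
        tv, mv = cycle_ventilation([2.0, 2.5], 12.0)
        assert tv == pytest.approx(0.5)
        assert mv == pytest.approx(6.0)

    def test_nominal_pairing(self):
        tv, mv = cycle_ventilation([2.0, 2.55], 12.0)
        assert mv == pytest.approx(6.6)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            cycle_ventilation([], 12.0)


def _open_loop_mv(params, fao, extra=None):
    """MV under fixed nominal gases (open loop) at a given obstruction."""
    ps = params.copy()
    if extra:
        for k, v in extra.items():
            ps[k] = ps[k] + v
    sc = Scenario(
        duration=2.0, mode="open_loop_gas", name=f"fao_{fao}",
        schedules={"pao2": Schedule.constant(ps["PaO2_n"]),
                   "paco2": Schedule.constant(ps["PaCO2_n"]),
                   "fao": Schedule.constant(fao)})
    return run_scenario(sc, ps).final("MV")


def test_mv_strictly_decreasing_in_obstruction(params):
    mvs = [_open_loop_mv(params, f) for f in (0.0, 0.25, 0.5, 0.75)]
    assert np.all(np.diff(mvs) < 0)


def test_equal_resistance_increase_is_location_independent(params):
    """The three serial segments only enter through their sum, so adding the
    same resistance increment at ml, lt or tb gives identical MV (a model
    property of the serial network, not a physiological claim)."""
    delta = 0.05
    mvs = [_open_loop_mv(params, 0.0, extra={name: delta})
           for name in ("R_ml0", "R_lt0", "R_tb0")]
    assert mvs[0] == pytest.approx(mvs[1], rel=1e-9)
    assert mvs[0] == pytest.approx(mvs[2], rel=1e-9)
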