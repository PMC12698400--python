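"""Reduced core: gas stores, O2-Hb dissociation, chemoreceptors, circulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crsim.surrogate import (CardioState, ExsanguinationError, GasState,
                             SurrogateParams, alveolar_co2_target,
                             alveolar_gas_update, alveolar_o2_target,
                             cardio_update, hb_saturation,
                             peripheral_activity)
from crsim import _kernel as K

DT = 4.17e-4


@pytest.fixture(scope="module")
def sp(params) -> SurrogateParams:
    return SurrogateParams.from_parameter_set(params)


class TestHbSaturation:
    def test_half_saturation_at_p50(self, sp):
        assert hb_saturation(sp["P_50"], sp) == pytest.approx(50.0)

    def test_zero_oxygen_zero_saturation(self, sp):
        assert hb_saturation(0.0, sp) == 0.0

    def test_baseline_anchor_98(self, sp):
        assert hb_saturation(sp["PaO2_n"], sp) == pytest.approx(98.0)

    def test_rejects_negative_pressure(self, sp):
        with pytest.raises(ValueError):
            hb_saturation(-1.0, sp)


class TestPeripheralActivity:
    def test_nominal_anchor_exact(self, sp):
        f = peripheral_activity(sp["PaO2_n"], sp["PaCO2_n"], sp)
        assert f == pytest.approx(sp["f_acn"], abs=1e-12)

    def test_hypoxic_monotonicity(self, sp):
        assert (peripheral_activity(40.0, 40.0, sp)
                > peripheral_activity(100.0, 40.0, sp))
        grid = [peripheral_activity(x, 40.0, sp)
                for x in np.linspace(20, 150, 30)]
        assert np.all(np.diff(grid) < 0)

    def test_hypercapnic_monotonicity(self, sp):
        assert (peripheral_activity(100.0, 48.0, sp)
                > peripheral_activity(100.0, 40.0, sp))


class TestGasStores:
    def test_steady_state_is_40_at_nominal_ventilation(self, sp):
        assert alveolar_co2_target(6.6, 0.0, sp) == pytest.approx(40.0)
        # relaxation holds the fixed point
        gas = GasState.nominal(sp)
        for _ in range(2000):
            gas = alveolar_gas_update(6.6, 0.21, 0.0, sp, DT, gas)
        assert gas.PaCO2 == pytest.approx(40.0, abs=1e-9)
        assert gas.ETCO2 == pytest.approx(40.0, abs=1e-9)
        assert gas.PaO2 == pytest.approx(sp["PaO2_n"], abs=1e-6)

    def test_halving_ventilation_doubles_hyperbola_target(self, sp):
        assert alveolar_co2_target(3.3, 0.0, sp) == pytest.approx(80.0)

    def test_alveolar_air_equation_baseline(self, sp):
        assert alveolar_o2_target(0.21, 40.0, sp) == pytest.approx(
            sp["PaO2_n"])

    def test_apnea_ramps(self, sp):
        """MV = 0 drives PaCO2 up at the apneic rate and SpO2 down
        monotonically."""
        gas = GasState.nominal(sp)
        spo2 = [gas.SpO2]
        for _ in range(int(round(1.0 / DT))):  # one minute of apnea
            gas = alveolar_gas_update(0.0, 0.21, 0.0, sp, DT, gas)
            spo2.append(gas.SpO2)
        assert gas.PaCO2 == pytest.approx(40.0 + sp["r_CO2_apnea"], rel=1e-3)
        assert np.all(np.diff(spo2) <= 0)
        assert spo2[-1] < spo2[0]

    def test_rejects_bad_fractions(self, sp):
        with pytest.raises(ValueError):
            alveolar_gas_update(6.6, 1.2, 0.0, sp, DT, GasState.nominal(sp))


class TestCirculation:
    def test_nominal_anchors_held(self, sp):
        cardio = CardioState.nominal(sp)
        gas = GasState.nominal(sp)
        assert (cardio.MAP, cardio.SBP, cardio.HR) == (90.0, 120.0, 70.0)
        assert cardio.DBP == pytest.approx(75.0)
        assert cardio.CO == pytest.approx(5.0)
        for _ in range(2000):
            cardio = cardio_update(cardio, gas, 0.0, sp, DT)
        assert cardio.MAP == pytest.approx(90.0, abs=1e-9)
        assert cardio.HR == pytest.approx(70.0, abs=1e-9)

    def test_hemorrhage_with_frozen_reflex_drops_map(self, sp):
        cardio = CardioState.nominal(sp)
        gas = GasState.nominal(sp)
        maps = []
        for _ in range(3000):
            cardio = cardio_update(cardio, gas, 0.1, sp, DT,
                                   freeze_reflex=True)
            maps.append(cardio.MAP)
        assert np.all(np.diff(maps) < 0)

    def test_blood_volume_conservation(self, sp):
        cardio = CardioState.nominal(sp)
        gas = GasState.nominal(sp)
        n, rate = 4000, 0.0625
        for _ in range(n):
            cardio = cardio_update(cardio, gas, rate, sp, DT)
        # total volume change equals the integral of the hemorrhage input
        assert cardio.V_blood == pytest.approx(
            sp["V_blood0"] - n * DT * rate, abs=1e-12)

    def test_quarter_blood_volume_loss(self, sp):
        """25% of a 5-L subject over 20 min at 0.0625 L/min -> 1.25 L."""
        cardio = CardioState.nominal(sp)
        gas = GasState.nominal(sp)
        steps = int(round(20.0 / DT))
        for _ in range(steps):
            cardio = cardio_update(cardio, gas, 0.0625, sp, DT)
        lost = sp["V_blood0"] - cardio.V_blood
        # 0.25 * 5 L, up to the sub-step remainder of the 20-min window
        assert lost == pytest.approx(1.25, abs=0.0625 * DT)
        assert lost == pytest.approx(steps * DT * 0.0625, abs=1e-10)

    def test_exsanguination_halts(self, sp):
        cardio = CardioState.nominal(sp)
        gas = GasState.nominal(sp)
        with pytest.raises(ExsanguinationError):
            for _ in range(100):
                cardio = cardio_update(cardio, gas, 1000.0, sp, DT)

    @settings(derandomize=True, max_examples=200)
    @given(u=st.floats(-0.9, 2.0), vv=st.floats(0.1, 4.0),
           vblood=st.floats(0.5, 5.0), fac=st.floats(0.0, 25.0))
    def test_pressure_ordering_invariant(self, u, vv, vblood, fac):
        """DBP <= MAP <= SBP and HR > 0 over the whole reachable state box."""
        sp_local = SurrogateParams.default()
        co, map_, sbp, dbp, hr, _ = K.cardio_eval(u, vv, vblood, fac,
                                                  sp_local.vector)
        assert dbp <= map_ <= sbp
        assert hr > 0
        assert co >= 0


class TestSensitivityDirections:
    """Steady-state response signs of the core (isolated, not closed-loop)."""

    def test_more_co2_production_raises_etco2_target(self, sp):
        hi = sp.vector.copy()
        from crsim import _indices as I
        hi[I.M_DCO2] *= 1.1
        hi_t = alveolar_co2_target(6.6, 0.0, SurrogateParams(vector=hi))
        assert hi_t > alveolar_co2_target(6.6, 0.0, sp)

    def test_more_dead_space_raises_etco2_target(self, sp):
        from crsim import _indices as I
        hi = sp.vector.copy()
        hi[I.K_DS] = min(hi[I.K_DS] * 1.1, 0.95)
        hi_t = alveolar_co2_target(6.6, 0.0, SurrogateParams(vector=hi))
        assert hi_t > alveolar_co2_target(6.6, 0.0, sp)

    def test_steeper_hill_raises_baseline_spo2(self, sp):
        from crsim import _indices as I
        hi = sp.vector.copy()
        hi[I.GAMMA] *= 1.1
        assert (hb_saturation(sp["PaO2_n"], SurrogateParams(vector=hi))
                > hb_saturation(sp["PaO2_n"], sp))

    def test_venous_volume_raises_sbp_unstressed_lowers_it(self, sp):
        from crsim import _indices as I
        for name, sign in ((I.V_V0, +1), (I.V_VU0, -1)):
            hi = sp.vector.copy()
            hi[name] *= 1.1
            sp_hi = SurrogateParams(vector=hi)
            c_hi = CardioState(MAP=90, SBP=120, DBP=75, HR=70, CO=5,
                               V_V=hi[I.V_V0], V_blood=hi[I.V_BLOOD0])
            gas = GasState.nominal(sp)
            for _ in range(6000):   # settle the sympathetic drive
                c_hi = cardio_update(c_hi, gas, 0.0, sp_hi, DT)
            assert sign * (c_hi.SBP - 120.0) > 0
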