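"""Reduced closed-loop core: blood gases, chemoreceptor activity, circulation.

This module closes the loop around the respiratory control and mechanics
components with a deliberately small gas-exchange and cardiovascular model
that shares their input/output signature, so the whole pipeline (scenario
engine, calibration, validation metrics, sensitivity machinery) runs
end-to-end.  It is *not* a re-implementation of a full-scale
cardio-respiratory core; any component with the same signature can be swapped
in behind :class:`crsim.model.CardioRespModel`.

Gas exchange
    Alveolar ventilation VA = MV*(1 - k_ds).  PaCO2 relaxes toward the
    metabolic hyperbola PiCO2 + 863*M_dCO2/VA; PaO2 toward the alveolar air
    target PiO2 - PaCO2/RQ.  As VA approaches zero both derivatives blend
    into constant asphyxia ramps.  ETCO2 tracks PaCO2 minus a configurable
    dead-space gradient (0 by default); SpO2 is the Hill sigmoid with
    exponent gamma and half-saturation pressure P_50.

Circulation
    Stressed venous volume sets cardiac output; MAP = CO * TPR with TPR and
    CO modulated by a first-order sympathetic drive that rises with MAP
    deficit and chemoreceptor activity; HR adds sympathetic, chemoreceptor
    and atrial-stretch (volume) contributions onto the intercept HR_0;
    SBP/DBP derive from MAP via a stroke-volume-proportional pulse pressure
    (MAP = DBP + PP/3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _indices as I
from . import _kernel as K
from .params import ParameterSet

__all__ = [
    "SurrogateParams", "GasState", "CardioState", "ExsanguinationError",
    "alveolar_gas_update", "hb_saturation", "peripheral_activity",
    "cardio_update", "alveolar_co2_target", "alveolar_o2_target",
]


class ExsanguinationError(RuntimeError):
    """Raised when total blood volume is exhausted."""


@dataclass(frozen=True)
class SurrogateParams:
    """Core parameters; carries the full registry vector internally."""

    vector: np.ndarray

    @classmethod
    def from_parameter_set(cls, ps: ParameterSet) -> "SurrogateParams":
        return cls(vector=ps.vector.copy())

    @classmethod
    def default(cls) -> "SurrogateParams":
        return cls.from_parameter_set(ParameterSet.default())

    def __getitem__(self, name: str) -> float:
        from .params import index_of
        return float(self.vector[index_of(name)])


@dataclass(frozen=True)
class GasState:
    PaO2: float
    PaCO2: float
    SpO2: float
    ETCO2: float
    f_ac: float

    @classmethod
    def nominal(cls, params: SurrogateParams) -> "GasState":
        p = params.vector
        return _gas_state(p, p[I.PAO2_N], p[I.PACO2_N])


@dataclass(frozen=True)
class CardioState:
    MAP: float
    SBP: float
    DBP: float
    HR: float
    CO: float
    V_V: float
    V_blood: float
    u_symp: float = 0.0

    @classmethod
    def nominal(cls, params: SurrogateParams) -> "CardioState":
        p = params.vector
        return _cardio_state(p, 0.0, p[I.V_V0], p[I.V_BLOOD0], p[I.F_ACN])


def _gas_state(p: np.ndarray, pao2: float, paco2: float) -> GasState:
    spo2 = K.hill_saturation(pao2, p[I.GAMMA], p[I.P_50])
    etco2 = max(paco2 - p[I.ETCO2_GRAD], 0.0)
    fac = K.fac_eval(pao2, paco2, p)
    return GasState(PaO2=pao2, PaCO2=paco2, SpO2=spo2, ETCO2=etco2, f_ac=fac)


def _cardio_state(p: np.ndarray, u: float, vv: float, vblood: float,
                  fac: float) -> CardioState:
    co, map_, sbp, dbp, hr, _vs = K.cardio_eval(u, vv, vblood, fac, p)
    return CardioState(MAP=map_, SBP=sbp, DBP=dbp, HR=hr, CO=co,
                       V_V=vv, V_blood=vblood, u_symp=u)


def hb_saturation(PaO2: float, params: SurrogateParams) -> float:
    """SpO2 (%) = 100 * PaO2^gamma / (PaO2^gamma + P_50^gamma)."""
    if PaO2 < 0:
        raise ValueError("PaO2 must be >= 0")
    p = params.vector
    return float(K.hill_saturation(PaO2, p[I.GAMMA], p[I.P_50]))


def peripheral_activity(PaO2: float, PaCO2: float,
                        params: SurrogateParams) -> float:
    """Peripheral chemoreceptor activity f_ac.

    Strictly decreasing in PaO2, strictly increasing in PaCO2 (while
    positive), and exactly f_acn at the nominal gases.
    """
    if PaO2 < 0 or PaCO2 < 0:
        raise ValueError("gas pressures must be >= 0")
    return float(K.fac_eval(PaO2, PaCO2, params.vector))


def alveolar_co2_target(MV: float, FiCO2: float,
                        params: SurrogateParams) -> float:
    """Steady-state PaCO2 on the metabolic hyperbola at ventilation MV."""
    p = params.vector
    pdry = p[I.P_ATM] - p[I.P_H2O]
    va = max(MV * (1.0 - p[I.K_DS]), p[I.VA_FLOOR])
    return FiCO2 * pdry + K.K_GAS * p[I.M_DCO2] / va


def alveolar_o2_target(FiO2: float, PaCO2: float,
                       params: SurrogateParams) -> float:
    """Alveolar-air-equation PaO2 target: FiO2*(P_atm - P_H2O) - PaCO2/RQ."""
    p = params.vector
    return max(FiO2 * (p[I.P_ATM] - p[I.P_H2O]) - PaCO2 / p[I.RQ], 0.0)


def alveolar_gas_update(MV: float, FiO2: float, FiCO2: float,
                        params: SurrogateParams, dt: float,
                        state: GasState) -> GasState:
    """One Euler step of the arterial gas stores; recomputes SpO2/ETCO2/f_ac."""
    if MV < 0:
        raise ValueError("MV must be >= 0")
    if not (0 <= FiO2 <= 1 and 0 <= FiCO2 <= 1):
        raise ValueError("inspired fractions must be in [0, 1]")
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params.vector
    dpao2, dpaco2 = K.gas_derivs(state.PaO2, state.PaCO2, MV, FiO2, FiCO2, p)
    pao2 = max(state.PaO2 + dt * dpao2, 0.0)
    paco2 = max(state.PaCO2 + dt * dpaco2, 0.0)
    return _gas_state(p, pao2, paco2)


def cardio_update(state: CardioState, gas: GasState, hemorrhage_rate: float,
                  params: SurrogateParams, dt: float,
                  freeze_reflex: bool = False) -> CardioState:
    """One Euler step of volumes and sympathetic drive; algebraic outputs.

    Raises :class:`ExsanguinationError` when the blood volume is exhausted.
    With ``freeze_reflex`` the sympathetic drive is held (used by tests to
    isolate the volume-pressure pathway).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params.vector
    vv = state.V_V - dt * hemorrhage_rate
    vblood = state.V_blood - dt * hemorrhage_rate
    if vblood <= 0:
        raise ExsanguinationError(
            f"total blood volume exhausted (V_blood={vblood:.3f} L)")
    co, map_, sbp, dbp, hr, _vs = K.cardio_eval(
        state.u_symp, vv, vblood, gas.f_ac, p)
    if freeze_reflex:
        u = state.u_symp
    else:
        u = state.u_symp + dt * K.symp_deriv(state.u_symp, map_, gas.f_ac, p)
    return CardioState(MAP=map_, SBP=sbp, DBP=dbp, HR=hr, CO=co,
                       V_V=vv, V_blood=vblood, u_symp=u)
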