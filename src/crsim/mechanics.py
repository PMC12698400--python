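"""Two-lung respiratory mechanics with graded airway obstruction.

Air flows from the airway opening through three serial segments
(mouth-larynx, larynx-trachea, trachea-bronchi) to a bronchial node, then
through two parallel branch resistances into the left and right lung
compliances, all inside the chest-wall compliance driven by the respiratory
muscle pressure.  Segment compliances of the larynx/trachea/bronchi are
omitted (they contribute negligibly); the bronchial pressure is an algebraic
node eliminated exactly from the flow balance at every step.

Obstruction multiplies the resistance of one serial segment by
1/(1 - F_ao)^2 (Poiseuille scaling of a narrowed cross-section); complete
obstruction (F_ao = 1) is represented as a zero-flow serial path rather than
a huge finite resistance, which keeps the explicit integrator well away from
stiffness blow-up.

The left and right lungs carry 45% and 55% of the total lung volume and
compliance; branch resistances are inversely proportional to those shares
(222% and 181% of the single-compartment bronchi-to-lung resistance), so
their parallel combination recovers the single-compartment value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _indices as I
from . import _kernel as K
from .params import ParameterSet

__all__ = [
    "MechanicsParams", "ObstructionSpec", "MechanicsState", "TwoLungSplit",
    "obstructed_resistance", "derive_two_lung_params", "step_mechanics",
    "cycle_ventilation", "LEFT_LUNG_FRACTION",
]

#: left lung's share of total lung volume and compliance
LEFT_LUNG_FRACTION = 0.45

LOCATIONS = ("ml", "lt", "tb")


@dataclass(frozen=True)
class MechanicsParams:
    R_ml0: float
    R_lt0: float
    R_tb0: float
    R_bll: float
    R_brl: float
    C_cw: float
    C_ll: float
    C_rl: float
    V_llu: float
    V_rlu: float

    def __post_init__(self):
        for name in ("R_ml0", "R_lt0", "R_tb0", "R_bll", "R_brl",
                     "C_cw", "C_ll", "C_rl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_parameter_set(cls, ps: ParameterSet) -> "MechanicsParams":
        return cls(**{f: ps[f] for f in (
            "R_ml0", "R_lt0", "R_tb0", "R_bll", "R_brl",
            "C_cw", "C_ll", "C_rl", "V_llu", "V_rlu")})

    def _vector(self) -> np.ndarray:
        vec = np.ones(I.N_PARAMS)
        vec[I.R_ML0] = self.R_ml0
        vec[I.R_LT0] = self.R_lt0
        vec[I.R_TB0] = self.R_tb0
        vec[I.R_BLL] = self.R_bll
        vec[I.R_BRL] = self.R_brl
        vec[I.C_CW] = self.C_cw
        vec[I.C_LL] = self.C_ll
        vec[I.C_RL] = self.C_rl
        vec[I.V_LLU] = self.V_llu
        vec[I.V_RLU] = self.V_rlu
        return vec


@dataclass(frozen=True)
class ObstructionSpec:
    """Fractional obstruction at one of the three serial airway segments."""

    F_ao: float = 0.0
    location: str = "ml"

    def __post_init__(self):
        if not 0.0 <= self.F_ao <= 1.0:
            raise ValueError(f"F_ao must be in [0, 1], got {self.F_ao}")
        if self.location not in LOCATIONS:
            raise ValueError(
                f"location must be one of {LOCATIONS}, got {self.location!r}")

    @property
    def location_code(self) -> int:
        return I.LOC_CODES[self.location]


@dataclass(frozen=True)
class MechanicsState:
    """Pressures (mmHg) and volumes (L) of the airway-lung network."""

    P_pl: float = 0.0
    P_ll: float = 0.0
    P_rl: float = 0.0
    P_b: float = 0.0
    V_ll: float = 0.0
    V_rl: float = 0.0

    @property
    def V_l(self) -> float:
        return self.V_ll + self.V_rl

    @classmethod
    def at_rest(cls, params: MechanicsParams) -> "MechanicsState":
        """Equilibrium at atmospheric pressure: volumes at unstressed values."""
        return cls(V_ll=params.V_llu, V_rl=params.V_rlu)


def obstructed_resistance(R_io: float, F_ao: float) -> float:
    """R = R_io / (1 - F_ao)^2; F_ao = 1 returns +inf (zero-flow sentinel)."""
    if R_io <= 0:
        raise ValueError("R_io must be positive")
    if not 0.0 <= F_ao <= 1.0:
        raise ValueError(f"F_ao must be in [0, 1], got {F_ao}")
    return float(K.obstructed_resistance(R_io, F_ao))


@dataclass(frozen=True)
class TwoLungSplit:
    """Two-lung parameters derived from a single-compartment lung."""

    C_ll: float
    C_rl: float
    V_llu: float
    V_rlu: float
    R_bll: float
    R_brl: float


def derive_two_lung_params(single_lung_C: float, single_lung_Vu: float,
                           single_lung_R: float,
                           left_fraction: float = LEFT_LUNG_FRACTION,
                           ) -> TwoLungSplit:
    """Split one lung compartment into left/right at the 45/55 volume ratio.

    Compliances and unstressed volumes are proportional to the volume share;
    branch resistances are inversely proportional to it, so the parallel
    combination of the two branches recovers the single-compartment
    resistance exactly.
    """
    if min(single_lung_C, single_lung_Vu, single_lung_R) <= 0:
        raise ValueError("single-compartment values must be positive")
    if not 0 < left_fraction < 1:
        raise ValueError("left_fraction must be in (0, 1)")
    fl, fr = left_fraction, 1.0 - left_fraction
    return TwoLungSplit(
        C_ll=fl * single_lung_C, C_rl=fr * single_lung_C,
        V_llu=fl * single_lung_Vu, V_rlu=fr * single_lung_Vu,
        R_bll=single_lung_R / fl, R_brl=single_lung_R / fr,
    )


def step_mechanics(state: MechanicsState, params: MechanicsParams,
                   P_mus: float, P_ao: float,
                   obstruction: ObstructionSpec | None, dt: float,
                   P_mus_rate: float = 0.0) -> MechanicsState:
    """One explicit-Euler step of the pressure ODEs plus algebraic updates.

    The mass balances couple the pressure *rates* to the muscle pressure
    rate, so the within-cycle derivative of P_mus (``P_mus_rate``, mmHg/min)
    drives the chest wall; ``P_mus`` itself only enters through the history
    already accumulated in the pressures.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    vals = (state.P_pl, state.P_ll, state.P_rl, P_mus, P_ao, P_mus_rate)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("non-finite mechanics state or input")
    obstruction = obstruction or ObstructionSpec()
    vec = params._vector()
    dppl, dpll, dprl, pb, _q = K.mech_derivs(
        state.P_pl, state.P_ll, state.P_rl, P_ao, P_mus_rate,
        obstruction.F_ao, obstruction.location_code, vec)
    ppl = state.P_pl + dt * dppl
    pll = state.P_ll + dt * dpll
    prl = state.P_rl + dt * dprl
    vll, vrl, _vl = K.lung_volumes(ppl, pll, prl, vec)
    if vll < 0 or vrl < 0:
        raise ValueError(
            f"negative lung volume (V_ll={vll:.4f}, V_rl={vrl:.4f} L): "
            "time step too large or pathological parameters")
    return MechanicsState(P_pl=ppl, P_ll=pll, P_rl=prl, P_b=pb,
                          V_ll=vll, V_rl=vrl)


def branch_flows(state: MechanicsState, params: MechanicsParams,
                 P_ao: float, P_mus_rate: float = 0.0,
                 obstruction: ObstructionSpec | None = None,
                 ) -> tuple[float, float, float]:
    """(Q_in, Q_left, Q_right) for the current state (L/min).

    Q_in is the serial-path inflow; by the bronchial-node flow balance it
    equals Q_left + Q_right exactly (P_b is eliminated analytically).
    """
    obstruction = obstruction or ObstructionSpec()
    vec = params._vector()
    _, _, _, pb, q_in = K.mech_derivs(
        state.P_pl, state.P_ll, state.P_rl, P_ao, P_mus_rate,
        obstruction.F_ao, obstruction.location_code, vec)
    q_l = (pb - state.P_ll) / params.R_bll
    q_r = (pb - state.P_rl) / params.R_brl
    return q_in, q_l, q_r


def cycle_ventilation(V_l_trace, RR: float) -> tuple[float, float]:
    """Tidal volume and minute ventilation from one completed cycle.

    TV = max(V_l) - min(V_l) over the cycle; MV = TV * RR.
    """
    v = np.asarray(V_l_trace, dtype=float)
    if v.size == 0:
        raise ValueError("empty lung-volume trace")
    if RR <= 0:
        raise ValueError("RR must be positive")
    tv = float(v.max() - v.min())
    return tv, tv * RR
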