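"""Chemoreceptor-driven respiratory control.

Central chemoreceptors respond to the deviation of arterial CO2 pressure
from its nominal value; peripheral chemoreceptors respond to the deviation
of their firing activity ``f_ac`` (itself a function of PaO2 and PaCO2,
computed in :mod:`crsim.surrogate`).  Each pathway drives a first-order
deviation of the respiratory rate (RR) and of the minimum respiratory muscle
pressure (P_mus,min); the deviations add onto the baselines, and once per
breath cycle the resulting (RR, P_mus,min) pair is frozen into a muscle
pressure waveform: a parabolic inspiratory descent over the first 0.375 of
the cycle, then an exponential recovery back to zero.

Two first-order ODE conventions are supported, selected by ``form``:

``printed``  : dx/dt + tau*x = G*u   (steady-state gain G/tau)
``standard`` : tau*dx/dt + x = G*u   (steady-state gain G)

The two differ only in how the gain and time constant are parameterized; the
calibration procedure absorbs the difference into the fitted gains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _indices as I
from . import _kernel as K
from .params import ParameterSet

logger = logging.getLogger(__name__)

__all__ = [
    "ChemoreflexParams", "ChemoreflexState", "BreathPattern",
    "step_chemoreflex", "combine_drives", "generate_waveform",
    "INSPIRATORY_FRACTION",
]

#: fixed inspiratory fraction of the breath cycle: T_i = 0.375 * T
INSPIRATORY_FRACTION = 0.375


@dataclass(frozen=True)
class ChemoreflexParams:
    """Gains, time constants and baselines of the four reflex pathways."""

    tau_cR: float
    tau_cP: float
    tau_pR: float
    tau_pP: float
    G_cR: float
    G_cP: float
    G_pR: float
    G_pP: float
    RR_o: float
    P_mus_min_o: float
    PaCO2_n: float
    f_acn: float
    rr_floor: float = 2.0
    form: str = "printed"

    def __post_init__(self):
        for name in ("tau_cR", "tau_cP", "tau_pR", "tau_pP"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.RR_o <= 0:
            raise ValueError("RR_o must be positive")
        if self.P_mus_min_o > 0:
            raise ValueError("P_mus_min_o must be <= 0 (inspiratory effort)")
        if self.PaCO2_n <= 0:
            raise ValueError("PaCO2_n must be positive")
        if self.form not in ("printed", "standard"):
            raise ValueError("form must be 'printed' or 'standard'")

    @classmethod
    def from_parameter_set(cls, ps: ParameterSet,
                           form: str = "printed") -> "ChemoreflexParams":
        return cls(
            tau_cR=ps["tau_cR"], tau_cP=ps["tau_cP"],
            tau_pR=ps["tau_pR"], tau_pP=ps["tau_pP"],
            G_cR=ps["G_cR"], G_cP=ps["G_cP"],
            G_pR=ps["G_pR"], G_pP=ps["G_pP"],
            RR_o=ps["RR_o"], P_mus_min_o=ps["P_mus_min_o"],
            PaCO2_n=ps["PaCO2_n"], f_acn=ps["f_acn"],
            rr_floor=ps["rr_floor"], form=form,
        )

    def _vector(self) -> np.ndarray:
        vec = np.ones(I.N_PARAMS)
        vec[I.TAU_CR] = self.tau_cR
        vec[I.TAU_CP] = self.tau_cP
        vec[I.TAU_PR] = self.tau_pR
        vec[I.TAU_PP] = self.tau_pP
        vec[I.G_CR] = self.G_cR
        vec[I.G_CP] = self.G_cP
        vec[I.G_PR] = self.G_pR
        vec[I.G_PP] = self.G_pP
        vec[I.PACO2_N] = self.PaCO2_n
        vec[I.F_ACN] = self.f_acn
        return vec


@dataclass(frozen=True)
class ChemoreflexState:
    """Deviations of RR and P_mus,min driven by the two chemoreceptor sites.

    All four deviations are zero at the nominal operating point
    (PaCO2 = PaCO2_n, f_ac = f_acn).
    """

    dRR_c: float = 0.0
    dRR_p: float = 0.0
    dPmusmin_c: float = 0.0
    dPmusmin_p: float = 0.0


def step_chemoreflex(state: ChemoreflexState, params: ChemoreflexParams,
                     PaCO2: float, f_ac: float, dt: float) -> ChemoreflexState:
    """One explicit-Euler step of the four first-order reflex ODEs."""
    for name, val in (("PaCO2", PaCO2), ("f_ac", f_ac), ("dt", dt)):
        if not math.isfinite(val):
            raise ValueError(f"non-finite input signal: {name}={val!r}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if PaCO2 <= 0:
        raise ValueError("PaCO2 must be positive")
    vec = params._vector()
    d0, d1, d2, d3 = K.chemo_derivs(
        state.dRR_c, state.dRR_p, state.dPmusmin_c, state.dPmusmin_p,
        PaCO2, f_ac, vec, params.form == "printed")
    return ChemoreflexState(
        dRR_c=state.dRR_c + dt * d0,
        dRR_p=state.dRR_p + dt * d1,
        dPmusmin_c=state.dPmusmin_c + dt * d2,
        dPmusmin_p=state.dPmusmin_p + dt * d3,
    )


def combine_drives(state: ChemoreflexState,
                   params: ChemoreflexParams) -> tuple[float, float]:
    """Total RR and P_mus,min: baselines plus both chemoreflex deviations.

    RR is clamped to a configurable floor (guards T = 1/RR during extreme
    hypocapnia); P_mus,min is clamped to zero from above (no expiratory
    'negative effort').
    """
    rr = params.RR_o + state.dRR_c + state.dRR_p
    if rr < params.rr_floor:
        logger.warning("RR %.3f below floor %.3f; clamped",
                       rr, params.rr_floor)
        rr = params.rr_floor
    pmin = params.P_mus_min_o + state.dPmusmin_c + state.dPmusmin_p
    if pmin > 0.0:
        logger.warning("P_mus,min %.3f above zero; clamped", pmin)
        pmin = 0.0
    return rr, pmin


@dataclass(frozen=True)
class BreathPattern:
    """One breath cycle of the respiratory muscle pressure waveform."""

    RR: float
    P_mus_min: float
    T: float
    T_i: float
    mode: str = "continuous"
    _literal: bool = field(init=False, repr=False, default=False)

    def __post_init__(self):
        object.__setattr__(self, "_literal", self.mode == "literal")

    def __call__(self, t):
        """P_mus at within-cycle time(s) t in [0, T] (mmHg)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t_arr)
        for i, ti in enumerate(t_arr):
            pm, _ = K.pmus_eval(ti, self.T, self.T_i, self.P_mus_min,
                                self.RR, self._literal)
            out[i] = pm
        return out if np.ndim(t) else float(out[0])

    def rate(self, t):
        """dP_mus/dt at within-cycle time(s) t (mmHg/min)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t_arr)
        for i, ti in enumerate(t_arr):
            _, dpm = K.pmus_eval(ti, self.T, self.T_i, self.P_mus_min,
                                 self.RR, self._literal)
            out[i] = dpm
        return out if np.ndim(t) else float(out[0])

    def sample(self, n: int = 200):
        """(time_min, P_mus_mmHg) sampled on n points over one cycle."""
        t = np.linspace(0.0, self.T, n)
        return t, self(t)


def generate_waveform(RR: float, P_mus_min: float,
                      mode: str = "continuous") -> BreathPattern:
    """Build the per-cycle P_mus profile for given RR and P_mus,min.

    ``continuous`` (default): the inspiratory parabola is constructed to be 0
    at t = 0 and to reach P_mus_min with zero slope at t = T_i, making the
    hand-off to the exponential expiration continuous.  ``literal``: the
    polynomial 4*P*RR*t - 4*P*RR^2*t^2, whose vertex is at T/2 so its value
    at T_i is 0.9375*P_mus_min (a 6.25% jump at the hand-off).
    """
    if RR <= 0:
        raise ValueError("RR must be positive")
    if P_mus_min > 0:
        raise ValueError("P_mus_min must be <= 0")
    if mode not in ("continuous", "literal"):
        raise ValueError("mode must be 'continuous' or 'literal'")
    T = 1.0 / RR
    return BreathPattern(RR=RR, P_mus_min=P_mus_min, T=T,
                         T_i=INSPIRATORY_FRACTION * T, mode=mode)


def steady_state_deviation(gain: float, tau: float, drive: float,
                           form: str = "printed") -> float:
    """Closed-form steady state of one reflex ODE under constant drive."""
    if form == "printed":
        return gain * drive / tau
    return gain * drive


def steady_state(params: ChemoreflexParams, PaCO2: float,
                 f_ac: float) -> ChemoreflexState:
    """Closed-form steady deviations for constant (PaCO2, f_ac)."""
    uc = PaCO2 - params.PaCO2_n
    up = f_ac - params.f_acn
    return ChemoreflexState(
        dRR_c=steady_state_deviation(params.G_cR, params.tau_cR, uc,
                                     params.form),
        dRR_p=steady_state_deviation(params.G_pR, params.tau_pR, up,
                                     params.form),
        dPmusmin_c=steady_state_deviation(params.G_cP, params.tau_cP, uc,
                                          params.form),
        dPmusmin_p=steady_state_deviation(params.G_pP, params.tau_pP, up,
                                          params.form),
    )
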