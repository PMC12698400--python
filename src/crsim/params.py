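"""Parameter registry and default parameter set.

The model exposes a flat, fixed registry of 163 named parameter slots
(64 live + 99 inert `reserved_*` placeholders standing in for the
full-scale core that this package deliberately does not re-implement).
Live defaults follow standard lumped-parameter respiratory-mechanics
magnitudes converted to mmHg/L/min units.  Three defaults are *solved* at
construction so that the closed loop has its fixed point exactly on the
textbook resting baselines
(MV 6.6 L/min, RR 12 breaths/min, SpO2 98%, ETCO2 40 mmHg, MAP 90 mmHg,
SBP 120 mmHg, HR 70 beats/min):

* ``M_dCO2`` from the metabolic hyperbola so PaCO2 = 40 mmHg at nominal
  alveolar ventilation,
* ``gamma`` from the Hill equation so SpO2(PaO2 baseline) = 98%,
* ``P_mus_min_o`` by bisection so the respiratory mechanics deliver a tidal
  volume of 0.55 L at RR = 12 (hence MV = 6.6 L/min).
"""

from __future__ import annotations

import math

import numpy as np
import yaml

from . import _indices as I

#: Euler integration step (min); ~25 ms.
DT_DEFAULT = 4.17e-4

# resting baselines the default parameter set is anchored to
MV_NOMINAL = 6.6          # L/min
RR_NOMINAL = 12.0         # breaths/min
SPO2_NOMINAL = 98.0       # %
ETCO2_NOMINAL = 40.0      # mmHg
MAP_NOMINAL = 90.0        # mmHg
SBP_NOMINAL = 120.0       # mmHg
HR_NOMINAL = 70.0         # beats/min
FIO2_NOMINAL = 0.21
FICO2_NOMINAL = 0.0

# unit conversions for the literature respiratory-mechanics defaults
_CMH2O = 0.7355           # mmHg per cmH2O
_R = _CMH2O / 60.0        # (cmH2O.s/L) -> (mmHg.min/L)
_C = 1.0 / _CMH2O         # (L/cmH2O) -> (L/mmHg)

# single-compartment lineage values: total lung compliance, unstressed
# (resting) lung volume, and bronchi-to-lung resistance
_C_LUNG_TOTAL = 0.2 * _C        # L/mmHg
_V_LUNG_UNSTRESSED = 2.2        # L
_R_BL_SINGLE = 0.0817 * _R      # mmHg.min/L

LIVE_NAMES = (
    "tau_cR", "tau_cP", "tau_pR", "tau_pP",
    "G_cR", "G_cP", "G_pR", "G_pP",
    "RR_o", "P_mus_min_o", "PaCO2_n", "f_acn", "rr_floor",
    "R_ml0", "R_lt0", "R_tb0", "R_bll", "R_brl",
    "C_cw", "C_ll", "C_rl", "V_llu", "V_rlu",
    "gamma", "P_50", "M_dCO2", "k_ds", "RQ",
    "tau_O2", "tau_CO2", "r_CO2_apnea", "r_O2_apnea",
    "VA_floor", "VA_apnea", "etco2_gradient", "P_atm", "P_H2O",
    "fac_fmin", "fac_fmax", "fac_phalf", "fac_kO2", "fac_kCO2", "PaO2_n",
    "V_V0", "V_Vu0", "V_sn", "V_blood0", "CO_0", "MAP_0", "TPR_0",
    "HR_0", "HR_1", "HR_2", "HR_v",
    "G_baro", "G_chemo", "k_tpr", "tau_symp",
    "PP_0", "SV_0", "k_ino", "k_veno", "HR_min", "u_max",
)

assert len(LIVE_NAMES) == I.N_LIVE

REGISTRY = LIVE_NAMES + tuple(
    f"reserved_{i:03d}" for i in range(I.FIRST_RESERVED, I.N_PARAMS))

GROUPS = {
    "control": LIVE_NAMES[0:13],
    "mechanics": LIVE_NAMES[13:23],
    "gas": LIVE_NAMES[23:37],
    "chemoreceptor": LIVE_NAMES[37:43],
    "cardio": LIVE_NAMES[43:64],
}

_INDEX = {name: i for i, name in enumerate(REGISTRY)}

# The eight chemoreflex parameters searched by the calibration procedure.
CHEMOREFLEX_PARAMS = ("tau_cR", "tau_cP", "tau_pR", "tau_pP",
                      "G_cR", "G_cP", "G_pR", "G_pP")


def _base_defaults() -> dict:
    """Literature-magnitude defaults before the anchored solves."""
    d = {
        # chemoreflex: printed ODE form dx/dt = G*u - tau*x, steady gain G/tau
        "tau_cR": 3.0, "tau_cP": 3.0, "tau_pR": 1.5, "tau_pP": 1.5,
        "G_cR": 2.4, "G_cP": -1.35, "G_pR": 0.9, "G_pP": -0.45,
        "RR_o": RR_NOMINAL, "P_mus_min_o": -4.0,  # solved below
        "PaCO2_n": 40.0, "f_acn": 1.0, "rr_floor": 2.0,
        # mechanics (literature magnitudes, converted)
        "R_ml0": 1.021 * _R, "R_lt0": 0.3369 * _R, "R_tb0": 0.3063 * _R,
        "R_bll": _R_BL_SINGLE / 0.45, "R_brl": _R_BL_SINGLE / 0.55,
        "C_cw": 0.2444 * _C,
        "C_ll": 0.45 * _C_LUNG_TOTAL, "C_rl": 0.55 * _C_LUNG_TOTAL,
        "V_llu": 0.45 * _V_LUNG_UNSTRESSED, "V_rlu": 0.55 * _V_LUNG_UNSTRESSED,
        # gas exchange
        "gamma": 2.9, "P_50": 26.6,  # gamma solved below
        "M_dCO2": 0.21,              # solved below
        "k_ds": 0.30, "RQ": 0.8,
        "tau_O2": 0.2, "tau_CO2": 1.5,
        "r_CO2_apnea": 5.0, "r_O2_apnea": 30.0,
        "VA_floor": 0.05, "VA_apnea": 0.5,
        "etco2_gradient": 0.0, "P_atm": 760.0, "P_H2O": 47.0,
        # peripheral chemoreceptor activity
        "fac_fmin": 0.8, "fac_fmax": 12.3, "fac_phalf": 45.0,
        "fac_kO2": 10.0, "fac_kCO2": 0.03, "PaO2_n": 100.0,  # solved below
        # cardiovascular
        "V_V0": 3.0, "V_Vu0": 2.0, "V_sn": 1.0, "V_blood0": 5.0,
        "CO_0": 5.0, "MAP_0": MAP_NOMINAL,
        "TPR_0": MAP_NOMINAL / 5.0,
        "HR_0": HR_NOMINAL, "HR_1": 30.0, "HR_2": 1.5, "HR_v": 18.0,
        "G_baro": 2.0, "G_chemo": 0.1, "k_tpr": 1.0, "tau_symp": 0.5,
        "PP_0": 1.5 * (SBP_NOMINAL - MAP_NOMINAL),
        "SV_0": 5.0 / HR_NOMINAL,
        "k_ino": 0.3, "k_veno": 0.7, "HR_min": 20.0, "u_max": 2.0,
    }
    return d


def _solve_anchored(d: dict, dt: float) -> dict:
    """Solve the three anchored defaults (see module docstring)."""
    from scipy.optimize import brentq
    from . import _kernel as K

    pdry = d["P_atm"] - d["P_H2O"]
    va_n = MV_NOMINAL * (1.0 - d["k_ds"])
    # PaCO2 fixed point on the metabolic hyperbola at nominal ventilation
    d["M_dCO2"] = (d["PaCO2_n"] - FICO2_NOMINAL * pdry) * va_n / K.K_GAS
    # alveolar air equation baseline
    d["PaO2_n"] = FIO2_NOMINAL * pdry - d["PaCO2_n"] / d["RQ"]
    # Hill exponent from the SpO2 anchor
    odds = SPO2_NOMINAL / (100.0 - SPO2_NOMINAL)
    d["gamma"] = math.log(odds) / math.log(d["PaO2_n"] / d["P_50"])

    # baseline respiratory effort from the tidal-volume anchor
    tv_target = MV_NOMINAL / d["RR_o"]
    vec = np.ones(I.N_PARAMS)
    for i, name in enumerate(LIVE_NAMES):
        vec[i] = d[name]

    def tv_of_pmin(pmin: float) -> float:
        p = vec.copy()
        p[I.PMM_O] = pmin
        n_steps = int(round(6.0 / (d["RR_o"] * dt)))  # six breath cycles
        x, cyc = _initial_state_vec(p)
        const = np.full(n_steps, 0.0)
        K.run_core(p, x, cyc, n_steps, dt, const, const, const, const,
                   np.zeros(n_steps, dtype=np.int8), const,
                   True, np.full(n_steps, d["PaO2_n"]),
                   np.full(n_steps, d["PaCO2_n"]),
                   max(1, n_steps), False, True)
        return cyc[I.C_TV] - tv_target

    d["P_mus_min_o"] = brentq(tv_of_pmin, -30.0, -0.1, xtol=1e-8)
    return d


def _initial_state_vec(p: np.ndarray):
    """Nominal initial continuous + cycle state for a parameter vector."""
    x = np.zeros(I.N_STATE)
    x[I.S_PAO2] = p[I.PAO2_N]
    x[I.S_PACO2] = p[I.PACO2_N]
    x[I.S_VV] = p[I.V_V0]
    x[I.S_VBLOOD] = p[I.V_BLOOD0]
    cyc = np.zeros(I.N_CYCLE)
    rr = p[I.RR_O]
    cyc[I.C_T] = 1.0 / rr
    cyc[I.C_TI] = 0.375 / rr
    cyc[I.C_RR] = rr
    cyc[I.C_PMIN] = p[I.PMM_O]
    frc = p[I.V_LLU] + p[I.V_RLU]
    cyc[I.C_VMIN] = frc
    cyc[I.C_VMAX] = frc
    # pre-seed last-cycle ventilation with the hyperbola-consistent value
    from . import _kernel as K
    va = K.K_GAS * p[I.M_DCO2] / max(p[I.PACO2_N], 1e-9)
    mv = va / max(1.0 - p[I.K_DS], 1e-9)
    cyc[I.C_MV] = mv
    cyc[I.C_TV] = mv / rr
    return x, cyc


class ParameterSet:
    """A named view over the flat 163-slot parameter vector."""

    def __init__(self, vector: np.ndarray):
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (I.N_PARAMS,):
            raise ValueError(
                f"parameter vector must have shape ({I.N_PARAMS},), "
                f"got {vector.shape}")
        self.vector = vector

    # -- construction -----------------------------------------------------
    @classmethod
    def default(cls, dt: float = DT_DEFAULT) -> "ParameterSet":
        global _DEFAULT_CACHE
        if _DEFAULT_CACHE is None:
            d = _solve_anchored(_base_defaults(), dt)
            vec = np.ones(I.N_PARAMS)
            for i, name in enumerate(LIVE_NAMES):
                vec[i] = d[name]
            _DEFAULT_CACHE = vec
        return cls(_DEFAULT_CACHE.copy())

    @classmethod
    def from_dict(cls, groups: dict) -> "ParameterSet":
        ps = cls.default()
        for group, entries in groups.items():
            if not isinstance(entries, dict):
                raise ValueError(f"group {group!r} must map names to values")
            for name, value in entries.items():
                ps[name] = float(value)
        return ps

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: parameter file must be a mapping")
        return cls.from_dict(data)

    # -- access -----------------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return float(self.vector[_INDEX[name]])

    def __setitem__(self, name: str, value: float) -> None:
        self.vector[_INDEX[name]] = value

    def __contains__(self, name: str) -> bool:
        return name in _INDEX

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.vector.copy())

    def perturbed(self, name: str, factor: float) -> "ParameterSet":
        """New set with one parameter multiplied by `factor`."""
        ps = self.copy()
        ps[name] = ps[name] * factor
        return ps

    def to_dict(self) -> dict:
        out = {}
        for group, names in GROUPS.items():
            out[group] = {n: self[n] for n in names}
        reserved = {n: self[n] for n in REGISTRY[I.FIRST_RESERVED:]
                    if self[n] != 1.0}
        if reserved:
            out["reserved"] = reserved
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Raise ValueError on structurally impossible parameter values."""
        checks = [
            ("tau_cR", self["tau_cR"] > 0), ("tau_cP", self["tau_cP"] > 0),
            ("tau_pR", self["tau_pR"] > 0), ("tau_pP", self["tau_pP"] > 0),
            ("RR_o", self["RR_o"] > 0),
            ("P_mus_min_o", self["P_mus_min_o"] <= 0),
            ("PaCO2_n", self["PaCO2_n"] > 0),
            ("gamma", self["gamma"] > 0), ("P_50", self["P_50"] > 0),
            ("k_ds", 0 <= self["k_ds"] < 1),
            ("V_Vu0", self["V_Vu0"] < self["V_V0"]),
        ]
        for name in ("R_ml0", "R_lt0", "R_tb0", "R_bll", "R_brl"):
            checks.append((name, self[name] > 0))
        for name in ("C_cw", "C_ll", "C_rl"):
            checks.append((name, self[name] > 0))
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ValueError(f"invalid parameter values: {', '.join(bad)}")

    def initial_state(self):
        return _initial_state_vec(self.vector)


_DEFAULT_CACHE: np.ndarray | None = None


def index_of(name: str) -> int:
    return _INDEX[name]
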