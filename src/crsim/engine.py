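"""Scenario definitions, fixed-step integration and steady-state start-up.

A :class:`Scenario` is a set of piecewise input schedules (inspired gas
fractions, airway-opening pressure, obstruction fraction, hemorrhage rate —
or prescribed arterial gases in open-loop mode) over a duration.  The engine
samples the schedules onto the integration grid, advances the model with
explicit Euler at a fixed step (default 4.17e-4 min) and logs decimated
output channels plus per-cycle ventilation aggregates.

The model has no stochastic terms: identical scenario and parameters yield
bit-identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _indices as I
from . import _kernel as K
from .params import (ParameterSet, DT_DEFAULT, FIO2_NOMINAL, FICO2_NOMINAL)

__all__ = [
    "Schedule", "Scenario", "TimeSeries", "SimulationResult", "SteadyState",
    "ConvergenceError", "BracketError", "ScheduleError",
    "initialize_steady_state", "run_scenario", "match_pao_to_target_mv",
    "scale_species_inputs",
]

#: default output decimation interval (min)
RECORD_INTERVAL = 0.01

CLOSED_LOOP_CHANNELS = ("fio2", "fico2", "pao", "fao", "hemorrhage_rate")
OPEN_LOOP_CHANNELS = ("pao2", "paco2", "pao", "fao", "hemorrhage_rate")

_DEFAULTS = {"fio2": FIO2_NOMINAL, "fico2": FICO2_NOMINAL, "pao": 0.0,
             "fao": 0.0, "hemorrhage_rate": 0.0}


class ScheduleError(ValueError):
    """Invalid or out-of-range scenario schedule."""


class ConvergenceError(RuntimeError):
    """Steady-state initialization failed to converge."""


class BracketError(RuntimeError):
    """Root bracketing failed for the airway-pressure match."""


@dataclass(frozen=True)
class Schedule:
    """Piecewise time course: sample-and-hold or piecewise-linear."""

    times: np.ndarray
    values: np.ndarray
    interp: str = "hold"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.shape != v.shape or t.size == 0:
            raise ScheduleError("times and values must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ScheduleError(
                "schedule breakpoints must be strictly increasing "
                "(overlapping segments)")
        if self.interp not in ("hold", "linear"):
            raise ScheduleError("interp must be 'hold' or 'linear'")

    @classmethod
    def constant(cls, value: float) -> "Schedule":
        return cls(times=np.array([0.0]), values=np.array([float(value)]))

    def sample(self, grid: np.ndarray) -> np.ndarray:
        if self.interp == "linear":
            return np.interp(grid, self.times, self.values)
        idx = np.searchsorted(self.times, grid, side="right") - 1
        idx = np.clip(idx, 0, self.times.size - 1)
        return self.values[idx]

    def to_dict(self) -> dict:
        return {"times": self.times.tolist(),
                "values": self.values.tolist(),
                "interp": self.interp}


@dataclass(frozen=True)
class Scenario:
    """Input protocol for one simulation run."""

    duration: float
    mode: str = "closed_loop"
    schedules: dict = field(default_factory=dict)
    fao_location: str = "ml"
    name: str = "scenario"
    species_scaling: dict | None = None

    def __post_init__(self):
        if self.duration <= 0:
            raise ScheduleError("duration must be positive")
        if self.mode not in ("closed_loop", "open_loop_gas"):
            raise ScheduleError(
                "mode must be 'closed_loop' or 'open_loop_gas'")
        if self.fao_location not in I.LOC_CODES:
            raise ScheduleError(f"unknown fao_location {self.fao_location!r}")
        allowed = (CLOSED_LOOP_CHANNELS if self.mode == "closed_loop"
                   else OPEN_LOOP_CHANNELS)
        for ch, sched in self.schedules.items():
            if ch not in allowed:
                raise ScheduleError(
                    f"channel {ch!r} not allowed in {self.mode} mode")
            if not isinstance(sched, Schedule):
                raise ScheduleError(f"schedule for {ch!r} must be a Schedule")
            if sched.times[0] < 0 or sched.times[-1] > self.duration:
                raise ScheduleError(
                    f"schedule for {ch!r} extends outside [0, duration]")
        if self.mode == "open_loop_gas":
            for ch in ("pao2", "paco2"):
                if ch not in self.schedules:
                    raise ScheduleError(
                        f"open-loop mode requires a {ch!r} schedule")
        for ch in ("fio2", "fico2", "fao"):
            if ch in self.schedules:
                v = self.schedules[ch].values
                if np.any(v < 0) or np.any(v > 1):
                    raise ScheduleError(f"{ch!r} values must lie in [0, 1]")

    def channel(self, name: str) -> Schedule:
        if name in self.schedules:
            return self.schedules[name]
        if name in _DEFAULTS:
            return Schedule.constant(_DEFAULTS[name])
        raise KeyError(name)

    def to_dict(self) -> dict:
        d = {"name": self.name, "mode": self.mode,
             "duration_min": self.duration,
             "fao_location": self.fao_location,
             "schedules": {ch: s.to_dict()
                           for ch, s in self.schedules.items()}}
        if self.species_scaling:
            d["species_scaling"] = dict(self.species_scaling)
        return d


@dataclass
class TimeSeries:
    """Uniform-grid multi-channel output with units."""

    frame: pd.DataFrame
    units: dict

    def channel(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    @property
    def time(self) -> np.ndarray:
        return self.frame["time_min"].to_numpy()

    def at(self, t: float, name: str) -> float:
        """Channel value at time t (linear interpolation on the grid)."""
        return float(np.interp(t, self.time, self.channel(name)))

    def plot(self, channels=("MV", "RR", "SpO2", "ETCO2", "MAP", "HR"),
             ax=None):
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(len(channels), 1, sharex=True,
                                 figsize=(8, 1.8 * len(channels)))
        axes = np.atleast_1d(axes)
        for a, ch in zip(axes, channels):
            a.plot(self.time, self.channel(ch), lw=1.0)
            a.set_ylabel(f"{ch}\n[{self.units.get(ch, '')}]")
        axes[-1].set_xlabel("time [min]")
        fig.tight_layout()
        return fig


@dataclass
class SimulationResult:
    timeseries: TimeSeries
    status: int
    n_cycles: int
    state: np.ndarray
    cycle_state: np.ndarray
    manifest: dict

    @property
    def status_name(self) -> str:
        return {I.STATUS_OK: "ok",
                I.STATUS_EXSANGUINATION: "exsanguination",
                I.STATUS_NONFINITE: "nonfinite",
                I.STATUS_NEGATIVE_VOLUME: "negative_volume"}[self.status]

    def final(self, name: str) -> float:
        return float(self.timeseries.frame[name].iloc[-1])


@dataclass
class SteadyState:
    """Converged nominal operating point of the closed loop."""

    state: np.ndarray
    cycle_state: np.ndarray
    outputs: dict
    n_cycles: int
    residual: float


def _outputs_from_state(p: np.ndarray, x: np.ndarray,
                        cyc: np.ndarray) -> dict:
    spo2 = K.hill_saturation(x[I.S_PAO2], p[I.GAMMA], p[I.P_50])
    fac = K.fac_eval(x[I.S_PAO2], x[I.S_PACO2], p)
    co, map_, sbp, dbp, hr, _ = K.cardio_eval(
        x[I.S_U], x[I.S_VV], x[I.S_VBLOOD], fac, p)
    return {
        "MV": cyc[I.C_MV], "RR": cyc[I.C_RR], "TV": cyc[I.C_TV],
        "PaO2": x[I.S_PAO2], "PaCO2": x[I.S_PACO2],
        "SpO2": spo2, "ETCO2": max(x[I.S_PACO2] - p[I.ETCO2_GRAD], 0.0),
        "f_ac": fac, "MAP": map_, "SBP": sbp, "DBP": dbp,
        "HR": hr, "CO": co,
    }


def initialize_steady_state(params: ParameterSet | None = None,
                            dt: float = DT_DEFAULT,
                            tol: float = 1e-6,
                            max_cycles: int = 10_000,
                            start: tuple | None = None,
                            waveform_mode: str = "continuous",
                            ode_form: str = "printed") -> SteadyState:
    """Iterate the closed loop at nominal inputs until cycle-to-cycle
    convergence of every tracked output.

    Nominal inputs: FiO2 = 21%, FiCO2 = 0%, P_ao = 0, F_ao = 0, zero
    hemorrhage.  Convergence: relative change across one respiratory cycle
    below ``tol`` for every tracked channel.  Raises
    :class:`ConvergenceError` with the final residual otherwise.
    """
    params = params or ParameterSet.default()
    params.validate()
    if start is None:
        x, cyc = params.initial_state()
    else:
        x, cyc = start[0].copy(), start[1].copy()
        # a reused state is one step past its last cycle rollover; rebasing
        # the cycle clock to -dt makes the restart an exact continuation
        cyc[I.C_TSTART] = -dt
    n_cycles, residual, status = K.run_steady(
        params.vector, x, cyc, dt, FIO2_NOMINAL, FICO2_NOMINAL,
        tol, max_cycles, waveform_mode == "literal", ode_form == "printed")
    if status != I.STATUS_OK:
        raise ConvergenceError(f"initialization aborted (status {status})")
    if residual >= tol:
        raise ConvergenceError(
            f"no convergence within {max_cycles} cycles; "
            f"worst per-channel relative residual {residual:.3e}")
    return SteadyState(state=x, cycle_state=cyc,
                       outputs=_outputs_from_state(params.vector, x, cyc),
                       n_cycles=n_cycles, residual=residual)


def _sample_inputs(scenario: Scenario, n_steps: int, dt: float):
    grid = np.arange(n_steps) * dt
    zeros = np.zeros(n_steps)
    pao = scenario.channel("pao").sample(grid)
    fao = scenario.channel("fao").sample(grid)
    hem = scenario.channel("hemorrhage_rate").sample(grid)
    loc = np.full(n_steps, I.LOC_CODES[scenario.fao_location], dtype=np.int8)
    if scenario.mode == "closed_loop":
        fio2 = scenario.channel("fio2").sample(grid)
        fico2 = scenario.channel("fico2").sample(grid)
        pao2 = zeros
        paco2 = zeros
        open_loop = False
    else:
        fio2 = zeros
        fico2 = zeros
        pao2 = scenario.schedules["pao2"].sample(grid)
        paco2 = scenario.schedules["paco2"].sample(grid)
        open_loop = True
    return fio2, fico2, pao, fao, loc, hem, open_loop, pao2, paco2


def _open_loop_start(params: ParameterSet, scenario: Scenario,
                     ode_form: str):
    """Start state for open-loop runs: reflex deviations at their closed-form
    steady values for the initial prescribed gases."""
    p = params.vector
    x, cyc = params.initial_state()
    pao2_0 = float(scenario.schedules["pao2"].values[0])
    paco2_0 = float(scenario.schedules["paco2"].values[0])
    x[I.S_PAO2] = pao2_0
    x[I.S_PACO2] = paco2_0
    fac = K.fac_eval(pao2_0, paco2_0, p)
    uc = paco2_0 - p[I.PACO2_N]
    up = fac - p[I.F_ACN]
    if ode_form == "printed":
        x[I.S_DRRC] = p[I.G_CR] * uc / p[I.TAU_CR]
        x[I.S_DRRP] = p[I.G_PR] * up / p[I.TAU_PR]
        x[I.S_DPMC] = p[I.G_CP] * uc / p[I.TAU_CP]
        x[I.S_DPMP] = p[I.G_PP] * up / p[I.TAU_PP]
    else:
        x[I.S_DRRC] = p[I.G_CR] * uc
        x[I.S_DRRP] = p[I.G_PR] * up
        x[I.S_DPMC] = p[I.G_CP] * uc
        x[I.S_DPMP] = p[I.G_PP] * up
    rr = max(p[I.RR_O] + x[I.S_DRRC] + x[I.S_DRRP], p[I.RR_FLOOR])
    pmin = min(p[I.PMM_O] + x[I.S_DPMC] + x[I.S_DPMP], 0.0)
    cyc[I.C_RR] = rr
    cyc[I.C_T] = 1.0 / rr
    cyc[I.C_TI] = 0.375 / rr
    cyc[I.C_PMIN] = pmin
    return x, cyc


def run_scenario(scenario: Scenario,
                 params: ParameterSet | None = None,
                 dt: float = DT_DEFAULT,
                 init: SteadyState | None = None,
                 record_interval: float = RECORD_INTERVAL,
                 full_rate: bool = False,
                 waveform_mode: str = "continuous",
                 ode_form: str = "printed",
                 seed: int | None = None) -> SimulationResult:
    """Integrate a scenario and return the decimated output time series.

    ``init`` may carry a pre-converged steady state (closed-loop mode); by
    default the engine initializes to the nominal steady state first.
    ``seed`` is accepted for manifest provenance only — the model itself is
    deterministic.
    """
    params = params or ParameterSet.default()
    params.validate()
    n_steps = int(round(scenario.duration / dt))
    if n_steps < 1:
        raise ScheduleError("duration shorter than one time step")
    inputs = _sample_inputs(scenario, n_steps, dt)
    open_loop = inputs[6]
    if open_loop:
        x, cyc = _open_loop_start(params, scenario, ode_form)
        cyc[I.C_TSTART] = 0.0
    else:
        if init is None:
            init = initialize_steady_state(params, dt=dt,
                                           waveform_mode=waveform_mode,
                                           ode_form=ode_form)
        x, cyc = init.state.copy(), init.cycle_state.copy()
        # continuation from a converged state: the state sits one step past
        # its last cycle rollover (see initialize_steady_state)
        cyc[I.C_TSTART] = -dt
    stride = 1 if full_rate else max(1, int(round(record_interval / dt)))
    rec, n_filled, n_cycles, status, _steps = K.run_core(
        params.vector, x, cyc, n_steps, dt, *inputs[:6],
        open_loop, inputs[7], inputs[8], stride,
        waveform_mode == "literal", ode_form == "printed")
    frame = pd.DataFrame(rec, columns=list(I.REC_CHANNELS))
    units = dict(zip(I.REC_CHANNELS, I.REC_UNITS))
    manifest = {
        "scenario": scenario.name,
        "scenario_sha1": _digest(repr(sorted(scenario.to_dict().items()))),
        "params_sha1": _digest(params.vector.tobytes()),
        "dt_min": dt,
        "seed": seed,
        "n_steps": n_steps,
        "status": status,
    }
    return SimulationResult(timeseries=TimeSeries(frame=frame, units=units),
                            status=status, n_cycles=n_cycles,
                            state=x, cycle_state=cyc, manifest=manifest)


def _digest(payload) -> str:
    if isinstance(payload, str):
        payload = payload.encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def match_pao_to_target_mv(target_mv: float,
                           params: ParameterSet | None = None,
                           bracket: tuple[float, float] = (0.0, 40.0),
                           tol: float = 0.05,
                           sim_minutes: float = 2.0,
                           dt: float = DT_DEFAULT,
                           init: SteadyState | None = None) -> float:
    """Find the constant inspiratory airway pressure that delivers a target
    minute ventilation (bisection to within ``tol`` L/min).

    Positive P_ao is applied during the inspiratory fraction of each breath
    cycle (ventilator insufflation).  If the spontaneous (P_ao = 0) MV
    already exceeds the target, or the top of the bracket cannot reach it,
    a :class:`BracketError` names the bracket — the actuation is one-sided.
    """
    if target_mv <= 0:
        raise ValueError("target_mv must be positive")
    params = params or ParameterSet.default()
    if init is None:
        init = initialize_steady_state(params, dt=dt)

    def mv_at(pao: float) -> float:
        scenario = Scenario(
            duration=sim_minutes, mode="closed_loop",
            schedules={"pao": Schedule.constant(pao)},
            name=f"pao_match_{pao:.3f}")
        res = run_scenario(scenario, params, dt=dt, init=init)
        return res.final("MV")

    lo, hi = bracket
    mv_lo = mv_at(lo)
    if abs(mv_lo - target_mv) <= tol:
        return lo
    if mv_lo > target_mv:
        raise BracketError(
            f"target MV {target_mv:.2f} L/min below the passive MV "
            f"{mv_lo:.2f} at P_ao={lo:g} (bracket {bracket}); "
            "positive-pressure actuation is one-sided")
    mv_hi = mv_at(hi)
    if mv_hi < target_mv - tol:
        raise BracketError(
            f"target MV {target_mv:.2f} L/min unreachable at P_ao={hi:g} "
            f"(achieved {mv_hi:.2f}; bracket {bracket})")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        mv_mid = mv_at(mid)
        if abs(mv_mid - target_mv) <= tol:
            return mid
        if mv_mid < target_mv:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def scale_species_inputs(hemorrhage_pct_BV: float, MV_animal: float,
                         animal_mass: float,
                         reference_mass: float = 70.0,
                         reference_blood_volume: float = 5.0,
                         ) -> tuple[float, float]:
    """Convert animal-study inputs to human-equivalent values.

    Hemorrhage percentage of blood volume maps onto the reference adult
    blood volume (5 L for 70 kg); minute ventilation scales by the mass
    ratio reference/animal.
    """
    if hemorrhage_pct_BV < 0:
        raise ValueError("hemorrhage percentage must be >= 0")
    if MV_animal <= 0 or animal_mass <= 0:
        raise ValueError("MV_animal and animal_mass must be positive")
    hemorrhage_volume = (hemorrhage_pct_BV / 100.0) * reference_blood_volume
    mv_human = MV_animal * (reference_mass / animal_mass)
    return hemorrhage_volume, mv_human
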