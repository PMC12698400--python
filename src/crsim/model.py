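"""High-level facade over the closed-loop simulator.

`CardioRespModel` bundles a parameter set with the integration settings and
exposes the operations a user strings together: steady-state initialization,
scenario simulation, ventilator pressure matching, and the one-at-a-time
sensitivity sweep over the full 163-slot parameter registry.
"""

from __future__ import annotations

import numpy as np

from .engine import (Scenario, SteadyState, SimulationResult,
                     initialize_steady_state, run_scenario,
                     match_pao_to_target_mv)
from .evaluation import SensitivityResult, local_sensitivity
from .params import ParameterSet, REGISTRY, DT_DEFAULT

__all__ = ["CardioRespModel", "SENSITIVITY_OUTPUTS"]

#: outputs analyzed by the sensitivity sweep: the four reported vital signs
#: plus the two intermediate respiratory outputs
SENSITIVITY_OUTPUTS = ("SpO2", "ETCO2", "SBP", "HR", "MV", "RR")


class CardioRespModel:
    """Closed-loop cardio-respiratory model with airway obstruction.

    Parameters
    ----------
    params
        Full parameter set; defaults to the anchored nominal set.
    dt
        Euler step in minutes (default 4.17e-4).
    waveform_mode
        'continuous' (default) or 'literal' inspiratory parabola.
    ode_form
        'printed' (default) or 'standard' chemoreflex ODE convention.
    """

    def __init__(self, params: ParameterSet | None = None,
                 dt: float = DT_DEFAULT,
                 waveform_mode: str = "continuous",
                 ode_form: str = "printed"):
        self.params = params or ParameterSet.default()
        self.dt = dt
        self.waveform_mode = waveform_mode
        self.ode_form = ode_form
        self._steady: SteadyState | None = None

    # -- core operations ---------------------------------------------------
    def initialize(self, force: bool = False, **kwargs) -> SteadyState:
        """Converge the closed loop at nominal inputs (cached)."""
        if self._steady is None or force or kwargs:
            self._steady = initialize_steady_state(
                self.params, dt=self.dt, waveform_mode=self.waveform_mode,
                ode_form=self.ode_form, **kwargs)
        return self._steady

    def simulate(self, scenario: Scenario, use_init: bool = True,
                 **kwargs) -> SimulationResult:
        init = self.initialize() if (use_init
                                     and scenario.mode == "closed_loop") \
            else None
        return run_scenario(scenario, self.params, dt=self.dt, init=init,
                            waveform_mode=self.waveform_mode,
                            ode_form=self.ode_form, **kwargs)

    def match_pao(self, target_mv: float, **kwargs) -> float:
        return match_pao_to_target_mv(target_mv, self.params,
                                      dt=self.dt, init=self.initialize(),
                                      **kwargs)

    # -- sensitivity analysis ----------------------------------------------
    def sensitivity(self, scenario: Scenario | None = None,
                    times=None, outputs=SENSITIVITY_OUTPUTS,
                    rel: float = 0.1) -> SensitivityResult:
        """±10% one-at-a-time sweep over all 163 registry slots.

        By default the scenario is the slow graded-obstruction protocol and
        the evaluation timepoints are the ends of its 0/25/50/75/100%
        phases.  Every perturbed run re-initializes the steady state with
        its own parameters before executing the protocol; the sweep costs
        2*163 + 1 = 327 simulations.
        """
        from .io import load_protocol
        if scenario is None:
            scenario = load_protocol("study7_slow")
        if times is None:
            times = obstruction_phase_ends(scenario)
        times = tuple(times)
        dt = self.dt
        wf, form = self.waveform_mode, self.ode_form

        def evaluate(p_vec) -> np.ndarray:
            ps = ParameterSet(np.asarray(p_vec, dtype=float).copy())
            ss = initialize_steady_state(ps, dt=dt, waveform_mode=wf,
                                         ode_form=form)
            res = run_scenario(scenario, ps, dt=dt, init=ss,
                               waveform_mode=wf, ode_form=form)
            ts = res.timeseries
            return np.array([[ts.at(t, ch) for t in times]
                             for ch in outputs])

        return local_sensitivity(evaluate, REGISTRY, self.params.vector,
                                 outputs, times, rel=rel)


def obstruction_phase_ends(scenario: Scenario) -> tuple:
    """End times of the constant-F_ao phases of an obstruction schedule."""
    sched = scenario.schedules.get("fao")
    if sched is None:
        return (scenario.duration,)
    ends = list(sched.times[1:]) + [scenario.duration]
    # the end of the final (release) segment is not a phase of interest if
    # the obstruction returns to zero there
    phases = [t for t, v in zip(ends, sched.values)]
    return tuple(phases[:5]) if len(phases) > 5 else tuple(phases)
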