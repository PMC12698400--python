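"""Synthetic "experimental study" generation.

Real validation studies of this kind report per-timepoint means and standard
errors of vital signs across a handful of subjects undergoing a scripted
perturbation (hypoxia/hypercapnia gas traces, graded airway obstruction,
hemorrhage).  No public time-series accompany them, so this module emulates
study-style observation tables from the simulator itself: per subject, the
chemoreflex parameters are jittered multiplicatively inside the calibration
box, the scenario is run, channels are sampled on an observation grid, and
i.i.d. Gaussian noise with per-channel standard deviation is added.  The
mean and SEM across subjects are aggregated exactly as a study report
would, and the ground-truth parameters are recorded so parameter
recovery can be tested.

Everything is reproducible under a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import SubjectRecord
from .engine import Scenario, Schedule, run_scenario
from .params import ParameterSet, CHEMOREFLEX_PARAMS, DT_DEFAULT

__all__ = ["SyntheticStudy", "StudyData", "generate_study",
           "study1_style_subjects", "make_calibration_subjects"]


@dataclass(frozen=True)
class SyntheticStudy:
    """Specification of a synthetic multi-subject study."""

    scenario: Scenario
    obs_times: np.ndarray
    channels: tuple = ("MV", "RR", "SpO2", "ETCO2", "MAP", "SBP", "HR")
    sigma: dict = field(default_factory=dict)   # per-channel noise SD
    n_subjects: int = 8
    jitter: float = 0.0   # multiplicative half-range on chemoreflex params
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "obs_times",
                           np.asarray(self.obs_times, dtype=float))
        for ch, s in self.sigma.items():
            if s < 0:
                raise ValueError(f"sigma[{ch!r}] must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= self.jitter < 0.5:
            raise ValueError("jitter must be in [0, 0.5) "
                             "(stays inside the 0.5-2x calibration box)")


@dataclass
class StudyData:
    """Aggregated observation table plus per-subject series and ground truth."""

    observations: pd.DataFrame      # time_min, channel, mean, sem, n
    per_subject: pd.DataFrame       # subject, time_min, channel, value
    truth: list                     # per-subject parameter dicts
    seed: int


def generate_study(spec: SyntheticStudy,
                   params: ParameterSet | None = None,
                   dt: float = DT_DEFAULT) -> StudyData:
    """Simulate all subjects of a synthetic study and aggregate mean/SEM."""
    base = params or ParameterSet.default()
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth = []
    for s in range(spec.n_subjects):
        ps = base.copy()
        jittered = {}
        for name in CHEMOREFLEX_PARAMS:
            factor = 1.0 + spec.jitter * rng.uniform(-1.0, 1.0)
            ps[name] = ps[name] * factor
            jittered[name] = ps[name]
        truth.append(jittered)
        try:
            res = run_scenario(spec.scenario, ps, dt=dt)
        except Exception as exc:
            raise RuntimeError(f"simulation failed for subject {s}") from exc
        ts = res.timeseries
        for ch in spec.channels:
            clean = np.interp(spec.obs_times, ts.time, ts.channel(ch))
            noise = rng.normal(0.0, spec.sigma.get(ch, 0.0),
                               size=clean.shape)
            for t, v in zip(spec.obs_times, clean + noise):
                rows.append((s, t, ch, v))
    per_subject = pd.DataFrame(
        rows, columns=["subject", "time_min", "channel", "value"])
    grouped = per_subject.groupby(["time_min", "channel"])["value"]
    obs = grouped.agg(["mean", "std", "count"]).reset_index()
    obs["sem"] = obs["std"] / np.sqrt(obs["count"])
    obs["sem"] = obs["sem"].fillna(0.0)
    observations = obs.rename(columns={"count": "n"})[
        ["time_min", "channel", "mean", "sem", "n"]]
    return StudyData(observations=observations, per_subject=per_subject,
                     truth=truth, seed=spec.seed)


def study1_style_subjects(n_subjects: int = 4, seed: int = 0,
                          duration: float = 16.0,
                          n_obs: int = 17) -> list:
    """Input traces emulating a progressive-hypoxia calibration study.

    Each subject sees a piecewise-linear PaO2 descent from normoxia
    (~100-140 mmHg) to a subject-specific hypoxic nadir (36-48 mmHg) and
    back, with mild PaCO2 drift in the 30-42 mmHg band — the input envelopes
    of a classic rebreathing-hypoxia protocol.  Returns (times, pao2, paco2,
    obs_times) tuples; observations are attached separately.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for s in range(n_subjects):
        nadir = rng.uniform(36.0, 48.0)
        top = rng.uniform(110.0, 141.0)
        start = rng.uniform(95.0, 105.0)
        co2_base = rng.uniform(31.0, 38.0)
        co2_swing = rng.uniform(-3.0, 4.0)
        t_in = np.array([0.0, 0.25 * duration, 0.55 * duration,
                         0.8 * duration, duration])
        pao2 = np.array([start, start, nadir, top, top])
        paco2 = np.array([co2_base, co2_base, co2_base + co2_swing,
                          co2_base, co2_base])
        obs_times = np.linspace(0.0, duration, n_obs)
        subjects.append((t_in, pao2, paco2, obs_times))
    return subjects


def make_calibration_subjects(truth_values: dict,
                              params: ParameterSet | None = None,
                              n_subjects: int = 4,
                              sigma_mv: float = 0.3,
                              seed: int = 0,
                              dt: float = DT_DEFAULT) -> list:
    """Build SubjectRecords whose observed MV comes from known parameters.

    The ground-truth chemoreflex values generate the noiseless MV response
    to each subject's gas trace; Gaussian noise with SD ``sigma_mv`` is
    added on the observation grid.  Used for parameter-recovery experiments.
    """
    base = params or ParameterSet.default()
    ps = base.copy()
    for name, v in truth_values.items():
        ps[name] = v
    rng = np.random.default_rng(seed)
    records = []
    for s, (t_in, pao2, paco2, obs_times) in enumerate(
            study1_style_subjects(n_subjects, seed=seed)):
        scenario = Scenario(
            duration=float(max(t_in[-1], obs_times[-1])),
            mode="open_loop_gas", name=f"truth_S{s + 1}",
            schedules={"pao2": Schedule(t_in, pao2, "linear"),
                       "paco2": Schedule(t_in, paco2, "linear")})
        res = run_scenario(scenario, ps, dt=dt)
        ts = res.timeseries
        clean = np.interp(obs_times, ts.time, ts.channel("MV"))
        noisy = clean + rng.normal(0.0, sigma_mv, size=clean.shape)
        records.append(SubjectRecord(
            name=f"S{s + 1}", input_times=t_in, pao2=pao2, paco2=paco2,
            obs_times=obs_times, observed_mv=noisy,
            baseline_mv=float(clean[0])))
    return records
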