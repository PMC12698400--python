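"""Latin-hypercube calibration of the eight chemoreflex parameters.

The four time constants and four gains of the central/peripheral chemoreflex
pathways are searched over a box of 0.5x to 2x their nominal values.  A
Latin Hypercube design of ``n_samples`` points (one sample per
equal-probability stratum in every dimension) is evaluated by simulating
each subject's prescribed arterial-gas trace open-loop, normalizing the
predicted minute ventilation to the subject's experimental baseline, and
scoring the sum over subjects of the RMSE against the observed series.  The
sample with the smallest summed RMSE becomes the nominal parameter set.

The module follows a Model/Results layout: :class:`ChemoreflexCalibration`
holds the data and the search specification; ``fit()`` returns a
:class:`CalibrationResults` carrying the selected parameters, per-subject
errors, the full sample ledger, and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .engine import Scenario, Schedule, run_scenario
from .evaluation import normalize_to_baseline, rmse
from .params import ParameterSet, CHEMOREFLEX_PARAMS, DT_DEFAULT

logger = logging.getLogger(__name__)

__all__ = ["SubjectRecord", "ChemoreflexCalibration", "CalibrationResults",
           "lhs_sample", "default_bounds"]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's open-loop input traces and observed minute ventilation."""

    name: str
    input_times: np.ndarray       # min
    pao2: np.ndarray              # mmHg, piecewise linear
    paco2: np.ndarray             # mmHg, piecewise linear
    obs_times: np.ndarray         # min, observation grid
    observed_mv: np.ndarray       # L/min
    baseline_mv: float | None = None

    def __post_init__(self):
        for attr in ("input_times", "pao2", "paco2", "obs_times",
                     "observed_mv"):
            object.__setattr__(self, attr,
                               np.asarray(getattr(self, attr), dtype=float))
        if self.obs_times.shape != self.observed_mv.shape:
            raise ValueError(f"{self.name}: observation grid mismatch")
        if self.baseline_mv is None:
            object.__setattr__(self, "baseline_mv", float(self.observed_mv[0]))
        if self.baseline_mv == 0:
            raise ValueError(f"{self.name}: baseline MV must be nonzero")

    @property
    def duration(self) -> float:
        return float(max(self.input_times[-1], self.obs_times[-1]))

    def scenario(self) -> Scenario:
        return Scenario(
            duration=self.duration, mode="open_loop_gas",
            name=f"subject_{self.name}",
            schedules={
                "pao2": Schedule(self.input_times, self.pao2, "linear"),
                "paco2": Schedule(self.input_times, self.paco2, "linear"),
            })


def default_bounds(params: ParameterSet | None = None,
                   lo: float = 0.5, hi: float = 2.0) -> dict:
    """Per-parameter search box: [lo, hi]-fold of the nominal values."""
    params = params or ParameterSet.default()
    out = {}
    for name in CHEMOREFLEX_PARAMS:
        nominal = params[name]
        a, b = sorted((lo * nominal, hi * nominal))
        out[name] = (a, b)
    return out


def lhs_sample(bounds: dict, n: int, seed: int) -> pd.DataFrame:
    """Latin Hypercube design over named parameter intervals.

    For every dimension the n samples occupy the n equal-probability strata
    exactly once.  Degenerate intervals (lo == hi) are held fixed with a
    warning.  Reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    degenerate = lo == hi
    if np.any(degenerate):
        warnings.warn(
            "degenerate bounds held fixed: "
            + ", ".join(np.array(names)[degenerate]))
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    samples = qmc.scale(unit, lo, np.where(degenerate, lo + 1.0, hi))
    samples[:, degenerate] = lo[degenerate]
    return pd.DataFrame(samples, columns=names)


class ChemoreflexCalibration:
    """Model object for the chemoreflex parameter search.

    Parameters
    ----------
    subjects
        Open-loop input traces and observed MV per subject.
    params
        Base parameter set providing the nominal values and everything
        outside the chemoreflex box.
    bounds
        Per-parameter (lo, hi); defaults to 0.5-2x nominal.
    """

    def __init__(self, subjects, params: ParameterSet | None = None,
                 bounds: dict | None = None, dt: float = DT_DEFAULT,
                 ode_form: str = "printed"):
        if not subjects:
            raise ValueError("at least one subject is required")
        self.subjects = list(subjects)
        self.params = params or ParameterSet.default()
        self.bounds = bounds or default_bounds(self.params)
        self.dt = dt
        self.ode_form = ode_form
        self._scenarios = [s.scenario() for s in self.subjects]

    # -- simulation --------------------------------------------------------
    def predict_subject(self, values: dict, subject_index: int,
                        normalized: bool = True) -> np.ndarray:
        """Predicted (optionally baseline-normalized) MV on the obs grid."""
        ps = self.params.copy()
        for name, v in values.items():
            ps[name] = v
        subject = self.subjects[subject_index]
        res = run_scenario(self._scenarios[subject_index], ps, dt=self.dt,
                           ode_form=self.ode_form)
        ts = res.timeseries
        pred = np.interp(subject.obs_times, ts.time, ts.channel("MV"))
        if not normalized:
            return pred
        baseline_sim = pred[0]
        return normalize_to_baseline(pred, subject.baseline_mv, baseline_sim)

    def score(self, values: dict) -> tuple[float, list]:
        """(summed RMSE, per-subject RMSEs) for one parameter set."""
        per_subject = []
        for i, subject in enumerate(self.subjects):
            try:
                pred = self.predict_subject(values, i)
                per_subject.append(rmse(pred, subject.observed_mv))
            except Exception as exc:  # scored as +inf, not fatal
                logger.warning("subject %s failed for %s: %s",
                               subject.name, values, exc)
                per_subject.append(np.inf)
        return float(np.sum(per_subject)), per_subject

    # -- fitting -----------------------------------------------------------
    def fit(self, n_samples: int = 10_000, seed: int = 17,
            design: pd.DataFrame | None = None) -> "CalibrationResults":
        """Evaluate the LHS design and return the argmin as the nominal set.

        Ties in the argmin are broken by first occurrence in sample order.
        ``design`` may supply a pre-built candidate table (columns = the
        eight parameter names), bypassing the internal LHS draw.
        """
        if design is None:
            design = lhs_sample(self.bounds, n_samples, seed)
        n = len(design)
        names = list(design.columns)
        objectives = np.empty(n)
        per_subject = np.empty((n, len(self.subjects)))
        for i in range(n):
            values = dict(zip(names, design.iloc[i].to_numpy()))
            total, per = self.score(values)
            objectives[i] = total
            per_subject[i] = per
        best = int(np.argmin(objectives))  # argmin keeps the first minimum
        ledger = design.copy()
        for j, s in enumerate(self.subjects):
            ledger[f"rmse_{s.name}"] = per_subject[:, j]
        ledger["total_rmse"] = objectives
        return CalibrationResults(
            model=self,
            params=dict(zip(names, design.iloc[best].to_numpy())),
            best_index=best,
            best_objective=float(objectives[best]),
            rmse_by_subject={s.name: float(per_subject[best, j])
                             for j, s in enumerate(self.subjects)},
            ledger=ledger, seed=seed, n_samples=n,
            n_simulations=n * len(self.subjects))


@dataclass
class CalibrationResults:
    """Selected nominal parameter set plus the full search ledger."""

    model: ChemoreflexCalibration
    params: dict
    best_index: int
    best_objective: float
    rmse_by_subject: dict
    ledger: pd.DataFrame
    seed: int
    n_samples: int
    n_simulations: int

    def as_parameter_set(self) -> ParameterSet:
        ps = self.model.params.copy()
        for name, v in self.params.items():
            ps[name] = v
        return ps

    def stratum_width(self, name: str) -> float:
        lo, hi = self.model.bounds[name]
        return (hi - lo) / self.n_samples

    def predict(self, subject_index: int) -> np.ndarray:
        return self.model.predict_subject(self.params, subject_index)

    def summary(self) -> str:
        lines = [
            "Chemoreflex calibration (Latin Hypercube search)",
            "=" * 56,
            f"samples: {self.n_samples}   subjects: "
            f"{len(self.model.subjects)}   simulations: "
            f"{self.n_simulations}   seed: {self.seed}",
            f"best sample: #{self.best_index}   "
            f"summed RMSE: {self.best_objective:.4f} L/min",
            "-" * 56,
            f"{'parameter':<14}{'value':>12}{'low':>12}{'high':>12}",
        ]
        for name, v in self.params.items():
            lo, hi = self.model.bounds[name]
            lines.append(f"{name:<14}{v:>12.5f}{lo:>12.5f}{hi:>12.5f}")
        lines.append("-" * 56)
        for name, r in self.rmse_by_subject.items():
            lines.append(f"RMSE {name:<16}{r:>10.4f} L/min")
        return "\n".join(lines)
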