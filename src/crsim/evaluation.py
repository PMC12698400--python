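"""Validation metrics and one-at-a-time local sensitivity analysis.

Validation compares baseline-normalized model predictions against observed
means via the root mean square error and the fraction of predictions lying
within two standard errors of the observed mean.  For total-obstruction
phases, where vital signs move too fast for pointwise comparison, the
maximum deviation from baseline inside a window around the release time
(2 min before to 1 min after) is extracted instead.

Local sensitivity of output i to parameter j at time t is the normalized
central difference

    S_ij(t) = (y_ij+(t) - y_ij-(t)) / (0.2 * y_i0(t))

for a +/-10% one-at-a-time perturbation; a registry of N parameters costs
exactly 2N + 1 simulations (one nominal).  Cells where the nominal output is
zero are flagged undefined and excluded from rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "normalize_to_baseline", "rmse", "sem_coverage",
    "extract_total_obstruction_response", "local_sensitivity",
    "SensitivityResult", "ValidationReport", "validate_channels",
]


def normalize_to_baseline(predicted, baseline_exp: float,
                          baseline_sim: float) -> np.ndarray:
    """Scale a predicted series by baseline_exp / baseline_sim.

    Maps the simulated baseline onto the experimental one so that series
    from subjects (or models) with different resting levels are comparable.
    """
    if baseline_sim == 0:
        raise ValueError("simulated baseline is zero; cannot normalize")
    return np.asarray(predicted, dtype=float) * (baseline_exp / baseline_sim)


def rmse(pred, obs) -> float:
    """Root mean square error between two equal-length series."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError(
            f"series must be equal-length and non-empty (got {p.shape} "
            f"vs {o.shape})")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def sem_coverage(pred, obs_mean, obs_sem) -> float:
    """Percentage of predictions within 2 SEM of the observed mean.

    The interval is closed: |pred - mean| <= 2*SEM counts as covered.
    """
    p = np.asarray(pred, dtype=float)
    m = np.asarray(obs_mean, dtype=float)
    s = np.asarray(obs_sem, dtype=float)
    if not (p.shape == m.shape == s.shape) or p.size == 0:
        raise ValueError("pred, obs_mean and obs_sem must be equal-length")
    if np.any(s < 0):
        raise ValueError("SEM values must be >= 0")
    covered = np.abs(p - m) <= 2.0 * s
    return 100.0 * float(np.count_nonzero(covered)) / p.size


def extract_total_obstruction_response(times, values, release_time: float,
                                       baseline: float,
                                       pre: float = 2.0,
                                       post: float = 1.0) -> float:
    """Largest-deviation value in the window around an obstruction release.

    Scans [release_time - pre, release_time + post] and returns the series
    value with maximal |value - baseline|; ties broken by earliest time.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    lo, hi = release_time - pre, release_time + post
    if lo < t[0] or hi > t[-1]:
        raise ValueError(
            f"window [{lo:g}, {hi:g}] outside series support "
            f"[{t[0]:g}, {t[-1]:g}]")
    mask = (t >= lo) & (t <= hi)
    dev = np.abs(v[mask] - baseline)
    return float(v[mask][int(np.argmax(dev))])


@dataclass
class SensitivityResult:
    """Full S_ij(t) matrix with ranking helpers."""

    S: np.ndarray                 # (n_outputs, n_params, n_times)
    outputs: tuple
    parameters: tuple
    times: tuple
    n_runs: int
    undefined: np.ndarray = field(default=None)  # bool mask where y0 == 0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (output, parameter, time, S)."""
        rows = []
        for i, out in enumerate(self.outputs):
            for j, par in enumerate(self.parameters):
                for k, t in enumerate(self.times):
                    rows.append((out, par, t, self.S[i, j, k]))
        return pd.DataFrame(rows,
                            columns=["output", "parameter", "time_min", "S"])

    def ranking(self, output: str, time: float) -> pd.DataFrame:
        """Parameters ordered by |S| (descending) for one output/time."""
        i = self.outputs.index(output)
        k = _closest(self.times, time)
        s = self.S[i, :, k]
        df = pd.DataFrame({"parameter": self.parameters, "S": s})
        df = df[np.isfinite(df["S"])]
        return (df.reindex(df["S"].abs().sort_values(ascending=False).index)
                .reset_index(drop=True))

    def top(self, output: str, time: float, k: int = 2) -> pd.DataFrame:
        return self.ranking(output, time).head(k)

    def value(self, output: str, parameter: str, time: float) -> float:
        i = self.outputs.index(output)
        j = self.parameters.index(parameter)
        return float(self.S[i, j, _closest(self.times, time)])


def _closest(times, t) -> int:
    arr = np.asarray(times, dtype=float)
    return int(np.argmin(np.abs(arr - t)))


def local_sensitivity(evaluate, parameters, p0,
                      outputs, times, rel: float = 0.1) -> SensitivityResult:
    """One-at-a-time central-difference sensitivities over a registry.

    ``evaluate(p_vector) -> (n_outputs, n_times) array`` runs the model;
    every parameter is perturbed by +/-``rel`` of its nominal value, for
    ``2*len(parameters) + 1`` evaluations in total.
    """
    p0 = np.asarray(p0, dtype=float)
    parameters = tuple(parameters)
    outputs = tuple(outputs)
    times = tuple(times)
    y0 = np.asarray(evaluate(p0), dtype=float)
    if y0.shape != (len(outputs), len(times)):
        raise ValueError(
            f"evaluate must return shape {(len(outputs), len(times))}, "
            f"got {y0.shape}")
    n_runs = 1
    S = np.empty((len(outputs), len(parameters), len(times)))
    undefined = np.zeros_like(S, dtype=bool)
    for j in range(len(parameters)):
        p_hi = p0.copy()
        p_hi[j] = p0[j] * (1.0 + rel)
        p_lo = p0.copy()
        p_lo[j] = p0[j] * (1.0 - rel)
        y_hi = np.asarray(evaluate(p_hi), dtype=float)
        y_lo = np.asarray(evaluate(p_lo), dtype=float)
        n_runs += 2
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (y_hi - y_lo) / (2.0 * rel * y0)
        bad = y0 == 0.0
        s[bad] = np.nan
        undefined[:, j, :] = bad
        S[:, j, :] = s
    return SensitivityResult(S=S, outputs=outputs, parameters=parameters,
                             times=times, n_runs=n_runs, undefined=undefined)


@dataclass
class ValidationReport:
    """Per-channel RMSE and 2-SEM coverage, mirroring a study-table layout."""

    table: pd.DataFrame     # columns: channel, rmse, coverage_pct, n_points
    units: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["channel          RMSE        2-SEM coverage   n",
                 "-" * 50]
        for _, row in self.table.iterrows():
            unit = self.units.get(row["channel"], "")
            lines.append(
                f"{row['channel']:<14} {row['rmse']:>8.3f} {unit:<8} "
                f"{row['coverage_pct']:>6.1f} %   {int(row['n_points']):>4}")
        return "\n".join(lines)


def validate_channels(pred: pd.DataFrame, obs: pd.DataFrame,
                      channels=None, units=None) -> ValidationReport:
    """Compare aligned prediction and observation tables channel by channel.

    ``pred`` columns: time plus one column per channel; ``obs`` long format
    with columns (time_min, channel, mean, sem).  Predictions are
    interpolated onto the observation grid per channel.
    """
    rows = []
    channels = channels or sorted(set(obs["channel"]))
    for ch in channels:
        sub = obs[obs["channel"] == ch]
        if ch not in pred.columns or sub.empty:
            continue
        p = np.interp(sub["time_min"].to_numpy(),
                      pred["time_min"].to_numpy(), pred[ch].to_numpy())
        m = sub["mean"].to_numpy()
        s = sub["sem"].to_numpy()
        rows.append((ch, rmse(p, m), sem_coverage(p, m, s), len(sub)))
    return ValidationReport(
        table=pd.DataFrame(
            rows, columns=["channel", "rmse", "coverage_pct", "n_points"]),
        units=units or {})
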