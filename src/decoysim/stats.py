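"""Stationary statistics from simulated trajectories.

All moment estimators are time-weighted (occupation-measure) rather than
event-sampled: event sampling over-weights fast-switching states.  Standard
errors are computed across replicates only; each replicate contributes one
time-averaged value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError
from .ssa import Trajectory


@dataclass(frozen=True)
class MomentSummary:
    """Across-replicate stationary moments per species."""

    labels: tuple[str, ...]
    mean: np.ndarray
    variance: np.ndarray
    fano: np.ndarray
    se_mean: np.ndarray
    se_fano: np.ndarray
    n_replicates: int
    replicate_means: np.ndarray       # (n_replicates, n_species)
    replicate_variances: np.ndarray

    def __getitem__(self, label: str) -> dict[str, float]:
        i = self.labels.index(label)
        return {"mean": float(self.mean[i]), "variance": float(self.variance[i]),
                "fano": float(self.fano[i]), "se_mean": float(self.se_mean[i]),
                "se_fano": float(self.se_fano[i])}


@dataclass(frozen=True)
class AutocorrelationCurve:
    """Stationary autocorrelation R(τ) averaged across replicates."""

    lags: np.ndarray
    r: np.ndarray
    se: np.ndarray
    dt: float
    n_replicates: int

    def at(self, tau: float) -> tuple[float, float]:
        """(R, SE) at the grid lag closest to ``tau``."""
        i = int(np.argmin(np.abs(self.lags - tau)))
        return float(self.r[i]), float(self.se[i])


def time_weighted_moments(times: Sequence[float], values: Sequence[float],
                          t_end: float, burn_in: float = 0.0
                          ) -> tuple[float, float]:
    """Exact mean and variance of a piecewise-constant path.

    ``values[i]`` holds on ``[times[i], times[i+1])``; the last value holds
    until ``t_end``.  Statistics are over ``[burn_in, t_end]``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or values.shape != times.shape:
        raise InvalidParameterError("times and values must be matching 1-D arrays")
    if not t_end > burn_in:
        raise InvalidParameterError("empty averaging window")
    edges = np.append(times, t_end)
    lo = np.maximum(edges[:-1], burn_in)
    hi = np.minimum(edges[1:], t_end)
    w = np.clip(hi - lo, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise InvalidParameterError("path does not cover the averaging window")
    mean = float(np.dot(w, values) / total)
    second = float(np.dot(w, values * values) / total)
    return mean, second - mean * mean


def stationary_moments(trajectories: Trajectory | Sequence[Trajectory]
                       ) -> MomentSummary:
    """Aggregate time-weighted moments across one or more replicates.

    Standard errors are the across-replicate standard deviation over √n and
    are zero when only a single replicate is supplied.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    trajectories = list(trajectories)
    if not trajectories:
        raise InvalidParameterError("no trajectories supplied")
    labels = trajectories[0].labels
    for tr in trajectories:
        if tr.labels != labels:
            raise InvalidParameterError("replicates have mismatched species")
    means = np.array([tr.means() for tr in trajectories])
    variances = np.array([tr.variances() for tr in trajectories])
    with np.errstate(divide="ignore", invalid="ignore"):
        fanos = np.where(means > 0, variances / means, np.nan)
    n = len(trajectories)
    mean = means.mean(axis=0)
    variance = variances.mean(axis=0)
    fano = np.nanmean(fanos, axis=0)
    if n >= 2:
        se_mean = means.std(axis=0, ddof=1) / np.sqrt(n)
        se_fano = np.nanstd(fanos, axis=0, ddof=1) / np.sqrt(n)
    else:
        se_mean = np.zeros_like(mean)
        se_fano = np.zeros_like(mean)
    return MomentSummary(labels=labels, mean=mean, variance=variance,
                         fano=fano, se_mean=se_mean, se_fano=se_fano,
                         n_replicates=n, replicate_means=means,
                         replicate_variances=variances)


def _single_autocorrelation(samples: np.ndarray, max_lag_steps: int
                            ) -> np.ndarray:
    """Biased (1/n) stationary autocorrelation of one sample series."""
    x = samples.astype(float)
    x = x - x.mean()
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f))[: max_lag_steps + 1] / n
    if acov[0] <= 0:
        raise InvalidParameterError("constant series has no autocorrelation")
    return acov / acov[0]


def autocorrelation(trajectories: Trajectory | Sequence[Trajectory],
                    max_lag: float, species: str = "x_f"
                    ) -> AutocorrelationCurve:
    """Stationary autocorrelation of one species from grid-sampled replicates.

    Each replicate is mean-subtracted and normalized by its own lag-0
    variance (the stationary definition), then curves are averaged.  Samples
    before the trajectory's burn-in are discarded.  ``max_lag`` must not
    exceed a fifth of the post-burn-in window.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    trajectories = list(trajectories)
    if not trajectories:
        raise InvalidParameterError("no trajectories supplied")
    first = trajectories[0]
    if first.grid_states is None:
        raise InvalidParameterError("autocorrelation requires grid-sampled trajectories")
    dt = first.grid_dt
    idx = first.labels.index(species)
    if max_lag > (first.t_end - first.burn_in) / 5:
        raise InvalidParameterError(
            "max_lag must be at most (t_end - burn_in)/5 for a stable estimate")
    lag_steps = int(round(max_lag / dt))
    curves = []
    for tr in trajectories:
        if tr.grid_states is None or tr.grid_dt != dt:
            raise InvalidParameterError("replicates must share the sampling grid")
        start = int(np.ceil(tr.burn_in / dt))
        samples = tr.grid_states[start:, idx]
        if samples.size <= 2 * lag_steps:
            raise InvalidParameterError("insufficient samples for the requested lag")
        curves.append(_single_autocorrelation(samples, lag_steps))
    curves = np.array(curves)
    n = curves.shape[0]
    r = curves.mean(axis=0)
    se = (curves.std(axis=0, ddof=1) / np.sqrt(n) if n >= 2
          else np.zeros_like(r))
    return AutocorrelationCurve(lags=np.arange(lag_steps + 1) * dt, r=r,
                                se=se, dt=dt, n_replicates=n)


def noise_propagation_ratio(summary: MomentSummary) -> tuple[float, float]:
    """Fano(y) / Fano(x_f) with a propagated standard error.

    Measures how strongly upstream TF fluctuations are transmitted to the
    downstream target protein.
    """
    for needed in ("x_f", "y"):
        if needed not in summary.labels:
            raise InvalidParameterError(f"summary lacks species {needed!r}")
    fx = summary["x_f"]
    fy = summary["y"]
    if fx["fano"] <= 0 or fy["fano"] <= 0:
        raise InvalidParameterError("Fano factors must be positive")
    ratio = fy["fano"] / fx["fano"]
    rel = np.sqrt((fy["se_fano"] / fy["fano"]) ** 2
                  + (fx["se_fano"] / fx["fano"]) ** 2)
    return ratio, ratio * rel


def flux_balance(summary: MomentSummary, model) -> dict[str, float]:
    """Stationary first-moment balance: production vs. mean degradation flux.

    At stationarity the exact identity k_x ⟨B_x⟩ = gamma_f ⟨x_f⟩ +
    gamma_b Σ ⟨x_bi⟩ holds (binding and unbinding conserve total TF).
    Returns the production rate, the estimated drain and its SE.
    """
    production = model.k_x * model.burst.mean
    weights = np.zeros(len(summary.labels))
    weights[0] = model.gamma_f
    for i in range(model.n_decoys):
        weights[1 + i] = model.gamma_b
    drains = summary.replicate_means @ weights
    n = summary.n_replicates
    se = drains.std(ddof=1) / np.sqrt(n) if n >= 2 else 0.0
    return {"production": production, "drain": float(drains.mean()),
            "se": float(se)}
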