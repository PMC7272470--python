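"""Exact stochastic simulation (Gillespie direct method) of the jump process.

Species order in the state vector: free TF ``x_f`` first, then one entry per
decoy species (``x_b`` or ``x_b1``, ``x_b2``), then the target protein ``y``
if present.  Channels (at most nine): TF burst; per decoy species binding,
unbinding, bound-TF degradation; free-TF degradation; target burst; target
degradation.  Burst sizes are drawn by inverse CDF from the tabulated pmf.

The inner loop is compiled with numba when available.  It accumulates exact
time-weighted first and second moments over the post-burn-in window and the
time integral of every propensity (for flux-balance and channel-count
checks), so stationary statistics need no stored path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidParameterError
from .lna import deterministic_fixed_point
from .model import TFDecoyModel

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func
        return wrap

#: longest horizon (in units of 1/gamma_f) allowed for event-resolution storage
_EVENT_STORAGE_HORIZON = 1e3


@njit(cache=True)
def _ssa_core(seed, t_end, burn_in,
              kx, bx_sizes, bx_cdf,
              gf, gb,
              n_dec, N_arr, kb_arr, ku_arr,
              has_y, ky, gy, by_sizes, by_cdf,
              x_init,
              grid_dt, n_grid,
              record_events, max_events):
    np.random.seed(seed)
    ns = x_init.shape[0]
    x = x_init.copy()
    n_chan = 2 + 3 * n_dec + (2 if has_y else 0)
    prop = np.zeros(n_chan)
    counts = np.zeros(n_chan, dtype=np.int64)
    prop_integral = np.zeros(n_chan)
    S1 = np.zeros(ns)
    S2 = np.zeros(ns)
    grid = np.zeros((n_grid, ns), dtype=np.int64)
    ev_t = np.zeros(max_events)
    ev_x = np.zeros((max_events, ns), dtype=np.int64)
    n_rec = 0
    gi = 0
    t = 0.0
    total_events = 0
    absorbed = False

    while t < t_end:
        c = 1
        prop[0] = kx
        for d in range(n_dec):
            xb = x[1 + d]
            prop[c] = kb_arr[d] * x[0] * (N_arr[d] - xb)
            prop[c + 1] = ku_arr[d] * xb
            prop[c + 2] = gb * xb
            c += 3
        prop[c] = gf * x[0]
        c += 1
        if has_y:
            prop[c] = ky * x[0]
            prop[c + 1] = gy * x[ns - 1]

        total = 0.0
        for j in range(n_chan):
            total += prop[j]
        if total <= 0.0:
            absorbed = True
            t_next = t_end
        else:
            u1 = np.random.random()
            t_next = t + (-np.log(1.0 - u1) / total)

        t_stop = t_next if t_next < t_end else t_end
        # grid samples in [t, t_stop): piecewise-constant state
        while gi < n_grid and gi * grid_dt < t_stop:
            for s in range(ns):
                grid[gi, s] = x[s]
            gi += 1
        # exact occupation-measure sums over the overlap with [burn_in, t_end]
        lo = t if t > burn_in else burn_in
        if t_stop > lo:
            w = t_stop - lo
            for s in range(ns):
                S1[s] += w * x[s]
                S2[s] += w * x[s] * x[s]
        w_full = t_stop - t
        for j in range(n_chan):
            prop_integral[j] += w_full * prop[j]

        if absorbed or t_next >= t_end:
            t = t_end
            break

        r = np.random.random() * total
        acc = 0.0
        ch = n_chan - 1
        for j in range(n_chan):
            acc += prop[j]
            if r < acc:
                ch = j
                break

        if ch == 0:
            u = np.random.random()
            idx = np.searchsorted(bx_cdf, u, side='right')
            if idx >= bx_sizes.shape[0]:
                idx = bx_sizes.shape[0] - 1
            x[0] += bx_sizes[idx]
        else:
            c = 1
            handled = False
            for d in range(n_dec):
                if ch == c:
                    x[0] -= 1
                    x[1 + d] += 1
                    handled = True
                elif ch == c + 1:
                    x[0] += 1
                    x[1 + d] -= 1
                    handled = True
                elif ch == c + 2:
                    x[1 + d] -= 1
                    handled = True
                c += 3
                if handled:
                    break
            if not handled:
                if ch == c:
                    x[0] -= 1
                elif ch == c + 1:
                    u = np.random.random()
                    idx = np.searchsorted(by_cdf, u, side='right')
                    if idx >= by_sizes.shape[0]:
                        idx = by_sizes.shape[0] - 1
                    x[ns - 1] += by_sizes[idx]
                else:
                    x[ns - 1] -= 1

        counts[ch] += 1
        total_events += 1
        t = t_next
        if record_events and n_rec < max_events:
            ev_t[n_rec] = t
            for s in range(ns):
                ev_x[n_rec, s] = x[s]
            n_rec += 1

    while gi < n_grid:
        for s in range(ns):
            grid[gi, s] = x[s]
        gi += 1

    return (grid, ev_t, ev_x, n_rec, total_events, counts, prop_integral,
            S1, S2, x, absorbed)


@dataclass
class Trajectory:
    """One exact sample path of the jump process.

    Grid samples (if requested) are left-continuous piecewise-constant
    snapshots at times ``k * grid_dt``.  ``weighted_sum`` / ``weighted_sq_sum``
    are exact time integrals of x and x² over ``[burn_in, t_end]``, so
    ``weighted_sum / window`` is the time-weighted stationary mean.
    """

    model: TFDecoyModel
    seed: int
    t_end: float
    burn_in: float
    labels: tuple[str, ...]
    initial_state: np.ndarray
    final_state: np.ndarray
    n_events: int
    channel_counts: np.ndarray
    channel_integrated_propensity: np.ndarray
    weighted_sum: np.ndarray
    weighted_sq_sum: np.ndarray
    absorbed: bool
    grid_dt: Optional[float] = None
    grid_states: Optional[np.ndarray] = None
    event_times: Optional[np.ndarray] = None
    event_states: Optional[np.ndarray] = None

    @property
    def window(self) -> float:
        return self.t_end - self.burn_in

    def means(self) -> np.ndarray:
        """Time-weighted stationary means over the post-burn-in window."""
        return self.weighted_sum / self.window

    def variances(self) -> np.ndarray:
        m = self.means()
        return self.weighted_sq_sum / self.window - m * m

    def grid_times(self) -> np.ndarray:
        if self.grid_states is None:
            raise InvalidParameterError("trajectory was not grid-sampled")
        return np.arange(self.grid_states.shape[0]) * self.grid_dt


def _channel_labels(model: TFDecoyModel) -> list[str]:
    labels = ["tf_burst"]
    for i in range(model.n_decoys):
        suffix = "" if model.n_decoys == 1 else str(i + 1)
        labels += [f"bind{suffix}", f"unbind{suffix}", f"bound_degradation{suffix}"]
    labels.append("free_degradation")
    if model.target is not None:
        labels += ["target_burst", "target_degradation"]
    return labels


def default_initial_state(model: TFDecoyModel) -> np.ndarray:
    """Rounded deterministic fixed point (shortens burn-in)."""
    return np.round(deterministic_fixed_point(model)).astype(np.int64)


def simulate(model: TFDecoyModel, t_end: float, seed: int,
             sampling: str = "none", grid_dt: Optional[float] = None,
             burn_in: Optional[float] = None,
             initial_state: Optional[Sequence[int]] = None,
             max_events: int = 2_000_000) -> Trajectory:
    """Run one exact Gillespie realization.

    Parameters
    ----------
    sampling
        ``"none"`` (moment accumulators only), ``"grid"`` (uniform snapshots
        every ``grid_dt``, default 0.02/gamma_f) or ``"events"`` (store every
        event; limited to t_end <= 1e3/gamma_f and ``max_events`` records).
    burn_in
        Time excluded from the stationary accumulators; default 10/gamma_f.
    initial_state
        Molecule counts at t=0; defaults to the rounded deterministic
        fixed point.  Pass zeros to start from an empty cell.
    seed
        Any non-negative integer < 2**32; identical (model, t_end, seed,
        sampling) arguments reproduce the event sequence bit for bit.
    """
    if not t_end > 0:
        raise InvalidParameterError("t_end must be positive")
    if burn_in is None:
        burn_in = 10.0 / model.gamma_f
    if burn_in >= t_end:
        raise InvalidParameterError("burn_in must be smaller than t_end")

    if sampling == "grid":
        if grid_dt is None:
            grid_dt = 0.02 / model.gamma_f
        n_grid = int(np.floor(t_end / grid_dt)) + 1
        record_events = False
    elif sampling == "events":
        if t_end > _EVENT_STORAGE_HORIZON / model.gamma_f:
            raise InvalidParameterError(
                "event-resolution storage is limited to t_end <= 1e3/gamma_f; "
                "use grid sampling for long runs")
        grid_dt, n_grid = 1.0, 0
        record_events = True
    elif sampling == "none":
        grid_dt, n_grid = 1.0, 0
        record_events = False
    else:
        raise InvalidParameterError(f"unknown sampling mode {sampling!r}")

    if initial_state is None:
        x0 = default_initial_state(model)
    else:
        x0 = np.asarray(initial_state, dtype=np.int64)
        if x0.shape != (model.n_species,):
            raise InvalidParameterError("initial state has wrong dimension")
        if np.any(x0 < 0):
            raise InvalidParameterError("initial counts must be non-negative")
    for i, d in enumerate(model.decoys):
        if x0[1 + i] > d.N:
            raise InvalidParameterError("initial bound count exceeds site number")

    n_dec = model.n_decoys
    pad = max(n_dec, 1)
    N_arr = np.zeros(pad, dtype=np.int64)
    kb_arr = np.zeros(pad)
    ku_arr = np.zeros(pad)
    for i, d in enumerate(model.decoys):
        N_arr[i], kb_arr[i], ku_arr[i] = d.N, d.k_b, d.k_u

    if model.target is not None:
        has_y, ky, gy = True, model.target.k_y, model.target.gamma_y
        by_sizes = model.target.burst.support.astype(np.int64)
        by_cdf = model.target.burst.cdf
    else:
        has_y, ky, gy = False, 0.0, 0.0
        by_sizes = np.array([0], dtype=np.int64)
        by_cdf = np.array([1.0])

    (grid, ev_t, ev_x, n_rec, total_events, counts, prop_int, S1, S2,
     x_final, absorbed) = _ssa_core(
        np.uint32(seed % (2 ** 32)), float(t_end), float(burn_in),
        float(model.k_x), model.burst.support.astype(np.int64),
        model.burst.cdf,
        float(model.gamma_f), float(model.gamma_b),
        n_dec, N_arr, kb_arr, ku_arr,
        has_y, float(ky), float(gy), by_sizes, by_cdf,
        x0,
        float(grid_dt), int(n_grid),
        record_events, int(max_events))

    return Trajectory(
        model=model, seed=int(seed), t_end=float(t_end), burn_in=float(burn_in),
        labels=model.species_labels,
        initial_state=x0, final_state=x_final,
        n_events=int(total_events),
        channel_counts=counts,
        channel_integrated_propensity=prop_int,
        weighted_sum=S1, weighted_sq_sum=S2,
        absorbed=bool(absorbed),
        grid_dt=grid_dt if sampling == "grid" else None,
        grid_states=grid if sampling == "grid" else None,
        event_times=ev_t[:n_rec] if record_events else None,
        event_states=ev_x[:n_rec] if record_events else None)


def simulate_replicates(model: TFDecoyModel, t_end: float, n_replicates: int,
                        seed: int, **kwargs) -> list[Trajectory]:
    """Independent replicates with seeds ``seed + 0, ..., seed + n - 1``."""
    if n_replicates < 1:
        raise InvalidParameterError("need at least one replicate")
    return [simulate(model, t_end, seed + r, **kwargs)
            for r in range(n_replicates)]
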