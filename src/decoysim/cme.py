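"""Brute-force steady state of the chemical master equation on a truncated box.

Intended as a ground-truth oracle for tiny models: the joint probability
over (x_f, x_b..., y) is solved exactly on a finite box by a sparse linear
solve of the truncated generator's null space.  Transitions that would
leave the box (burst jumps past x_max or y_max) are dropped; the stationary
probability flux they would have carried is reported as the leak estimate,
which must stay below 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .errors import InvalidParameterError, NumericalError, TruncationError
from .model import TFDecoyModel

_MAX_STATES = 250_000
_LEAK_TOL = 1e-6


@dataclass(frozen=True)
class TruncatedDistribution:
    """Exact steady state of the truncated CME."""

    labels: tuple[str, ...]
    shape: tuple[int, ...]
    p: np.ndarray                 # joint probabilities, reshaped to ``shape``
    leak: float                   # fraction of stationary event flux leaving the box
    mean: np.ndarray
    variance: np.ndarray
    fano: np.ndarray

    def marginal(self, species: str) -> np.ndarray:
        i = self.labels.index(species)
        axes = tuple(k for k in range(len(self.shape)) if k != i)
        return self.p.sum(axis=axes)

    def __getitem__(self, label: str) -> dict[str, float]:
        i = self.labels.index(label)
        return {"mean": float(self.mean[i]), "variance": float(self.variance[i]),
                "fano": float(self.fano[i])}


def cme_steady_state(model: TFDecoyModel, x_max: int,
                     y_max: int | None = None) -> TruncatedDistribution:
    """Solve the stationary truncated CME exactly.

    The state space is the box x_f <= x_max, x_bi <= N_i (and y <= y_max if
    the model has a target gene).  Burst pmfs are used in full; jump mass
    beyond the box is dropped and tracked as leak.  Raises
    :class:`TruncationError` when the leak exceeds 1e-6.
    """
    if x_max < 1:
        raise InvalidParameterError("x_max must be at least 1")
    dims = [x_max + 1] + [d.N + 1 for d in model.decoys]
    if model.target is not None:
        if y_max is None:
            raise InvalidParameterError("model has a target gene: y_max is required")
        dims.append(y_max + 1)
    shape = tuple(dims)
    n_states = int(np.prod(shape))
    if n_states > _MAX_STATES:
        raise InvalidParameterError(
            f"truncated state space has {n_states} states (limit {_MAX_STATES})")

    strides = np.ones(len(shape), dtype=np.int64)
    for i in range(len(shape) - 2, -1, -1):
        strides[i] = strides[i + 1] * shape[i + 1]

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(n_states)
    out_rate = np.zeros(n_states)    # rate of dropped (out-of-box) transitions
    total_rate = np.zeros(n_states)

    grids = np.meshgrid(*[np.arange(d) for d in shape], indexing="ij")
    coords = [g.ravel() for g in grids]   # per-species counts for every state
    index = np.arange(n_states)

    def add_channel(rate: np.ndarray, shift: np.ndarray) -> None:
        """Add one jump channel with per-state rates and a fixed jump vector."""
        active = rate > 0
        if not np.any(active):
            return
        total_rate[index[active]] += rate[active]
        new_coords = [coords[i][active] + shift[i] for i in range(len(shape))]
        inside = np.ones(active.sum(), dtype=bool)
        for i, nc in enumerate(new_coords):
            inside &= (nc >= 0) & (nc < shape[i])
        src = index[active]
        r = rate[active]
        out_rate[src[~inside]] += r[~inside]
        if np.any(inside):
            dst = np.zeros(inside.sum(), dtype=np.int64)
            for i, nc in enumerate(new_coords):
                dst += nc[inside] * strides[i]
            rows.append(dst)
            cols.append(src[inside])
            vals.append(r[inside])
            np.add.at(diag, src[inside], r[inside])

    xf = coords[0].astype(float)
    # TF bursts: one channel per burst size with positive probability
    for size, prob in zip(model.burst.support, model.burst.pmf):
        if size == 0:
            continue  # no state change
        shift = np.zeros(len(shape), dtype=np.int64)
        shift[0] = size
        add_channel(np.full(n_states, model.k_x * prob), shift)
    # free TF degradation
    shift = np.zeros(len(shape), dtype=np.int64)
    shift[0] = -1
    add_channel(model.gamma_f * xf, shift)
    for i, d in enumerate(model.decoys):
        bi = 1 + i
        xb = coords[bi].astype(float)
        shift = np.zeros(len(shape), dtype=np.int64)
        shift[0], shift[bi] = -1, +1
        add_channel(d.k_b * xf * (d.N - xb), shift)
        shift = np.zeros(len(shape), dtype=np.int64)
        shift[0], shift[bi] = +1, -1
        add_channel(d.k_u * xb, shift)
        shift = np.zeros(len(shape), dtype=np.int64)
        shift[bi] = -1
        add_channel(model.gamma_b * xb, shift)
    if model.target is not None:
        t = model.target
        yi = len(shape) - 1
        yc = coords[yi].astype(float)
        for size, prob in zip(t.burst.support, t.burst.pmf):
            if size == 0:
                continue
            shift = np.zeros(len(shape), dtype=np.int64)
            shift[yi] = size
            add_channel(t.k_y * xf * prob, shift)
        shift = np.zeros(len(shape), dtype=np.int64)
        shift[yi] = -1
        add_channel(t.gamma_y * yc, shift)

    generator = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_states, n_states)).tocsr()
    generator = generator - sp.diags(diag)

    # replace the last balance row with the normalization constraint
    system = generator.tolil()
    system[n_states - 1, :] = 1.0
    rhs = np.zeros(n_states)
    rhs[-1] = 1.0
    p = spsolve(system.tocsr(), rhs)
    if not np.all(np.isfinite(p)):
        raise NumericalError("stationary solve produced non-finite probabilities")
    p = np.clip(p, 0.0, None)
    p = p / p.sum()

    leak_flux = float(np.dot(p, out_rate))
    total_flux = float(np.dot(p, total_rate))
    leak = leak_flux / total_flux if total_flux > 0 else 0.0
    if leak > _LEAK_TOL:
        raise TruncationError(
            f"truncation leaks {leak:.2e} of stationary flux; "
            f"increase x_max (currently {x_max})")

    p_box = p.reshape(shape)
    means, variances, fanos = [], [], []
    for i, d in enumerate(shape):
        axes = tuple(k for k in range(len(shape)) if k != i)
        marg = p_box.sum(axis=axes)
        vals_i = np.arange(d, dtype=float)
        m = float(np.dot(vals_i, marg))
        v = float(np.dot(vals_i ** 2, marg)) - m * m
        means.append(m)
        variances.append(v)
        fanos.append(v / m if m > 0 else float("nan"))

    return TruncatedDistribution(
        labels=model.species_labels, shape=shape, p=p_box, leak=leak,
        mean=np.array(means), variance=np.array(variances),
        fano=np.array(fanos))
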