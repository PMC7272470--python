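"""Linear noise approximation at finite binding rates.

The jump process is linearized around its deterministic fixed point.  The
fluctuation covariance solves the steady-state Lyapunov equation
A Σ + Σ Aᵀ + D = 0 where A is the Jacobian of the rate equations (drift)
and D the diffusion matrix assembled channel by channel as
Σ_c rate_c(x̄) · v_c v_cᵀ, with burst channels contributing the second
moment of the jump size (k_x ⟨B_x²⟩ on the free-TF diagonal, k_y x̄_f ⟨B_y²⟩
on the target diagonal).  Lag covariances follow from exp(Aτ) Σ, giving the
model-based autocorrelation of the free TF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm, solve_continuous_lyapunov
from scipy.optimize import brentq

from .errors import NumericalError, StabilityError
from .model import TFDecoyModel


@dataclass(frozen=True)
class LinearizedSystem:
    """Drift and diffusion of the linearized model at its fixed point."""

    labels: tuple[str, ...]
    fixed_point: np.ndarray   # molecules
    A: np.ndarray             # hr^-1
    D: np.ndarray             # molecules^2 hr^-1, symmetric PSD


def deterministic_fixed_point(model: TFDecoyModel) -> np.ndarray:
    """Steady state of the deterministic rate equations (finite k_b).

    Each bound pool satisfies x̄_bi = N_i x̄_f / (k_di + x̄_f + gamma_b/k_bi);
    substituting into the production/degradation balance
    k_x ⟨B_x⟩ = gamma_f x̄_f + gamma_b Σ x̄_bi leaves a monotone scalar
    equation for x̄_f, bracketed on [0, k_x ⟨B_x⟩ / gamma_f] and solved by
    Brent's method.
    """
    production = model.k_x * model.burst.mean
    x_f0 = production / model.gamma_f

    def bound_pool(x_f: float) -> list[float]:
        return [d.N * x_f / (d.k_d + x_f + model.gamma_b / d.k_b)
                for d in model.decoys]

    if not model.decoys or model.gamma_b == 0.0 or production == 0.0:
        x_f = x_f0
    else:
        def balance(x_f: float) -> float:
            return (production - model.gamma_f * x_f
                    - model.gamma_b * sum(bound_pool(x_f)))

        x_f = brentq(balance, 0.0, x_f0, xtol=1e-14, rtol=1e-15)
        if abs(balance(x_f)) > 1e-10 * max(production, 1.0):
            raise NumericalError("fixed-point flux balance did not converge")

    point = [x_f] + bound_pool(x_f)
    if model.target is not None:
        t = model.target
        point.append(x_f * t.k_y * t.burst.mean / t.gamma_y)
    return np.asarray(point, dtype=float)


def build_lna_system(model: TFDecoyModel,
                     fixed_point: np.ndarray | None = None) -> LinearizedSystem:
    """Assemble drift (Jacobian) and diffusion matrices at the fixed point."""
    if fixed_point is None:
        fixed_point = deterministic_fixed_point(model)
    fixed_point = np.asarray(fixed_point, dtype=float)
    labels = model.species_labels
    n = len(labels)
    if fixed_point.shape != (n,):
        raise NumericalError("fixed point dimension does not match species count")

    x_f = fixed_point[0]
    A = np.zeros((n, n))
    D = np.zeros((n, n))

    # TF burst channel: jump +i on x_f with rate k_x * alpha(i)
    D[0, 0] += model.k_x * model.burst.second_moment
    # free TF degradation: jump -1, rate gamma_f * x_f
    A[0, 0] -= model.gamma_f
    D[0, 0] += model.gamma_f * x_f

    for i, d in enumerate(model.decoys):
        bi = 1 + i
        x_b = fixed_point[bi]
        bind = d.k_b * x_f * (d.N - x_b)        # jump (-1 on x_f, +1 on x_b)
        unbind = d.k_u * x_b                    # jump (+1, -1)
        bdeg = model.gamma_b * x_b              # jump (0, -1)
        # drift derivatives
        A[0, 0] -= d.k_b * (d.N - x_b)
        A[0, bi] += d.k_b * x_f + d.k_u
        A[bi, 0] += d.k_b * (d.N - x_b)
        A[bi, bi] -= d.k_b * x_f + d.k_u + model.gamma_b
        # diffusion: sum of rate * v v^T over the three channels
        D[0, 0] += bind + unbind
        D[bi, bi] += bind + unbind + bdeg
        D[0, bi] -= bind + unbind
        D[bi, 0] -= bind + unbind

    if model.target is not None:
        t = model.target
        yi = n - 1
        y = fixed_point[yi]
        A[yi, 0] += t.k_y * t.burst.mean
        A[yi, yi] -= t.gamma_y
        D[yi, yi] += t.k_y * x_f * t.burst.second_moment + t.gamma_y * y

    eig = np.linalg.eigvals(A)
    if np.max(eig.real) >= 0:
        raise StabilityError(
            f"drift matrix is not stable; eigenvalues {np.sort_complex(eig)}")
    return LinearizedSystem(labels=tuple(labels), fixed_point=fixed_point,
                            A=A, D=D)


def steady_covariance(system: LinearizedSystem) -> np.ndarray:
    """Solve the steady-state Lyapunov equation A Σ + Σ Aᵀ + D = 0."""
    sigma = solve_continuous_lyapunov(system.A, -system.D)
    sigma = 0.5 * (sigma + sigma.T)
    scale = max(np.abs(np.diag(sigma)).max(), 1.0)
    if np.min(np.linalg.eigvalsh(sigma)) < -1e-8 * scale:
        raise NumericalError("steady covariance is not positive semidefinite")
    return sigma


def lna_fano(model: TFDecoyModel) -> dict[str, float]:
    """Per-species LNA Fano factors Σ_ii / x̄_i at the deterministic fixed point.

    This is the numeric route for models where the fast-binding closed forms
    do not apply, in particular mixtures of two decoy species.
    """
    system = build_lna_system(model)
    sigma = steady_covariance(system)
    out = {}
    for i, label in enumerate(system.labels):
        mean = system.fixed_point[i]
        out[label] = sigma[i, i] / mean if mean > 0 else float("nan")
    return out


def lna_moments(model: TFDecoyModel) -> tuple[LinearizedSystem, np.ndarray]:
    """Convenience: (linearized system, steady covariance)."""
    system = build_lna_system(model)
    return system, steady_covariance(system)


def lna_autocorrelation(system: LinearizedSystem, covariance: np.ndarray,
                        lags: np.ndarray, species: str = "x_f") -> np.ndarray:
    """Model-based autocorrelation R(τ) of one species.

    The stationary lag covariance of a linear system is exp(Aτ) Σ; R(τ) is
    its (species, species) element normalized by the stationary variance, so
    R(0) = 1.  For the no-decoy model this reduces to exp(-gamma_f τ).
    """
    idx = system.labels.index(species)
    var = covariance[idx, idx]
    if var <= 0:
        raise NumericalError("stationary variance must be positive")
    lags = np.asarray(lags, dtype=float)
    out = np.empty_like(lags)
    for k, tau in enumerate(lags):
        out[k] = (expm(system.A * tau) @ covariance)[idx, idx] / var
    return out
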