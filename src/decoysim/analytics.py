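"""Closed-form fast-binding results for the TF/decoy model.

These formulas hold in the adiabatic (fast binding/unbinding) limit:
k_b, k_u -> infinity with the dissociation constant k_d = k_u / k_b fixed.
Notation follows the field's convention: x_f0 and F0 are the stationary
mean and Fano factor of the free TF with no decoys, N the number of decoy
sites, beta = gamma_b / gamma_f the bound-vs-free stability ratio, and
f the stationary fraction of occupied decoy sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .bursts import BurstDistribution
from .errors import InvalidParameterError, NumericalError


@dataclass(frozen=True)
class FastBindingSolution:
    """Stationary mean levels in the fast-binding limit.

    ``x_free`` and ``x_bound`` are the mean free and bound TF counts,
    ``bound_fraction`` is f = x_bound / N, and ``x_free_no_decoy`` the
    no-decoy reference mean the solution was computed from.
    """

    x_free: float
    x_bound: float
    bound_fraction: float
    x_free_no_decoy: float


def no_decoy_mean(k_x: float, burst_mean: float, gamma_f: float) -> float:
    """Stationary mean free TF count without decoys: k_x * ⟨B⟩ / gamma_f."""
    if not gamma_f > 0:
        raise InvalidParameterError("gamma_f must be positive")
    return k_x * burst_mean / gamma_f


def no_decoy_fano(dist: BurstDistribution) -> float:
    """Stationary Fano factor without decoys: (⟨B⟩ + ⟨B²⟩) / (2⟨B⟩).

    Depends only on the burst-size distribution; equals 1 for non-bursty
    production (B = 1) and ⟨B⟩ for geometric bursts.
    """
    if dist.mean <= 0:
        raise InvalidParameterError("burst mean must be positive for a Fano factor")
    return (dist.mean + dist.second_moment) / (2.0 * dist.mean)


def mean_with_decoys(x_f0: float, N: float, k_d: float,
                     beta: float) -> FastBindingSolution:
    """Stationary mean free/bound TF in the fast-binding limit.

    The mean free count is the non-negative root of a quadratic:

        x_f = [x_f0 - N*beta - k_d + sqrt((x_f0 - N*beta - k_d)^2
                                           + 4*k_d*x_f0)] / 2,

    and x_b = N x_f / (k_d + x_f).  With beta = 0 this collapses to
    x_f = x_f0 for every N (decoys cannot titrate a protected TF).
    """
    if x_f0 < 0 or N < 0 or beta < 0:
        raise InvalidParameterError("x_f0, N and beta must be non-negative")
    if not k_d > 0:
        raise InvalidParameterError(
            "k_d must be positive (irreversible binding degenerates the "
            "fast-binding closed forms; use the SSA with k_u = 0 instead)")
    a = x_f0 - N * beta - k_d
    x_f = 0.5 * (a + math.sqrt(a * a + 4.0 * k_d * x_f0))
    x_f = max(x_f, 0.0)
    f = x_f / (k_d + x_f)
    return FastBindingSolution(x_free=x_f, x_bound=N * f,
                               bound_fraction=f, x_free_no_decoy=x_f0)


def mean_small_N_approx(x_f0: float, N: float, k_d: float, beta: float) -> float:
    """Small-N expansion of the mean: x_f0 - N*beta*x_f0/(x_f0 + k_d)."""
    return x_f0 - N * beta * x_f0 / (x_f0 + k_d)


def mean_large_N_approx(x_f0: float, N: float, k_d: float, beta: float) -> float:
    """Large-N limit of the mean, k_d*x_f0/(N*beta): a 1/N titration scaling."""
    if not (beta > 0 and N > 0):
        raise InvalidParameterError("large-N limit requires beta > 0 and N > 0")
    return k_d * x_f0 / (N * beta)


def fano_with_decoys(x_f0: float, F0: float, N: float, k_d: float,
                     beta: float) -> float:
    """Stationary Fano factor of the free TF with N decoy sites.

    F = 1 + x_f * [(F0 - 1) x_f0 + beta f^2 N]
            / [(x_f0 - beta f^2 N) (N f (1 - f) + x_f)],

    with x_f and f from :func:`mean_with_decoys`.  Approaches F0 as N -> 0
    and the Poisson limit 1 as N -> infinity.
    """
    sol = mean_with_decoys(x_f0, N, k_d, beta)
    x_f, f = sol.x_free, sol.bound_fraction
    if N == 0:
        return F0
    depletion = x_f0 - beta * f * f * N
    denom = depletion * (N * f * (1.0 - f) + x_f)
    if denom <= 0:
        raise NumericalError(
            "fast-binding Fano denominator is non-positive; the adiabatic "
            "closed form does not apply at these parameters")
    return 1.0 + x_f * ((F0 - 1.0) * x_f0 + beta * f * f * N) / denom


def fano_beta0(x_f0: float, F0: float, N: float, k_d: float) -> float:
    """Fano factor when bound TFs are protected from degradation (beta = 0).

    F = 1 + (F0 - 1) / (N f (1 - f) / x_f0 + 1) with f = x_f0/(k_d + x_f0);
    monotonically decreasing in N, so protected decoys always buffer noise.
    """
    if not k_d > 0:
        raise InvalidParameterError("k_d must be positive")
    f = x_f0 / (k_d + x_f0)
    return 1.0 + (F0 - 1.0) / (N * f * (1.0 - f) / x_f0 + 1.0)


def kd_threshold(F0: float, x_f0: float, beta: float) -> float:
    """Critical dissociation constant below which decoys amplify noise.

    k_d^th = F0 * beta * x_f0 / (F0 - 1); for strongly bursty production
    (F0 >> 1) this tends to beta * x_f0.  Requires super-Poissonian input
    noise (F0 > 1) — there is no bursty noise to amplify otherwise.
    """
    if not F0 > 1:
        raise InvalidParameterError("threshold requires F0 > 1 (bursty production)")
    return F0 * beta * x_f0 / (F0 - 1.0)


def occupancy_threshold(beta: float) -> float:
    """Minimum bound fraction for noise enhancement at small N: f > 1/(1+beta)."""
    if beta < 0:
        raise InvalidParameterError("beta must be non-negative")
    return 1.0 / (1.0 + beta)


def required_kx_for_mean(x_f_target: float, N: float, k_d: float, beta: float,
                         burst_mean: float, gamma_f: float) -> float:
    """Burst frequency giving a prescribed mean free TF count with decoys.

    Inverts the fast-binding mean relation: the no-decoy mean consistent
    with the target is x_f0 = x_f + beta*N*x_f/(k_d + x_f), whence
    k_x = gamma_f * x_f0 / ⟨B⟩.  Used for constant-mean parameter sweeps.
    """
    if not x_f_target > 0:
        raise InvalidParameterError("target mean must be positive")
    if not k_d > 0:
        raise InvalidParameterError("k_d must be positive")
    x_f0 = x_f_target + beta * N * x_f_target / (k_d + x_f_target)
    return gamma_f * x_f0 / burst_mean


def target_fano(x_f0: float, F0: float, N: float, k_d: float, beta: float,
                k_y: float, by_mean: float, by_second: float,
                gamma_y: float, gamma_f: float) -> float:
    """Stationary Fano factor of the downstream target protein.

    Sum of an intrinsic bursting term (⟨B_y²⟩ + ⟨B_y⟩)/(2⟨B_y⟩) and a term
    propagated from upstream free-TF fluctuations:

        F0 * ybar * x_f0 * gamma_y
        / [(x_f0 - beta f^2 N) ((N f (1-f) + x_f) gamma_y
                                 + (x_f0 - beta f^2 N) gamma_f)],

    with ybar = x_f * k_y * ⟨B_y⟩ / gamma_y.
    """
    if not (gamma_y > 0 and gamma_f > 0):
        raise InvalidParameterError("gamma_y and gamma_f must be positive")
    if by_mean <= 0:
        raise InvalidParameterError("target burst mean must be positive")
    sol = mean_with_decoys(x_f0, N, k_d, beta)
    x_f, f = sol.x_free, sol.bound_fraction
    ybar = x_f * k_y * by_mean / gamma_y
    burst_term = (by_second + by_mean) / (2.0 * by_mean)
    depletion = x_f0 - beta * f * f * N
    denom = depletion * ((N * f * (1.0 - f) + x_f) * gamma_y + depletion * gamma_f)
    if denom <= 0:
        raise NumericalError("target Fano denominator is non-positive")
    return burst_term + F0 * ybar * x_f0 * gamma_y / denom


def target_fano_no_decoy(F0: float, k_y: float, by_mean: float,
                         by_second: float, gamma_y: float,
                         gamma_f: float) -> float:
    """Target-protein Fano factor with no decoys:

    (⟨B_y²⟩ + ⟨B_y⟩)/(2⟨B_y⟩) + F0 * ⟨B_y⟩ * k_y / (gamma_y + gamma_f).
    """
    if not (gamma_y > 0 and gamma_f > 0):
        raise InvalidParameterError("gamma_y and gamma_f must be positive")
    if by_mean <= 0:
        raise InvalidParameterError("target burst mean must be positive")
    burst_term = (by_second + by_mean) / (2.0 * by_mean)
    return burst_term + F0 * by_mean * k_y / (gamma_y + gamma_f)
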