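"""Burst-size distributions for bursty protein synthesis.

Synthesis is modelled as a Poisson arrival of burst events; each event
instantaneously adds ``B`` molecules, where ``B`` is drawn i.i.d. from a
distribution on the non-negative integers.  The stationary noise of the
product depends on the distribution only through its first two moments,
so both are carried explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import InvalidParameterError

#: tail mass discarded when tabulating an analytically-defined pmf
_TAIL_MASS = 1e-12
#: maximum deficit tolerated for a user-supplied explicit pmf
_EXPLICIT_MASS_TOL = 1e-9


@dataclass(frozen=True, eq=False)
class BurstDistribution:
    """Probability mass over non-negative integer burst sizes.

    Parameters
    ----------
    kind
        ``"degenerate"``, ``"geometric"`` or ``"explicit"``.
    support
        Sorted integer burst sizes with non-zero probability.
    pmf
        Probabilities matching ``support``; non-negative, summing to 1.
    mean, second_moment
        First two moments ⟨B⟩ and ⟨B²⟩.  For the geometric kind these are
        the closed-form values; for explicit pmfs they are direct sums.
    """

    kind: str
    support: np.ndarray
    pmf: np.ndarray
    mean: float
    second_moment: float

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=np.int64)
        pmf = np.asarray(self.pmf, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "pmf", pmf)
        if support.ndim != 1 or pmf.shape != support.shape:
            raise InvalidParameterError("support and pmf must be matching 1-D arrays")
        if np.any(support < 0):
            raise InvalidParameterError("burst sizes must be non-negative integers")
        if np.any(np.diff(support) <= 0):
            raise InvalidParameterError("support must be strictly increasing")
        if np.any(pmf < 0):
            raise InvalidParameterError("probabilities must be non-negative")
        if abs(pmf.sum() - 1.0) > 1e-12:
            raise InvalidParameterError(
                f"probabilities must sum to 1 (got {pmf.sum()!r})"
            )

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def degenerate(cls, size: int) -> "BurstDistribution":
        """All bursts have exactly ``size`` molecules."""
        size = int(size)
        if size < 0:
            raise InvalidParameterError("burst size must be non-negative")
        return cls("degenerate", np.array([size]), np.array([1.0]),
                   float(size), float(size) ** 2)

    @classmethod
    def geometric(cls, mean: float) -> "BurstDistribution":
        """Geometric bursts on {1, 2, ...} with the given mean.

        P(B = i) = (1 - 1/⟨B⟩)^(i-1) / ⟨B⟩.  Moments use the closed forms
        ⟨B⟩ and ⟨B²⟩ = 2⟨B⟩² - ⟨B⟩.  The tabulated pmf is truncated once
        its cumulative mass reaches 1 - 1e-12 and renormalized.
        """
        mean = float(mean)
        if mean < 1.0:
            raise InvalidParameterError("geometric burst mean must be >= 1")
        if mean == 1.0:
            support = np.array([1])
            pmf = np.array([1.0])
        else:
            p = 1.0 / mean
            # smallest n with (1-p)^n <= tail mass
            n = int(np.ceil(np.log(_TAIL_MASS) / np.log1p(-p))) + 1
            support = np.arange(1, n + 1)
            pmf = p * (1.0 - p) ** (support - 1)
            pmf = pmf / pmf.sum()
        return cls("geometric", support, pmf, mean, 2.0 * mean * mean - mean)

    @classmethod
    def explicit(cls, probabilities: Mapping[int, float]) -> "BurstDistribution":
        """Arbitrary finite pmf given as ``{burst size: probability}``.

        The supplied mass must be within 1e-9 of 1; it is renormalized to
        exactly 1 and the moments are computed by direct summation.
        """
        if not probabilities:
            raise InvalidParameterError("explicit pmf must be non-empty")
        items = sorted((int(k), float(v)) for k, v in probabilities.items())
        support = np.array([k for k, _ in items], dtype=np.int64)
        pmf = np.array([v for _, v in items], dtype=float)
        if np.any(pmf < 0):
            raise InvalidParameterError("probabilities must be non-negative")
        total = pmf.sum()
        if abs(total - 1.0) > _EXPLICIT_MASS_TOL:
            raise InvalidParameterError(
                f"explicit pmf mass {total!r} deviates from 1 by more than "
                f"{_EXPLICIT_MASS_TOL}"
            )
        pmf = pmf / total
        mean = float(np.dot(support, pmf))
        second = float(np.dot(support.astype(float) ** 2, pmf))
        return cls("explicit", support, pmf, mean, second)

    # ------------------------------------------------------------------ #

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BurstDistribution):
            return NotImplemented
        return (self.kind == other.kind
                and np.array_equal(self.support, other.support)
                and np.array_equal(self.pmf, other.pmf))

    def __hash__(self) -> int:
        return hash((self.kind, self.support.tobytes(), self.pmf.tobytes()))

    @property
    def cdf(self) -> np.ndarray:
        """Cumulative probabilities over the support (for inverse-CDF sampling)."""
        return np.cumsum(self.pmf)

    def to_dict(self) -> dict:
        if self.kind == "degenerate":
            return {"kind": "degenerate", "size": int(self.support[0])}
        if self.kind == "geometric":
            return {"kind": "geometric", "mean": self.mean}
        return {"kind": "explicit",
                "pmf": {str(int(k)): float(v)
                        for k, v in zip(self.support, self.pmf)}}

    @classmethod
    def from_dict(cls, spec: Mapping) -> "BurstDistribution":
        kind = spec.get("kind")
        if kind == "degenerate":
            return cls.degenerate(spec["size"])
        if kind == "geometric":
            return cls.geometric(spec["mean"])
        if kind == "explicit":
            return cls.explicit({int(k): v for k, v in spec["pmf"].items()})
        raise InvalidParameterError(f"unknown burst distribution kind {kind!r}")


def make_geometric_burst(mean: float) -> BurstDistribution:
    """Geometric burst-size distribution with the given mean (molecules/burst)."""
    return BurstDistribution.geometric(mean)


def burst_moments(dist: BurstDistribution) -> tuple[float, float]:
    """Return (⟨B⟩, ⟨B²⟩) of a burst-size distribution."""
    return dist.mean, dist.second_moment
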