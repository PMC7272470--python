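"""Model definition: a bursty transcription factor, decoy sites, optional target gene.

A :class:`TFDecoyModel` describes a continuous-time Markov jump process.  Free
TF molecules (count ``x_f``) are produced in bursts arriving at rate ``k_x``,
bind reversibly to each of ``N`` identical decoy sites (per-pair rate ``k_b``,
unbinding rate ``k_u``), and both free and bound TFs degrade (rates ``gamma_f``
and ``gamma_b = beta * gamma_f``).  Up to two decoy species with different
affinities are supported, plus an optional downstream target protein whose
burst frequency ``k_y * x_f`` is proportional to the free TF count.

All rates are in hr^-1; counts are molecules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .bursts import BurstDistribution
from .errors import InvalidParameterError

#: default diffusion-limited binding rate, hr^-1 per pair of molecules
DEFAULT_KB = 50.0


@dataclass(frozen=True)
class DecoySpecies:
    """One class of identical decoy binding sites.

    ``N`` total sites, binding rate ``k_b`` (hr^-1 per free-TF/site pair) and
    unbinding rate ``k_u`` (hr^-1 per bound TF).  The dissociation constant
    ``k_d = k_u / k_b`` is in molecules.
    """

    N: int
    k_b: float
    k_u: float

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 0:
            raise InvalidParameterError("decoy site number N must be a non-negative integer")
        object.__setattr__(self, "N", int(self.N))
        if not self.k_b > 0:
            raise InvalidParameterError("binding rate k_b must be positive")
        if self.k_u < 0:
            raise InvalidParameterError("unbinding rate k_u must be non-negative")

    @property
    def k_d(self) -> float:
        """Dissociation constant k_u / k_b (molecules)."""
        return self.k_u / self.k_b

    @classmethod
    def from_kd(cls, N: int, k_d: float, k_b: float = DEFAULT_KB) -> "DecoySpecies":
        if k_d < 0:
            raise InvalidParameterError("dissociation constant k_d must be non-negative")
        return cls(N=N, k_b=k_b, k_u=k_d * k_b)

    def to_dict(self) -> dict:
        return {"N": self.N, "k_b": self.k_b, "k_u": self.k_u}

    @classmethod
    def from_dict(cls, spec: Mapping) -> "DecoySpecies":
        if "k_u" in spec:
            return cls(N=spec["N"], k_b=spec.get("k_b", DEFAULT_KB), k_u=spec["k_u"])
        return cls.from_kd(spec["N"], spec["k_d"], spec.get("k_b", DEFAULT_KB))


@dataclass(frozen=True)
class TargetGene:
    """Downstream protein activated linearly by the free TF.

    Burst frequency ``k_y * x_f`` (hr^-1), burst sizes from ``burst``,
    first-order decay at ``gamma_y`` (hr^-1).
    """

    k_y: float
    burst: BurstDistribution
    gamma_y: float

    def __post_init__(self) -> None:
        if self.k_y < 0:
            raise InvalidParameterError("target activation rate k_y must be non-negative")
        if not self.gamma_y > 0:
            raise InvalidParameterError("target degradation rate gamma_y must be positive")

    def to_dict(self) -> dict:
        return {"k_y": self.k_y, "gamma_y": self.gamma_y,
                "burst": self.burst.to_dict()}

    @classmethod
    def from_dict(cls, spec: Mapping) -> "TargetGene":
        return cls(k_y=spec["k_y"], gamma_y=spec["gamma_y"],
                   burst=BurstDistribution.from_dict(spec["burst"]))


@dataclass(frozen=True)
class TFDecoyModel:
    """Full parameterization of the TF / decoy / target jump process."""

    k_x: float
    burst: BurstDistribution
    gamma_f: float
    gamma_b: float
    decoys: tuple[DecoySpecies, ...] = ()
    target: Optional[TargetGene] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "decoys", tuple(self.decoys))
        if self.k_x < 0:
            raise InvalidParameterError("burst frequency k_x must be non-negative")
        if not self.gamma_f > 0:
            raise InvalidParameterError("free-TF degradation rate gamma_f must be positive")
        if self.gamma_b < 0:
            raise InvalidParameterError("bound-TF degradation rate gamma_b must be non-negative")
        if len(self.decoys) > 2:
            raise InvalidParameterError("at most two decoy species are supported")

    @property
    def beta(self) -> float:
        """Bound-vs-free TF stability ratio gamma_b / gamma_f."""
        return self.gamma_b / self.gamma_f

    @property
    def n_decoys(self) -> int:
        return len(self.decoys)

    @property
    def species_labels(self) -> tuple[str, ...]:
        if len(self.decoys) == 0:
            labels = ["x_f"]
        elif len(self.decoys) == 1:
            labels = ["x_f", "x_b"]
        else:
            labels = ["x_f", "x_b1", "x_b2"]
        if self.target is not None:
            labels.append("y")
        return tuple(labels)

    @property
    def n_species(self) -> int:
        return len(self.species_labels)

    # ------------------------------------------------------------------ #
    # config I/O (JSON dialect described in the README)

    def to_dict(self) -> dict:
        out = {
            "tf": {
                "k_x": self.k_x,
                "burst": self.burst.to_dict(),
                "gamma_f": self.gamma_f,
                "gamma_b": self.gamma_b,
            },
            "decoys": [d.to_dict() for d in self.decoys],
        }
        if self.target is not None:
            out["target"] = self.target.to_dict()
        return out

    @classmethod
    def from_dict(cls, spec: Mapping) -> "TFDecoyModel":
        tf = spec["tf"]
        gamma_f = tf["gamma_f"]
        if "gamma_b" in tf:
            gamma_b = tf["gamma_b"]
        elif "beta" in tf:
            gamma_b = tf["beta"] * gamma_f
        else:
            raise InvalidParameterError("tf block needs 'gamma_b' or 'beta'")
        target = spec.get("target")
        return cls(
            k_x=tf["k_x"],
            burst=BurstDistribution.from_dict(tf["burst"]),
            gamma_f=gamma_f,
            gamma_b=gamma_b,
            decoys=tuple(DecoySpecies.from_dict(d) for d in spec.get("decoys", [])),
            target=TargetGene.from_dict(target) if target else None,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TFDecoyModel":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        return cls.from_dict(json.loads(text))


def load_model(path: str | Path) -> TFDecoyModel:
    """Read a model config (JSON) from disk."""
    return TFDecoyModel.from_dict(json.loads(Path(path).read_text()))
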