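"""Simulation configuration.

A :class:`SimConfig` fully specifies one stochastic realization of the
scent-avoidance model: lattice geometry, number of animals, the active
scent time ``tas`` (how long a deposited mark keeps repelling neighbours),
the movement variant and the random seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from typing import Any

import yaml

__all__ = ["SimConfig", "ConfigError", "INFINITE_TAS"]

#: Sentinel accepted for a never-expiring scent mark.
INFINITE_TAS = math.inf

_VARIANTS = ("plain", "correlated_retreat")
_PLACEMENTS = ("grid", "random")


class ConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one territory simulation.

    Parameters
    ----------
    dims
        Lattice dimensionality, 1 (ring) or 2 (torus).
    L
        Sites per axis of the periodic box.
    N
        Number of animals.
    tas
        Active scent time in time-steps.  A mark deposited at time ``t0``
        repels other animals while ``t - t0 < tas`` (strict).  ``0`` turns
        avoidance off, ``math.inf`` makes scent permanent.
    variant
        ``"plain"`` — uniformly random choice among admissible moves;
        ``"correlated_retreat"`` — short-lived directional persistence
        after a retreat from foreign scent.
    snoop_p
        Fraction of the territory perimeter re-scented on each boundary
        visit (0 disables snooping).
    seed
        Seed of the per-run random generator.
    T_max
        Number of time-steps to simulate.
    record_every
        Stride (in steps) between scent-field snapshots.
    placement
        ``"grid"`` — animals on a regular sublattice (deterministic);
        ``"random"`` — uniformly random distinct sites.
    q0, lam0
        Correlated-retreat parameters: persistence probability right
        after a retreat (1D) and turning-kernel concentration right
        after a retreat (2D).  Both halve with every step since the last
        encounter.  Defaults are package choices, not externally fixed.
    """

    dims: int = 1
    L: int = 100
    N: int = 2
    tas: float = 1000.0
    variant: str = "plain"
    snoop_p: float = 0.0
    seed: int = 0
    T_max: int = 10_000
    record_every: int = 1
    placement: str = "grid"
    q0: float = 0.5
    lam0: float = 2.0

    def __post_init__(self) -> None:
        if self.dims not in (1, 2):
            raise ConfigError(f"dims must be 1 or 2, got {self.dims}")
        if self.L < 2:
            raise ConfigError(f"need at least 2 sites per axis, got L={self.L}")
        if self.N < 1:
            raise ConfigError("need at least one animal")
        if self.N > self.n_sites:
            raise ConfigError(
                f"{self.N} animals do not fit on {self.n_sites} sites"
            )
        if not (self.tas >= 0):  # also rejects NaN
            raise ConfigError(f"active scent time must be >= 0, got {self.tas}")
        if self.variant not in _VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}")
        if not 0.0 <= self.snoop_p <= 1.0:
            raise ConfigError(f"snoop_p must lie in [0, 1], got {self.snoop_p}")
        if self.placement not in _PLACEMENTS:
            raise ConfigError(f"unknown placement {self.placement!r}")
        if self.T_max < 0:
            raise ConfigError("T_max must be non-negative")
        if self.record_every < 1:
            raise ConfigError("record_every must be >= 1")
        if not 0.0 <= self.q0 <= 1.0:
            raise ConfigError("q0 must lie in [0, 1]")
        if self.lam0 < 0:
            raise ConfigError("lam0 must be >= 0")

    # -- derived geometry ------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.L**self.dims

    @property
    def scent_never_expires(self) -> bool:
        return math.isinf(self.tas)

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if math.isinf(self.tas):
            d["tas"] = "infinite"
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        tas = d.get("tas", d.pop("T_AS", None))
        d.pop("tas", None)
        if tas is not None:
            if isinstance(tas, str):
                if tas.lower() in ("inf", "infinite", "infinity"):
                    tas = math.inf
                else:
                    tas = float(tas)
            d["tas"] = float(tas)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: expected a mapping of config keys")
        return cls.from_dict(d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        """Short stable hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kw: Any) -> "SimConfig":
        return dataclasses.replace(self, **kw)
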