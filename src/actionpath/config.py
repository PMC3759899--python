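"""Structured run configuration with lossless YAML round-tripping.

A :class:`RunConfig` bundles everything a full pipeline run needs: the
potential selection and its parameters, the action-minimization settings,
the temperature ladder, the reference-set parameters and the global seed.
Every pipeline stage writes its resolved configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path as FilePath

import yaml

from .admd import ADMDConfig
from .potentials import (POTENTIALS, GaussianSurface2D, GaussianWell,
                         PotentialModel)
from .remd import LadderConfig


@dataclass(frozen=True)
class ReferenceConfig:
    """Reference-set parameters: selection stride along the path, the
    flat-bottom radius (Å) and harmonic force constant (kcal/mol/Å²)."""

    stride: int = 9
    radius: float = 2.0
    force_constant: float = 2.24
    superpose: bool | None = None  # None: decide by dimensionality


@dataclass(frozen=True)
class PathConfig:
    """Discretization of the transition path: P slices of Δ fs each, and
    the noise amplitude (Å) of the random initial interior frames."""

    n_slices: int = 100
    delta: float = 8.06
    noise_amplitude: float = 0.1
    n_paths: int = 1


@dataclass
class RunConfig:
    potential: str = "double_well_1d"
    potential_params: dict = field(default_factory=dict)
    n_atoms: int = 1
    masses: list = field(default_factory=lambda: [1.0])
    path: PathConfig = field(default_factory=PathConfig)
    admd: ADMDConfig = field(default_factory=ADMDConfig)
    ladder: LadderConfig = field(default_factory=LadderConfig)
    references: ReferenceConfig = field(default_factory=ReferenceConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: conv(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return [conv(v) for v in obj]
            if isinstance(obj, list):
                return [conv(v) for v in obj]
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            return obj
        return conv(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "path" in data:
            data["path"] = PathConfig(**data["path"])
        if "admd" in data:
            data["admd"] = ADMDConfig(**data["admd"])
        if "ladder" in data:
            ladder = dict(data["ladder"])
            if "temperatures" in ladder:
                ladder["temperatures"] = tuple(ladder["temperatures"])
            data["ladder"] = LadderConfig(**ladder)
        if "references" in data:
            data["references"] = ReferenceConfig(**data["references"])
        return cls(**data)

    def save(self, path) -> None:
        FilePath(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(FilePath(path).read_text()))

    def build_potential(self) -> PotentialModel:
        """Instantiate the configured potential model."""
        try:
            factory = POTENTIALS[self.potential]
        except KeyError:
            raise ValueError(
                f"unknown potential {self.potential!r}; options: "
                f"{sorted(POTENTIALS)}") from None
        params = dict(self.potential_params)
        params.setdefault("n_atoms", self.n_atoms)
        if factory is GaussianSurface2D and "wells" in params:
            params["wells"] = [
                GaussianWell.isotropic(w["amplitude"], tuple(w["center"]),
                                       w["width"])
                if "width" in w else
                GaussianWell(w["amplitude"], tuple(w["center"]),
                             tuple(tuple(r) for r in w["inv_cov"]))
                for w in params["wells"]]
        return factory(**params)
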