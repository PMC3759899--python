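"""Molecular system metadata and single-conformation containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class MolecularSystem:
    """Static description of the simulated system.

    Parameters
    ----------
    masses : array of float
        Per-atom masses in amu; strictly positive.
    labels : tuple of str
        One label per atom (element symbols for molecular systems, free-form
        for toy particles).
    dim : int
        Spatial dimensionality per atom: 1, 2 or 3.
    """

    masses: np.ndarray
    labels: tuple[str, ...]
    dim: int = 3

    def __post_init__(self) -> None:
        masses = np.ascontiguousarray(self.masses, dtype=float)
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "labels", tuple(self.labels))
        if masses.ndim != 1:
            raise ValueError("masses must be one-dimensional")
        if not np.all(masses > 0):
            raise ValueError("all masses must be strictly positive")
        if len(self.labels) != masses.size:
            raise ValueError(
                f"{len(self.labels)} labels for {masses.size} atoms"
            )
        if self.dim not in (1, 2, 3):
            raise ValueError("dim must be 1, 2 or 3")

    @property
    def n_atoms(self) -> int:
        return self.masses.size

    @classmethod
    def uniform(cls, n_atoms: int, mass: float = 1.0, dim: int = 3,
                label: str = "X") -> "MolecularSystem":
        """Convenience constructor for toy systems of identical particles."""
        return cls(np.full(n_atoms, float(mass)), (label,) * n_atoms, dim)


@dataclass
class Conformation:
    """A single conformation: (N, dim) coordinates in Å plus its system."""

    coords: np.ndarray
    system: MolecularSystem = field(repr=False)

    def __post_init__(self) -> None:
        self.coords = np.ascontiguousarray(self.coords, dtype=float)
        if self.coords.ndim == 1:
            self.coords = self.coords[:, None]
        expected = (self.system.n_atoms, self.system.dim)
        if self.coords.shape != expected:
            raise ValueError(
                f"coordinate shape {self.coords.shape} does not match "
                f"system shape {expected}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
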