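"""Pluggable potential-energy models with analytic gradients.

Every model implements :class:`PotentialModel`: ``evaluate(coords)`` returns
the potential energy in kcal/mol and the forces (negative gradient) in
kcal/mol/Å for an ``(N, dim)`` coordinate array.  The built-in toy systems —
a 1D quartic double well, a 2D multi-Gaussian surface, a Lennard-Jones
cluster, a harmonic chain and an isotropic harmonic well — have stationary
points and Boltzmann statistics that are known in closed form or computable
by brute force, which is what the test suite exploits.

All real physics plugs in here: a user-supplied force field enters through
:class:`CallbackPotential` without touching the rest of the pipeline.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


class PotentialModel(ABC):
    """Contract for potential-energy models.

    Attributes
    ----------
    n_atoms : int
        Number of atoms the model expects.
    dim : int
        Spatial dimensionality per atom (1, 2 or 3).
    """

    n_atoms: int
    dim: int

    @abstractmethod
    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Return ``(energy, forces)`` for an ``(N, dim)`` conformation."""

    def energy(self, coords: np.ndarray) -> float:
        return self.evaluate(coords)[0]

    def forces(self, coords: np.ndarray) -> np.ndarray:
        return self.evaluate(coords)[1]

    def _check_shape(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 1:
            coords = coords[:, None]
        if coords.shape != (self.n_atoms, self.dim):
            raise ValueError(
                f"expected coordinates of shape {(self.n_atoms, self.dim)}, "
                f"got {coords.shape}"
            )
        return coords


class DoubleWell1D(PotentialModel):
    """Independent 1D particles in the quartic double well.

    V(x) = h·((x/a)² − 1)² per particle: minima at x = ±a with V = 0 and a
    barrier of height ``h`` at x = 0.

    Parameters
    ----------
    barrier_height : float
        h, kcal/mol.
    well_position : float
        a, Å.
    """

    dim = 1

    def __init__(self, barrier_height: float = 3.0, well_position: float = 1.0,
                 n_atoms: int = 1):
        if barrier_height <= 0 or well_position <= 0:
            raise ValueError("barrier height and well position must be > 0")
        self.h = float(barrier_height)
        self.a = float(well_position)
        self.n_atoms = int(n_atoms)

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = self._check_shape(coords)
        x = coords[:, 0]
        u = (x / self.a) ** 2 - 1.0
        energy = self.h * np.sum(u**2)
        # dV/dx = 4 h x u / a²
        forces = (-4.0 * self.h * x * u / self.a**2)[:, None]
        return float(energy), forces


@dataclass(frozen=True)
class GaussianWell:
    """One term A·exp(−½ dᵀ B d) of a multi-Gaussian surface.

    ``B`` is a symmetric positive-definite 2×2 matrix (inverse squared
    widths); negative amplitude A makes a well, positive a bump.
    """

    amplitude: float
    center: tuple[float, float]
    inv_cov: tuple[tuple[float, float], tuple[float, float]] = (
        (1.0, 0.0), (0.0, 1.0))

    @classmethod
    def isotropic(cls, amplitude: float, center: tuple[float, float],
                  width: float) -> "GaussianWell":
        """Isotropic term A·exp(−|q−c|²/(2·width²))."""
        b = 1.0 / width**2
        return cls(amplitude, center, ((b, 0.0), (0.0, b)))


# Default three-well / two-saddle surface: two deep outer basins, a shallower
# intermediate basin above, and a repulsive core at the origin that forces
# transition paths over the upper channel.  Stationary points were located by
# Newton search and are frozen in the tests.
DEFAULT_SURFACE: tuple[GaussianWell, ...] = (
    GaussianWell.isotropic(-4.0, (-2.0, 0.0), 0.8),
    GaussianWell.isotropic(-4.0, (2.0, 0.0), 0.8),
    GaussianWell.isotropic(-3.0, (0.0, 1.7), 0.8),
    GaussianWell.isotropic(6.0, (0.0, 0.0), 0.9),
)


class GaussianSurface2D(PotentialModel):
    """Sum of 2D Gaussian wells/bumps: V(q) = Σ_k A_k exp(−½ dᵀ B_k d)."""

    dim = 2

    def __init__(self, wells: Sequence[GaussianWell] | None = None,
                 n_atoms: int = 1):
        if wells is None:
            wells = DEFAULT_SURFACE
        wells = tuple(wells)
        if not wells:
            raise ValueError("at least one Gaussian term is required")
        self.wells = wells
        self.n_atoms = int(n_atoms)
        self._amps = np.array([w.amplitude for w in wells])
        self._centers = np.array([w.center for w in wells])  # (K, 2)
        self._inv_cov = np.array([w.inv_cov for w in wells])  # (K, 2, 2)

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = self._check_shape(coords)
        # d: (N, K, 2) displacement of each particle from each center
        d = coords[:, None, :] - self._centers[None, :, :]
        bd = np.einsum("kab,nkb->nka", self._inv_cov, d)
        quad = np.einsum("nka,nka->nk", d, bd)
        terms = self._amps[None, :] * np.exp(-0.5 * quad)  # (N, K)
        energy = float(terms.sum())
        # ∂V/∂q_n = Σ_k term_nk · (−B_k d_nk); force is the negative of that
        forces = np.einsum("nk,nka->na", terms, bd)
        return energy, forces


class LJCluster(PotentialModel):
    """Pairwise 12-6 Lennard-Jones cluster, no cutoff.

    V = Σ_{i<j} 4ε[(σ/r)¹² − (σ/r)⁶]; the dimer minimum sits at
    r = 2^(1/6)·σ with energy −ε.
    """

    dim = 3

    def __init__(self, n_atoms: int, epsilon: float = 1.0, sigma: float = 1.0):
        if n_atoms < 2:
            raise ValueError("a cluster needs at least two atoms")
        self.n_atoms = int(n_atoms)
        self.epsilon = float(epsilon)
        self.sigma = float(sigma)

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = self._check_shape(coords)
        diff = coords[:, None, :] - coords[None, :, :]
        r2 = np.einsum("ija,ija->ij", diff, diff)
        iu = np.triu_indices(self.n_atoms, k=1)
        if np.any(r2[iu] == 0.0):
            raise ValueError("coincident atoms: Lennard-Jones energy diverges")
        s2 = self.sigma**2 / r2[iu]
        s6 = s2**3
        energy = 4.0 * self.epsilon * np.sum(s6 * (s6 - 1.0))
        # pair force magnitude/r: 24ε(2 s12 − s6)/r²
        coef = np.zeros_like(r2)
        coef[iu] = 24.0 * self.epsilon * s6 * (2.0 * s6 - 1.0) / r2[iu]
        coef = coef + coef.T
        forces = np.einsum("ij,ija->ia", coef, diff)
        return float(energy), forces


class HarmonicChain(PotentialModel):
    """1D chain of particles with nearest-neighbour springs.

    V = ½k Σ_i (x_{i+1} − x_i − b)² with equilibrium spacing ``b``;
    translation invariant, handy for Verlet-consistency checks.
    """

    dim = 1

    def __init__(self, n_atoms: int, spring_constant: float = 10.0,
                 spacing: float = 1.0):
        if n_atoms < 2:
            raise ValueError("a chain needs at least two atoms")
        self.n_atoms = int(n_atoms)
        self.k = float(spring_constant)
        self.b = float(spacing)

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = self._check_shape(coords)
        x = coords[:, 0]
        stretch = np.diff(x) - self.b
        energy = 0.5 * self.k * np.sum(stretch**2)
        grad = np.zeros_like(x)
        grad[:-1] -= self.k * stretch
        grad[1:] += self.k * stretch
        return float(energy), -grad[:, None]


class HarmonicWell(PotentialModel):
    """Isotropic harmonic well V = ½k Σ_I |q_I − c|² in any dimensionality."""

    def __init__(self, n_atoms: int = 1, dim: int = 1,
                 spring_constant: float = 1.0,
                 center: np.ndarray | float = 0.0):
        self.n_atoms = int(n_atoms)
        self.dim = int(dim)
        self.k = float(spring_constant)
        self.center = np.broadcast_to(
            np.asarray(center, dtype=float), (self.n_atoms, self.dim)).copy()

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = self._check_shape(coords)
        d = coords - self.center
        return float(0.5 * self.k * np.sum(d**2)), -self.k * d


class ZeroPotential(PotentialModel):
    """Free particles: V ≡ 0."""

    def __init__(self, n_atoms: int = 1, dim: int = 1):
        self.n_atoms = int(n_atoms)
        self.dim = int(dim)

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = self._check_shape(coords)
        return 0.0, np.zeros_like(coords)


class CallbackPotential(PotentialModel):
    """Hook for an external evaluator (e.g. a force-field engine).

    The callback receives the ``(N, dim)`` coordinate array and must return
    ``(energy, forces)`` in kcal/mol and kcal/mol/Å.  No adapter to a
    specific MD package is shipped; this is the seam where one would attach.
    """

    def __init__(self, func: Callable[[np.ndarray], tuple[float, np.ndarray]],
                 n_atoms: int, dim: int = 3):
        self._func = func
        self.n_atoms = int(n_atoms)
        self.dim = int(dim)

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = self._check_shape(coords)
        energy, forces = self._func(coords)
        forces = np.asarray(forces, dtype=float).reshape(coords.shape)
        return float(energy), forces


def finite_difference_forces(potential: PotentialModel, coords: np.ndarray,
                             step: float = 1e-6) -> np.ndarray:
    """Central finite-difference forces; the universal gradient oracle."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    out = np.zeros_like(coords)
    for idx in np.ndindex(coords.shape):
        plus = coords.copy()
        minus = coords.copy()
        plus[idx] += step
        minus[idx] -= step
        out[idx] = -(potential.energy(plus) - potential.energy(minus)) / (
            2.0 * step)
    return out


def find_stationary_points(potential: PotentialModel,
                           grid: np.ndarray,
                           gtol: float = 1e-10,
                           max_iter: int = 200,
                           round_decimals: int = 6) -> list[dict]:
    """Locate stationary points of a 1-particle surface by Newton search.

    Runs damped Newton iterations from every point of ``grid`` (shape
    ``(M, dim)``), deduplicates converged roots, and classifies each by the
    eigenvalues of a finite-difference Hessian: ``'minimum'``, ``'saddle'``
    or ``'maximum'``.  Roots outside the bounding box of the grid (plus a
    small margin) are discarded: on surfaces that flatten out at infinity
    the gradient test would otherwise accept arbitrary far-field points.
    """
    if potential.n_atoms != 1:
        raise ValueError("stationary-point search expects a 1-particle model")
    dim = potential.dim
    h = 1e-5
    grid = np.asarray(grid, dtype=float).reshape(-1, dim)
    lo = grid.min(axis=0) - 0.5
    hi = grid.max(axis=0) + 0.5

    def grad(q):
        return -potential.forces(q.reshape(1, dim)).ravel()

    def hess(q):
        out = np.zeros((dim, dim))
        for a in range(dim):
            e = np.zeros(dim)
            e[a] = h
            out[:, a] = (grad(q + e) - grad(q - e)) / (2.0 * h)
        return 0.5 * (out + out.T)

    found: list[dict] = []
    for start in grid:
        q = start.copy()
        ok = False
        for _ in range(max_iter):
            g = grad(q)
            if np.linalg.norm(g) < gtol:
                ok = True
                break
            try:
                step_vec = np.linalg.solve(hess(q), g)
            except np.linalg.LinAlgError:
                break
            if np.linalg.norm(step_vec) > 1.0:  # damp far-field steps
                step_vec *= 1.0 / np.linalg.norm(step_vec)
            q = q - step_vec
            if not np.all(np.isfinite(q)) or np.linalg.norm(q) > 1e3:
                break
        if not ok or np.any(q < lo) or np.any(q > hi):
            continue
        key = tuple(np.round(q, round_decimals))
        if any(tuple(np.round(p["point"], round_decimals)) == key
               for p in found):
            continue
        eigvals = np.linalg.eigvalsh(hess(q))
        if np.all(eigvals > 0):
            kind = "minimum"
        elif np.all(eigvals < 0):
            kind = "maximum"
        else:
            kind = "saddle"
        found.append({
            "point": q,
            "energy": potential.energy(q.reshape(1, dim)),
            "kind": kind,
            "eigvals": eigvals,
        })
    found.sort(key=lambda p: p["energy"])
    return found


#: Registry used by the config layer to build potentials by name.
POTENTIALS: dict[str, type] = {
    "double_well_1d": DoubleWell1D,
    "gaussian_2d": GaussianSurface2D,
    "lj_cluster": LJCluster,
    "harmonic_chain": HarmonicChain,
    "harmonic_well": HarmonicWell,
    "zero": ZeroPotential,
}
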