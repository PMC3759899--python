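"""Pathway quality metrics.

A discrete path is judged by how closely it follows the position-Verlet
recursion.  The per-atom, per-slice residual

    ε_I,j = 2q_I,j − q_I,j−1 − q_I,j+1 − (Δ²/m_I)·∂V/∂q_I,j

vanishes identically on a Verlet trajectory; its scalar components are the
"error variables" (dim·N·(P−1) of them) and their mean square is the
Onsager–Machlup action S_OM — zero for a true Verlet path, small for a
near-Newtonian one.

The discrete curvature profile C(j) quantifies how sharply the path bends
at each interior frame; it is zero on a straight line and equals 1/r on a
uniformly discretized circle of radius r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .admd import Path, _check_path_system
from .constants import KCAL_PER_AMU_A2_FS2
from .potentials import PotentialModel
from .system import MolecularSystem


@dataclass
class ErrorVariableSet:
    """Scalar Verlet residuals for every atom, component and interior slice.

    ``values`` has shape (P−1, N, dim) in Å; ``flat`` gives the
    dim·N·(P−1) scalars in a single vector.
    """

    values: np.ndarray

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()

    @property
    def count(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.flat.mean())

    @property
    def max_abs(self) -> float:
        return float(np.abs(self.flat).max())

    def histogram(self, bins: int = 101,
                  span_sigmas: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
        """Symmetric histogram about 0, range auto-set to ±span_sigmas·σ."""
        sigma = float(self.flat.std())
        half = span_sigmas * sigma if sigma > 0 else 1e-12
        counts, edges = np.histogram(self.flat, bins=bins,
                                     range=(-half, half))
        return counts, edges


def error_variables(path: Path, potential: PotentialModel,
                    system: MolecularSystem) -> ErrorVariableSet:
    """Verlet residuals ε for interior slices j = 1..P−1, in Å."""
    _check_path_system(path, system)
    frames = path.frames
    grad_v = np.stack([-potential.forces(f) for f in frames[1:-1]])
    second_diff = 2.0 * frames[1:-1] - frames[:-2] - frames[2:]
    # ∂V/∂q is kcal/mol/Å; Δ²/m · ∇V needs the energy-unit conversion to
    # come out in Å.
    coef = path.delta**2 / (system.masses[None, :, None]
                            * KCAL_PER_AMU_A2_FS2)
    return ErrorVariableSet(second_diff - coef * grad_v)


def onsager_machlup_action(path: Path, potential: PotentialModel,
                           system: MolecularSystem) -> float:
    """S_OM: mean squared error variable, Å²; zero for a Verlet path."""
    eps = error_variables(path, potential, system)
    return float(np.mean(eps.flat**2))


def curvature_profile(path: Path) -> np.ndarray:
    """Discrete curvature C(j) for j = 1..P−1, in Å⁻¹.

    C(j) = ‖2q_j − q_{j−1} − q_{j+1}‖ / (‖q_j − q_{j−1}‖·‖q_j − q_{j+1}‖)
    with norms over all atoms jointly.  Calibration: exactly zero on a
    collinear path, exactly 1/r on a uniformly stepped circle of radius r.
    Slices with a zero-length step are reported as NaN (undefined), not
    fatal.
    """
    frames = path.frames.reshape(path.n_slices + 1, -1)
    second_diff = 2.0 * frames[1:-1] - frames[:-2] - frames[2:]
    back = frames[1:-1] - frames[:-2]
    fwd = frames[1:-1] - frames[2:]
    num = np.linalg.norm(second_diff, axis=1)
    den = np.linalg.norm(back, axis=1) * np.linalg.norm(fwd, axis=1)
    out = np.full(num.shape, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def step_rmsd_profile(path: Path) -> np.ndarray:
    """Unfitted RMSD between successive frames, length P, in Å."""
    disp = np.diff(path.frames, axis=0)
    return np.sqrt(np.mean(np.sum(disp**2, axis=2), axis=1))
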