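"""Structural comparison primitives.

Optimal rigid-body superposition uses the quaternion eigenvalue method
(Horn/Kearsley): the rotation minimizing the all-atom RMSD between two
centered coordinate sets is encoded by the eigenvector of a 4×4 symmetric
matrix belonging to its largest eigenvalue.  The parameterization covers
proper rotations only, so chirality is always preserved.

RMSD is all-atom and unweighted; the radius of gyration is mass-weighted by
default (switchable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Superposition:
    """Result of an optimal rigid superposition of ``mobile`` onto ``target``.

    ``rotation`` and ``translation`` map mobile coordinates onto the target
    frame: ``x_aligned = x_mobile @ rotation.T + translation``.  For systems
    with fewer than 3 atoms in 3D (or dimensionality below 3) the rotation
    is under-determined / not applied and ``underdetermined`` is set.
    """

    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray
    underdetermined: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _as_coords(obj) -> np.ndarray:
    coords = getattr(obj, "coords", obj)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    return coords


def _quaternion_rotation(mobile_c: np.ndarray,
                         target_c: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal proper rotation of centered ``mobile_c`` onto ``target_c``.

    Returns the 3×3 rotation matrix and the largest eigenvalue λ of the
    Horn matrix, from which RMSD² = (G_a + G_b − 2λ)/N.
    """
    m = mobile_c.T @ target_c  # correlation matrix, (3, 3)
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    eigvals, eigvecs = np.linalg.eigh(key)
    lam = eigvals[-1]
    q0, q1, q2, q3 = eigvecs[:, -1]
    rot = np.array([
        [q0*q0 + q1*q1 - q2*q2 - q3*q3, 2*(q1*q2 - q0*q3), 2*(q1*q3 + q0*q2)],
        [2*(q1*q2 + q0*q3), q0*q0 - q1*q1 + q2*q2 - q3*q3, 2*(q2*q3 - q0*q1)],
        [2*(q1*q3 - q0*q2), 2*(q2*q3 + q0*q1), q0*q0 - q1*q1 - q2*q2 + q3*q3],
    ])
    return rot, float(lam)


def superpose(mobile, target) -> Superposition:
    """Minimum all-atom RMSD over rigid motions, via the quaternion method.

    In 3D with N ≥ 3 the full rotational optimum is found; with N < 3 the
    rotation is under-determined and the translational optimum is returned
    with ``underdetermined=True``.  For dimensionality below 3 superposition
    degenerates to translation-only alignment.
    """
    a = _as_coords(mobile)
    b = _as_coords(target)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    n, dim = a.shape
    mu_a = a.mean(axis=0)
    mu_b = b.mean(axis=0)
    ac = a - mu_a
    bc = b - mu_b
    if dim != 3 or n < 3:
        rmsd = float(np.sqrt(np.mean(np.sum((ac - bc) ** 2, axis=1))))
        return Superposition(rmsd, np.eye(dim), mu_b - mu_a,
                             underdetermined=(dim == 3))
    rot, _ = _quaternion_rotation(ac, bc)
    # evaluate the RMSD from the aligned coordinates rather than from
    # G_a + G_b − 2λ, which loses half the digits to cancellation
    rmsd = float(np.sqrt(np.mean(np.sum((ac @ rot.T - bc) ** 2, axis=1))))
    translation = mu_b - rot @ mu_a
    return Superposition(rmsd, rot, translation)


def rmsd_no_fit(a, b) -> float:
    """Root-mean-square deviation without superposition."""
    ca = _as_coords(a)
    cb = _as_coords(b)
    if ca.shape != cb.shape:
        raise ValueError(f"shape mismatch: {ca.shape} vs {cb.shape}")
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def radius_of_gyration(conformation, masses: np.ndarray | None = None,
                       mass_weighted: bool = True) -> float:
    """Radius of gyration about the (mass-weighted) center of mass, Å."""
    coords = _as_coords(conformation)
    if masses is None:
        system = getattr(conformation, "system", None)
        masses = system.masses if (system is not None and mass_weighted) \
            else np.ones(coords.shape[0])
    masses = np.asarray(masses, dtype=float)
    if not mass_weighted:
        masses = np.ones(coords.shape[0])
    total = masses.sum()
    com = (masses[:, None] * coords).sum(axis=0) / total
    return float(np.sqrt(
        np.sum(masses * np.sum((coords - com) ** 2, axis=1)) / total))
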