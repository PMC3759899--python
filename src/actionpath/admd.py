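"""Action-derived pathway generation.

A transition path between two fixed conformations is found by minimizing a
penalized discrete action over all interior frames — a boundary-value
formulation of classical dynamics.  The objective is

    Φ = Σ_{j=0}^{P−1} L_j·Δ  +  μ_E·Σ_{j=0}^{P−1} (E_j − E)²
                             +  μ_K·Σ_I (⟨K_I⟩ − (d/2)·k_B·T)²

with the discretized Lagrangian of slice j

    L_j = Σ_I (m_I / 2Δ²)·|q_I,j − q_I,j+1|² − V({q_j}).

The μ_E penalty pins the per-slice total energy E_j to a pre-set target E
(so the optimum conserves total energy and cannot lower Φ by running up the
potential), and the μ_K penalty pins each atom's trajectory-averaged
kinetic energy to the equipartition value of a fictitious temperature T.
A stationary point of the unpenalized action satisfies the position-Verlet
recursion, so optimized paths are near-Newtonian trajectories.

Conventions the discretization leaves open: E_j uses forward-difference
velocities, E_j = Σ_I (m_I/2)·|(q_I,j+1 − q_I,j)/Δ|² + V({q_j}), and ⟨K_I⟩
averages the same forward-difference kinetic energy over j = 0..P−1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .constants import KB, KCAL_PER_AMU_A2_FS2
from .potentials import PotentialModel
from .system import MolecularSystem

logger = logging.getLogger(__name__)


@dataclass
class Path:
    """An ordered sequence of P+1 frames with fixed endpoints.

    Parameters
    ----------
    frames : array, shape (P+1, N, dim)
        Coordinates in Å; frames 0 and P are the boundary conditions.
    delta : float
        Time step Δ between frames, fs.
    """

    frames: np.ndarray
    delta: float

    def __post_init__(self) -> None:
        self.frames = np.ascontiguousarray(self.frames, dtype=float)
        if self.frames.ndim == 2:  # (P+1, N) shorthand for 1D systems
            self.frames = self.frames[:, :, None]
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (P+1, N, dim)")
        if self.frames.shape[0] < 3:
            raise ValueError("a path needs at least P+1 = 3 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("path coordinates must be finite")
        if not self.delta > 0:
            raise ValueError("delta must be positive")

    @property
    def n_slices(self) -> int:
        """P: the number of time slices (frame count minus one)."""
        return self.frames.shape[0] - 1

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def dim(self) -> int:
        return self.frames.shape[2]

    @property
    def tau(self) -> float:
        """Total time interval τ = P·Δ, fs."""
        return self.n_slices * self.delta

    def copy(self) -> "Path":
        return Path(self.frames.copy(), self.delta)


@dataclass(frozen=True)
class ADMDConfig:
    """Settings of the penalized-action minimization.

    ``target_energy`` is the pre-set total energy E (kcal/mol) the μ_E
    penalty enforces slice by slice; ``temperature`` is the fictitious
    temperature (K) whose equipartition value the μ_K penalty imposes on
    every atom's average kinetic energy.  The penalty weights are
    dimensionless multipliers in the package unit system and should be
    large compared to the kinetic-action scale of the initial path.
    """

    target_energy: float = 0.0
    temperature: float = 300.0
    mu_e: float = 1.0
    mu_k: float = 1.0
    max_iterations: int = 5000
    gradient_tolerance: float = 1e-6
    phi_relative_tolerance: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_e < 0 or self.mu_k < 0:
            raise ValueError("penalty weights must be non-negative")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


@dataclass
class ActionComponents:
    """Φ and its three pieces, all in the action's natural units."""

    total: float
    lagrangian_term: float
    energy_penalty: float
    kinetic_penalty: float


@dataclass
class MinimizeDiagnostics:
    phi_history: list = field(default_factory=list)
    converged: bool = False
    reason: str = ""
    n_iterations: int = 0
    final_components: ActionComponents | None = None
    final_gradient_norm: float = float("nan")


def _check_path_system(path: Path, system: MolecularSystem) -> None:
    if path.n_atoms != system.n_atoms or path.dim != system.dim:
        raise ValueError("path shape does not match the molecular system")


def slice_kinetic_energies(path: Path, system: MolecularSystem) -> np.ndarray:
    """Per-slice, per-atom kinetic energies K_I,j in kcal/mol, shape (P, N).

    Uses forward-difference velocities (q_{j+1} − q_j)/Δ.
    """
    disp = np.diff(path.frames, axis=0)  # (P, N, dim)
    sq = np.einsum("jnd,jnd->jn", disp, disp)
    coef = system.masses * (KCAL_PER_AMU_A2_FS2 / (2.0 * path.delta**2))
    return coef[None, :] * sq


def slice_potential_energies(path: Path,
                             potential: PotentialModel) -> np.ndarray:
    """V({q_j}) for every frame j = 0..P, kcal/mol."""
    return np.array([potential.energy(f) for f in path.frames])


def slice_total_energies(path: Path, potential: PotentialModel,
                         system: MolecularSystem) -> np.ndarray:
    """E_j = K_j + V_j for j = 0..P−1 (forward-difference convention)."""
    kin = slice_kinetic_energies(path, system).sum(axis=1)
    pot = slice_potential_energies(path, potential)[:-1]
    return kin + pot


def mean_kinetic_per_atom(path: Path, system: MolecularSystem) -> np.ndarray:
    """⟨K_I⟩: trajectory average of each atom's kinetic energy, (N,)."""
    return slice_kinetic_energies(path, system).mean(axis=0)


def discrete_lagrangian(path: Path, j: int, potential: PotentialModel,
                        system: MolecularSystem) -> float:
    """L_j = Σ_I (m_I/2Δ²)|q_I,j − q_I,j+1|² − V({q_j}), kcal/mol."""
    _check_path_system(path, system)
    if not 0 <= j <= path.n_slices - 1:
        raise IndexError(f"slice index {j} outside 0..{path.n_slices - 1}")
    disp = path.frames[j] - path.frames[j + 1]
    kinetic = float(np.sum(
        system.masses[:, None] * disp**2
    )) * KCAL_PER_AMU_A2_FS2 / (2.0 * path.delta**2)
    return kinetic - potential.energy(path.frames[j])


def modified_action(path: Path, potential: PotentialModel,
                    system: MolecularSystem,
                    cfg: ADMDConfig) -> ActionComponents:
    """Evaluate Φ and its components for a path."""
    _check_path_system(path, system)
    kin = slice_kinetic_energies(path, system)  # (P, N)
    pot = slice_potential_energies(path, potential)  # (P+1,)
    lagrangian = float((kin.sum(axis=1) - pot[:-1]).sum()) * path.delta
    e_j = kin.sum(axis=1) + pot[:-1]
    energy_pen = cfg.mu_e * float(np.sum((e_j - cfg.target_energy) ** 2))
    k_target = 0.5 * path.dim * KB * cfg.temperature
    kinetic_pen = cfg.mu_k * float(
        np.sum((kin.mean(axis=0) - k_target) ** 2))
    return ActionComponents(lagrangian + energy_pen + kinetic_pen,
                            lagrangian, energy_pen, kinetic_pen)


def _action_and_gradient(path: Path, potential: PotentialModel,
                         system: MolecularSystem,
                         cfg: ADMDConfig) -> tuple[float, np.ndarray]:
    """Φ and its analytic gradient w.r.t. the interior frames.

    Returns the gradient with shape (P−1, N, dim); endpoint frames are
    boundary conditions and carry no gradient entries.
    """
    frames = path.frames
    p = path.n_slices
    delta = path.delta
    masses = system.masses[None, :, None]  # broadcast over frames/dims
    c = KCAL_PER_AMU_A2_FS2

    disp = np.diff(frames, axis=0)  # D_j = q_{j+1} − q_j, (P, N, dim)
    kin_atom = np.einsum("jnd,jnd->jn", disp, disp) \
        * (system.masses * c / (2.0 * delta**2))  # (P, N)
    pot = np.empty(p + 1)
    grad_v = np.empty_like(frames)
    for j in range(p + 1):
        energy, forces = potential.evaluate(frames[j])
        pot[j] = energy
        grad_v[j] = -forces

    second_diff = 2.0 * frames[1:-1] - frames[:-2] - frames[2:]  # (P−1, N, dim)

    # Lagrangian term  Σ_j L_j Δ
    lagrangian = float((kin_atom.sum(axis=1) - pot[:-1]).sum()) * delta
    grad = (masses * c / delta) * second_diff - delta * grad_v[1:-1]

    # Energy-conservation penalty  μ_E Σ_j (E_j − E)²
    e_j = kin_atom.sum(axis=1) + pot[:-1]  # (P,)
    resid = e_j - cfg.target_energy
    energy_pen = cfg.mu_e * float(np.sum(resid**2))
    if cfg.mu_e != 0.0:
        mc_d2 = masses * c / delta**2
        # ∂E_j/∂q_k contributions: j = k (kinetic −D_k and potential ∇V_k)
        # and j = k−1 (kinetic +D_{k−1})
        grad += 2.0 * cfg.mu_e * (
            resid[1:, None, None] * (-(mc_d2 * disp[1:]) + grad_v[1:-1])
            + resid[:-1, None, None] * (mc_d2 * disp[:-1])
        )

    # Per-atom kinetic-temperature penalty  μ_K Σ_I (⟨K_I⟩ − (d/2)k_B T)²
    k_target = 0.5 * path.dim * KB * cfg.temperature
    k_resid = kin_atom.mean(axis=0) - k_target  # (N,)
    kinetic_pen = cfg.mu_k * float(np.sum(k_resid**2))
    if cfg.mu_k != 0.0:
        coef = 2.0 * cfg.mu_k * k_resid[None, :, None] \
            * (masses * c / (p * delta**2))
        grad += coef * second_diff

    total = lagrangian + energy_pen + kinetic_pen
    return total, grad


def generate_initial_path(endpoints: tuple[np.ndarray, np.ndarray], P: int,
                          delta: float, noise_amplitude: float = 0.1,
                          seed: int | np.random.Generator = 0) -> Path:
    """Linear interpolation of the endpoints plus uniform interior noise.

    Interior frames get zero-mean uniform noise in
    [−noise_amplitude, +noise_amplitude] per coordinate; the endpoints are
    copied verbatim.  Deterministic for a fixed seed.
    """
    start = np.asarray(endpoints[0], dtype=float)
    end = np.asarray(endpoints[1], dtype=float)
    if start.ndim == 1:
        start, end = start[:, None], end[:, None]
    if start.shape != end.shape:
        raise ValueError(
            f"endpoint shapes differ: {start.shape} vs {end.shape}")
    if P < 2:
        raise ValueError("P must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, P + 1)[:, None, None]
    frames = (1.0 - t) * start[None] + t * end[None]
    if noise_amplitude > 0:
        frames[1:-1] += rng.uniform(-noise_amplitude, noise_amplitude,
                                    size=frames[1:-1].shape)
    frames[0] = start
    frames[-1] = end
    return Path(frames, delta)


def minimize_action(initial: Path, potential: PotentialModel,
                    system: MolecularSystem,
                    cfg: ADMDConfig) -> tuple[Path, MinimizeDiagnostics]:
    """Minimize Φ over the dim·N·(P−1) interior coordinates.

    Limited-memory quasi-Newton (L-BFGS) descent with the analytic gradient.
    Endpoint frames are never touched.  Convergence: max interior-gradient
    component below ``gradient_tolerance``, or relative Φ change below
    ``phi_relative_tolerance`` sustained over 10 iterations, or the
    iteration cap; the outcome is reported in the diagnostics.
    """
    _check_path_system(initial, system)
    p = initial.n_slices
    shape = (p - 1, initial.n_atoms, initial.dim)
    start, end = initial.frames[0].copy(), initial.frames[-1].copy()
    work = initial.copy()
    diag = MinimizeDiagnostics()
    flat_stale = [0]

    def assemble(x: np.ndarray) -> None:
        work.frames[1:-1] = x.reshape(shape)

    def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
        assemble(x)
        phi, grad = _action_and_gradient(work, potential, system, cfg)
        if not np.isfinite(phi) or not np.all(np.isfinite(grad)):
            raise FloatingPointError(
                "non-finite action or gradient: penalty weights diverge")
        return phi, grad.ravel()

    def callback(x: np.ndarray) -> None:
        assemble(x)
        phi, _ = _action_and_gradient(work, potential, system, cfg)
        if diag.phi_history:
            prev = diag.phi_history[-1]
            denom = max(abs(prev), 1e-300)
            if abs(prev - phi) / denom < cfg.phi_relative_tolerance:
                flat_stale[0] += 1
            else:
                flat_stale[0] = 0
        diag.phi_history.append(phi)
        if flat_stale[0] >= 10:
            raise StopIteration

    x0 = initial.frames[1:-1].ravel().copy()
    phi0, _ = fun(x0)
    diag.phi_history.append(phi0)
    try:
        result = _scipy_minimize(
            fun, x0, jac=True, method="L-BFGS-B", callback=callback,
            options={"maxiter": cfg.max_iterations,
                     "ftol": 1e-16, "gtol": cfg.gradient_tolerance,
                     "maxcor": 20, "maxls": 60})
        x_best = result.x
        n_iter = int(result.nit)
        stalled = flat_stale[0] >= 10
    except StopIteration:
        x_best = work.frames[1:-1].ravel().copy()
        n_iter = len(diag.phi_history) - 1
        stalled = True

    assemble(x_best)
    _, grad = _action_and_gradient(work, potential, system, cfg)
    gmax = float(np.max(np.abs(grad))) if grad.size else 0.0
    diag.final_gradient_norm = gmax
    diag.n_iterations = n_iter
    if gmax <= cfg.gradient_tolerance:
        diag.converged, diag.reason = True, "gradient tolerance reached"
    elif stalled:
        diag.converged, diag.reason = True, "action change below tolerance"
    elif n_iter >= cfg.max_iterations:
        diag.converged, diag.reason = False, "iteration cap reached"
    else:
        diag.converged, diag.reason = True, "optimizer converged"

    out = Path(np.concatenate([start[None], work.frames[1:-1].copy(),
                               end[None]], axis=0), initial.delta)
    out.frames[0] = start
    out.frames[-1] = end
    diag.final_components = modified_action(out, potential, system, cfg)
    logger.info("minimize_action: %s after %d iterations, |grad|max=%.3e",
                diag.reason, diag.n_iterations, gmax)
    return out, diag


def path_barrier(path: Path, potential: PotentialModel) -> float:
    """max_j V(frame j) − max(V(frame 0), V(frame P)), kcal/mol."""
    v = slice_potential_energies(path, potential)
    return float(v.max() - max(v[0], v[-1]))


def run_admd_ensemble(endpoints: tuple[np.ndarray, np.ndarray],
                      potential: PotentialModel, system: MolecularSystem,
                      cfg: ADMDConfig, P: int, delta: float,
                      n_paths: int = 1, noise_amplitude: float = 0.1,
                      seeds: list[int] | None = None) -> list[dict]:
    """Independent ADMD runs from independently seeded initial paths.

    Returns one record per successful run, sorted by (barrier, seed) so the
    lowest-barrier pathway — taken as the most relevant one — comes first.
    Failed runs are recorded with their exception, not fatal.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be at least 1")
    if seeds is None:
        seeds = [cfg.seed + i for i in range(n_paths)]
    if len(seeds) != n_paths:
        raise ValueError("need one seed per path")
    results, failures = [], []
    for seed in seeds:
        initial = generate_initial_path(endpoints, P, delta,
                                        noise_amplitude, seed)
        try:
            path, diag = minimize_action(initial, potential, system,
                                         replace(cfg, seed=seed))
        except FloatingPointError as exc:
            logger.warning("ADMD run with seed %d failed: %s", seed, exc)
            failures.append({"seed": seed, "error": str(exc)})
            continue
        results.append({
            "path": path,
            "barrier": path_barrier(path, potential),
            "seed": seed,
            "diagnostics": diag,
        })
    results.sort(key=lambda r: (r["barrier"], r["seed"]))
    for rec in results:
        rec["failures"] = failures
    return results
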