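"""Restrained Langevin replica-exchange sampling along a pathway.

Conformations are sampled near the generated transition pathway by Langevin
dynamics under a flat-bottom restraint: the sampled conformation is compared
against an ordered set of reference frames taken from the pathway, and

    V_add = 0                              if min-RMSD < r_flat,
    V_add = (k/2)·Σ_I |q_I − q_I,0|²       otherwise,

where {q_I,0} is the nearest reference (after rigid-body alignment when the
reference set is configured to superpose).  Inside the 2 Å transition tube
the restraint is identically zero, so populations along the pathway are
unbiased; outside, a harmonic wall pulls the walker back.

Replicas run at a ladder of temperatures; Metropolis swap moves between
neighbouring temperatures use the conventional probability

    P(exchange) = min[1, exp{(1/k_B·T_i − 1/k_B·T_j)·(V_i − V_j)}].

The integrator is the BAOAB splitting scheme (deterministic kick/drift plus
an exact Ornstein–Uhlenbeck velocity update) with a 1 fs time step and a
damping constant quoted in ps⁻¹.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import FS_PER_PS, KB, KCAL_PER_AMU_A2_FS2
from .potentials import PotentialModel
from .structure_metrics import rmsd_no_fit, superpose
from .system import MolecularSystem

logger = logging.getLogger(__name__)


def select_references(P: int, stride: int) -> np.ndarray:
    """Pathway step indices used as reference states.

    All multiples of ``stride`` not exceeding P − stride, with the final
    frame P appended: the last regular reference keeps a full-stride gap
    before the appended endpoint.  For P = 300, stride = 9 this yields the
    34 indices 0, 9, …, 279, 288, 300.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    if stride > P:
        raise ValueError("stride cannot exceed P")
    regular = np.arange(0, P - stride + 1, stride)
    return np.append(regular, P)


@dataclass
class ReferenceSet:
    """Ordered reference conformations defining the discrete reaction
    coordinate.

    ``frames`` has shape (S, N, dim); ``indices`` are the source pathway
    step indices (strictly increasing, first 0, last P).  ``radius`` is the
    flat-bottom RMSD threshold in Å and ``force_constant`` the harmonic k in
    kcal/mol/Å².  ``superpose`` selects whether RMSD and the harmonic
    displacement use rigid-body alignment (the molecular convention) or raw
    coordinates (appropriate for low-dimensional toys, where removing the
    centroid would erase the reaction coordinate itself).
    """

    frames: np.ndarray
    indices: np.ndarray
    radius: float = 2.0
    force_constant: float = 2.24
    superpose: bool = True

    def __post_init__(self) -> None:
        self.frames = np.ascontiguousarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[:, :, None]
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) != len(self.frames):
            raise ValueError("one source index per reference frame")
        if len(self.frames) == 0:
            raise ValueError("reference set cannot be empty")
        if len(self.indices) > 1 and not np.all(np.diff(self.indices) > 0):
            raise ValueError("reference indices must be strictly increasing")

    @property
    def n_references(self) -> int:
        return len(self.frames)

    @classmethod
    def from_path(cls, path, stride: int, radius: float = 2.0,
                  force_constant: float = 2.24,
                  superpose: bool | None = None) -> "ReferenceSet":
        idx = select_references(path.n_slices, stride)
        if superpose is None:
            superpose = path.dim == 3
        return cls(path.frames[idx].copy(), idx, radius, force_constant,
                   superpose)

    def nearest(self, coords: np.ndarray) -> tuple[int, float, np.ndarray]:
        """Nearest reference: (index, RMSD, reference aligned to coords).

        Ties break toward the lower index.
        """
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 1:
            coords = coords[:, None]
        if not self.superpose:
            diffs = coords[None] - self.frames
            rmsds = np.sqrt(np.mean(np.sum(diffs**2, axis=2), axis=1))
            best = int(np.argmin(rmsds))
            return best, float(rmsds[best]), self.frames[best]
        best, best_rmsd, best_aligned = 0, np.inf, None
        for s, ref in enumerate(self.frames):
            sup = superpose(ref, coords)
            if sup.rmsd < best_rmsd - 1e-15:
                best, best_rmsd = s, sup.rmsd
                best_aligned = sup.apply(ref)
        return best, float(best_rmsd), best_aligned

    def restraint(self, coords: np.ndarray
                  ) -> tuple[float, int, float, np.ndarray]:
        """Flat-bottom restraint: (V_add, nearest index, RMSD, forces).

        Zero inside the tube; otherwise harmonic in the displacement from
        the (aligned) nearest reference.  Because the alignment minimizes
        the squared displacement, the gradient through the alignment
        vanishes and the force is simply −k·(q − q_0).
        """
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 1:
            coords = coords[:, None]
        idx, rmsd, aligned = self.nearest(coords)
        if rmsd < self.radius:
            return 0.0, idx, rmsd, np.zeros_like(coords)
        disp = coords - aligned
        v_add = 0.5 * self.force_constant * float(np.sum(disp**2))
        return v_add, idx, rmsd, -self.force_constant * disp


def exchange_probability(vi: float, vj: float, ti: float, tj: float) -> float:
    """Metropolis probability for swapping conformations between
    temperatures ``ti`` and ``tj`` with potential energies ``vi``, ``vj``."""
    if ti <= 0 or tj <= 0:
        raise ValueError("temperatures must be positive")
    arg = (1.0 / (KB * ti) - 1.0 / (KB * tj)) * (vi - vj)
    return float(min(1.0, np.exp(min(arg, 0.0)) if arg < 0 else 1.0))


@dataclass(frozen=True)
class LadderConfig:
    """Temperature ladder and Langevin/exchange schedule.

    Defaults: eight temperatures 275–450 K in 25 K steps, four independent
    ladders (replicas per temperature), 1 fs time step and 91 ps⁻¹ damping.
    ``total_steps`` and ``exchange_interval`` are desk-scale settings; both
    are freely configurable.
    """

    temperatures: tuple[float, ...] = (275.0, 300.0, 325.0, 350.0,
                                       375.0, 400.0, 425.0, 450.0)
    n_ladders: int = 4
    timestep: float = 1.0
    damping_ps: float = 91.0
    exchange_interval: int = 250
    total_steps: int = 20000
    snapshot_interval: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.timestep <= 0 or self.damping_ps < 0:
            raise ValueError("bad integrator settings")

    @property
    def damping(self) -> float:
        """Friction in fs⁻¹."""
        return self.damping_ps / FS_PER_PS


@dataclass
class ReplicaState:
    """One Langevin walker: coordinates, velocities (Å/fs), its temperature
    slot, and its private random stream."""

    coords: np.ndarray
    velocities: np.ndarray
    slot: int
    replica_id: int
    rng: np.random.Generator
    alive: bool = True

    def __post_init__(self) -> None:
        if self.coords.shape != self.velocities.shape:
            raise ValueError("velocity shape must match coordinates")


def maxwell_boltzmann_velocities(system: MolecularSystem, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Draw velocities in Å/fs from the Maxwell–Boltzmann distribution."""
    sigma = np.sqrt(KB * temperature
                    / (system.masses * KCAL_PER_AMU_A2_FS2))
    return rng.standard_normal((system.n_atoms, system.dim)) \
        * sigma[:, None]


def _total_force(coords: np.ndarray, potential: PotentialModel,
                 refs: ReferenceSet | None) -> tuple[float, float, np.ndarray]:
    energy, forces = potential.evaluate(coords)
    if refs is None:
        return energy, 0.0, forces
    v_add, _, _, f_add = refs.restraint(coords)
    return energy, v_add, forces + f_add


def langevin_step(state: ReplicaState, potential: PotentialModel,
                  refs: ReferenceSet | None, temperature: float,
                  timestep: float, damping: float,
                  system: MolecularSystem,
                  forces: np.ndarray | None = None) -> np.ndarray:
    """One BAOAB update at the given temperature; returns the forces at the
    new position (reusable as the next step's input).

    With zero friction and zero temperature the O-step is the identity and
    the update reduces to velocity-Verlet; with zero forces as well, motion
    is ballistic.
    """
    m = system.masses[:, None] * KCAL_PER_AMU_A2_FS2  # amu→energy units
    if forces is None:
        _, _, forces = _total_force(state.coords, potential, refs)
    half = 0.5 * timestep
    state.velocities = state.velocities + half * forces / m
    state.coords = state.coords + half * state.velocities
    if damping > 0:
        c1 = np.exp(-damping * timestep)
        c2 = np.sqrt(1.0 - c1 * c1)
        sigma = np.sqrt(KB * temperature / m)
        noise = state.rng.standard_normal(state.coords.shape)
        state.velocities = c1 * state.velocities + c2 * sigma * noise
    state.coords = state.coords + half * state.velocities
    _, _, new_forces = _total_force(state.coords, potential, refs)
    if not np.all(np.isfinite(new_forces)):
        state.alive = False
        raise FloatingPointError(
            f"replica {state.replica_id}: non-finite forces")
    state.velocities = state.velocities + half * new_forces / m
    return new_forces


@dataclass
class SampleStore:
    """Pooled REMD snapshots plus exchange statistics.

    Column arrays, one entry per snapshot: simulation step, ladder id,
    temperature-slot index, slot temperature (K), replica id, nearest
    reference index, potential energy V, restraint energy V_add, radius of
    gyration, no-fit RMSD to the final reference, and (optionally, at a
    stride) coordinates.
    """

    step: np.ndarray
    ladder: np.ndarray
    slot: np.ndarray
    temperature: np.ndarray
    replica_id: np.ndarray
    state_index: np.ndarray
    potential_energy: np.ndarray
    restraint_energy: np.ndarray
    rg: np.ndarray
    rmsd_to_final: np.ndarray
    coords: np.ndarray | None = None
    coords_stride: int = 0
    exchange_attempts: dict = field(default_factory=dict)
    exchange_accepts: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.step)

    def acceptance_rates(self) -> dict[tuple[int, int], float]:
        """Per-neighbour-pair swap acceptance rates."""
        return {pair: self.exchange_accepts.get(pair, 0) / att
                for pair, att in self.exchange_attempts.items() if att > 0}

    def at_temperature(self, temperature: float) -> np.ndarray:
        """Boolean mask of snapshots taken at the given slot temperature."""
        return np.isclose(self.temperature, temperature)


def run_remd(potential: PotentialModel, system: MolecularSystem,
             refs: ReferenceSet, cfg: LadderConfig,
             initial_coords: np.ndarray | None = None,
             store_coords: bool = True,
             restrained: bool = True) -> SampleStore:
    """Restrained replica-exchange Langevin sampling.

    ``cfg.n_ladders`` independent ladders each hold one replica per
    temperature.  Replicas start from conformations sampled uniformly from
    the reference set (or from ``initial_coords`` of shape
    (n_ladders, n_temperatures, N, dim)) with Maxwell–Boltzmann velocities
    at their slot temperature.  Every ``exchange_interval`` steps, swap
    moves are attempted between adjacent slots with alternating even/odd
    pairing; accepted swaps exchange conformations and rescale velocities
    by sqrt(T_new/T_old).  A replica whose energy diverges is excluded from
    further exchanges; its past samples are kept.
    """
    temps = np.asarray(cfg.temperatures)
    n_temps = len(temps)
    root = np.random.SeedSequence(cfg.seed)
    ladder_seeds = root.spawn(cfg.n_ladders)
    active_refs = refs if restrained else None

    rows: dict[str, list] = {k: [] for k in
                             ("step", "ladder", "slot", "temperature",
                              "replica_id", "state_index",
                              "potential_energy", "restraint_energy",
                              "rg", "rmsd_to_final")}
    coords_rows: list[np.ndarray] = []
    attempts: dict[tuple[int, int], int] = {}
    accepts: dict[tuple[int, int], int] = {}
    final_ref = refs.frames[-1]
    masses = system.masses

    for ladder_idx in range(cfg.n_ladders):
        streams = ladder_seeds[ladder_idx].spawn(n_temps + 1)
        exchange_rng = np.random.default_rng(streams[-1])
        replicas: list[ReplicaState] = []
        for slot in range(n_temps):
            rng = np.random.default_rng(streams[slot])
            if initial_coords is not None:
                q0 = np.array(initial_coords[ladder_idx][slot], dtype=float)
                if q0.ndim == 1:
                    q0 = q0[:, None]
            else:
                q0 = refs.frames[rng.integers(refs.n_references)].copy()
            v0 = maxwell_boltzmann_velocities(system, temps[slot], rng)
            replicas.append(ReplicaState(
                q0, v0, slot, ladder_idx * n_temps + slot, rng))

        by_slot = list(replicas)  # slot -> replica
        forces = [None] * n_temps
        parity = 0
        n_rounds = cfg.total_steps // cfg.exchange_interval
        for rnd in range(n_rounds):
            for local_step in range(cfg.exchange_interval):
                step = rnd * cfg.exchange_interval + local_step
                for slot, rep in enumerate(by_slot):
                    if not rep.alive:
                        continue
                    try:
                        forces[slot] = langevin_step(
                            rep, potential, active_refs, temps[slot],
                            cfg.timestep, cfg.damping, system, forces[slot])
                    except FloatingPointError as exc:
                        logger.warning("ladder %d: %s", ladder_idx, exc)
                        forces[slot] = None
                        continue
                    if (step + 1) % cfg.snapshot_interval == 0:
                        energy, v_add, _ = _total_force(
                            rep.coords, potential, active_refs)
                        state_idx, _, _ = refs.nearest(rep.coords)
                        com = (masses[:, None] * rep.coords).sum(0) \
                            / masses.sum()
                        rg = np.sqrt(np.sum(
                            masses * np.sum((rep.coords - com)**2, 1))
                            / masses.sum())
                        rows["step"].append(step + 1)
                        rows["ladder"].append(ladder_idx)
                        rows["slot"].append(slot)
                        rows["temperature"].append(temps[slot])
                        rows["replica_id"].append(rep.replica_id)
                        rows["state_index"].append(state_idx)
                        rows["potential_energy"].append(energy)
                        rows["restraint_energy"].append(v_add)
                        rows["rg"].append(float(rg))
                        rows["rmsd_to_final"].append(
                            rmsd_no_fit(rep.coords, final_ref))
                        if store_coords:
                            coords_rows.append(rep.coords.copy())
            # exchange phase: adjacent pairs, alternating parity
            for low in range(parity, n_temps - 1, 2):
                hi = low + 1
                rep_lo, rep_hi = by_slot[low], by_slot[hi]
                if not (rep_lo.alive and rep_hi.alive):
                    continue
                e_lo, add_lo, _ = _total_force(rep_lo.coords, potential,
                                               active_refs)
                e_hi, add_hi, _ = _total_force(rep_hi.coords, potential,
                                               active_refs)
                prob = exchange_probability(e_lo + add_lo, e_hi + add_hi,
                                            temps[low], temps[hi])
                pair = (low, hi)
                attempts[pair] = attempts.get(pair, 0) + 1
                if exchange_rng.uniform() < prob:
                    accepts[pair] = accepts.get(pair, 0) + 1
                    scale_up = np.sqrt(temps[hi] / temps[low])
                    by_slot[low], by_slot[hi] = rep_hi, rep_lo
                    by_slot[low].velocities = \
                        by_slot[low].velocities / scale_up
                    by_slot[hi].velocities = \
                        by_slot[hi].velocities * scale_up
                    by_slot[low].slot, by_slot[hi].slot = low, hi
                    forces[low], forces[hi] = forces[hi], forces[low]
            parity = 1 - parity

    store = SampleStore(
        **{k: np.asarray(v) for k, v in rows.items()},
        coords=np.asarray(coords_rows) if store_coords and coords_rows
        else None,
        coords_stride=cfg.snapshot_interval if store_coords else 0,
        exchange_attempts=attempts,
        exchange_accepts=accepts,
    )
    logger.info("REMD finished: %d snapshots, acceptance %s",
                store.n_samples,
                {p: round(r, 3) for p, r in store.acceptance_rates().items()})
    return store
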