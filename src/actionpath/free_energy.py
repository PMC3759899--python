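"""Free-energy profiles along the discrete reaction coordinate.

REMD samples are classified to their nearest reference conformation; the
reference index then serves as the reaction coordinate.  At each ladder
temperature the state populations p_s give free energies

    F_s = −k_B·T·ln p_s,   shifted so min_s F_s = 0.

No reweighting across temperatures is performed: populations are counted
directly per temperature, matching the protocol this package implements.
Error bars come from block averaging; profiles against scalar metrics
(radius of gyration, RMSD to the final state) and the energy-histogram
overlap between neighbouring temperatures serve as ladder diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB
from .remd import ReferenceSet, SampleStore


def classify_samples(conformations: np.ndarray,
                     refs: ReferenceSet) -> np.ndarray:
    """Assign each conformation the index of its nearest reference.

    ``conformations`` has shape (M, N, dim).  Nearness is the same RMSD
    (superposed or raw, per the reference set) used by the restraint; ties
    break toward the lower index.
    """
    conformations = np.asarray(conformations, dtype=float)
    if conformations.ndim == 2:
        conformations = conformations[:, :, None]
    return np.array([refs.nearest(c)[0] for c in conformations], dtype=int)


@dataclass
class StateProfile:
    """Populations and free energies over reference states at one
    temperature.

    Empty states are flagged in ``occupied``; their F entries are NaN
    rather than infinite so that downstream tables stay finite-valued.
    """

    temperature: float
    counts: np.ndarray
    populations: np.ndarray
    free_energy: np.ndarray
    occupied: np.ndarray
    stderr: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return len(self.counts)


def profile_from_populations(labels: np.ndarray, n_states: int,
                             temperature: float) -> StateProfile:
    """Direct-counting free-energy profile at one temperature."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("no classified samples")
    counts = np.bincount(labels, minlength=n_states).astype(float)
    populations = counts / counts.sum()
    occupied = counts > 0
    free_energy = np.full(n_states, np.nan)
    free_energy[occupied] = -KB * temperature * np.log(populations[occupied])
    free_energy[occupied] -= free_energy[occupied].min()
    return StateProfile(temperature, counts, populations, free_energy,
                        occupied)


@dataclass
class FreeEnergyProfile:
    """Per-temperature state profiles plus bookkeeping of the run."""

    profiles: dict[float, StateProfile]
    restraint_violation: float
    n_states: int

    def at(self, temperature: float) -> StateProfile:
        for t, prof in self.profiles.items():
            if np.isclose(t, temperature):
                return prof
        raise KeyError(f"no profile at {temperature} K")


def _block_stderr(labels_blocks: list[np.ndarray], n_states: int,
                  temperature: float) -> np.ndarray:
    """Standard error of F_s from block-wise profiles."""
    f_blocks = []
    for block in labels_blocks:
        if block.size == 0:
            continue
        prof = profile_from_populations(block, n_states, temperature)
        f_blocks.append(prof.free_energy)
    if len(f_blocks) < 2:
        return np.full(n_states, np.nan)
    f = np.array(f_blocks)
    with np.errstate(invalid="ignore"):
        return np.nanstd(f, axis=0, ddof=1) / np.sqrt(
            np.sum(~np.isnan(f), axis=0).clip(min=1))


def build_profile(store: SampleStore, refs: ReferenceSet,
                  burn_in: float = 0.1,
                  n_blocks: int = 10) -> FreeEnergyProfile:
    """Free-energy profile at every ladder temperature from a sample store.

    The first ``burn_in`` fraction of each replica's samples (by step) is
    discarded as equilibration; errors are estimated by block averaging
    over ``n_blocks`` contiguous time blocks.
    """
    if store.n_samples == 0:
        raise ValueError("empty sample store")
    max_step = store.step.max()
    keep = store.step > burn_in * max_step
    n_states = refs.n_references
    profiles: dict[float, StateProfile] = {}
    for temp in np.unique(store.temperature):
        mask = keep & store.at_temperature(temp)
        labels = store.state_index[mask]
        if labels.size == 0:
            continue
        prof = profile_from_populations(labels, n_states, float(temp))
        steps = store.step[mask]
        edges = np.linspace(steps.min(), steps.max() + 1, n_blocks + 1)
        blocks = [labels[(steps >= edges[b]) & (steps < edges[b + 1])]
                  for b in range(n_blocks)]
        prof.stderr = _block_stderr(blocks, n_states, float(temp))
        profiles[float(temp)] = prof
    violation = restraint_violation_fraction(store)
    return FreeEnergyProfile(profiles, violation, n_states)


def profile_vs_metric(values: np.ndarray, temperature: float,
                      bins: int = 50,
                      bin_range: tuple[float, float] | None = None
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram-based free energy against a scalar metric.

    Returns (bin centers, normalized histogram, F) with F min-shifted to
    zero and empty bins masked as NaN.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no metric values")
    counts, edges = np.histogram(values, bins=bins, range=bin_range)
    if np.count_nonzero(counts) < 2 and values.std() > 0:
        raise ValueError("fewer than 2 occupied bins")
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / counts.sum()
    f = np.full(len(counts), np.nan)
    occ = counts > 0
    f[occ] = -KB * temperature * np.log(density[occ])
    f[occ] -= f[occ].min()
    return centers, density, f


def energy_pdf_overlap(store: SampleStore, ti: float, tj: float,
                       bins: int = 50) -> float:
    """Overlap Σ_bins min(p_i, p_j) of the potential-energy histograms at
    two ladder temperatures, with shared bin edges over the pooled range."""
    ei = store.potential_energy[store.at_temperature(ti)]
    ej = store.potential_energy[store.at_temperature(tj)]
    if ei.size == 0 or ej.size == 0:
        raise ValueError("one of the temperatures has no samples")
    lo = min(ei.min(), ej.min())
    hi = max(ei.max(), ej.max())
    if hi == lo:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    pi, _ = np.histogram(ei, bins=edges)
    pj, _ = np.histogram(ej, bins=edges)
    return float(np.minimum(pi / pi.sum(), pj / pj.sum()).sum())


def restraint_violation_fraction(store: SampleStore) -> float:
    """Fraction of snapshots with active (non-zero) restraint energy."""
    if store.n_samples == 0:
        raise ValueError("empty sample store")
    return float(np.mean(store.restraint_energy > 0))


def barrier_heights(free_energy: np.ndarray
                    ) -> list[tuple[tuple[int, int], float]]:
    """Barriers between adjacent local minima of a state-index profile.

    A local minimum is a state strictly lower than its occupied neighbours
    (plateau edges count once).  For each adjacent pair of minima the
    barrier is the maximum F between them minus the shallower (higher)
    minimum.  NaN entries (empty states) are skipped over.
    """
    f = np.asarray(free_energy, dtype=float)
    idx = np.flatnonzero(~np.isnan(f))
    if idx.size < 2:
        return []
    vals = f[idx]
    minima = []
    for k in range(len(vals)):
        left = vals[k - 1] if k > 0 else np.inf
        right = vals[k + 1] if k < len(vals) - 1 else np.inf
        if vals[k] < left and vals[k] <= right:
            minima.append(k)
    out = []
    for a, b in zip(minima[:-1], minima[1:]):
        peak = vals[a:b + 1].max()
        shallower = max(vals[a], vals[b])
        if peak > shallower:
            out.append(((int(idx[a]), int(idx[b])),
                        float(peak - shallower)))
    return out
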