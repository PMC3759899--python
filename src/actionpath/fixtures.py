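"""Ready-to-run toy scenarios.

Each fixture writes endpoint conformations, potential parameters and a
complete :class:`~actionpath.config.RunConfig` into a directory, sized so
that the full optimize → quality → remd → profile pipeline completes in
minutes on one CPU.  The toy systems stand in for a molecular test system:
their stationary points and Boltzmann statistics are known or brute-force
computable, which is what makes the pipeline verifiable end to end.
"""

from __future__ import annotations

from pathlib import Path as FilePath

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .admd import ADMDConfig
from .config import PathConfig, ReferenceConfig, RunConfig
from .io import write_toy_coords, write_xyz
from .potentials import (DoubleWell1D, GaussianSurface2D, LJCluster,
                         find_stationary_points)
from .remd import LadderConfig

FIXTURE_NAMES = ("double_well_1d", "gaussian_2d", "lj7_3d", "harmonic_chain")

# Double-well study conditions: a light particle and a barrier on the scale
# of the free-energy barriers the protocol is meant to resolve (a few
# kcal/mol), so that ladder temperatures of 275-450 K produce measurable
# inter-well traffic within desk-scale run lengths.
DOUBLE_WELL = {"barrier_height": 2.5, "well_position": 1.0, "mass": 1.0}


def _gaussian_minima_and_saddles(pot: GaussianSurface2D):
    grid = np.array(np.meshgrid(np.linspace(-3.0, 3.0, 25),
                                np.linspace(-1.5, 3.0, 19)))
    pts = find_stationary_points(pot, grid.reshape(2, -1).T, gtol=1e-12)
    minima = [p for p in pts if p["kind"] == "minimum"]
    saddles = [p for p in pts if p["kind"] == "saddle"]
    return minima, saddles


def _lj7_endpoints(seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two distinct local minima of the 7-atom Lennard-Jones cluster.

    Local minimization from a pentagonal-bipyramid start (the global
    minimum basin) and from a capped-octahedron start (a higher local
    minimum) gives two reproducible endpoint structures.
    """
    pot = LJCluster(7)

    def minimize_from(x0):
        res = _scipy_minimize(
            lambda x: pot.energy(x.reshape(7, 3)), x0.ravel(),
            jac=lambda x: -pot.forces(x.reshape(7, 3)).ravel(),
            method="L-BFGS-B", options={"gtol": 1e-10, "maxiter": 2000})
        return res.x.reshape(7, 3)

    r = 2 ** (1 / 6)  # dimer separation at the LJ minimum
    ring = np.array([[r * np.cos(2 * np.pi * k / 5),
                      r * np.sin(2 * np.pi * k / 5), 0.0]
                     for k in range(5)])
    bipyramid = np.vstack([ring, [[0, 0, 0.85 * r], [0, 0, -0.85 * r]]])
    octa = r * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                         [0, 0, 1], [0, 0, -1]]) / np.sqrt(2)
    capped_octa = np.vstack([octa, [[0.9, 0.9, 0.9]]])
    rng = np.random.default_rng(seed)
    a = minimize_from(bipyramid + 0.01 * rng.standard_normal((7, 3)))
    b = minimize_from(capped_octa + 0.01 * rng.standard_normal((7, 3)))
    return a - a.mean(axis=0), b - b.mean(axis=0)


def make_fixtures(name: str, seed: int, outdir) -> RunConfig:
    """Write a toy scenario into ``outdir``; returns its RunConfig."""
    outdir = FilePath(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if name == "double_well_1d":
        h, a = DOUBLE_WELL["barrier_height"], DOUBLE_WELL["well_position"]
        cfg = RunConfig(
            potential="double_well_1d",
            potential_params={"barrier_height": h, "well_position": a},
            n_atoms=1, masses=[DOUBLE_WELL["mass"]],
            path=PathConfig(n_slices=100, delta=0.5, noise_amplitude=0.05),
            admd=ADMDConfig(target_energy=1.05 * h, temperature=300.0,
                            mu_e=10.0, mu_k=10.0, seed=seed),
            ladder=LadderConfig(seed=seed),
            references=ReferenceConfig(stride=3, superpose=False),
            seed=seed)
        write_toy_coords(outdir / "endpoint_a.txt", np.array([[-a]]),
                         "left well minimum")
        write_toy_coords(outdir / "endpoint_b.txt", np.array([[a]]),
                         "right well minimum")
    elif name == "gaussian_2d":
        pot = GaussianSurface2D()
        minima, saddles = _gaussian_minima_and_saddles(pot)
        deep = [m for m in minima
                if m["energy"] <= minima[0]["energy"] + 1e-6]
        deep.sort(key=lambda m: m["point"][0])
        start, end = deep[0]["point"], deep[-1]["point"]
        barrier_top = min(s["energy"] for s in saddles)
        cfg = RunConfig(
            potential="gaussian_2d", potential_params={},
            n_atoms=1, masses=[1.0],
            path=PathConfig(n_slices=100, delta=3.0, noise_amplitude=0.05),
            admd=ADMDConfig(target_energy=barrier_top + 0.02,
                            temperature=300.0, mu_e=1000.0, mu_k=1.0,
                            seed=seed),
            ladder=LadderConfig(seed=seed),
            references=ReferenceConfig(stride=3, superpose=False),
            seed=seed)
        write_toy_coords(outdir / "endpoint_a.txt", start[None, :],
                         "left basin minimum")
        write_toy_coords(outdir / "endpoint_b.txt", end[None, :],
                         "right basin minimum")
    elif name == "lj7_3d":
        a, b = _lj7_endpoints(seed)
        pot = LJCluster(7)
        cfg = RunConfig(
            potential="lj_cluster",
            potential_params={"epsilon": 1.0, "sigma": 1.0},
            n_atoms=7, masses=[1.0] * 7,
            path=PathConfig(n_slices=60, delta=1.0, noise_amplitude=0.05),
            admd=ADMDConfig(
                target_energy=max(pot.energy(a), pot.energy(b)) + 2.0,
                temperature=300.0, mu_e=10.0, mu_k=10.0, seed=seed),
            ladder=LadderConfig(seed=seed, total_steps=4000),
            references=ReferenceConfig(stride=6, radius=0.5,
                                       superpose=True),
            seed=seed)
        labels = ["Ar"] * 7
        write_xyz(outdir / "endpoint_a.xyz", a, labels,
                  "LJ7 pentagonal bipyramid")
        write_xyz(outdir / "endpoint_b.xyz", b, labels,
                  "LJ7 capped octahedron")
    elif name == "harmonic_chain":
        n = 5
        x_a = np.arange(n, dtype=float)[:, None]
        x_b = x_a + 1.5
        cfg = RunConfig(
            potential="harmonic_chain",
            potential_params={"spring_constant": 10.0, "spacing": 1.0},
            n_atoms=n, masses=[1.0] * n,
            path=PathConfig(n_slices=60, delta=0.5, noise_amplitude=0.02),
            admd=ADMDConfig(target_energy=0.5, temperature=150.0,
                            mu_e=10.0, mu_k=10.0, seed=seed),
            ladder=LadderConfig(seed=seed, total_steps=4000),
            references=ReferenceConfig(stride=6, superpose=False),
            seed=seed)
        write_toy_coords(outdir / "endpoint_a.txt", x_a,
                         "chain at equilibrium")
        write_toy_coords(outdir / "endpoint_b.txt", x_b,
                         "translated chain")
    else:
        raise ValueError(
            f"unknown fixture {name!r}; options: {FIXTURE_NAMES}")

    cfg.save(outdir / "config.yaml")
    return cfg
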