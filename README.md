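# actionpath

Transition pathways between two fixed molecular conformations by
discrete-action minimization, and temperature-dependent free-energy
profiles along those pathways by restrained replica-exchange Langevin
sampling.

## Who this is for

Researchers in molecular modelling who want a *boundary-value* treatment of
a rare conformational transition: instead of waiting for a long forward
simulation to cross a barrier, the transition path is obtained by
optimization between known endpoints, and the thermodynamics along it are
then measured by temperature-ladder sampling confined to a tube around the
path.  All physics enters through a pluggable potential-energy contract;
the package ships analytically tractable toy systems (1D double well, 2D
multi-Gaussian surface, Lennard-Jones cluster, harmonic chain) so the whole
protocol is verifiable end to end against closed forms and quadrature.

## The method in brief

**Stage 1 — pathway.**  A path is P+1 frames q_j with fixed endpoints and
time step Δ.  The objective

    Φ = Σ_j L_j·Δ + μ_E·Σ_j (E_j − E)² + μ_K·Σ_I (⟨K_I⟩ − (d/2)k_B T)²,
    L_j = Σ_I (m_I/2Δ²)|q_{I,j} − q_{I,j+1}|² − V(q_j)

is minimized over all interior frames (L-BFGS with analytic gradients).
The penalties enforce energy conservation at a pre-set target E and
equipartition at a fictitious temperature T; stationary paths of the bare
action satisfy the position-Verlet recursion, so optimized paths are
near-Newtonian.  Path quality is scored by the Onsager–Machlup action
(mean squared Verlet residual, zero for a true Verlet trajectory) and a
discrete curvature profile calibrated so a line gives 0 and a circle of
radius r gives 1/r.

**Stage 2 — thermodynamics.**  The path is subsampled into ordered
reference conformations (for P = 300, stride 9: 34 references).  Langevin
replicas (BAOAB, 1 fs, 91 ps⁻¹ damping) at a temperature ladder
(275–450 K by default) sample under a flat-bottom restraint: zero within
2 Å RMSD of the nearest reference, harmonic (k = 2.24 kcal/mol/Å²) beyond.
Metropolis swaps between neighbouring temperatures use
P = min[1, exp{(1/k_BT_i − 1/k_BT_j)(V_i − V_j)}].  Each sample is
classified to its nearest reference; per-temperature populations give
F_s = −k_B T ln p_s, minimum shifted to zero.

## Worked example

```bash
actionpath fixtures --name double_well_1d --seed 3 --out run/
actionpath optimize --config run/config.yaml \
    --endpoints run/endpoint_a.txt run/endpoint_b.txt --out run/path.npz
actionpath quality  --archive run/path.npz --out run/quality.txt
actionpath remd     --archive run/path.npz --out run/samples.npz
actionpath profile  --store run/samples.npz --archive run/path.npz \
    --out run/profiles
```

Output printed by the pipeline stages (seed 3):

```
best barrier 2.4999 kcal/mol (seed 3); archive: run/path.npz
S_OM = 8.129089e-05 A^2 over 99 error variables; report: run/quality.txt
64000 snapshots; acceptance {'0-1': 0.994, '2-3': 0.975, ...}; store: run/samples.npz
restraint-violation fraction: 0.0000
profiles written to run/profiles
```

Reading the numbers: the optimized path crosses the quartic double-well
barrier at 2.4999 kcal/mol against an exact barrier height of 2.5 — the
path passes essentially through the transition state.  The small
Onsager–Machlup score (≈ 8·10⁻⁵ Å² mean squared Verlet residual) says the
path is close to a true Newtonian trajectory at this Δ.  Exchange
acceptance near 0.97 means neighbouring temperatures overlap well, and a
zero restraint-violation fraction means sampling stayed inside the 2 Å
transition tube, where the restraint is exactly zero and populations are
unbiased.  `run/profiles/profile_T300K.txt` then lists, per reference
state, the population and free energy with block-averaged standard errors;
for this symmetric double well the two wells come out equally populated
within error, and the inter-well free-energy difference matches direct
quadrature of the Boltzmann integral (the test suite asserts this at every
ladder temperature).

The same flow runs for `gaussian_2d`, `lj7_3d` and `harmonic_chain`
fixtures; everything is driven by `config.yaml`, which each stage copies,
resolved, next to its outputs.

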