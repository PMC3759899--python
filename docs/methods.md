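# Methods

`actionpath` implements a two-stage protocol for characterizing a
conformational transition between two fixed structures: (1) generate a
low-barrier transition pathway by minimizing a penalized discrete classical
action over all interior frames (a boundary-value formulation of Newtonian
dynamics), and (2) measure the temperature-dependent free-energy profile
along that pathway by restrained Langevin replica-exchange sampling
projected onto a discrete set of reference conformations.  This note
records the model, its assumptions, the numerical choices, and what the
toy-system validation does and does not establish.

## Units

Lengths in Å, energies in kcal/mol, masses in amu, time in fs,
temperatures in K.  `k_B = 0.0019872041` kcal/mol/K.  The single conversion
constant `KCAL_PER_AMU_A2_FS2 = 1e7/4184 ≈ 2390.057` (kcal/mol per
amu·Å²/fs²) is applied wherever kinetic energy in mechanical units meets
potential energy in thermochemical units.

## Stage 1: pathway generation by action minimization

A path is P+1 frames `q_j` (j = 0..P) with fixed endpoints and uniform time
step Δ, so τ = P·Δ.  The objective minimized over the dim·N·(P−1) interior
coordinates is

    Φ = Σ_{j=0}^{P−1} L_j·Δ + μ_E·Σ_{j=0}^{P−1} (E_j − E)²
                            + μ_K·Σ_I (⟨K_I⟩ − (d/2)·k_B·T)²

with `L_j = Σ_I (m_I/2Δ²)|q_{I,j} − q_{I,j+1}|² − V(q_j)`.  A stationary
point of the bare action term satisfies the position-Verlet recursion, so
the optimum is a near-Newtonian trajectory; the test suite verifies that a
Verlet-integrated trajectory zeroes the interior gradient of Σ L_j·Δ to
1e-6.

The two penalties make the problem well-posed: minimizing K − V alone would
reward running up the potential without bound, while pinning every slice's
total energy `E_j` to the target E ties kinetic energy to potential energy
(energy conservation along the path), and pinning each atom's average
kinetic energy to the equipartition value of a fictitious temperature T
spreads the motion over all atoms.

Conventions the discretization leaves genuinely open, fixed here once:

- `E_j = Σ_I (m_I/2)|(q_{I,j+1} − q_{I,j})/Δ|² + V(q_j)` —
  forward-difference velocities, the simplest convention consistent with
  the kinetic term of `L_j`.
- `⟨K_I⟩` is the average of the same forward-difference kinetic energy over
  j = 0..P−1.
- For d-dimensional toy systems the equipartition target is (d/2)·k_B·T.

**Optimizer.**  L-BFGS (scipy, `maxcor=20`) on the interior coordinates
with the analytic gradient of Φ assembled term by term (verified against
central finite differences to 1e-6 relative in the tests).  Endpoint frames
are never part of the variable vector, so boundary preservation is
structural, not numerical.  Convergence: max interior-gradient component
below `gradient_tolerance` (default 1e-6), or relative Φ change below
`phi_relative_tolerance` (default 1e-8) sustained over 10 iterations, or
the iteration cap (default 5000); the diagnostics report which fired.  Note
that for objectives with a large constant baseline (e.g. a free particle)
the relative-change rule can stop before the gradient rule; tighten
`phi_relative_tolerance` when coordinate-level accuracy matters.

**Choosing E and the penalty weights.**  The default target energy is V at
the higher-energy endpoint plus a configurable margin.  For barrier
crossing, E must exceed the saddle energy; how closely it brackets it
controls how tightly the path is funneled through the saddle region
(since K ≥ 0 forces V ≲ E along an energy-conserving path).  The shipped
2D fixture sets E = V_saddle + 0.02 with μ_E = 1000, which pins the path's
closest approach to the Newton-located saddles below 0.05 length units;
the 1D double-well fixture sets E = 1.05·h with μ_E = μ_K = 10, recovering
the barrier height to 0.1%.  τ must also be generous enough that the path
can cross the saddle slowly; too small a τ forces high kinetic energy and
corner-cutting (the 2D fixture uses P = 100, Δ = 3 fs).

**Initial paths** are the linear interpolation of the endpoints plus
zero-mean uniform noise (amplitude configurable) on the interior frames;
ensembles use consecutive seeds and report pathways sorted by barrier
height with stable (barrier, seed) tie-breaking.

## Path quality

The per-atom, per-slice Verlet residual

    ε_I,j = 2q_I,j − q_I,j−1 − q_I,j+1 − (Δ²/m_I)·∂V/∂q_I,j,  j = 1..P−1

gives dim·N·(P−1) scalar "error variables" in Å; their mean square is the
Onsager–Machlup score S_OM (Å²), zero exactly on a Verlet trajectory.
Sampling an exact continuous trajectory at decreasing Δ (fixed τ) drives
S_OM → 0, verified by a Δ-halving sequence in the tests.  The error
histogram defaults to 101 bins over ±5σ, symmetric about zero.

The discrete curvature at interior frame j is

    C(j) = ‖2q_j − q_{j−1} − q_{j+1}‖ / (‖q_j − q_{j−1}‖·‖q_j − q_{j+1}‖)

with norms over all atoms jointly.  This normalization is fixed by two
calibration properties: C ≡ 0 on a straight line, and C = 1/r exactly on a
uniformly stepped circle of radius r (an identity that holds at any arc
step, which the tests exploit at radii 2 and 10 Å).  Coincident adjacent
frames make C(j) undefined; it is reported as NaN, not an error.

## Structural metrics

Optimal superposition uses the quaternion eigenvalue method (the largest
eigenvalue of the 4×4 Horn matrix of the centered correlation).  The
parameterization covers proper rotations only, so chirality is preserved by
construction.  The RMSD is evaluated from the aligned coordinates rather
than from the G_a + G_b − 2λ identity, which loses half the significant
digits to cancellation near zero.  RMSD is all-atom and unweighted; the
radius of gyration is mass-weighted about the center of mass (switchable to
geometric).  With fewer than 3 atoms in 3D the rotation is
under-determined: the translational optimum is returned with a flag.  For
dimensionality below 3, superposition degenerates to translation-only
alignment.

## Stage 2: restrained replica-exchange sampling

**Reference states.**  The pathway is subsampled at a stride: all
multiples of the stride up to P − stride, plus the final frame (for
P = 300, stride 9: the 34 indices 0, 9, …, 288, 300).  The ordered
reference index is the discrete reaction coordinate.

**Flat-bottom restraint.**  Each sampled conformation is compared to all
references; if the lowest RMSD is below the tube radius (default 2 Å) the
restraint is identically zero, otherwise `V_add = (k/2)·Σ_I |q_I − q_I,0|²`
with k = 2.24 kcal/mol/Å² and `{q_I,0}` the nearest reference.  Populations
inside the tube are therefore exactly unbiased — a trajectory that stays
inside is bit-identical to an unrestrained one under the same random
stream, which the tests assert literally.

Two choices the restraint formula leaves open:

- *Alignment.*  When the reference set is configured to superpose (the
  molecular 3D convention), the nearest reference is rigid-body aligned to
  the current conformation before the displacement is taken; a
  raw-coordinate restraint would penalize rigid rotation while the RMSD
  gate ignores it.  Because the alignment minimizes the squared
  displacement, the envelope theorem makes the force exactly
  −k·(q − q_aligned); the finite-difference check in the tests confirms
  this through the alignment.  For 1D/2D toys alignment is disabled
  (`superpose=False`): removing the centroid of a 1-particle system would
  erase the reaction coordinate itself.
- *The discontinuity* of the force at the tube boundary is accepted as the
  formula is written.

**Integrator.**  BAOAB splitting (half kick, half drift, exact
Ornstein–Uhlenbeck velocity refresh, half drift, half kick) at 1 fs with
damping 91 ps⁻¹ (converted to fs⁻¹ internally).  Velocities are initialized
from the Maxwell–Boltzmann distribution at each replica's slot temperature.
Equipartition in a harmonic well is verified to 3 standard errors.

**Ladder and exchanges.**  Default temperatures 275–450 K in 25 K steps.
The "replicas per temperature" multiplicity is realized as independent
ladders (default 4), each with one replica per temperature, samples pooled;
how multiple replicas per temperature would interact in a single ladder is
not defined by the protocol, and independent ladders keep every swap
well-defined.  Swap moves between adjacent slots are attempted every
`exchange_interval` steps with alternating even/odd pairing, using

    P(exchange) = min[1, exp{(1/k_B·T_i − 1/k_B·T_j)·(V_i − V_j)}]

where V includes `V_add`.  On acceptance, conformations swap slots and
velocities are rescaled by sqrt(T_new/T_old) (regenerating them would also
be valid; rescaling preserves the Maxwell–Boltzmann marginal).  The swap
kernel's exact stationarity on a two-level surrogate is verified by linear
algebra in the tests.  A replica whose forces diverge is excluded from
further stepping and exchanges; its past samples are kept.

**Random streams.**  A single global seed expands through
`numpy.random.SeedSequence.spawn` into one stream per replica plus one
exchange stream per ladder, so every replica has an independent,
reproducible generator and identical configurations reproduce identical
sample stores bit for bit.

## Free-energy profiles

Samples are classified to their nearest reference (ties to the lower
index); at each ladder temperature, `F_s = −k_B·T·ln p_s` from direct
counting, minimum shifted to zero.  No cross-temperature reweighting is
performed — the protocol defines per-temperature populations by counting,
and reweighting would change the estimator.  Empty states are flagged and
carry NaN, never ±inf, in output tables.  The first 10% of samples (by
step) are discarded as burn-in (configurable); standard errors come from
block averaging over 10 contiguous time blocks.  Profiles against scalar
metrics (Rg, RMSD-to-final) are histogram-based with empty bins masked;
the energy-histogram overlap between two temperatures uses 50 shared bins
over the pooled range.  Barriers are reported between adjacent local
minima of the occupied profile as max-between minus the shallower minimum.

## Study conditions of the shipped toy systems

- **1D double well** `V(x) = h((x/a)² − 1)²`: h = 2.5 kcal/mol, a = 1 Å,
  m = 1 amu.  The barrier sits in the range the protocol is meant to
  resolve (a few kcal/mol, a few k_BT at the ladder temperatures) and the
  light mass gives a well frequency near the damping constant, so
  inter-well crossings occur often enough at desk scale that the sampled
  profile can be compared to numerical quadrature of the Boltzmann
  integral.  The headline validation runs 4 ladders × 8 temperatures ×
  30,000 steps (960k Langevin steps, under a minute) and reproduces the
  inter-well ΔF from quadrature within 3 Monte-Carlo standard errors at
  every ladder temperature.
- **2D three-well surface**: two deep basins (V ≈ −3.59) at (±2.15, 0.00),
  an intermediate basin (V ≈ −2.30) at (0, 1.98), two saddles
  (V ≈ −0.71) at (±1.34, 1.45), and a repulsive core at the origin that
  forces transition paths over the upper channel.  All stationary points
  are located at runtime by damped Newton search from a coarse grid and
  classified by Hessian eigenvalues; nothing is hard-coded.
- **LJ7 cluster** and **harmonic chain** exercise the 3D superposition
  pipeline and the translation-invariant multi-atom case respectively.

## What the toy validation does and does not show

The toy systems have smooth, inexpensive, analytically tractable
potentials.  Passing tests establish that the action minimization, the
restraint logic, the exchange moves and the profile estimator are
implemented correctly — i.e. that the machinery reproduces exact Boltzmann
statistics where those are computable.  They do not establish anything
about force-field accuracy, solvent effects, or the sampling difficulty of
a real peptide's conformational space; a molecular application plugs its
own energy model into the `PotentialModel` contract (or the
`CallbackPotential` hook) and inherits only the protocol, not the
validation.

## Numerical and I/O choices

- Coordinates are float64 throughout; XYZ/PDB emit format-limited
  precision (6 and 3 decimals respectively, the documented lossy
  boundary), while toy columnar endpoints keep 12 significant digits so
  stationary points survive the round trip.
- Path archives and sample stores are single-file NumPy `.npz` containers
  with an explicit format version; a version mismatch is an error, never a
  silent migration.
- PDB reading/writing goes through biotite; element masses come from
  standard atomic weights (Biopython's table).
- Desk-scale default sampling (20,000 steps per replica, exchanges every
  250 steps, snapshots every 10) keeps a full pipeline run on one CPU in
  the minutes range; all schedule parameters are configuration, not code.

## Known limitations

- The penalized action has many local minima on rough landscapes; the
  ensemble-of-seeds strategy mitigates but does not eliminate this.
- The stride-based reference selection assumes the pathway is roughly
  uniformly resolved; strongly non-uniform paths would warrant
  arc-length-based selection.
- Per-temperature direct counting needs every state visited at every
  temperature for a finite profile; sparse high-barrier profiles will show
  flagged empty states rather than estimates.
- No bonded topology, cutoffs, or neighbor lists: potentials are evaluated
  in full, which is appropriate for the system sizes the toys target.
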