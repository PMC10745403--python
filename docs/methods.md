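# Methods

This note records the model assumptions, numerical choices and their
rationale, what the synthetic benchmarks do and do not demonstrate, and
the known limitations.

## Units and conventions

* kB = 1 everywhere.  Energies are in units of the thermal/contact
  energy scale ε, temperatures in ε/kB.
* Time is measured in units of the integrator step dt; rates are
  reported per unit time (for discrete chains one step *is* dt = 1, so
  chain rates read directly per step).
* Free-energy profiles are stored in kBT units with the sampled minimum
  shifted to 0; unsampled bins are +inf.
* The TS region `[TS⁻, TS⁺]` is inclusive at both ends so that integer
  reaction coordinates (e.g. a native-contact count) can use intervals
  like `[50, 51]`.

## The estimators

**Direct (path-ensemble) rate.**  A trajectory is cut at two planes
placed at the basin minima.  The cut convention is purely frame-based:
a crossing occurs between consecutive frames when `(q_t − plane)` and
`(q_{t+1} − plane)` have opposite signs, or when `q_{t+1}` lands exactly
on the plane; the cut is placed at the first frame on/beyond the plane,
which closes the terminating path and seeds the next (the shared frame
is counted once in conservation checks).  No sub-step interpolation is
performed — the paths are frame sequences at stride dt, and inventing
sub-frame crossing times would add precision the sampled process does
not have.  The dominant-path estimator divides the A→B event count by
the total duration of A–A paths; the exact variant divides by all
frames on the source side of a divider (default: the plane midpoint).
On the bundled 5 kBT systems the two differ by well under 2% (tested),
which is why the dominant form is the default.

**First-passage rate.**  Runs start at the source minimum, are
pre-equilibrated in-basin, and are timed to the first hit of the far
plane; k = 1/⟨τ⟩ with a delta-method standard error.  The
pre-equilibration default is ten basin correlation times, estimated
from the curvature at the source minimum for continuous systems
(τ_corr = kBT/(D·U″)) and as 10·n² steps for an n-state chain; the rare
equilibration that crosses the divider is redrawn.  Runs exceeding the
step budget are censored: excluded from the mean and counted in the
metadata.

**tRPS.**  Seeds are drawn from the equilibrium distribution restricted
to the TS region; each seed is shot forward and backward until a plane
is hit, the backward half is time-reversed and concatenated (seed kept
once), and the rate is

    k(A→B) = (N_TS/N_A) · (1/M) · Σ_i H_AB(𝒫_i)/t_TS(𝒫_i).

Key choices:

* *Restricted seeding.*  The spec of the sampler is "a restrained
  simulation confined to the region with hard-wall rejection of exits".
  We implement it as a Metropolis random walk (continuous: Gaussian
  proposals with σ = 0.3 × region width; discrete: the chain's own ±1
  proposals) that rejects exits, which leaves the restricted Boltzmann
  distribution *exactly* invariant.  A Brownian-dynamics walk with exit
  rejection would instead carry an O(√dt) boundary-layer bias into the
  seed distribution and hence into the reweighting identity.
* *Velocities.*  For inertial dynamics one Maxwell–Boltzmann velocity
  is drawn at shoot time and used as +v / −v for the two halves.
  Momenta are independent of configurations at equilibrium, so drawing
  them fresh preserves the phase-space distribution exactly.  For
  velocity-free dynamics (overdamped, chains) the backward half is an
  independent relaxation from the same seed with fresh noise; by
  reversibility it is statistically equivalent to the time-reverse of
  an incoming path.
* *Independent noise streams.*  The two halves always use separate
  streams (reusing one stream would correlate them and bias assembled
  path statistics).
* *Censoring.*  Shoots whose halves exceed `max_steps` are excluded
  from M and reported.  The bundled budgets (5×10⁵ chain steps, 10⁶
  continuous steps) are ~100× the observed mean transition-path
  duration at the benchmark conditions; no censoring occurs there.
* *Endpoint typing.*  A path's type comes from its two terminal planes
  only; interior re-crossings never reclassify it.
* *Uncertainty.*  Bootstrap over shoots (1000 resamples) for tRPS; a
  50-block stationary block bootstrap over contiguous paths for the
  direct estimator (successive paths are autocorrelated); delta method
  for first-passage.
* *Basin extent for N_A.*  Basin A is everything on the A side of the
  nearest TS edge.  The Boltzmann weight makes the near-barrier
  contribution exponentially negligible, and bounding the basin away
  from the barrier would introduce an arbitrary parameter.
* *Both directions from one ensemble.*  The shoot set is
  direction-agnostic; A→B and B→A use the same shoots with their own
  population ratios, and their ratio reproduces the equilibrium
  constant N_B/N_A (tested as a detailed-balance check).

**Pre-equilibrium diagnostic.**  Plane-to-plane counting assumes a path
that reaches a basin minimum relaxes there rather than promptly
re-crossing.  `preequilibrium_check` extends every shoot endpoint and
reports the fraction that reach the opposite plane within the
extension; ≤ 5% is treated as safe.  On the 8 kBT benchmark the
fraction is far below that; on a near-flat landscape it rises above
20%, as it should.

## Propagators

* Overdamped: Euler–Maruyama, `x' = x − (D/kBT)·U′(x)·dt + √(2D·dt)·ξ`,
  with D = kBT/(mass·friction) and reflecting domain walls placed far
  enough out (±2.5 half-separations by default) that they never touch
  transition paths.
* Underdamped: BAOAB splitting.  BAOAB was chosen over Euler-type
  schemes because its configurational sampling error is superconvergent
  in dt — this matters for umbrella sampling, where Euler–Maruyama's
  O(dt) configurational bias alone exceeded the 0.2 kBT reconstruction
  tolerance at usable time steps.  With friction 0 it reduces to
  velocity Verlet (energy-conservation tested).
* Discrete: nearest-neighbour Metropolis with proposal ½ each way,
  acceptance min(1, e^(−ΔE/kBT)), rejected boundary moves staying in
  place.  Discrete-time stepping (not Gillespie) keeps "one step = dt"
  aligned with the frame-based path representation.
* dt values are configuration, not constants: the benchmarks use
  dt = 10⁻³ (overdamped, where stability needs dt·max|U″| ≪ 1) and
  dt = 5×10⁻³ (BAOAB umbrella).  A convergence test verifies the direct
  rate moves by < 10% (beyond noise) when dt is halved.
* Randomness: one root seed per experiment; every kernel call gets a
  31-bit seed derived via `SeedSequence((root, counter...))`, so runs
  are bit-reproducible and forward/backward halves are independent.

## Equilibrium machinery

WHAM iterates the standard self-consistency equations on shared bins
until the window free energies move by less than 10⁻⁷ kBT (default;
10⁵ iteration cap), with per-window bias offsets subtracted for
numerical headroom.  The profile is invariant under window order and
under adding a constant to all biases (tested to 10⁻¹⁰).

The bundled umbrella protocol for the 5 kBT double well uses 17 windows
(spring 40 ε per unit², centers ±1.6), 8×10⁵ BAOAB steps per window,
10% burn-in, 120 bins.  Reconstruction error against the bin-integrated
analytic profile is 0.08–0.15 kBT across seeds.  Two caveats learned in
sizing this: (i) where the profile is steep, F varies by > 1 kBT within
a bin, so the analytic reference must be the bin-integrated Boltzmann
weight, not F at the bin center; (ii) umbrella samples are correlated
over several steps, so a bin needs ~10³ raw counts before its
free-energy noise drops to ~0.1 kBT — "well-sampled" is defined
accordingly.

Population ratios weight each bin by `width · exp(−F/kBT)`; discrete
profiles use unit-width bins at the integer states, making the ratio
exactly the stationary-distribution ratio.  The midpoint temperature
(equal basin stability) is found by bisection on ΔF(T) with the 0.05
kBT equal-stability tolerance.

## Synthetic systems and oracles

The generator produces (i) quartic double wells
U(x) = barrier·[(x/a)²−1]² + tilt·x/(2a), minima at ±a, and (ii)
birth–death chains from any per-state energy list, including
discretisations of (i).  Benchmark conditions: 30 states / barrier
≈ 5 kBT / T = 1 for the discrete system; barrier 5 kBT, overdamped,
dt = 10⁻³ for the continuous one; 4000 shoots per rate; 10⁷-step direct
trajectories (~300 transition events, ~6% statistical resolution).
These sizes give few-percent standard errors in seconds per study on
one core.

Ground truth comes from two independent oracles: the overdamped MFPT
double quadrature (reflecting at the wall, absorbing at the far
minimum, Richardson-checked grids) and the exact first-passage linear
solve `(I − P_restricted)·τ = 1` for chains.  The two agree to < 2% on
a 400-state discretisation (tested).  The reference rate is k_ref = 1/τ
(basin-A minimum → basin-B minimum); for barriers ≥ 4 kBT relaxation is
single-exponential and this matches the phenomenological rate to within
the few-percent resolution tested.  The tRPS-vs-oracle comparisons
therefore carry a small systematic floor (~2–5%: basin-definition and
discrete-time effects) that sits well inside the 3-SE statistical
bands used.

What passing these benchmarks shows: the estimator, reweighting and
equilibrium machinery are consistent and unbiased at the few-percent
level on smooth two-state landscapes with clean time-scale separation.
What they do not show: behaviour on rugged or glassy landscapes, under
hysteresis, with poor reaction coordinates whose TS region fails to
separate the basins, or in high dimensions — the known hard cases for
all path-based methods.

## Protein (Gō) model

The optional Cα model uses the standard structure-based
parameterization: harmonic bonds (100 ε/Å²) and angles (20 ε/rad²),
1-/3-periodic dihedrals (1 and 0.5 ε), 10–12 wells at the native Cα
distances for native contacts (heavy-atom 4.5 Å cutoff, sequence
separation ≥ 4), σ = 4 Å repulsion for non-native pairs, ε = kB = 1.
Q counts contacts within 1.2× their native distance.  All constants are
overridable on the topology.  Forces are analytic (verified against
central differences to 10⁻⁵ relative) and energy is invariant under
rigid motion to 10⁻⁹.  The model is exercised on synthetic fixtures in
the tests; full protein kinetics studies (building from a real PDB
entry, umbrella profiles over Q, chevron scans) run through the Python
API and are deliberately outside the desk-scale test suite, as they
need hours of simulation.  The CLI covers the synthetic systems only.

## Limitations

* 1D reaction coordinates only; no 2D profiles, MBAR, or committor
  machinery.
* The overdamped backward-shot equivalence relies on time reversal of
  the equilibrium ensemble; driven or irreversible dynamics are out of
  scope.
* Censored-shoot exclusion slightly biases rates downward if the
  censoring budget is set too low; budgets default to ~100× the mean
  transition-path duration and censored counts are always reported.
* Euler–Maruyama carries O(dt) sampling bias; for equilibrium-sensitive
  work (umbrella windows, seed generation) the package uses BAOAB or
  exact Metropolis samplers instead.
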