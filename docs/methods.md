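# Methods

## Scope and model

`pfmhop` simulates nonadiabatic molecular dynamics on analytic diabatic
model Hamiltonians with fewest-switches trajectory surface hopping (TSH),
and validates the trajectory ensembles against exact 1-D wave-packet
dynamics.  The scientific focus is electronic *decoherence*: bare TSH
carries the electronic coefficients coherently along each trajectory, so an
initial superposition — e.g. one created by a broadband pulse — never loses
the nuclear-overlap factor that damps coherences in the exact treatment.
The package implements a family of corrections that damp the inactive-state
coefficients with a first-order estimate of the nuclear-overlap decay rate:

* **nd** — no correction (reference; the ensemble average still loses
  coherence by *dephasing* when trajectories accumulate different phases);
* **edc** — energy-based correction, `k_ia = |E_ia| · T/(T + C)` with
  kinetic energy `T` and `C = 0.1` hartree by default;
* **fm / fmi** — forces-and-momenta rate for diatomics,
  `k_ia = (σ²/2)(p_ia f_ia + |p_ia| √(f_ia² + 1/(μ²σ⁶)))`, built from the
  *actual* bond-coordinate momentum and force differences between the
  active surface and auxiliary wave packets on the inactive surfaces;
* **pfm / pfmi** — projected variant for multidimensional systems,
  `k_ia = (π²/8ω)|P_ia||F_ia| + |P_ia|·√(π² N_D ω/8)`, where `P`, `F` are
  mass-weighted trajectory-velocity-projected (TVP) momenta and forces —
  obtainable from active-surface energies alone — and the projection angle
  between velocity and force-difference vectors has been replaced by its
  isotropic average ⟨|cos θ|⟩ = 2/π.

The trailing **i** marks *active-momentum injection*: whenever an inactive
population grows, its auxiliary momentum is blended with the
energy-rescaled active-surface momentum in proportion to the gained
population.  This cures the "momentum history problem" — without it, an
auxiliary momentum propagated since a long-past birth misrepresents
population added later — and is what makes the rates insensitive to the
population threshold η (see the threshold study below).

### Auxiliary force/momentum bookkeeping

Auxiliary forces are numerical forward time derivatives of the adiabatic
energies divided by the reference velocity (midpoint velocity of the
nuclear step; signed bond velocity for FM, mass-weighted speed for PFM),
zeroed when the speed is below κ = 1e-9 a.u.  All states start from the
same auxiliary momentum (the trajectory's own), so every rate vanishes at
t = 0 and an initial coherent superposition is not damped spuriously.
Inactive states with population ≥ η (default 1e-4) propagate their momentum
classically with their own auxiliary force; states below η carry no packet
and track the active momentum rescaled for energy conservation,
`P_i = P_a √(max{0, 1 − E_ia/T})`.  A population falling below η is a
*death*: the residual is moved to the active coefficient.  Rising above η
is a *birth*: propagation restarts from the rescaled active value.  Note
that the rescale factor *boosts* the momentum of states far below the
active surface (the radicand exceeds one); this is intended — the
transferred packet would accelerate — but it means rates for deeply
subthreshold states can be large, which is harmless since their
coefficients are already negligible.

## Propagation algorithm

One nuclear step of size Δt (default 0.1 fs in 1-D, 0.2 fs multi-D):

1. Velocity-Verlet half-step → midpoint velocity and end position.
2. Adiabatize the diabatic matrix at the new position (`numpy.linalg.eigh`,
   batched over trajectories), fix eigenvector signs for temporal
   continuity, and build the state-overlap matrix `S` and the
   finite-difference time-derivative coupling `K = (1 − S)/Δt`.  No
   nonadiabatic-coupling vectors are ever evaluated, which is why energy
   conservation at hops uses *isotropic* velocity rescaling.
3. Local diabatization: the step propagator basis is the closest orthogonal
   matrix `U` to `S` (polar decomposition via SVD, diagonal made
   non-negative).  The adiabatic potential at the step end is rotated into
   this basis; the residual coupling `(1 − UᵀS)/Δt` is retained.
4. Electronic propagation: 51 RK4 substeps of `i dc̃/dt = (Ṽ − iK̃)c̃`
   with all matrices interpolated linearly across the step.  With only two
   genuine nodes per step a spline degenerates to a line, so linear is the
   default and only scheme.  After each substep the coefficients are
   transformed to the adiabatic basis with the *geodesic* interpolant
   `U^τ` (closed forms for 2×2/3×3 rotations, eigen-decomposition
   otherwise), which is exactly orthogonal at every τ — populations and the
   decoherence damping are therefore basis-consistent mid-step.  The norm
   is restored after every substep (RK4 is not exactly unitary; the
   correction is at the 1e-12 level per substep).
5. Hopping: density-flux probabilities per substep,
   `P_{a→k} = [max(0, −Δρ_aa)/ρ_aa] · [max(0, Δρ_kk)/Σ_l max(0, Δρ_ll)]`,
   cumulative-interval target selection against a per-trajectory uniform
   draw, frustrated when the interpolated gap exceeds the midpoint kinetic
   energy.  The classic fewest-switches expression (from coefficients and
   `K`) is available as `hop_scheme: fewest_switches` for cross-checking;
   on the shipped presets both give statistically identical ensembles.
   The population flux feeding the probabilities is the TDSE-driven change
   only — decoherence damping (which also moves population toward the
   active state) is applied *after* the hop decision each substep and does
   not trigger hops.
6. Decoherence: rates are evaluated once per nuclear step from step-start
   auxiliary quantities and applied each substep as `c_i ← c_i e^{−k_ia δt}`
   with the active amplitude rescaled to restore the norm exactly.
7. Second Velocity-Verlet half-step with the (possibly new) active-surface
   force; if the active surface changed during the substeps, the velocity
   is rescaled once by `√(1 − ΔE/T)` so the post-step total energy equals
   the pre-step value to machine precision.  Auxiliary momenta are then
   propagated (active slot keeps continuity across hops and shares the
   rescale factor), and deaths are collapsed.

Trajectories are statistically independent: trajectory ν draws all its
randomness (initial active-state collapse, hop draws) from a dedicated
`numpy` PCG64 stream seeded with `SeedSequence((base_seed, ν))`.  The
engine propagates the whole ensemble as a batch of arrays purely for speed;
a batched run is bit-identical to running the trajectories one at a time
(asserted by a test), so results do not depend on batching or execution
order.

## Exact reference and initial conditions

The 1-D oracle propagates all diabatic components on an equidistant grid
(default 1024 points) with symmetric split-operator steps of 0.01 fs or
smaller; the multi-state potential half-step diagonalizes the diabatic
matrix pointwise (precomputed — the models are time-independent).  Bound
eigenstates come from a sinc-DVR Hamiltonian (spectrally accurate on the
grid).  The grid has hard walls; a warning fires when edge amplitude
exceeds 1e-6 and all shipped scenarios end before wrap-around.  Observables
are analyzed in the adiabatic basis via the pointwise eigenbasis with an
x-continuous sign gauge, so that `ρ_ij(t) = ∫ χ̃_i χ̃_j* dx` (populations
*and* overlap-weighted coherences) is well defined.

Initial conditions are Wigner samples at zero temperature: analytic
Gaussians for harmonic normal modes (mass-weighted position variance
`1/2ω`, momentum variance `ω/2`), or rejection sampling from the numerical
Wigner transform of a grid eigenstate with cells below 1e-10 discarded.
Only ground states (non-negative Wigner functions) are supported
numerically; signed quasi-probabilities are out of scope.  Electronic
amplitudes, including complex phases, come from the run configuration;
diabatic-basis specifications are rotated to the adiabatic basis with
`Wᵀ(R(0))` per trajectory, which produces the expected tiny occupations of
other adiabatic states at t = 0 when couplings do not vanish at the
starting geometry.

The decoherence width parameters follow the same estimation route at both
levels: in 1-D, σ is the sample standard deviation of the bond coordinate
over the initial ensemble; in multi-D, ω is the geometric mean of the
normal-mode frequencies (conserving the volume of the variance ellipsoid),
overridable in the configuration as a free parameter of the model.

## Ensemble analytics

Averages are taken over *balanced valid* trajectories: a trajectory is
valid when `max_t |E_tot(t) − E_tot(0)| ≤ E_D` (default 1 eV); when several
states were populated at t = 0, the initially-active fractions are restored
by stochastically removing trajectories started in states *other than* the
one with the highest failure probability, to a tolerance of half a
trajectory (`1/2N`).  Reported quantities: the averaged density matrix
`ρ_ij(t) = ⟨c_i c_j*⟩` with normal-approximation 95% confidence intervals,
active-trajectory fractions `Π_j(t)`, the internal-consistency gap
`max_j |ρ_jj − Π_j|`, and operator expectations evaluated from the full
electronic wave function, `⟨O⟩ = ⟨Σ_ij c_i* c_j O_ij(R)⟩` — the convention
that is sensitive to coherences, which is the point of the package.

## Shipped models and what the synthetic setups do (and do not) show

All presets are analytic, smooth, low-dimensional surrogates; they exercise
every algorithmic pathway (crossings, frustrated hops, births/deaths,
injection, balancing) under controlled conditions, but they cannot expose
issues specific to ab initio surfaces: noisy/discontinuous electronic
structure, near-degenerate seams in many dimensions, or active-space
instabilities.  Multi-dimensional dynamics is validated only by internal
property tests (the oracle is 1-D).

* `avoided_crossing_2s` — mass 20000 a.u., bound Morse diabat crossed on
  its outer limb (~3.6 bohr) by a repulsive diabat, constant coupling
  1.5e-3.  A σ = 0.05 bohr packet released on the inner wall reaches the
  crossing after ~20 fs and splits roughly 55/45.  This is the
  oracle-equivalence benchmark; the parameters were chosen (before the
  acceptance suite was frozen) so that the crossing is traversed
  classically and the packet stays narrow — the regime the frozen-Gaussian
  rate derivation assumes.  In a light-mass/wide-packet scattering regime
  the FM correction visibly damps coherence *during* the passage and
  branching ratios degrade; the package reproduces that behaviour too, but
  it is not claimed as a validity regime.
* `ibr_surrogate_3s` — a heavy interhalogen-like diatomic (reduced mass
  89,000 a.u.): deep Morse ground state whose ground-state bond-length
  spread is ≈ 0.069 bohr, a bound excited diabat and a repulsive diabat
  crossing it at 6.0 bohr (well outside the Franck–Condon region), constant
  coupling 2e-3 between the excited states only.  A packet promoted to the
  bound excited diabat reaches the crossing near 55 fs and splits ~79/21.
  The diagonal curves are this package's own construction — they reproduce
  the *qualitative* predissociation topology, not any published parameter
  set, and quantitative agreement with published interhalogen curves is
  expressly not a goal.
* `tully3_sloped` — the extended-coupling reflection model (flat diabats,
  exponentially saturating coupling), kept for qualitative studies of
  repeated crossing passages.
* `lvc_nd` — a 2-state, 3-mode linear vibronic coupling model in
  mass-weighted coordinates for exercising the multi-D (PFM) pathway.
* Uncoupled displaced-harmonic pairs (built from parameter tables in the
  tests) isolate pure coherence physics: equal slopes with a constant gap
  (no dephasing, zero FM/PFM rate — coherence survives), inclined surfaces
  (true decoherence vs. ensemble dephasing), and a near-parallel pair
  separated by 0.3 hartree, where the gap-driven EDC damps much faster
  than the slope-driven PFM rate.

## Numerical choices and limitations

* Eigenvector sign gauge: largest-magnitude component positive pointwise;
  temporal continuity is enforced at propagation time from step overlaps.
  Hellmann–Feynman gradients refuse exactly degenerate points
  (gap < 1e-10 hartree).
* Density-flux hop probabilities use the normalized-population flux between
  consecutive substeps as written above; with a single gaining state this
  reduces to the active-population loss fraction.
* Frustrated hops leave the velocity untouched (no reversal), matching the
  isotropic-rescaling philosophy.
* The per-step decoherence damping factors are constant across the 51
  substeps (`e^{−k δt}` precomputed), equivalent to applying the step-start
  rate over the whole step.
* Problem sizes used by the validation suites — 2000 trajectories for the
  stochastic benchmarks, 1000/600 in the summary script, 100–140 fs
  horizons — were chosen so that ensemble confidence intervals (~±0.02 on
  a population) are small compared to the effects being measured; the
  stochastic assertions hold with margin at these sizes.
* Velocity-direction reversals between steps flip the sign of TVP forces
  (the collinear velocity-change approximation is applied as-is); around
  turning points the forward difference `−ΔE/(vΔt)` remains bounded because
  numerator and denominator vanish together.
* The stochastic balancing tolerance (half a trajectory) and its RNG stream
  are explicit; removals are logged in the result metadata.

## Threshold (η) study, in brief

On the three-state surrogate with matched initial conditions and matched
per-trajectory seeds, FMi population curves for η ∈ {1e-3, 1e-4, 1e-5}
agree to a few 1e-3 — far inside the 95% confidence band — while FM without
injection drifts systematically as η decreases (stale auxiliary momenta
accumulate on barely-populated states).  This motivates the default
η = 1e-4 with injection enabled; the acceptance suite re-runs this study.
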