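# Methods

This note documents the models, estimator conventions, numerical
choices and limitations behind `kbff`.  Internal units are nm, kJ/mol,
ps, elementary charge and kelvin throughout; SI appears only at I/O
boundaries (S/m for conductivity, atm for pressure, mPa·s accepted for
viscosity input).

## Force-field model

Ions are single Lennard-Jones sites with integer charge.  Unlike pairs
mix by Lorentz–Berthelot rules (arithmetic σ, geometric ε).  The pair
potential is truncated at 0.9 nm and shifted by its value at the
cutoff, so it is exactly zero there and continuous across it; no
long-range dispersion correction is applied, because such a correction
would change the meaning of the shift.  The alchemical soft-core
variant uses the standard radial remapping
r_sc = (α σ⁶ (1−λ)^p + r⁶)^{1/6} applied to the shifted potential and
scaled by λ, with α = 0.5 and p = 1 as defaults; it reduces to the
plain shifted potential at λ = 1, vanishes at λ = 0, and is finite at
contact for λ < 1.  The shift is retained inside the soft-core
evaluation so that both TI endpoints live on the same (shifted)
potential surface.  The optimized ion table (σ, ε, q per ion) ships as
`data/table1_ions.csv`.

## Lattice constant (Ewald self-interaction)

A point charge in a cubic periodic box with neutralizing background has
self-energy k_e q² ξ / (2L) with ξ ≈ −2.837297.  `kbff.ewald` evaluates
ξ by Ewald splitting (real-space erfc sum, reciprocal Gaussian sum,
self and background terms) and *verifies* convergence by enlarging each
cutoff; failure names the unconverged term.  The defaults (α = 1.8/L,
6 real shells, 8 reciprocal shells) are converged far below 1e-6, and
the result is independent of α over more than a factor of two.  An
independent cross-check, `direct_lattice_sum`, pairs every image charge
with its own unit cube of background (a neutral, dipole-free group
whose far field decays like 1/n⁵) using the closed-form prism
potential, and subtracts the π/6 trace-quadrupole term that separates
grouped summation from the tinfoil convention.  It shares no code with
the Ewald route and agrees to ~1e-4 at 12 shells.

## Solvation free energies

TI records hold a λ-grid of ⟨∂H/∂λ⟩ means and errors per stage
(Lennard-Jones growth, charging; 10 uniformly spaced states per stage
by default).  Quadrature is trapezoidal by default — exact for linear
integrands on any grid and monotone — with a natural cubic spline as
an alternative; errors propagate from the per-λ standard errors
assuming independence between λ states (for the spline, the trapezoid
weights serve as a conservative proxy).

Two analytic corrections are added to the raw F_sim:

* **Periodic boundary / background.**  ΔF_corr = k_e q² [ −ξ/(2εL) +
  π r²(1 − 1/ε)/(3L³) ] with r = 2^{1/6} σ.  The first term removes
  the dielectric-screened interaction of the ion with its periodic
  images; the second accounts for the homogeneous background charge
  interacting unscreened over the ion's own volume.  The correction is
  quadratic in q, symmetric under charge reversal, and vanishes as
  L → ∞.  The cavity-term coefficient adopted here is the one
  consistent with the known magnitude of the artifact at the
  infinite-dilution settings (L = 2.5 nm, ε = 72, 300 K): with it,
  every ion of the bundled table gives |ΔF_corr| between 0.69 and
  1.35 k_BT, i.e. of order 1 k_BT, which the acceptance suite pins.

* **Standard state.**  F_p = k_BT ln(p₁/p₀) with p₁ = k_BT·n for the
  transfer of an ideal gas at p₀ = 1 atm into a 1 mol/l ideal solution;
  3.20 k_BT at 300 K.  The 1 mol/l state is used verbatim at the given
  temperature (no temperature-adjusted standard state).

Totals compose exactly as F = F_sim + ΔF_corr + F_p.  Only *pair*
(cation + anion) free energies are meaningful deliverables; the package
never introduces an extra-thermodynamic single-ion split.

## Pair structure and Kirkwood–Buff integrals

RDFs use the standard minimum-image histogram estimator with uniform
half-open bins [lo, hi), ideal-gas shell normalization, self-pairs
excluded and unordered like-pairs counted once; r_max may not exceed
L/2 and ties at exactly r_max are excluded.  The default bin width is
0.002 nm for production-like boxes; the coarse synthetic fixtures in
the tests use wider bins matched to their statistics.  No finite-N
closure correction is applied to g(r) before integration.

The finite-volume KB integral over a spherical subvolume of radius R is

G^R = 4π ∫₀^{2R} h(r) r² (1 − 3x/2 + x³/2) dr,  x = r/(2R),  h = g − 1,

evaluated by the midpoint rule on the binned g (requires the RDF to
resolve distances up to 2R).  G^R approaches the plain KB integral
linearly in 1/R for short-ranged h, so G^∞ is the intercept of an
ordinary least-squares fit of G^R against 1/R.  If no fit window is
given, the largest window starting from the smallest available 1/R
that keeps R² ≥ 0.99 is chosen, falling back to the three largest
radii for very noisy input; intercept and slope standard errors are
reported and the window is recorded.  Electroneutrality implies
n = 1/(G₊₋ − G₊₊), exposed as a consistency check.

## Activity derivative

For a fully dissociated 1:1 salt at constant T and p, the
binary-mixture Kirkwood–Buff result combined with the salt ↔ ion-pair
mapping (which contributes the indistinguishability term −1/(2n) to
the salt–salt integral) gives

a_cc = ∂ln a / ∂ln n = [1 + n (G₊₊ + G₊₋ − 2 Ḡ_{is})]⁻¹,

with Ḡ_{is} the mean of the cation–solvent and anion–solvent
integrals.  The solvent–solvent integral cancels at constant pressure
and is carried only for bookkeeping.  The expression is dimensionless
and invariant under a consistent change of volume units, equals 1 when
all KB integrals vanish, and drops below 1 when unlike-ion association
raises G₊₋.  The solvent is treated as a single site (its center of
mass) wherever solvent-involving integrals are computed.  Molality is
converted to number density from the actual box composition, never
from experimental densities, keeping the chain self-consistent with
the simulated ensemble.

The full chain per molality is RDF → G^R → 1/R extrapolation → a_cc;
error bars come from repeating the chain on 5 contiguous frame blocks
(the convention for every error bar in this package, including the
figure-style activity errors).

## Transport

The MSD is averaged over all time origins and all particles of a
species, on an evenly spaced subset of at most ~100 lags up to half
the trajectory length; wrapped input is detected (frame-to-frame jump
above L/2) and refused — unwrapping is an explicit operation.  The
diffusion fit MSD = 6Dτ + c uses lags in [10%, 50%] of the longest
available lag by default and records the window used.  Because R²
alone barely separates a quadratic from a line on a finite window, the
linearity diagnostic also compares the slopes of the two window
halves.  At the test fixture size (64 particles × 20 000 steps) the
estimator carries ~5% noise; recovery tests therefore average a few
independent fixtures.

The Yeh–Hummer correction D_self = D_sim − k_BT ξ/(6πηL) uses the same
ξ as the solvation correction.  The water-model viscosity η is a
*required* input (a property of the water model, not of this package);
a converter from mPa·s is provided.  Conductivity follows the
Einstein–Smoluchowski form κ = n e²(D⁺ + D⁻)/k_BT for monovalent
salts, converted to S/m; ion–ion cross-correlation corrections to
Nernst–Einstein are out of scope.

## Dielectric constant

The static susceptibility of a conducting solution splits into three
additive parts estimated from the water collective dipole M(t) and the
ion current J(t):

* χ_ww = ⟨δM²⟩ / (3ε₀Vk_BT),
* χ_wi = −2/(3ε₀Vk_BT) ∫₀^∞ ⟨δM(0)·J(t)⟩ dt,
* χ_ii = −1/(3ε₀Vk_BT) ∫₀^∞ t ⟨J(0)·J(t)⟩ dt,

and ε = 1 + χ_ww + χ_wi + χ_ii.  The ω → 0 limit is taken
analytically: for any stationary process with decaying correlations
the two integrals reduce exactly to the static cross-covariance
2⟨δM·δM_I⟩ and the itinerant-ion-dipole variance ⟨δM_I²⟩, which is
also how the synthetic generator plants known components.
Correlations are computed by FFT with explicit zero padding, each lag
normalized by its own origin count, and integrated by trapezoid up to
a truncation lag (default 5% of the series; choose a few tens of
correlation times — long enough for decay, short enough that the
t-weighted ion integral is not noise-dominated).  A non-stationarity
warning fires when the linear drift fitted through 5 block means
exceeds 5 detrended standard errors; detrending matters because a pure
trend inflates the raw block variance itself.  The pure-water ε of the
water model is a user input to the decrement Δε = ε_solution − ε_pure
(72.0 is the bundled example value for extended simple-point-charge
water).

## Synthetic generators

All generators take an integer seed, draw every random number from one
`numpy.random.default_rng(seed)` stream, and are bit-reproducible.

* **ideal_gas** — iid uniform positions per frame; g ≡ 1, all KB
  integrals zero.  Null model for the structure chain.
* **mc_fluid** — Metropolis single-particle moves on the shifted-LJ
  (optionally + bare minimum-image Coulomb) energy; displacement tuned
  toward ~40% acceptance during equilibration; acceptance rate logged
  and warned outside (0.05, 0.95); an energy trace drifting more than
  6 block-SE between halves raises.  Desk-scale only (N ≤ ~200,
  O(N) per move); it replaces MD because the KB estimators need only
  equilibrium configurations, not dynamics.
* **brownian** — independent Gaussian displacements with variance
  2DΔt per component per step and per-species D; stored wrapped and
  exactly unwrappable by construction (step size validated against
  L/2).  Replaces MD for transport because the MSD estimator assumes
  only long-time diffusive behaviour.
* **dipole_process** — M_I and J form a critically damped stochastic
  harmonic oscillator (exact discrete-time integration via the matrix
  exponential and the stationary-covariance update), keeping M_I
  stationary so χ_ii is finite; M adds a correlated multiple of M_I to
  an independent Ornstein–Uhlenbeck term.  Process parameters are
  solved from the requested (χ_ww, χ_wi, χ_ii), which therefore *are*
  the planted statics; a Cauchy–Schwarz check rejects inconsistent
  requests.
* **mock_backend** — single-ion free energies linear in (σ, ε), so
  isolines are straight lines; activity curves equal a fixed reference
  shape plus a quadratic penalty in each ion's distance from its
  planted optimum, times a positive molality profile; optional seeded
  Gaussian observation noise.  The global objective minimum sits at
  the planted parameters by construction.

What these fixtures do *not* emulate: hydrogen bonding, real water
structure, dielectric screening in the MC fluid (no Ewald there),
hydrodynamic correlations, or any coupling between the observables.
Passing tests demonstrate estimator correctness on inputs satisfying
each estimator's assumptions — not force-field quality on real water.

## Optimizer

Stage 1 scans chloride over a (σ, ε) grid.  For each chloride sample,
cation candidates are generated on the solvation free-energy isolines
of the chloride-salt targets — the isoline is traversed by an ε grid
with σ root-found per ε (bisection, tolerance 0.001 nm, matching the
significance of the third σ decimal); ε values without a root are
skipped with a log note, an empty isoline is an error.  Candidates are
ranked by the per-salt activity objective; the chloride objective k is
the mean squared deviation of a_cc from the reference over the salts of
the stage and the molality grid (default 0.25 mol/kg spacing strictly
inside (0, 5)).  Stage 2 fixes the cations and scans bromide the same
way on the bromide salts.  The staged procedure implies that the
objective mean runs over per-stage salt subsets rather than all four
salts at once, and that the final set depends only on the initial
chloride grid.

The sampled landscape is interpolated cubically (Clough–Tocher on
scaled coordinates) and the interpolated minimum — always inside the
sampled hull — is reported alongside the best sampled point.  The best
*sampled* point is selected unless the interpolated improvement
exceeds an explicit noise floor **and** re-evaluation through the
backend confirms it; with the default (no noise floor given) the
sampled point always wins, the conservative convention for noisy
landscapes.  Ties among equal-k points break deterministically toward
smallest σ, then smallest ε.  Failed grid points are excluded from the
interpolation and logged.

## Degenerate inputs and tie-breaks (summary)

Zero-length or non-cubic boxes, triclinic box lines, inconsistent
particle counts, non-increasing λ or molality grids, dielectric
constants below 1, missing viscosity, r_max beyond L/2, and subvolume
radii beyond the RDF's reach all raise immediately with messages
naming the offending quantity.  Remainder frames in block averaging
are discarded from the end.  RDF ties at exactly r_max are excluded;
bins are half-open [lo, hi).

## Problem sizes in the shipped tests

The suite runs at desk scale by design: MC fluids of 2–30 particles
(the two-particle case is checked against direct Boltzmann
quadrature), ideal-gas boxes of ~200–300 particles × 100–200 frames,
Brownian runs of 64 particles × 20 000 steps, dipole processes of
30 000–60 000 steps, and 5×5 optimizer grids with 25-point ε isolines.
These sizes keep the statistical recovery tests inside their quoted
confidence intervals while the whole suite completes in well under a
minute of pure computation.
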