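# Methods

This note documents the models, conventions, numerical choices and known
limitations of `ribomech`. Units everywhere: kcal·mol⁻¹ for energies, Å for
distances, degrees for angles, K for temperature, min⁻¹ for rates, with
R = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹ and a default temperature of 298.15 K.

## Reaction coordinates and active-state geometry

Proton and methyl transfer are tracked by difference-of-distances progress
variables: ξ_PT = |R(C10:N3)−R(H)| − |R(O6mG:N1)−R(H)| and
ξ_MT = |R(O6mG:O6)−R(Cm)| − |R(A63:N1)−R(Cm)|. Reactant-like geometries sit
near (ξ_PT, ξ_MT) ≈ (−1, −1.5); product-like near (+1, +1.5). Both are
bounded by the triangle inequality (|ξ_PT| ≤ d(C10:N3, O6mG:N1)), which the
tests assert as a property.

**Inline fitness.** A frame is catalytically competent when the
nucleophile–electrophile distance (Cm–A63:N1) lies in [2.75, 3.50] Å and
the attack angle θ_inl (O6mG:O6–Cm–A63:N1) in [140°, 180°]. The binary
in-box fraction is the headline quantity and depends only on those bounds.
The graded score inside the box — a product of two linear ramps rewarding
shorter distances and straighter angles, clipped to [0, 1] — is this
package's own definition, documented here precisely because graded scoring
conventions vary; it is not tuned to reproduce any published coloring, and
nothing downstream depends on it.

**Fluctuations and B-values.** Per-atom σ is the RMS 3D deviation from the
reference after global Kabsch superposition (heavy atoms by default);
per-residue values average σ over heavy atoms. The isotropic convention
B = (8π²/3)·⟨Δr²⟩ with ⟨Δr²⟩ = σ² is used and stated in the output,
because B conventions differ by a factor of 3 between "per-axis" and "full
squared displacement" definitions. The conversion round-trips exactly.

**Hydrogen bonds.** Geometric criterion only: donor–acceptor distance ≤
3.5 Å and donor–H–acceptor angle ≥ 135° (both configurable). No energetic
or topological bond perception.

## Free-energy surfaces (WHAM)

Umbrella windows bias (ξ_PT, ξ_MT) with independent harmonic restraints
½k(ξ−ξ⁰)². The estimator is standard binned WHAM: the self-consistent
equations for unbiased bin probabilities and window free energies are
iterated in log space until the relative change in window free energies
drops below 10⁻⁷ (cap 100 000 iterations), with the bias evaluated at bin
centers. Grid spacing defaults to 0.2 Å, matching the window spacing of a
typical reaction-coordinate scan; the analytic testbeds use 0.05 Å. A
variational free-energy-profile spline estimator would be an alternative;
WHAM was chosen because it is reproducible from primary literature and
testable against analytic surfaces and against an independent MBAR
implementation (the test suite carries one operating on unbinned samples).

Bins never visited carry +∞ free energy and a mask flag; they are never
interpolated, and path searches refuse to traverse them. Windows whose
occupied bins form disjoint islands are rejected (relative free energies
between islands would be undefined). Samples falling outside the requested
grid are dropped with a logged count, and the per-window normalization uses
the retained counts, making the estimator self-consistent on the truncated
domain. Known bias: evaluating the bias at bin centers adds a
discretization term of order ½k·(w/2)² in steep-bias bins (~0.1 kcal/mol
at k = 100, w = 0.1), which the MBAR cross-check quantifies; fine grids
keep it well below the statistical error.

**Uncertainty.** Per-bin standard errors come from a block bootstrap:
each window's (time-ordered) samples are cut into contiguous blocks
(default 5), blocks are redrawn with replacement per window, and WHAM is
re-run per replicate. Because every replicate is re-anchored at its own
minimum, the reported SE includes the anchor covariance and is mildly
conservative. No autocorrelation-time estimation is attempted beyond the
blocking itself.

## Minimum free energy paths and stationary points

A simplified zero-temperature string method runs on the *estimated*
surface: images take steepest-descent steps using the component of the
interpolated gradient normal to the path (the tangential component only
fights reparameterization), displacements are capped at half a grid cell,
a mild curvature smoothing (coefficient 5·step) damps the discrete string's
sawtooth mode, and images are then redistributed to equal arc length.
Because the smoothing scales with the step, the converged curve is
independent of the step actually used, and a converged path is a fixed
point of the iteration. The step is halved whenever the mean displacement
stalls for 30 iterations, which stabilizes steep surfaces where
step × transverse curvature would otherwise overshoot. Defaults: 32 images,
step 0.01 Å, tolerance 10⁻³ Å mean displacement, 20 000 iterations.
Endpoints descend freely so they settle into their basin minima. This is
deliberately an analysis-time method: an on-the-fly finite-temperature
string would require the simulation engine and is out of scope.

**Stationary points.** The 1D profile along the path (bilinear surface
interpolation against normalized progress) is scanned for interior extrema
on a 5-point moving-average copy, each refined by a local quadratic fit on
the raw profile (5-point window, ties toward lower progress). One interior
maximum labels R/TS/P; two maxima flanking a minimum label R/TS1/I/TS2/P,
keeping the two highest maxima if the detector finds more. Energies are
relative to the profile start (R ≡ 0). A strictly decreasing profile is a
"no barrier" error, not a silent empty result.

**Mechanism classification.** With thresholds pt_done = +0.5 and
mt_done = −1.0: a path is proton-transfer-first if it reaches
ξ_PT ≥ +0.5 while ξ_MT ≤ −1.0, methyl-transfer-first under the mirrored
condition (ξ_MT ≥ +1.0 while ξ_PT ≤ −0.5), otherwise concerted. Endpoints
must lie in the reactant (−,−) and product (+,+) quadrants.

## Alchemical free energies and pKa shifts

Per-λ samples of ∂U/∂λ are integrated by trapezoid (default) or natural
cubic spline; both are linear in the per-λ means, so the SE propagates
exactly through the quadrature weights. Neighbor-exchange work samples feed
a self-consistent Bennett acceptance ratio (brentq root of the Fermi-weight
imbalance, tolerance 10⁻¹²) with the standard asymptotic variance;
degenerate acceptance weights raise an explicit overlap error. How the λ
intermediates were constructed (softcore forms, enhanced sampling) is
irrelevant here: the module consumes sample tables.

pKa shifts follow ΔpKa = [ΔG_RNA(AH⁺→A) − ΔG_aq(AH⁺→A)]/(RT ln 10), and
apparent pKa = solution pKa + ΔpKa, an exact sum. Solution reference values
(cytosine 4.2, adenine 3.5) are *inputs*, not constants: the arithmetic
stage is deliberately decoupled from where the numbers come from.

## Rates and the activity–pH model

Rates use the Eyring expression k = κ·(k_BT/h)·exp(−ΔG‡/RT) with an
explicit transmission coefficient (default κ = 1) and are reported in
min⁻¹ (prefactor 3.727×10¹⁴ min⁻¹ at 298.15 K). Published intrinsic-rate
tables for this system evidently use a modified prefactor (direct Eyring
evaluation at a 19.43 kcal/mol barrier gives ≈2 min⁻¹, not 0.45), so κ and
T are exposed rather than hard-coded; the robust statement — a
32.59 kcal/mol barrier yields < 10⁻⁶ min⁻¹, below experimental detection —
holds for any κ ≤ 1.

The two-state noncooperative model
k_obs = k_int/(1 + 10^(pKa_B−pH) + 10^(pH−pKa_A) + 10^(pKa_B−pKa_A))
is evaluated overflow-safely via log-sum-exp; its maximum sits at
(pKa_A + pKa_B)/2. Fitting uses weighted nonlinear least squares (weights
1/se when provided) in the parameterization (ln k_int, pKa_A, s) with
pKa_B = pKa_A − eˢ, which enforces the ordering, makes the optimum
invariant to swapped initial guesses, and keeps k_int positive. CIs come
from the Gauss–Newton quadratic with a delta-method transform. Data whose
observed maximum sits at the boundary of the pH range is rejected as
unidentifiable (single limb). The lower apparent pKa is treated as a
phenomenological parameter throughout — the model makes no claim about its
molecular origin.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical* structure of simulation outputs,
not physics: no force field, no solvent, no quantum Hamiltonian.

- **Umbrella sampler.** Vectorized Metropolis random walk (all windows
  advance in lockstep) on analytic potentials (flat, harmonic, 1D double
  well U = a(x²−1)² with barrier exactly a, and a tilted two-channel 2D
  surface U = a[(x²−1)²+(y²−1)²] + c(y−x) whose tilt c > 0 makes the
  x-first channel the low one). Step size auto-tunes to 30–50% acceptance
  during burn-in (default 500); recorded samples are stride-thinned
  (default every 4th state) to reduce chain autocorrelation; non-finite
  proposals are rejected, never raised. Stationarity is verified by a
  χ² goodness-of-fit of long-run histograms against Boltzmann weights.
  A union-find flood over a dense grid provides the independent
  minima/saddle oracle for the two-channel surface.
- **λ-series.** Mean ∂U/∂λ curves (linear or cubic in λ−½) whose exact
  integral equals the target ΔG; Gaussian per-λ noise; work samples from
  the equal-variance Gaussian model satisfying the Crooks relation, so TI
  and BAR both have exact known targets.
- **Trajectories.** Six active-site atoms placed by a fixed convention
  (O6 at the origin, Cm on +x, nucleophile in the xy-plane, proton on the
  N3–N1 axis at the requested asymmetry) so the drawn distance/angle are
  reproduced to ≤10⁻⁹. Distance/angle distributions come from a small
  serializable registry (point, uniform, truncated normal, mixture).
- **Toy structures.** Deterministic helix-like reference plus isotropic
  per-residue Gaussian noise; expected RMSF is σ√3 and reference B-factors
  are 8π²σ², both closed forms the tests check.

Consequently, passing tests demonstrate estimator correctness and
calibration on data matching the generators' assumptions (independent
Gaussian noise, exact harmonic biases, Markovian sampling). They do not
demonstrate robustness to force-field error, slow conformational
relaxation, anharmonic restraint artifacts or hysteresis in real
trajectories.

## Problem sizes and determinism

Study sizes used by the test suite, the CLI `report` demo and
`scripts/acceptance.py` were chosen so each estimate's statistical error is
several times smaller than the effect being measured: 16 windows × 5000
samples for the double-well recovery (demo: 1500), 12 λ × 500 samples per
alchemical leg with a 100-replicate calibration study, 5000-frame
fluctuation fixtures, and 10 000-frame fitness mixtures. Every stochastic
stage takes an explicit integer seed; identical seeds give bit-identical
outputs, and the end-to-end report is byte-reproducible.

A note on the 100-replicate calibration check: a two-sided 2·SE interval
has nominal coverage 95.45%, so the count of successes in 100 replicates
is a Binomial(100, 0.9545) draw whose fluctuations (±2 replicates) straddle
a 95-of-100 line by construction. Large-replicate runs (2000–8000) place
both estimators at 95.2–96.1% coverage, i.e. correctly calibrated.

## Known limitations

- WHAM is binned; very steep biases on coarse grids incur the documented
  center-evaluation bias. No 3D+ surfaces.
- The string method is zero-temperature on an interpolated surface; it
  finds MFEPs, not free-energy-weighted transition tubes, and no committor
  or TS-ensemble analysis is attempted.
- The pH model is strictly two-state and noncooperative; no Hill
  coefficients, no substrate-binding (K_d) correction.
- PDB support covers the fixed-width v3.3 ATOM/HETATM subset (plus XYZ);
  no mmCIF or binary trajectory formats.
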