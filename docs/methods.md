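# Methods

## Energy model

The lattice energy of a rigid-molecule crystal is split into an
intramolecular deformation penalty (frozen here: conformations are fixed
to the reference geometry, so the penalty is constant and dropped) and an
intermolecular part `U_inter = U_elec + U_rd`, evaluated per mole of
molecules (lattice sums divided by Z).

**Electrostatics.** Atom-centered point charges (units of e) interact
through an Ewald sum under tinfoil boundary conditions: real-space sum
over intermolecular pairs, reciprocal-space sum over all sites, self term,
and a constant intramolecular correction that removes the screened images
of excluded (rigid, intramolecular) pairs. The conversion constant is
1389.35458 kJ mol⁻¹ Å e⁻². The splitting parameter defaults to the
balance heuristic `α = (N π³ / V²)^(1/6)` (clamped to [0.2, 1.2] Å⁻¹) and
the real/reciprocal cutoffs are chosen from a dimensionless tail tolerance
δ = 1e−10 (`r_c = √(−ln δ)/α`, `g_c = 2α√(−ln δ)`), giving absolute errors
around 1e−8 kJ/mol; the result is invariant to doubling α well within the
1e−6 kJ/mol accuracy target.

**Repulsion/dispersion.** Buckingham pair potentials
`φ = A e^(−Br) − C/r⁶` per atom-type pair, summed in direct space over
all intermolecular pairs and periodic images within a cutoff (default
15 Å; the synthetic pipeline uses 10 Å for its small cells). Two
numerical choices depart from a naive truncated sum:

* a **C² quintic taper** takes φ smoothly to zero over the outer 2 Å of
  the cutoff sphere. Bare truncation leaves O(C/r_c⁶) ≈ 1e−3 kJ/mol
  discontinuities whenever a pair crosses the cutoff, which is fatal for
  line searches that must reach ∞-norm gradients of 1e−9. The taper is
  applied consistently in energies, all derivative blocks, reference-data
  generation and fitting, so the fitted model is exactly the evaluated
  model;
* a **soft-core guard** used only inside minimization line searches: below
  1.0 Å a smooth penalty `k((r₀/r)⁷ − 1)²` (k = 1e6 kJ/mol) dominates the
  unphysical short-range Buckingham turnover, letting trial steps recover
  instead of diverging. No physical intermolecular contact approaches
  1 Å, so the surface is unchanged at any legitimate geometry; a terminal
  state with a contact inside the soft-core region is reported as an
  overlap failure (collapse), as is any contact below the hard 0.3 Å
  bound.

Combining rules (geometric mean for A, C; harmonic mean for B) are
supported as an alternative to explicit cross terms; parameter
derivatives are chained onto the homoatomic values analytically.

## Rigid variables and derivatives

`Ω` = free cell parameters (triclinic 6; monoclinic a, b, c, β;
orthorhombic 3; tetragonal/hexagonal a, c; cubic a) + fractional centroid
and orientation per asymmetric molecule. Orientations are stored as unit
quaternions; optimizers see a 3-vector incremental axis-angle about the
current orientation (exponential map), re-baselined whenever a geometry is
applied, which avoids Euler-angle gimbal singularities while keeping the
degree-of-freedom count of Euler angles. Centroids are mass-unweighted
(the choice is irrelevant to energies). Atoms are never wrapped
independently of their molecule — only molecule-instance centers are
wrapped to [0, 1) — so intramolecular pairs always share an image cell
and the exclusion bookkeeping is exact.

All derivatives are assembled by chain rule through the site positions:
cell-matrix first/second derivatives are generated symbolically (sympy,
cached at first use); orientation first/second derivatives use the
exponential-map expansions at the zero-increment baseline, with the SO(3)
left Jacobian mapping gradients into a fixed chart during stage-1 line
searches. Validated blocks (against central finite differences on
randomized toys): gradient ~1e−9 relative, Hessian ~1e−9 (chart-
consistent), ∂U_rd/∂p ~1e−10, ∂²U_rd/∂Ω∂p ~1e−9.

## Lattice minimization (inner problem)

Stage 1: bound-constrained L-BFGS (cell lengths ≥ 1 Å, angles in
[20°, 160°]) on the soft-core surface to a loose gradient tolerance
(1e−5) — a warm start only. Stage 2: modified Newton, re-baselined each
iteration; indefinite Hessians are eigenvalue-shifted (absolute value with
a floor of 1e−6·max|λ|), steps are trust-bounded (0.25 ∞-norm) and
backtracked so accepted energies never increase; convergence at ∞-norm
gradient < 1e−9. The terminal point is re-evaluated on the true (hard)
surface; statuses are converged / saddle (negative eigenvalue beyond
−1e−8·scale) / not_converged / overlap_failure. Starting from a converged
minimum is a fixed point to < 1e−10 kJ/mol.

## Sensitivities (implicit function theorem)

At a converged minimum, `dU*/dp = ∂U_rd/∂p|_{Ω*}` (envelope), and
`dΩ*/dp` solves `H x = −∂²U_rd/∂Ω∂p`. Space groups with a free origin
(e.g. P1: 3 directions; P2₁: 1) leave exact zero modes in H; the solve is
performed in the orthogonal complement by eigendecomposition and the
flat-direction components are set to zero — a pure gauge choice, since
the residuals are invariant along those directions by the reference-atom
construction. A negative eigenvalue beyond tolerance raises a
sensitivity-unavailable error (the estimator treats it as a structure
failure). Geometry-residual rows chain `dΩ*/dp` analytically through the
cell free-parameter map and the fractional-position dependence (centroid,
orientation, inverse cell matrix); the energy row scales the envelope
derivative by 1/|U_ref|.

## Residuals and merit function

Cell residuals are relative deviations of free parameters over √n_x
(angles compare in degrees or radians identically, being relative).
Coordinate residuals subtract the first asymmetric atom's fractional
coordinates (removing the free-origin degeneracy), wrap each component to
the nearest periodic image of its reference, and normalize by
√(3N_at − 3). One energy residual per structure is
`(U* − U_ref)/|U_ref|` by default; a "signed"-denominator convention is
available (the sign convention affects nothing after squaring).
`MF_s = ½(w_G(‖X‖² + ‖Y‖²) + w_E E²)`; defaults w_G = 1 always, w_E = 1
except 0 for structures containing polarized hydrogens (Hp), which keeps
hydrogen-bond-dominated energies from contaminating the empirical terms.

## Outer estimation

The weighted residual vector over the training set feeds a
bound-constrained trust-region-reflective least-squares solver with the
analytic Jacobian and parameter scaling by starting magnitudes. Around
it, the control loop:

* **dynamic starting points** — lattice minimizations warm-start from the
  previous TMF evaluation's optima (references on the first evaluation of
  each attempt), suppressing basin-hopping discontinuities;
* **re-evaluation and B-criteria** — after each solver termination the
  TMF is recomputed from the original reference geometries. Unchanged
  (|Δ| ≤ max(1e−12, 1e−8·TMF)) ⇒ accept (B3). Otherwise compare with the
  previous attempt: relative decrease < 1e−3 ⇒ accept current (B4);
  increase ⇒ accept previous (B5); reinitialization limit (default 10)
  reached ⇒ accept the better (B6); else reinitialize at the current
  estimates. The 1e−3 B4 threshold is a design choice (the stall
  criterion is not quantified in the source method);
* **structure removal** — a failed lattice minimization aborts the solve;
  the structure is removed and the solve restarts from the last
  successful iterate. After termination all removed structures are
  reintroduced for one final optimization + re-evaluation, reported
  without further iterations. Failure handling takes precedence over the
  termination checks when both could fire;
* **Sobol multistart** — unscrambled Sobol' points mapped into finite
  user-specified bounds (deterministic; later points extend, never
  reshuffle). Results are clustered greedily: same minimum when
  re-evaluated TMFs agree to 1e−3 relative and scaled parameters agree to
  1e−2 ∞-norm;
* **scheduling** — structures are dispatched to a thread pool in stable
  order of decreasing measured cost, and results are assembled in
  training-set order, so parallel and serial runs are bit-identical.

A TMF evaluation costs exactly one lattice minimization per structure;
its gradient costs none (asserted by call counting in the tests).

## Synthetic data

The generator emulates reference training data: small rigid polar
molecules (bent triatomic, planar 4-atom quadrupolar unit, alternating
6-ring) packed with ≥ 2 Å clearance into P1, P−1 or P2₁ cells with
realistic starting dimensions (5.5–7.5 Å lengths, angles near 90°, β in
95–115° for P2₁), then relaxed under "true" FIT-magnitude Buckingham
parameters (carbon-like A = 369743 kJ/mol, B = 3.60 Å⁻¹,
C = 2439.8 kJ Å⁶/mol; hydrogen-like A = 11971, B = 3.74, C = 136.4; cross
terms from the combining rules, fitted explicitly). Charges (±0.25 e
patterns) put the electrostatic share of U_inter between roughly 20 and
60%, so fitting always exercises the Ewald path. B parameters are held
fixed, as is standard for transferable Buckingham fits.

This is an inverse crime by construction: the reference energies come
from the same (tapered) force-field family being fitted, so the global
optimum is known exactly (TMF = 0 at the true parameters). A green
recovery test therefore establishes that the estimation machinery —
energies, derivatives, minimizer, sensitivities, control flow — is
internally correct; it says nothing about force-field accuracy against
quantum-chemical reference data, about chemical diversity, or about noisy
references with a nonzero optimal misfit. Linear molecules are excluded
from estimator fixtures: a diatomic's rigid-body Hessian has an exact
zero mode (rotation about its own axis), making the implicit-function
solve singular — the same reason the underlying method excludes them.

## Known limitations

Point charges only (no distributed multipoles or polarization); rigid
molecules only (no intramolecular relaxation); integer Z′; special
positions rejected rather than handled; dispersion has no tail
correction beyond the tapered cutoff; no uncertainty estimates on fitted
parameters (no second-order parameter derivatives).
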