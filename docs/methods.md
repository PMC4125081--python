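# Methods

`duplexmc` simulates kilobase double-stranded DNA and RNA at base-pair-step
resolution under stretching force and torsional (link) constraint, and
converts the simulated observables into the four elastic-rod constants that
single-molecule tweezers experiments report: bending persistence length *A*,
stretch modulus *S*, torsional persistence length *C*, and link-extension
(twist-stretch) coupling *g*.

## The base-pair level model

Each base pair is a rigid body: an origin (the base-pair center) and a
right-handed orthonormal frame (x short axis, y long axis, z normal).  The
degrees of freedom are the N-1 base-pair steps, each a 6-vector
(shift, slide, rise in angstroms; tilt, roll, twist in degrees) in the
Calladine--El Hassan (CEHS) convention used by 3DNA: with bend magnitude
Gamma = hypot(tilt, roll) and phase phi = atan2(tilt, roll),

    R_step = Rz(twist/2 - phi) Ry(Gamma) Rz(twist/2 + phi)

and the translation is expressed in the mid-step triad
`Rz(twist/2 - phi) Ry(Gamma/2) Rz(phi)`.  The transform is exactly
invertible (`transform_to_step`), with the convention pinned by round-trip
tests at 1e-10 and by the ideal-helix geometry below.  The first base pair
is clamped canonically (origin 0, normal +z, long axis +y), mimicking a
molecule attached to a flow-cell surface.

The intra-helix energetics are carried entirely by the step-parameter
distribution: each step is assumed multivariate normal (per dinucleotide
type, or pooled for random-sequence simulations), so a Monte Carlo proposal
is simply a fresh draw from the distribution, and the Metropolis energy
contains only the external terms.  A fragment library (verbatim resampling
of observed rows) is supported as a Gaussianity-free alternative.

### Bundled default models and their limits

The bundled random-sequence models carry the survey means and standard
deviations (DNA: shift 0.00/0.57, slide 0.32/0.86, rise 3.30/0.23 A, tilt
-0.05/3.56, roll 1.60/5.17, twist 35.21/6.24 deg; RNA: 0.00/0.57,
-1.58/0.39, 3.22/0.20, 0.02/2.86, 7.89/4.33, 31.72/4.25) with a **diagonal**
covariance.  The full 6x6 covariances of the curated crystallographic
datasets are not distributed here.  Consequences, verified by the test
suite:

* quantities dominated by the diagonal reproduce the published
  full-covariance simulations closely -- bending persistence (set by the
  tilt/roll variances; A ~ 2h/(sd_tilt^2 + sd_roll^2) in the small-angle
  isotropic limit), torsional persistence (set by the twist variance and,
  for RNA, the spring geometry), and the Metropolis acceptance rates;
* quantities that live in the off-diagonal couplings are **not**
  reproduced; above all the link-extension coupling g, which requires the
  twist-rise/twist-slide covariance and comes out near zero for DNA
  instead of ~ -130 pN nm.  The acceptance tests assert the published
  values anyway and fail for this documented reason.  Supply a
  full-covariance model (JSON schema in `models.py`) to recover them.

### Ideal-helix geometry

A repeated rigid step is a screw motion; `superhelix_descriptors` finds its
invariant axis in closed form.  The DNA default means give a nearly
straight axis (screw radius 0.29 A).  The RNA means give an A-form spiral:
screw radius 4.08 A (spiral diameter 8.2 A), rise along the axis
2.76 A/step, pitch 30.4 A -- quantitatively matching fiber A-form geometry.
Note one literature convention trap: the printed "8 A" figure for this
spiral is its *diameter* (the number is sometimes loosely called a radius).
This spring-like axis is what halves the dsRNA stretch modulus relative to
dsDNA and gives dsRNA its negative writhe-vs-force slope.

Contour length is defined as `n_steps x rise-along-the-screw-axis` of the
mean step, not the axis-curve arc length; for dsRNA the two differ by 17%
and the screw-axis rise is the one conjugate to the measured extension
(the fitted contour length of simulated dsRNA force-extension data agrees
with it to 0.1%).

## Twist, writhe, link of a discrete open ribbon

The ribbon is the polyline through base-pair centers plus the base-pair
long axes as ribbon vectors.  Writhe of the open curve is defined by
closing it with straight rays to z = -infinity below the first vertex and
+infinity above the last, joined by a coplanar return path at infinity
whose Gauss-integral contributions vanish.

* **Exact writhe** (O(N^2)): the polygon-polygon double sum of signed
  spherical-quadrangle solid angles, plus the two curve-ray cross terms,
  which reduce analytically to Fuller-like single sums over the direction
  curves taken from each endpoint (no explicit long rays are ever
  evaluated).  Validated against dense Gauss-Legendre quadrature of the
  Gauss double integral over an explicit closed polygon (1e-4) and against
  translation invariance.
* **Fuller writhe** (O(N)): the signed spherical-triangle area sum of the
  tangent indicatrix about the pole +z (van Oosterom-Strackee solid
  angles).  Correct modulo 4*pi; exact while the tangents stay away from
  -z, i.e. under sufficient stretching force.  Property tests assert the
  mod-4*pi congruence with nonzero multiples actually exercised.

* **Twist**: at each vertex the reference ribbon vector is the unit
  binormal b_i = unit(t_{i-1} x t_i) (normal to both adjacent segments);
  virtual straight segments toward -z/+z supply the terminal references.
  Per-step twist T_i = fold(beta_i + alpha_{i+1} - alpha_i) into
  [-pi, pi), with beta_i the dihedral b_i - t_i - b_{i+1} and alpha_i the
  signed *direct* angle between the ribbon vector and b_i (not a
  projection, so sharp bends -- which occur between the last segment and
  the virtual one -- stay well defined).  At straight vertices the
  binormal is undefined and any perpendicular is a valid gauge; a
  deterministic one is used, and the alpha/beta bookkeeping makes the
  total twist exactly gauge-invariant.  This construction makes
  Lk = Tw + Wr the experimentally observable bead rotation: for the ideal
  straight helix Lk equals the sum of the twist parameters exactly, and on
  mildly bent (high-force) conformations the folded link tracks the
  terminal bead rotation to a few degrees RMS, the residual coming from
  the terminal normal not pointing exactly along +z.

Sign conventions: positive twist (right-handed helix) gives positive link
and positive bead rotation, measured right-handedly about +z from the
global y axis; a left-handed (Z-form) duplex yields negative link by the
same rule.  Angle folds map to [-pi, pi); unit-vector triples with triple
product below 1e-12 (and non-positive denominator) are treated as
degenerate with zero area.

## Monte Carlo engine

One cycle is a sequential sweep over all steps.  A proposal redraws one
step's 6-vector from the sampler; the Metropolis energy is

    E = -F z  [+ k_rot/2 (Lk - Lk_t)^2]  [+ k_xy/2 (x^2 + y^2)]

in pN nm (kB T = 4.114 pN nm at the default 298 K).  A free helix
therefore accepts every move, and a 2-bp toy system with two fluctuating
coordinates matches dense numerical integration of its stationary
distribution.

Implementation notes that matter for correctness and speed:

* Unconstrained sweeps evaluate the terminal-position change of a
  proposal in O(1) using suffix vectors, so a 3 kbp sweep costs
  milliseconds.  Constrained sweeps re-evaluate twist + Fuller writhe
  after every proposal (O(N), fully scalarized streaming kernel), making
  a sweep O(N^2).
* Accepted moves rigid-transform the downstream block.  The block
  rotation is re-orthonormalized (Gram-Schmidt) on every acceptance:
  without this the frame error compounds double-exponentially along the
  chain within a single sweep.  State is additionally rebuilt from the
  (exactly orthonormal) local transforms at every sweep start, so
  incremental and from-scratch evaluation agree to 1e-8 over arbitrarily
  long runs (tested).
* Reproducibility: one numpy Generator per run, seeded from the config;
  draw order is (type indices, 6-vector normals, acceptance uniforms) per
  sweep.  Identical seeds give bit-identical traces.  Scan drivers derive
  per-condition seeds from the base seed via `SeedSequence(seed, (i,))`.

Constrained simulations use the Fuller writhe for the per-proposal link
(the O(N^2) exact sum would make sweeps O(N^3)); a validity guard warns
(or raises, configurably) below 1 pN of tension.  The envelope was mapped
directly: at 1 kbp the Fuller-vs-exact RMSD is zero above ~0.5 pN for DNA
(~1 pN for RNA) and jumps to tens of degrees -- in 4*pi quanta -- below.

**Protocol** (mimicking a torsional-trap experiment): initialize all steps
at the database means; 120 force-only relaxation cycles; for constrained
runs set the trap target to the current link, then alternately step the
target 20 degrees toward the desired link and sweep until the helix link
is within 20 degrees of the target (cap 10^4 sweeps/stage); then 50
further constrained cycles before sampling begins.  Standard errors of
recorded means use 20-block averaging so sweep-to-sweep correlation does
not understate them.

## Elastic-rod analysis

Energy density per kBT: `1/2 [A b^2 + B u^2 + C th^2 + 2 D u th]` with
B = S/kBT, D = g/kBT, u the fractional extension and th the twist density
(rad/nm).

* **A, S**: nonlinear least squares of force-extension data against the
  Bouchiat et al. seven-coefficient extensible WLC (the relative
  extension solves `FA/kBT = l - 1/4 + 1/(4(1-l)^2) + sum a_i l^i`,
  bracket-solved per force), its inextensible limit, or the Odijk
  high-force form `z = L(1 - sqrt(kBT/(4FA)) + F/S)`.  L may be fixed or
  fitted; asymptotic errors from the Jacobian.
* **C_eff, C**: C_eff(F) = L / Var(Lk) from unconstrained link
  fluctuations; the intrinsic C from the Moroz-Nelson high-force
  expansion `C_eff = C (1 - C/(4A) sqrt(kBT/(A F)))`, fitted by default to
  the six highest forces (it is a high-force expansion).
* **C from torque**: in link-constrained scans the trap torque is
  `k_rot (Lk_t - <Lk>)`; its slope against the target link times L/kBT
  gives C.  The trap and helix act as springs in series, biasing the
  slope by a factor `1/(1 + k_helix/k_rot)`; at the scales used
  (k_helix/k_rot < 1%) this is negligible.
* **g, mode 1** (link vs force): slope m1 = dLk/dF at zero torque obeys
  `m1 = -D L / (C kBT B)` with the bare `B = S/kBT + D^2/C`; the quadratic
  `m1 kBT D^2 + L D + m1 C S = 0` is solved with the stable root.  Only
  forces >= 1 pN enter the slope (the link recordings below the Fuller
  envelope are unreliable).
* **g, mode 2** (extension vs link at fixed force):
  `g = -slope[nm/turn] S / (2 pi)`; the first and last scan points are
  dropped by default (the linear relation breaks at high turns).  The two
  modes carry a known convention skew of order `1 - g^2/(kBT S C)` (~10%),
  consistent with the spread between the two published estimates; the
  cross-mode test asserts consistency at that level.
* **A from the mean transform**: tangent correlations decay per step by
  the dominant real eigenvalue of the sampler-averaged step rotation, so
  A = -h/ln(lambda) with h the screw-axis rise; verified against the
  h/sigma^2 closed form in the isotropic small-angle limit.

Negative g means the duplex over-winds when stretched, matching the sign
convention in which the published dsDNA values are about -90 pN nm
(experiment) and -130 pN nm (base-pair-level simulation).

## Synthetic data

`fixtures` generates everything the tests consume: ideal repeated-step
helices; labeled step-parameter tables (a B-like Gaussian main cluster, an
A-form-like decoy cluster, and planted gross outliers -- Z-form twists,
intercalation rises, 6.5-sigma excursions); closed-form known-topology
ribbons; and noisy WLC force-extension curves.  What the defaults emulate
and what they do not:

* The default table mimics a curated crystallographic survey: B cluster at
  the DNA means/SDs, decoy at A-form step parameters (slide -1.55, roll 8,
  twist 31.5; note A-form *rise* in step-parameter space is a normal
  ~3.2 A -- the low "rise" of A-form helices is an axis-rise property), at
  a 1:3 decoy:main ratio.  With these survey-like widths the A and B
  clusters genuinely overlap; curation removes the decoy cluster entirely
  plus the adjacent B tail, exactly as the real k-means procedure does.
  Label-recovery oracles at the >= 99% level therefore use a
  better-separated decoy (a machinery test, not a realism claim).
* Fixture WLC curves use multiplicative extension noise.  At 1% relative
  noise the stretch modulus is statistically identifiable to 5% only with
  instrument-realistic point counts, so recovery tests use dense
  (3000-point) force ladders, like real force-extension traces.
* Nothing in the fixtures models crystallographic artifacts beyond these
  three populations (no resolution-correlated bias, no sequence
  composition bias), so passing curation tests show filter correctness,
  not field-realism of any bundled dataset.

## Curation

Filter order: metadata (resolution cutoff 2.8 A, protein-bound excluded by
default), hard thresholds (twist <= 5 deg dropped as Z-form contamination;
rise >= 5.5 A dropped as intercalation), a single-pass 4-SD outlier filter
computed on the thresholded set (per step type in 16-type mode, pooled
otherwise), then optional k-means A-form removal for DNA: k = 3,
features standardized, 10 restarts, fixed seed; clusters whose centroid
slide is below -0.9 A are removed.  The absolute slide rule (rather than
"remove the most extreme cluster") is what the A-form signature actually
is in step-parameter space, and it makes the removal idempotent on
already-curated B data.  The single-pass SD filter is idempotent in
practice (a second pass removes nothing at these sample sizes).

Symmetrization (optional, off by default) pools each dinucleotide type
with the strand-reversed data of its complement (shift and tilt negate),
leaving 10 independent distributions; palindromic types get exactly zero
shift and tilt means, and observation counts are conserved.

## Problem sizes in the test suite

The suite reproduces the published random-sequence constants at the
original 3 kbp chain length but with reduced sampling (1500 recorded
sweeps per force, standard errors ~0.1-0.5%), which keeps each force scan
to ~2 minutes.  Link-constrained scans, whose sweeps are O(N^2), run at
600 bp over +/-1.2 trap turns (the same supercoiling-density window as
the published +/-40 turns at 3 kbp) with a 50 pN nm trap -- a deliberately
softer trap than the 200 pN nm default, because the torque estimator's
statistical noise scales like sqrt(k_rot) and the scaled runs cannot
average it away.  At these sizes the two C estimates agree to a few
percent (the published full-scale claim is 1%); the extension-vs-link
coupling g2 is measured with ~100 pN nm uncertainty and is a smoke-level
check only, with the precise (and honestly failing, see above) g
comparison carried by the link-vs-force mode.

## Known limitations

* No electrostatics, excluded volume, or structural transitions
  (melting, plectonemes); the Fuller-based constrained engine must not be
  pushed into the plectonemic regime (the guard only covers low force).
* The bundled diagonal-covariance models: see above.
* Exact writhe is O(N^2); link-constrained sweeps are O(N^2) per sweep.
  Long-chain link-constrained studies are compute-bound.
* The Moroz-Nelson fit is a leading-order expansion; at forces ~< 1 pN
  the C_eff data leave its validity range (and the Fuller link recording
  breaks down at similar forces), so both are restricted to >= 1 pN.
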