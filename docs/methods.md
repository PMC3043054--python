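# Methods

## Model and definitions

The package treats an ion–protein system as one protein plus one or more
tracked ions on a uniform frame grid (1 ps spacing is the reference
condition; any uniform spacing works). All internal distances are nm and
times ps; diffusion coefficients are reported in cm²/s (1 nm²/ps =
10⁻² cm²/s) and association rates in M⁻¹s⁻¹.

**Distance and shells.** The ion's distance from the protein surface is
the minimum-image distance to its nearest protein atom, heavy atoms only
by default. Whether hydrogens should count toward "nearest atom" is a
genuine modelling choice; excluding them is the default because hydrogen
positions are the noisiest degrees of freedom and most contact analyses
use heavy atoms, but `heavy_atoms_only=False` restores them. Shells are
half-open `[lo, hi)` intervals over the default boundaries 0.35, 0.60,
0.85, …, 2.10 nm; a distance exactly on a boundary belongs to the outer
shell (measure-zero choice, fixed for determinism). Beyond the last
boundary is bulk, which behaves as the outermost layer for flux-direction
purposes.

**Residence events.** For each shell, the per-frame indicator is bridged:
interior gaps of at most `grace_time` (default 2 ps, i.e. ⌊grace/Δt⌋
frames) do not terminate a stay. Bridging is applied independently per
shell and does not distinguish inward from outward excursions (the
direction of a 1–2 frame excursion is mostly discretization noise). A
maximal bridged run of `k` frames is one event of duration `k·Δt`; its
exit direction compares the shell occupied at the first post-run frame
with the run's shell. Bridging is idempotent, and per-shell total event
time never exceeds the trajectory length.

**Survival curves and exponential fits.** `N(t)` counts events with
duration ≥ t on the frame grid; `N(0)` is the event count. The
interpretation of the decay curve as per-event survival (rather than
per-frame occupancy conditioned on elapsed time) is a deliberate reading;
it is the one under which the fitted time constants are the event-duration
time constants. Fits minimize unweighted squared residuals of
`ΣᵢAᵢe^(−t/τᵢ)` (order 1 or 2) over the retained points, with two filters:

* points with counts ≤ `min_fit_count` (default 10) are discarded — the
  sparse tail is shot-noise dominated;
* the leading saturated plateau is discarded. Because every event lasts at
  least one frame, `N(0)` and `N(Δt)` both equal the event count; these
  points are fixed by definition, carry no decay information, and their
  large values would otherwise dominate the least squares and bias the
  fast phase (and, through it, the slow τ).

Parameters are optimized in log space (positivity by construction) by
Levenberg–Marquardt from a deterministic initial guess (log-linear fit of
the tail for the slow phase, of the residual head for the fast phase) plus
up to 20 seeded multi-start perturbations; the lowest cost wins, so the
fit is deterministic given data and config. Amplitudes are free
parameters. The reported `rel_rms_error` is RMS(residual)/RMS(N) over the
retained points. Order-2 fits report τ₁ < τ₂ by construction.

**MSD and diffusion.** MSD is time-origin averaged over all frame pairs
lying within a single segment; segments default to the whole trajectory
and otherwise come from residence events, so shell-conditioned statistics
never average across a shell exit. `D = slope/6` from an ordinary
least-squares line on the default 10–100 ps lag window. The window is a
compromise: below ~10 ps the MSD carries inertial/discretization
artifacts, beyond ~100 ps origin statistics thin out. The fit's r² is
reported and values below 0.98 are logged as a warning — trapped or
ballistic regimes violate the Einstein relation and the number returned is
then an effective slope, not a diffusion coefficient. Shell-conditioned
MSD requires segments from at least 8 independent simulations before it
reports a curve; short segments (< 2 frames) contribute nothing.

**Per-event mobility.** The surface-roaming measure of one residence event
is the maximum over the event of `|x(t) − x(t_entry)|²` with `x` in the
protein-fitted frame (each frame Kabsch-superposed onto the reference
frame on Cα atoms, the same transform applied to the unwrapped ion
position). An alternative reading — maximum over all intra-event frame
pairs — would be ≥ the entry-anchored value by at most a factor 4; the
entry-anchored version is implemented because it answers "how far did the
ion get from where it landed". The reference frame is the first frame;
the fit set defaults to Cα and falls back to all heavy atoms for
pseudo-proteins without Cα.

**Encounters.** A contact is a maximal (grace-bridged) interval during
which any heavy atom of an entity is within `contact_cutoff` of the ion.
The cutoff defaults to 0.35 nm, the first-shell boundary, with 0.30 nm the
common stricter alternative; extending the 2 ps bridging rule from shells
to contacts is a package decision (switchable via `grace_time=0`).
Entities exist at three granularities: residue, single atom, and
"carboxylate" (atom-level, but the two carboxylate oxygens of an ASP/GLU
side chain form one entity, since shuttling between them is not a
transfer). A contact is **secondary** iff the ion has remained within the
bridged first shell continuously since the last frame at which it touched
a different entity — including an entity it is still touching, because a
new contact formed while another persists is precisely a surface-mediated
hand-off; otherwise it is **primary**. The look-back window is unbounded
in time and broken only by a first-shell exit. The origin of a secondary
contact is the most recently touched other entity (ties by entity name).
Headline statistics: secondary/primary ratio, mean encounter intervals
(total time / counts), mean number of simultaneously contacted residues
over bound frames, and the free fraction. For the packaged per-residue
table, the headline ratio pools both protein variants; that pooling is the
convention under which the table's printed summary numbers are arithmetic
consequences of its counts.

**Kinetics.** Debye length `κ⁻¹ = √(εε₀k_BT / 2N_Ae²I·10³)` and Bjerrum
length use CODATA constants (scipy.constants), water ε = 78.5 at 300 K by
default. The Debye–Smoluchowski rate uses the effective-radius integral
`1/R_eff = ∫_R^∞ e^{βU(r)}r⁻² dr` with screened Coulomb
`βU = z₁z₂ l_B e^{−κ(r−R)} / (r(1+κR))`, evaluated by adaptive quadrature
on the substitution `u = 1/r` (finite interval, tolerance 10⁻¹⁰, verified
against a fine Riemann sum); the neutral case reduces exactly to
`4π(D₁+D₂)R·N_A·10⁻³`. The headline ~3×10¹⁰ M⁻¹s⁻¹ figure for a small
acidic protein is not derivable from first principles without knowing the
effective charge product and contact radius used; the module therefore
takes both as explicit inputs, and the tests only pin the neutral closed
form, monotonicity in the charge product, and the 10¹⁰–10¹¹ envelope for
plausible attractive parameterizations (R 1.5–2.5 nm, z₁z₂ ≈ −8,
measured D values). At 25 mM free ion — the concentration implied by two
ions in a ~140 nm³ box — `k_on·C` gives ~0.8×10⁹ s⁻¹, one encounter per
~1.3 ns.

## Synthetic generators

All generators use counter-based Philox streams keyed by (seed, generator
name), so results are bit-reproducible and adding a draw in one generator
never shifts another. Continuous event times are discretized by rounding
boundaries half-up to the frame grid; sub-half-frame events are kept at
one frame (an event that happened occupies at least the frame it was
observed in).

* **Free Brownian ion** — isotropic Gaussian steps, per-axis variance
  `2DΔt`, wrapped into a periodic cubic box. Default `D` is the
  experimental bulk Ca²⁺ value 1.584×10⁻⁵ cm²/s; 10⁶ steps at 1 ps give
  the MSD estimator ≲2% sampling error on the 10–100 ps window.
* **Two-exponential residence durations** — equal-weight mixture by
  default, component means set from the packaged per-shell (τ₁, τ₂)
  table when emulating a specific shell. After discretization the
  survival curve is still a sum of two exponentials in the frame index
  with unchanged time constants, which is what makes exact recovery
  possible in expectation.
* **Langevin surface walk** — overdamped Euler–Maruyama around a rigid
  sphere (radius 1.5 nm, 192 surface atoms on a Fibonacci lattice, 6 of
  them labelled GLU-carboxylate sites) with Gaussian attractive wells
  (depth in k_BT, width 0.15 nm) at the sites, a harmonic wall excluding
  the sphere interior and a soft outer wall confining the ion to the box.
  Optional two-zone mobility switches the step size within 0.35 nm of the
  surface. With uniform mobility, any measured first-shell slow-down is
  pure well-trapping — which is the point: trapping alone reproduces the
  qualitative shell-D drop. The stability bound `√(2DΔt) ≪` well width is
  enforced.
* **Markov site hopping** — CTMC over {bulk, k sites}: bulk→site at
  `entry_rate`, site→site at `hop_rate` per pair, site→bulk at
  `escape_rate`. The ledger labels every discretized contact primary or
  secondary by an independent frame-level scan implementing the same
  first-shell look-back definition as the classifier, and carries exact
  transfer counts and summary statistics. The secondary/primary ratio is
  controlled by `(k−1)·hop/( (k−1)·hop + escape )`.

### What the generators do and do not emulate

They reproduce the statistical structure the analyses consume: correct
Brownian scaling, two-phase residence, surface trapping, and
surface-transfer bookkeeping with exact ground truth. They do not emulate
water structure, electrostatic anisotropy (the positive/negative lobes of
a real protein), protein flexibility, or correlated ion–protein motion.
Passing tests therefore demonstrate that the estimators recover known
truth under the stated stochastic models — not that a particular protein
has particular time constants; the packaged printed tables are the only
protein-specific data in the package.

## Numerical choices and degenerate inputs

* Ties for the nearest atom break toward the lowest atom id; exact
  distance ties are measure-zero but the rule keeps runs bit-stable.
* Minimum-image distances use the component-wise nearest image, exact for
  orthorhombic cells; triclinic input is rejected at load time.
  The scan is the exhaustive vectorized one, chunked over frames to bound
  temporary memory; at the atom counts this package targets a cell list
  would not change observable runtime.
* Unwrapping requires per-frame displacements under half a box length and
  refuses otherwise (the nearest image is ambiguous beyond that).
* Kabsch superposition rejects collinear fit sets (singular value ratio
  < 10⁻¹⁰) and enforces det(R) = +1 via the usual sign correction.
* Exponential fits clip log-parameters to ±700 and map non-finite
  residuals to a large penalty so Levenberg–Marquardt restarts cannot
  overflow.
* Empty inputs raise: zero-frame trajectories, empty event lists, empty
  direction classes, occupancy requests with no frame inside `d_max`,
  zero concentration in the pseudo-first-order interval.
* The internal text format stores coordinates at 10⁻⁹ precision; reading
  a written file reproduces the trajectory to that tolerance and writing
  it again is byte-identical.

## Problem sizes

The test-suite and acceptance computations use the sizes at which the
statistical claims are made: 10⁵ durations per residence-fit recovery,
10⁶ steps for the bulk-diffusion recovery, 10⁵–3×10⁵ frame hopping
ledgers, and 8-run ensembles of 2.5×10⁴-step Langevin walks for the
shell-conditioned diffusion contrast. These sizes put sampling error
comfortably inside the stated tolerances (5% for D, 10% for τ₂) while a
full run of everything stays in the minutes range on one core.

## Known limitations

* Single protein, single chain; no multi-protein or multi-ion correlation
  analysis (multiple ions are tracked independently).
* The occupancy-vs-survival reading of decay curves is fixed to the
  survival interpretation; an occupancy-based alternative would need its
  own estimator.
* Shell-conditioned D for rarely-visited shells is undefined by design
  (min-sims threshold) rather than extrapolated.
* The Debye–Smoluchowski module predicts rates from given parameters; it
  does not fit effective charges to measured rates.
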