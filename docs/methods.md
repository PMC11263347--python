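# Methods

## Channel mechanics

The culture chamber is a straight cuboid duct, length 10 mm, width 1 mm,
height h = 150 μm, perfused at a constant volumetric rate Q.  The velocity
field is the classical Fourier-series solution of the Stokes equations for
a rectangular duct; the series is truncated when the next term changes the
mid-width wall shear by less than 10⁻⁶ relative (for w/h ≈ 6.7 the lateral
corrections decay like sech(nπw/2h), so one or two terms suffice, and the
mid-width profile is a plane-Poiseuille parabola to ~10⁻⁴).  The shear
forcing reported for attached cells is ∂v/∂z averaged over the monolayer
height z ∈ [0, 3 μm] at mid-width; because v(0) = 0 this average is exactly
v(3 μm)/(3 μm).  Shear stress is τ_w = μγ̇ with μ(37 °C) = 0.691 mPa·s.
The profile shape — and therefore every shear rate derived from a given
Q — is independent of μ, which cancels between the pressure gradient and
the velocity solution.

Transport limitation is screened by two Damköhler numbers: oxygen, τ_D/τ_c
with τ_D = e²/D the diffusion time through the gas-permeable membrane
(e = 150 μm; D must be supplied explicitly — literature values for oxygen
in PDMS are near 3.4×10⁻⁹ m²/s, and the code refuses to guess silently);
and glucose, τ_a/τ_c with τ_a = L/v.  The advection length defaults to
1 mm, the scale used in the original estimate, and is configurable
separately from the geometric channel length; the printed estimate and the
channel geometry are not mutually consistent, and the package does not try
to reconcile them.  Consumption times are τ_c = c·h/(μ_X·B) with per-cell
consumption rates μ_O₂ = 7×10⁻²¹ and μ_glu = 5×10⁻²⁰ kg·cell⁻¹·s⁻¹.

## The colonization simulator

The generator emulates a monolayer of 2 μm × 1 μm rod-shaped cells at an
initial surface density of 10⁻² cells/μm², observed at 1 frame/min for up
to 6 h at 0.1 μm/px.  Each agent carries one of three phenotypes:

* **continuous dividers** — division time drawn as
  τ_d = floor + Exp(mean − floor) with floor 20 min and mean 40 min: an
  exponential shifted to the observed support whose realized mean equals
  the nominal mean division time.  The cell elongates linearly from one to
  two cell lengths over its clock with the anchored (old) pole fixed, then
  is replaced by two daughters of unit length placed end-to-end along its
  axis (0.4 μm apart, small angular noise), each anchored at its outer
  pole.  Each daughter is independently a divider with probability f and a
  non-divider otherwise — the bistable assignment the analysis is designed
  to recover.
* **lagged dividers** — a fixed delay (default 240 min) with no growth,
  then the same clock.  Lag is assigned to a fraction (default 12.5%) of
  the *initial* dividers only: the data show an initial lagged cohort that
  depletes in time (the population's mean division time relaxes to the
  continuous clock), and regenerating lag at division would prevent that
  relaxation and would systematically misclassify colony-born lagged cells
  (censored during their lag) as non-dividers.  A
  `daughter_lagged_fraction` knob reinstates heritable lag if wanted.  The
  default delay puts the initial cohort's mixture mean division time,
  0.875·40 + 0.125·(240 + 40) = 70 min, inside the observed 65–105 min
  initial band.
* **non-dividers** — never divide; both poles jitter weakly
  (0.004 μm/frame) and symmetrically, so their end-of-trajectory MSD stays
  two orders of magnitude below the dividers' ~1 μm².  Dividers' anchored
  pole jitters at 0.01 and the free pole at 0.02 μm/frame, encoding the
  observed ~2× pole-mobility asymmetry.

Detachment is a per-cell Poisson event (rate per hour); a detached cell
reattaches immediately with probability p at a downstream offset
(|N(7, 1.5²)| μm along the flow), matching the observed 5–10 μm hops at
low shear, and otherwise leaves the system.  Advection of detached cells
is not simulated; a detach→reattach is an instantaneous repositioning.
Every birth, completed division, detachment and reattachment goes to an
event log, the oracle all downstream stages are tested against.

Hard overlaps are relaxed by pushing capsules apart along the line joining
their centroids to a 0.3 μm surface clearance.  Non-dividers — anchored by
both poles — act as immovable obstacles; dividers absorb the displacement.
This relaxation exists so that rendered colonies remain segmentable (cells
closer than the optical blur merge into one component); it is rigid-body
and therefore cancels part of a crowded divider's elongation displacement,
an artifact real cells avoid by sliding and buckling.  Scenarios that
classify ground-truth trajectories directly (no rendering) disable it.

Division clocks other than the truncated exponential are available: a
`gamma` clock with configurable CV and a `fixed` clock.  The recursion
N_d(t+τ̄) = 2f·N_d(t) behind η_eff = ln(2f)/τ̄ assumes near-synchronous
generations; with a genuinely exponential clock the age-structured
Malthusian rate (root of 2f·E[e^{−ατ}] = 1) exceeds ln(2f)/τ̄ by ~9% at
f = 0.8, τ̄ = 52 min.  The replication scenario for the lowest-shear
regime therefore uses the gamma clock at CV 0.15, for which the two agree
to ~1%.  `initial_age_randomized` spreads initial cells' first division
over their clock to avoid start-up division waves.

## Imaging emulation and segmentation

Cells are drawn as anti-aliased capsules spanning pole to pole (area
≈ 178 px² at 0.1 μm/px, read out as ~200 px after the soft boundary),
darker than the background by default, then blurred (σ = 1 px) and
degraded with Gaussian camera noise; with probability `flicker_prob` a
cell is omitted from a frame while persisting in ground truth.  Optical
halos, mosaics and focus selection are deliberately out of scope: the
stacks exist to exercise the analysis against exact ground truth, not to
imitate optics.  The rendered field extends a configurable margin (10 μm)
beyond the simulation domain so growing colonies stay in view.

Segmentation follows standard monolayer practice: background subtraction,
difference-of-Gaussians bandpass (1 px / 15 px defaults, calibrated on the
renderer), one fixed intensity threshold per experiment, 8-connected
components, a minimum area (50 px), an ellipse fit from image moments, an
eccentricity acceptance band [0.5, 0.995] that drops round-ish objects,
and poles at centroid ± (major/2)(cos θ, sin θ).  Touching cells are not
split by watershed; the simulator's clearance keeps test densities below
heavy-contact regimes.  The per-experiment threshold is robust: a ±18%
perturbation changes per-frame counts only at object boundaries, so the
fitted growth rate moves by far less than 1% on rendered stacks.  One
deliberate difference from a real acquisition: the simulator seeds cells
at full density from frame 0, so the pipeline builds its background from
rendered cell-free frames instead of the movie's first frames (which, in
a real experiment, are nearly empty and serve that role).

## Tracking and event detection

Detections are linked frame to frame by a global minimum-distance
assignment (Hungarian algorithm) between predicted track positions and new
detections, gated at a search radius (default 1 μm — below the ~1.2 μm
mother-to-daughter centroid offset, so a division ends the mother's track
rather than continuing into a daughter).  Unmatched tracks survive
`memory_frames` (default 3) frames with constant-velocity prediction,
bridging detection flicker.  Pole identity is propagated by minimal-motion
matching against the previous frame.

A division is declared when an ended track can absorb two new tracks
beginning within `division_pair_radius` (2 μm, one cell length) at the
next occupied frame; contention between near-simultaneous divisions in
adjacent colonies is resolved by a capacitated assignment (each candidate
mother duplicated twice in the cost matrix, global minimum total
distance).  On ground-truth trajectories this recovers ≈98.5% of
divisions; the residue is spatially ambiguous simultaneous sister
divisions.  The measured division time is the mother's trackable duration,
one frame short of the generative clock (the mother's last point precedes
the split).  Trajectory ends that are not divisions are detachments;
starts that are neither daughters nor the movie start are attachments; a
single step longer than `detach_displacement_threshold` (5 μm, the low end
of the observed hops) counts one detachment plus one attachment.

Erosion rates are quantified on dilute fixtures without divisions,
mirroring the separation in the original study design (high-frame-rate
dilute recordings): in dense dividing scenarios the ~1.5% of missed
divisions leak daughter starts into the attachment channel, which swamps
R_a = N_a/N_d precisely when true reattachments are few.

## MSD and classification

The lag-τ MSD of a trajectory pairs points by time difference (so bridged
gaps contribute no spurious pairs).  Two normalizations are exposed: the
*printed* form divides the pair sum by the number of trajectory points N,
and the conventional *pair average* divides by the number of pairs.  At
the maximum lag τ = T they differ by a factor N: the printed form decays
like 1/N and cannot express the ~1 μm² end-of-trajectory signature of a
divider, so the classifier uses the pair average (the estimator standard
particle-tracking software computes), while the MSD function defaults to
the printed form for fidelity to the stated estimator.  At τ = T the sum
has a single term — the squared net displacement.

Classification: end MSD > (0.5 μm)² → divider; otherwise duration > 40 min
→ non-divider; otherwise censored (possible pre-division detachment),
excluded from fractions and division statistics.  Dividers with division
time beyond 160 min are flagged lagged.  Pole statistics sum per-frame
step lengths for each pole and the centroid, after correcting
pole-identity flips, and report max/min per bacterium.

## Population rates and division statistics

η is the least-squares slope of ln N versus t (equivalent to the
time-averaged per-capita rate for exponential growth; the direct
instantaneous-average estimator is available behind a flag), fitted by
default from 80 min onward, with an optional truncation time for runs
whose late data are contaminated (the study discards t > 280 min at the
lowest shear because of upstream reattachment).  η_d and η_a use
left-aligned finite differences of the cumulative counts over the current
attached count, time-averaged over the same window; η_eff = η + η_d − η_a
holds by construction.  Birth classes tag each trajectory by its 40-min
birth interval (initially attached cells in class 1) and count attached
members per class per frame.

The division-time fit is a maximum-likelihood exponential on the bulk
(floor < τ_d ≤ 160 min), accounting for both the 20-min support shift and
the right truncation at the cutoff; the reported mean is floor + θ̂.  Two
sampling caveats matter when reading simulated statistics.  First,
completed divisions under-sample long clocks near the end of a movie, so
pooled fits are biased low; the unbiased readout restricts to birth
cohorts the movie can fully observe.  Second, the "late-bin" mean used to
show convergence to the continuous clock takes births in
[horizon − 240, horizon − 160) min: lagged cells born there cannot divide
before the movie ends (delay 240), while a continuous division is censored
only with probability e⁻⁷.

## Measured η_eff versus the model rate

The attached count N mixes dividers with accumulating non-dividers whose
share relaxes toward its branching-equilibrium value 2(1−f)/(2f−1) over a
few generations.  Over a 6-h window this relaxation adds roughly
+0.02 h⁻¹ to the fitted slope relative to the divider-subpopulation rate
ln(2f)/τ̄ that the model describes.  The end-to-end recovery checks
therefore use a ±0.05–0.08 h⁻¹ band around the model value — about the
level of agreement the model itself achieves on real data ("relatively
good agreement") — rather than pretending the two rates are identical
estimators.

## Problem sizes

Tests and the acceptance script run at desk scale: rendered fixtures use
15–40 initial cells over 100–200 min at 0.1 μm/px (field ≲ 850 px);
classifier-recovery runs use 400–500 initial cells over 320 min on
ground-truth trajectories (5 replicate seeds, ~30 000 classified
trajectories); division-time runs collect 1 500–8 000 events.  The full
suite completes in about two minutes and the acceptance script in under
one on a single CPU.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis assumes —
phenotype mixture, truncated-exponential clocks, bistable daughter
assignment, shear-style detachment/reattachment, pole-anchoring asymmetry,
detection flicker — so passing tests demonstrate that the pipeline
recovers known generative parameters through imaging, tracking and
classification.  They do not validate optics realism (halos, defocus,
second layers), mechanosensing dynamics, nutrient fields, EPS mechanics,
or cell mechanics beyond rigid elongating rods with a heuristic overlap
relaxation; conclusions about real micrographs still require the real
data.  Known limitations: simultaneous adjacent divisions are ~1.5%
ambiguous to the tracker; crowded rendered colonies can merge at
segmentation (no watershed); the rigid overlap push slightly suppresses
crowded dividers' centroid displacement; and detached-cell transport is
instantaneous rather than advected.
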