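# Methods

This note documents the models implemented in `arceval`, their
assumptions, the defaults and why, and what the synthetic-data generators
do and do not emulate.

## Delivery-time model

Beam time is decomposed into spot beam-on, spot switching and energy
switching, the standard PBS log-file decomposition:

* spot beam-on: `max(MU × spot_time_per_mu, spot_time_min)` — linear in MU
  with a per-spot floor. The functional form is a modelling choice (the
  components are standard; the hinge makes the floor identifiable from
  logs).
* spot switching: a constant per intra-layer transition.
* energy switching: direction dependent, `energy_up_switch_time` (order
  seconds on cyclotron systems) vs `energy_down_switch_time` (sub-second).
  Equal-energy transitions cost nothing, so re-scans at one energy are
  free at this level of the model.

Defaults (5 ms/MU, 2 ms floor, 2 ms spot switch, 6.0 s up, 0.8 s down) are
**illustrative placeholders** for simulation and round-trip testing; they
are not calibrated to any specific delivery system. The gantry kinematics
defaults (0.6 °/s² acceleration, 6.0 °/s maximum speed) are the published
limits of the modelled gantry class.

**Static (auto-sequenced) delivery** serializes everything: beam time +
energy switches + rest-to-rest gantry moves between control points
(triangular or trapezoidal velocity profile in closed form) + a
range-shifter penalty per flagged field — 60 s when the snout is also
moved (multi-field practice), 30 s when only the range shifter moves
(static-arc practice). Serializing gantry motion with energy switching is
deliberately conservative; real systems may overlap the two, which would
only shorten the static totals.

**Dynamic delivery** simulates the arc controller. Each control point owns
an angular window (full width, centred on its gantry angle; windows must
not overlap). The required time of a window is its layers' beam time plus
the energy switch *into* the window — charged inside the window because no
buffer window is modelled. The controller enforces "window not crossed
faster than its required time" as a per-window velocity cap
`width / required_time` (any velocity profile under the cap needs at least
the required time to cross); the minimum-time profile under piecewise
caps, the global speed limit and the acceleration limit is computed by a
forward feasibility pass and a backward smoothing pass over segment
boundaries, then closed-form accelerate/cruise/decelerate algebra per
segment. The gantry starts at rest at the first window's leading edge and
ends at rest at the last window's trailing edge. Consequences, used as
invariants in the tests: the total is always ≥ max(total beam time,
rest-to-rest move over the full span), with equality in the
beam-dominated and motion-dominated limits respectively.

Numerical notes: the production path is exact segment algebra; test
oracles are a dt = 1e-4 s bang-bang time-stepping integrator (rest-to-rest
moves) and a fine space-marching velocity-limit integrator (controller),
both independent of the closed forms they check.

## Timing calibration

The delivery log is an artifact-defined CSV event stream
(`timestamp, event_type, energy, mu, control_point_index`) with paired
start/end events; vendor-native log formats are proprietary and out of
scope. Estimation:

* **Spot slope and floor** — spot duration is a hinge in MU. An iterative
  hinge fit classifies each spot as floor- or MU-limited under the current
  estimates, refits the slope by through-origin least squares on the
  MU-limited spots and the floor as the mean duration of the floor-limited
  spots, and repeats to a fixed point. On noiseless logs this is exact.
  A fixed censoring window around the minimum *observed* duration was
  considered and rejected: with timestamp jitter comparable to the floor
  (0.5 ms jitter vs a 2 ms floor) such a window straddles the lower noise
  tail and biases the floor estimate severely, while classification by
  *predicted* duration is noise-free.
* **Spot switch** — mean of intra-layer gaps.
* **Energy switches** — 10% trimmed means of switch durations, split by
  direction (destination energy vs. the preceding layer's energy). A
  direction never observed is reported absent (`None`), never guessed, and
  `to_machine_model()` refuses to fill it silently.

Standard errors: through-origin OLS residual SE for the slope, `sd/√n`
for the means. The floor is only identifiable if some spots carry little
enough MU to hit it; the synthetic plan generator's MU distribution
(log-normal, clipped to [0.02, 6] MU) guarantees this.

## Dose metrics

Voxels are point samples at their centres; a voxel is in an ROI iff the
mask says so (no partial-volume weighting) — deterministic and exactly
checkable against per-voxel counting oracles. The DVH is the exact sorted
voxel-dose curve (binning exists only for plotting); the cumulative curve
is right-continuous and Dx at a step returns the upper dose, matching
"minimum dose to the hottest x% of the volume". D1cc is the absolute-volume
analogue at 1 cm³; it errors on ROIs smaller than 1 cm³. CI is evaluated
at 95% of the relevant target's prescription in the shipped pipelines;
integral dose is body mean dose × body volume in litres. Degenerate
inputs (empty ROI, no voxel at the prescription isodose, mismatched
geometries) raise rather than return sentinel numbers.

## NTCP

Logistic models over named OAR dose metrics,
`NTCP = 1/(1 + exp(−S))`, `S = β₀ + Σ βᵢ xᵢ` (+ optional clinical
covariates). The shipped coefficient sets are **illustrative**, shaped
like published head-and-neck xerostomia/dysphagia models (salivary-gland
mean doses for xerostomia, pharyngeal-constrictor and oral-cavity mean
doses for dysphagia; grade ≥ 2 / ≥ 3 as separate models); clinically
validated coefficients must be supplied by the user via YAML. Technique
comparisons use the exact two-sided Wilcoxon signed-rank test with zero
differences dropped (all-zero ⇒ p = 1); at the 6-patient scale this test's
smallest attainable two-sided p is 2/2⁶ = 0.03125. A paired t-test is
available behind a flag.

## Robustness evaluation

The 28-scenario set crosses 14 setup-shift directions — the 6 axis-aligned
face directions and the 8 corner directions (±1,±1,±1)/√3 of the setup
sphere, all scaled to the setup magnitude — with density scalings
{1−f, 1+f}. Only the count of 28 is externally anchored; the
faces-plus-corners polyhedron is the standard evaluation set consistent
with that count and is documented here as an assumption. The nominal
scenario is *not* a member. Default settings: 3 mm/3% on the planning
anatomy, 1 mm/3% on repeat anatomies (residual uncertainties only, since
the repeat anatomy itself captures positioning and anatomical change).

Voxel-wise minimum, warping (pull-back with trilinear interpolation,
0 Gy outside the grid) and accumulation are element-wise operations with
exhaustive oracles. For course accumulation, scenario s of week k is
matched with scenario s of every other week — the worst-case-correlated
pairing — and weeks carry equal fraction weights by default. With a
single week of weight 1 the course result reduces exactly to the
fraction-wise result.

## Synthetic data

The generators are pure functions of (config, seed).

* **Phantom** — 64³ voxels at 3 mm (head-and-neck-scale field of view,
  chosen to keep full pipelines interactive): nested spherical/ellipsoidal
  targets (CTV at 70 Gy inside an elective CTV at 54.25 Gy), a body
  contour, and the standard OAR inventory (cord, brainstem, parotids,
  submandibulars, three pharyngeal-constrictor levels, oral cavity), with
  nesting guaranteed by construction.
* **Plans** — layer/spot structure matching the published archetypes: 30-
  and 10-beam static arcs with descending intra-beam energies and rising
  inter-beam transitions (so up-switches = beams − 1: 29 and 9), the
  +2-range-shifter variant (420 layers total, 31 up-switches), ELSA-style
  single-layer windows and SPArc-style 1–5-layer windows whose up-switch
  count is a configurable target (the published optimizers that determine
  it are out of scope). Spot totals land in the published 9k–18k range.
* **Dose engine** — parametric-geometric, *not* physics-based: each
  target's prescription falls off logistically around its surface
  (distance-transform based), plus a technique-dependent low-dose bath
  (higher and longer-ranged for few-field IMPT than for arcs, so arc
  engines spare OARs better by construction) and a smooth seeded ripple
  for finite homogeneity. Response hooks are exact by construction: a
  setup shift translates the dose (trilinear; exact at integer-voxel
  shifts), and a density scaling shifts the falloff radially by
  (scale − 1) × 30 mm (denser patient ⇒ shorter range ⇒ falloff pulled
  inward). Technique margins are set so the 95% isodose clears the first
  voxel shell, keeping conformity resolvable on the 3 mm grid.
* **Weekly anatomies** — rigid shoulder-like shifts (zero-mean Gaussian,
  default SD 2/0.5/2 mm), progressive surface regression (0.3 mm/week) and
  small density deltas, all mapped onto the engine as an anatomical shift
  plus a margin offset; the ground-truth deformation field of the modelled
  rigid change is the constant shift vector. Week 0 is the planning
  anatomy with the identity field.
* **Delivery logs** — event streams generated from the delivery-time
  model itself; per-interval Gaussian jitter truncated at zero keeps
  timestamps monotone by construction, and the noiseless log's elapsed
  time equals the simulator's motionless components exactly.

What the synthetic data does **not** emulate: proton transport (no range
mixing, scatter, or heterogeneity effects), realistic CT numbers,
deformable (non-rigid) anatomical change, optimizer behaviour (spot
weights are not optimized against objectives), or vendor log formats.
Passing tests therefore demonstrate the correctness of the evaluation
machinery and the qualitative orderings built into the generators — not
clinical dose accuracy.

## Problem sizes

Default test and acceptance runs use 24³–64³ grids, plans of 20–420
layers, logs of ~10⁴ spots, 28-scenario sets, and up to 7 synthetic weeks;
the full 6-patient × 6-technique × 7-week study runs on one CPU core in
tens of minutes at the 64³ default and in about a minute at 24³.

## Known limitations

* Static delivery assumes no overlap between gantry motion and energy
  switching; published static-arc gantry overheads suggest real systems
  overlap them, so static totals here are upper bounds.
* The dynamic controller's per-window velocity cap is slightly
  conservative: a profile that accelerates inside a window could cross it
  in exactly the required time with a higher entry speed. The cap
  guarantees feasibility and the documented invariants at the cost of, at
  most, the intra-window ramp time.
* Dx uses the step-curve convention throughout; on coarse grids this can
  differ from interpolating DVH implementations by up to one voxel's dose.
* The intra-beam delivery order of static arcs (descending energy) is an
  assumption; it is the fast order on machines with cheap down-switches
  and is overridable at the sequencing rule.
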