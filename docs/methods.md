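# Methods

## The planning problem

Step-and-shoot IMRT delivers dose through a small number of co-planar
beams whose 2D fluence maps are discretized into bixels. Conventional
inverse planning drives those bixel weights by iteratively optimizing a
piece-wise quadratic penalty function; the planner steers the result
only indirectly, through constraint weights. Interactive dose shaping
(IDS) inverts this interface: the planner points at the 3D dose
distribution and asks for a *local* change, and the system finds the
fluence change that enforces it — then repairs the collateral damage.
This package implements that operator, the surrounding planning
workflow, the standard plan-quality mathematics, and a sequencer, on
fully synthetic pelvic phantoms so every experiment is reproducible
from a seed.

## Dose modification and recovery (DMR)

One DMR instance has two steps.

**Modification.** A request asks for a signed dose change `dd` at voxel
`v`, together with a modification region `V_M` (the voxels whose change
is intended; at minimum `{v}`). With `a` the row of the dose-influence
matrix at `v`, the fluence patch is the minimum-norm solution of
`a · P = dd`, i.e. `P = dd · a / ‖a‖²`, solved on the row support with
non-negativity of the resulting weights enforced by iterative clamping
(clamped entries frozen at bound, the residual re-solved on the free
entries, at most 10 passes). The achieved change `a · P` therefore has
the sign of the request; when every weight bottoms out at zero it is
the best achievable decrease.

**Recovery.** The patch perturbs dose outside `V_M`. Voxels whose dose
moved more than a tolerance `τ` from the pre-modification dose are
ranked by deviation magnitude (ties broken by ascending voxel index)
and truncated to a budget `N_R` (default 15, the budget at which a
desktop machine keeps one instance under a second). Each selected voxel
then receives its own counteracting minimum-norm patch, in rank order,
single pass — recovery patches trigger no further recovery, which
bounds an instance at `1 + N_R` patches.

Two design choices here were genuinely open:

* **Recovery targets are re-evaluated live.** Each recovery patch
  enforces the return to the voxel's *original* dose, computed against
  the dose at application time rather than frozen at identification
  time. Frozen deviations double-count: earlier recovery patches
  perturb later recovery voxels, and enforcing a stale deviation then
  overshoots (in a representative phantom experiment the worst
  deviation grew from 4.8 Gy to 10.7 Gy with frozen targets and shrank
  to below the 0.38 Gy tolerance with live targets). Ranking still uses
  the identification snapshot.
* **Protection by support exclusion.** A bixel that carries at least
  90% of the modification's enforced change is excluded from the
  instance's recovery-patch supports, so recovery can never outright
  undo the intent it is cleaning up after. On sparse, near-separable
  geometries this makes the operator exact (the modification is
  preserved exactly and recovery voxels restored exactly); in realistic
  plans the change spreads over hundreds of bixels, no single bixel
  reaches the share, and the guard is inert. A bound-based guard was
  considered and rejected: any touch of a dominant bixel perturbs the
  modified voxel, so a bound cannot give exactness.

`τ` defaults to 0.5% of the boost prescription (0.38 Gy at 76 Gy) so
that the tolerance scales with the prescription rather than being an
absolute constant.

## Shaping tools

Three gestures expand into ordered DMR request lists:

* **voxel** — one request at one voxel.
* **sphere** — one request per body voxel inside the sphere, the
  requested change weighted by a raised-cosine radial falloff (full at
  the center, zero at the surface); the sphere is the shared `V_M`, so
  intra-sphere collateral is intended and not recovered. A radius below
  half a voxel degenerates to the center voxel alone.
* **isodose drag** — the voxels along the from→to segment are raised to
  the level (dragging outward from the hot side) or lowered to it
  (dragging inward); a zero-length drag is a no-op.

Requests run consecutively; execution is order-dependent by design (it
emulates a planner's sequence of hand edits), and the first infeasible
instance aborts the remainder while earlier instances persist.

## Dose engine

The engine is a transparent analytic finite pencil beam in a
homogeneous, water-equivalent body, chosen so that every property the
DMR operator relies on (linearity, locality, depth monotonicity,
symmetry) is testable in closed form:

* parallel rays per beam (no divergence correction), beams co-planar
  about the z axis, 9 equispaced gantry angles by default;
* exponential depth attenuation, `μ = 0.005/mm`, with radiological
  depth ray-marched through the body mask at half the smallest voxel
  spacing (sample points staggered off the voxel lattice so symmetric
  geometries march symmetrically);
* lateral profile per transverse axis: the bixel top-hat convolved
  with a Gaussian penumbra (`σ = 3 mm`), i.e. a difference of error
  functions;
* bixel size 5 × 5 mm², matching the 5 mm MLC leaf width so one bixel
  row per leaf pair (no resampling at sequencing time);
* per-bixel sparsity threshold 10⁻⁴ of that bixel's maximum entry.

No beam energy or kernel parameters are claimed to be clinical; they
are exposed in `KernelParams`. Dose is `D · w`, linear in the weights,
and sparse column updates give the incremental evaluation the
interactive workflow depends on (identical to full recomputation to
10⁻⁹ Gy by construction, asserted by oracle tests).

## Planning workflow

`init_plan` opens uniform fields conformed to the PTV plus a 5 mm
margin and applies one exact scale factor so that D50% of the PTV
equals the average of the PTV and boost prescriptions — D50% is linear
in a global fluence scale, so no search is needed. No normalization is
ever applied afterwards; the scale factor is recorded and untouched by
shaping.

`goal_script_run` replaces the interactive planner with a scripted
greedy loop over a strict-priority goal list: the nine Quantec
dose-volume constraints (rectum V50<50, V60<35, V65<25, V70<20,
V75<15; bladder V65<50, V70<35, V75<25, V80<15, all strict, in
percent), then target-coverage floors (D98% ≥ 95% of prescription for
PTV and boost), then budgeted organ-sparing exploration. Per goal the
loop picks the hottest organ voxel at or above the constraint threshold
(coldest target voxel below the floor, for coverage goals), runs a
sphere gesture there (radius 3 voxels, aiming 1 Gy past the threshold),
and keeps the instance only if a scalar objective strictly improves
*and* no previously satisfied higher-priority constraint breaks;
otherwise the state is rolled back and the voxel blacklisted. The
objective sums Quantec violations (1 per percentage point) and
coverage-floor deficits (weight 10 per Gy); sparing phases add 0.05
times the organ's mean dose so progress is measurable once all
constraints are met. A goal that exhausts its gesture budget is
reported unmet, not fatal.

`baseline_optimize` stands in for a conventional inverse-planning
reference: projected gradient descent with backtracking line search on
a weighted piece-wise quadratic objective (targets pinned to their
prescriptions, OARs and normal tissue bounded above), initialized from
the scaled open field, fully deterministic.

## Plan-quality metrics

All metrics are voxel-exact. `D_q%` is the largest sampled dose
received by at least q% of the structure (D50% is the reported median);
`V_x` uses an inclusive threshold, matching the cumulative-DVH
convention. The conformity index is the van't Riet product
`CI = CI1 · CI2` with `CI1 = V_t,ref / V_t` and `CI2 = V_t,ref /
V_ref`, evaluated at a threshold fraction of the prescription
(default 0.95); when nothing reaches the threshold all three indices
are 0 by convention. The homogeneity index is the population standard
deviation of dose in the structure (sample-variance correction is
negligible at voxel counts and left out). The non-tumor integral dose
is `ρ · V · mean dose` over body-minus-PTV in litre·Gy with ρ = 1.
PTV indicators include the boost region. The duplicated bladder bound
found in some published constraint lists (V75 printed twice) is
implemented as V80 < 15%, consistent with reporting V80 as its own
column.

## Sequencing

Fluence maps are stratified per beam onto 7 equidistant levels (step =
beam maximum / 7, rounding half-up, so the per-bixel error is at most
half a step) and decomposed by the classic unidirectional sweep: per
leaf-pair row, the left/right leaf trajectories are the first columns
at which the cumulative positive/negative gradients of the integer
profile reach the segment index. Summing the unit apertures
reconstructs the stratified map *exactly*, leaves move monotonically,
and the per-beam segment count equals the worst row's summed positive
gradients. Finished rows park closed at their final right-leaf position
so no leaf ever moves backwards. No interdigitation or tongue-and-groove
constraints are modelled, which is what keeps the decomposition exact.
`deliverability_delta` recomputes the dose and the full metric set from
the reconstructed fluence and reports the change against the unsequenced
plan, together with its linearity bound (the dose of a uniform half-step
fluence perturbation); exact reconstruction makes the quantization the
only source of dose difference.

## Synthetic phantoms

The generator emulates a segmented male pelvis: a body contour, a PTV
around the prostate, a boost volume inside it, the rectum posterior and
the bladder anterior/superior. Organs are superellipsoids whose
boundary radius is modulated by a smooth low-order angular field drawn
from the seeded generator (amplitude 3 mm, bounded at ±25% so organs
never collapse); containment (boost ⊆ PTV ⊆ body) and OAR/PTV
disjointness are enforced exactly by mask algebra, so they hold for
every seed. Default prescriptions are 76 Gy (boost) and 73 Gy (PTV),
the top of the published clinical range; organ positions and the
PTV–OAR gaps are parameters because published geometries do not state
margins or overlap conventions.

What the phantoms do **not** emulate: CT heterogeneity (the body is
water-equivalent), concave or wrapping organ shapes, inter-patient
anatomical variability beyond smooth jitter, and any scatter outside
the analytic kernel. Tests passing on these phantoms therefore
demonstrate the *algorithmic* contracts — exactness, monotonicity,
constraint satisfaction under the stated geometry — not clinical dose
accuracy.

## Problem sizes and numerical choices

The default test grid is 64×64×48 at 4 mm isotropic; the study
emulation runs 64³ at 4 mm (≈262 k voxels, ≈21 k bixels, ≈30 M sparse
entries), and a 256×256×160 grid at 1.95×1.95×2.0 mm is available as
the clinical-scale preset. Tolerances: dose-engine oracle equivalence
at 10⁻⁹ Gy; patch achieved-change at the closed form; recovery
tolerance τ at 0.5% of the boost prescription; the half-step bound for
sequencing is exact. Degenerate inputs are defined rather than
rejected wherever a convention exists (all-zero fluence maps have step
0 and no segments; all-cold conformity is (0, 0, 0); a sphere smaller
than half a voxel is a single-voxel gesture).

## Known limitations

* Recovery is single-pass and local; like the workflow it emulates, it
  trades residual off-target deviation for bounded runtime, and the
  mid-dose bath (NTID) is not actively controlled.
* The greedy goal loop is one automation of a human-in-the-loop
  procedure; it stops at budget exhaustion without a principled
  stopping rule for the trade-off phase.
* The sweep sequencer is a generic exact decomposition; its segment
  counts are comparable in spirit, not in value, to any specific
  vendor sequencer.
* Open-field initialization considers only the median-dose condition
  and produces no steep dose gradient around the target; conformity of
  the mid-dose region (CI2) is accordingly loose, which mirrors the
  behaviour this planning strategy is known for.
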