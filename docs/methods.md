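# Methods

`hemoflow` replicates, at desk scale, a within-subject hemodilution
experiment: blood viscosity is measured before and after an intravenous
saline infusion, both rheologies are run through the same
carotid-bifurcation flow model, and wall shear stress (WSS) and wall
shear rate are compared region by region with paired statistics.  This
note records the models, the defaults and why they hold, the numerical
choices, and what the synthetic data can and cannot stand in for.

## Blood rheology

Whole blood is modelled as a Casson fluid,

    sqrt(tau) = sqrt(tau_y) + sqrt(k * gamma_dot),

with yield stress `tau_y` [Pa] and Casson constant `k` [Pa s] (the
high-shear limiting viscosity).  The apparent viscosity
`mu = tau / gamma_dot` factors as `sqrt(mu) = sqrt(k) +
sqrt(tau_y / gamma_dot)`, which has two consequences used throughout:

* **Fitting** is linear least squares in square-root coordinates
  (`x = sqrt(gamma_dot)`, `y = sqrt(mu * gamma_dot)`), weighted by
  `1/y`.  Viscometer error is multiplicative in `mu`, i.e. a uniform
  *relative* error in `y`; the `1/y` weighting is the corresponding
  maximum-likelihood weighting and keeps the low-shear points — which
  carry essentially all of the yield-stress information — from being
  swamped by the numerically large high-shear values.  A negative
  intercept is clipped to zero (Newtonian data) and the slope refit.
  Under the generator's own noise model (2% multiplicative, 20 grid
  points) the worst-case parameter error over 100 replicates stays
  below 5%; the noiseless round trip is exact to machine precision.
* **Calibration** of the condition means is a closed-form inversion:
  two (shear rate, viscosity) anchors determine `(tau_y, k)` exactly.
  The before/after means are inverted from the published group-mean
  anchors — 33.64/28.40 cP at 1 1/s and 5.02/4.51 cP at 300 1/s —
  giving before `(tau_y, k) = (0.01427 Pa, 0.004090 Pa s)` and after
  `(0.01157 Pa, 0.003714 Pa s)`.  The saline effect thus appears
  predominantly as a yield-stress reduction, which reproduces the
  published asymmetry (≈18% viscosity drop at low shear vs ≈11% at
  high shear) without any further tuning.

A note on provenance: the source study prints its constitutive relation
without radicals (`tau = tau_y + k*gamma_dot`, which is the Bingham
law) while naming and citing the Casson model; the canonical Casson
form above is implemented.

Casson apparent viscosity diverges as `gamma_dot -> 0`.  Inside the
solver the law is regularized by flooring the shear rate at
`gamma_min = 1e-3 1/s` and capping the viscosity at `mu_max = 10 Pa s`,
so unyielded plugs behave as a very viscous fluid.  The measured range
1–1000 1/s is untouched; at the benchmark channel's plug (half-width
`tau_y/G` ≈ 1.6% of the channel half-height) the regularization error
is below the 2% verification tolerance.

Units: cP and 1/s at every I/O boundary (laboratory convention), SI
internally; 1 cP = 1e-3 Pa s, converted exactly once per crossing.

## Synthetic cohort

The study's raw data (per-participant viscometer curves, MRA lumen
geometries, the Doppler inflow waveform) were never published, so a
seeded generator module produces statistically matched stand-ins:

* **Viscosity curves** — n = 8 participants by default.  Each
  participant draws one lognormal factor per Casson parameter
  (between-subject CV 10%, matching the published ≈10–16% relative
  SDs) applied to *both* condition means — the paired, within-subject
  structure: subject identity is the shared factor, the saline effect
  is the deterministic mean shift.  Per-point measurement noise is
  multiplicative lognormal with CV 2% (scale-proportional, keeps
  positivity).  The 17-point grid is log-spaced over 1–1000 1/s.
  Across seeds the cohort grand means reproduce the four anchors to
  well within 5%.
* **Waveform** — one cycle of mean inlet velocity,
  `v(t) = v_mean (1 + c * sum_i a_i cos(2 pi i t/T + phi_i))`, three
  harmonics phase-aligned to a systolic peak at t = 0.15 s, rescaled so
  peak/mean = 2.5 with the cycle mean exactly `v_mean = 0.3 m/s` —
  typical healthy common-carotid Doppler values (period 1.0 s).  The
  same waveform drives both conditions, as a saline infusion is not
  assumed to change the cardiac waveform shape; this is configurable.
* **Geometries** — lognormal jitter (CV 5% by default, hard-capped at
  15%) of branch diameters and of the bulb's excess width over 1.0, so
  `bulb_factor >= 1` always; invariant-violating draws are resampled a
  bounded number of times.

What the generator does *not* emulate: the physiology of hemodilution
(hematocrit and plasma-viscosity kinetics — the after condition is a
parameter shift, not a mechanism), viscometer systematics such as
temperature drift, true anatomical variation beyond diameter/bulb
scaling, and any left/right anatomical asymmetry.  Passing tests
therefore demonstrate that the *pipeline* recovers the direction and
rough size of a rheology-driven WSS change under realistic geometry
and noise — not that it reproduces any individual subject.

## Geometry and mesh

The flow domain is a parametric two-dimensional planform of the carotid
bifurcation: a common-carotid (CCA) trunk along +x from the inlet at
the origin, an internal-carotid (ICA) branch carrying a smooth
cosine-bump bulb on its outer (non-flow-divider) wall, and an
external-carotid (ECA) branch, at a mutual angle of 50° by default.
Defaults (mm): d_cca 6.2, d_ica 4.5, d_eca 3.6, bulb factor 1.2 (max
bulb width / d_ica), segment lengths 20/15/12 with a ≥3-diameter
entrance-length floor, bulb over 45% of the ICA length.  The outline is
the union of three channel strips, morphologically smoothed
(dilate–erode–dilate, round joins) into C1 fillets at the junction,
then clipped by the inlet and outlet planes so the caps are straight.

Going 2-D instead of reconstructing 3-D lumens is the central fidelity
compromise: it preserves the flow topology that drives the study's
qualitative results — the branch flow split, apex impingement, and
bulb recirculation with low WSS — at desk-scale cost, but absolute WSS
magnitudes are indicative only and per-subject table cells are not
comparable to a 3-D patient-specific computation.

Meshing is a force-equilibrium (truss relaxation) scheme over
scipy-Delaunay retriangulations with a shapely signed distance:
boundary nodes fixed at a uniform resampling of the outline (sharp cap
corners preserved), interior nodes relaxed from a hexagonal seed.  On
the default geometry this yields minimum triangle angles ≳ 25° and an
Euler-characteristic-1 disk.  Boundary edges are tagged
inlet / wall / outlet_ica / outlet_eca by proximity to the analytic cap
planes; wall vertices are partitioned into cca, bifurcation_apex_zone
(within 0.5 d_cca of the analytic inner-wall apex), ica, ica_bulb
(outer ICA wall within the bulb arc) and eca.  "Whole artery" means
all wall vertices — the boundary minus the one inlet and two outlets.
Table-style "ICA" summaries use ica ∪ ica_bulb; the apex zone is
reported with the bifurcation, not the ICA.

## Flow solver

Incompressible Navier–Stokes with shear-dependent viscosity on the
inf-sup-stable Taylor–Hood pair (quadratic velocity, linear pressure).
Each time step solves one monolithic saddle-point system: implicit
time derivative and viscous term, convection linearized with the
previous-step velocity in skew-symmetric form (discretely
energy-stable), viscosity evaluated from the previous iterate's shear
rate through the regularized Casson law and Picard-iterated within the
step (tolerance 1e-3, max 2 iterations; the field changes slowly over
a 2.5 ms step, so the first iterate usually converges).  Direct sparse
LU solves per iteration.

Two numerical decisions deserve their rationale:

* **Coupled solve rather than pressure-correction splitting.**  A
  projection (IPCS) scheme was implemented first; its pressure
  Dirichlet rows at the outlet vertices remove the divergence
  constraint exactly where the flux leaves the domain, and the
  resulting diastolic flux leak (≈2% of instantaneous inflow) resisted
  time-step and mesh refinement.  The monolithic system keeps the
  constraint active in the full pressure test space; testing it with
  the constant mode *is* the global divergence theorem, so the
  instantaneous inlet/outlet flux balance closes to solver accuracy
  (measured ~1e-13).
* **Gradient-form viscous term** `(mu grad u, grad v)`, matching the
  Laplacian momentum equation the study states, rather than the full
  stress-divergence form.  Its natural boundary condition is the
  classical do-nothing outflow, which leaves developed profiles
  undisturbed at open boundaries and fixes the pressure level; the
  full-stress form's zero-tangential-traction outlet measurably
  distorts Poiseuille flow in short domains.  For unidirectional flows
  the two forms coincide, so the channel verification problems are
  form-independent.  Wall traction in postprocessing always uses the
  full stress `sigma = -pI + 2 mu D`.

Boundary conditions: parabolic inlet profile with the waveform's
instantaneous mean (centerline 1.5×, exact depth-1 flux), rigid
no-slip walls, traction-free outlets shared between ICA and ECA so the
flow split emerges from the solve.  A lumped backflow penalization
`rho/2 (u.n)_- u` on outlet edges guards against the open-boundary
instability during flow reversal; it vanishes identically for outflow
and is disabled in benchmark channels whose open caps carry genuine
through-flow.  Density 1060 kg/m³ (not stated by the source study).
Runs start from rest and cover three cardiac cycles; the first two
absorb the transient and only the last is retained (third-vs-second
cycle periodicity residual ~1e-6 at default settings).  Default
dt = 2.5 ms (400 steps per 1 s cycle), snapshots every 8 steps.
Peak Reynolds number at default settings is ≈900, comfortably laminar.

Verification anchors: plane Poiseuille (centerline/mean = 1.5 within
1%), the Casson plane channel against an independently quadrature-
integrated closed-form profile (≤2% L2) with wall stress equal to
`G h` (momentum balance, rheology-independent, within 1%), a symmetric
bifurcation splitting flow 50/50 within 1%, and exact pulsatile flux
closure.

## Wall quantities and summaries

Shear rate is `sqrt(2 D:D)`, `D = (grad u + grad u^T)/2`.  WSS samples
live at the midside node of every wall edge: the discrete velocity
gradient of the adjacent element gives `D` and the shear rate, the
viscosity is the same regularized Casson law the solver used, and the
signed WSS is the tangential fluid-on-wall traction component with the
tangent oriented along the local branch's downstream direction —
attached forward flow is positive, recirculation negative.

The reduction protocol (the published tables do not define the order
of reductions) is: length-weighted spatial mean of the quantity's
magnitude over a region at each saved time, then minimum / trapezoidal
time average / maximum over the retained cycle — one scalar triple per
region, side and condition.  Recirculation is the length-and-time
fraction of a region with negative signed WSS.  "End-diastole" field
snapshots are the final saved instant of the cycle.

## Paired statistics

Per variable (region × side × statistic × quantity), the paired
differences are gated by Shapiro–Wilk at alpha = 0.05 (the study
protocol names no normality test; this is a declared choice): normal
goes to the two-sided paired t-test, non-normal to the two-sided
Wilcoxon signed-rank test with an exact null distribution for up to 25
nonzero differences, computed by integer convolution over doubled
midranks — exact under ties, verified against full 2^n enumeration.
Zero differences are dropped (Pratt handling available).  All-zero
difference vectors return a flagged degenerate result (p = 1).  Left
and right arteries are separate n = 8 samples, never pooled.  No
multiple-testing correction is applied across the 24 table cells,
matching the replicated protocol; with 24 correlated tests at
alpha = 0.05 this inflates the family-wise error rate, which is a
property of the protocol, not of this implementation.  The composite
gated procedure holds its type-I error within [0.035, 0.065] under a
Gaussian null at n = 8 (10^4-replicate simulation).

## Problem sizes

Default study profile: mesh edge length 0.7 mm (~1500 triangles,
~6800 velocity + 850 pressure unknowns), dt 2.5 ms, 3 cycles; a
participant-side simulation takes a few minutes on one core, the
16-artery × 2-condition full cohort a few hours.  The smoke profile
(2 participants, one side, 1.1 mm mesh, dt 5 ms) runs the whole
pipeline in about a minute and is bit-reproducible under a fixed seed.
The single-geometry headline contrast used in the automated checks
runs at 0.7–0.8 mm mesh resolution in a few minutes; its directional
conclusions are stable across that range.

## Known limitations

* 2-D planform: WSS magnitudes indicative; no secondary (Dean) flows,
  no helical structures, no out-of-plane branch angling.
* Rigid walls, laminar flow, one shared inflow waveform — as in the
  replicated protocol.
* The published per-subject table values require the unpublished MRA
  geometries and viscometer curves; only directions, relative changes
  and orders of magnitude are reproducible, and the automated checks
  are designed accordingly.
* The Wilcoxon/t gate is applied per variable; which test the source
  study used for which cell is unreported, so per-cell p-values are a
  convention, not a reproduction.
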