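# hemoflow

Hemodynamics of hemodilution in the carotid bifurcation: a tested
pipeline that asks what an intravenous saline infusion — which lowers
whole-blood viscosity — does to wall shear stress (WSS) and wall shear
rate in the carotid artery.

It is written for biofluid-mechanics and hemorheology researchers who
want the full chain as reusable, verified parts:

* **Casson rheology** — whole blood as a yield-stress shear-thinning
  fluid, `√τ = √τ_y + √(k·γ̇)`; apparent viscosity
  `μ(γ̇) = τ/γ̇`, regularized for flow solvers; weighted least-squares
  fitting of `(τ_y, k)` from viscometer curves (1–1000 s⁻¹).
* **Synthetic paired cohort** — seeded generators for before/after
  viscosity curves (group means calibrated to ≈33.6/28.4 cP at 1 s⁻¹
  and ≈5.0/4.5 cP at 300 s⁻¹), a pulsatile carotid inflow waveform,
  and per-participant parametric bifurcation geometries.
* **2-D carotid bifurcation CFD** — parametric CCA/ICA/ECA planform
  with a carotid bulb, in-package unstructured triangulation, and a
  monolithic Taylor–Hood (P2/P1) Navier–Stokes solver with
  Picard-lagged Casson viscosity: ρ(∂u/∂t + u·∇u) = −∇p + μ(γ̇)∇²u,
  ∇·u = 0; parabolic pulsatile inlet, no-slip rigid walls,
  traction-free outlets; three cardiac cycles, last retained.
* **Wall summaries and paired statistics** — signed WSS and shear rate
  along the wall, min/time-averaged/max per anatomical region, bulb
  recirculation fractions, and normality-gated paired tests (exact
  Wilcoxon signed-rank or paired t, α = 0.05) arranged into
  study-style before/after tables with percent differences.

The design is within-subject throughout: each participant-side is
simulated twice — before- and after-saline Casson parameters on the
*same* geometry and waveform — so every change in the output is
attributable to rheology alone.

## Worked example

Generate a cohort, fit it, and look at the group viscosity contrast:

```bash
python analysis/01_generate_inputs.py --seed 0
python analysis/02_fit_rheology.py
```

```
Group-mean viscosity contrast (denominator-after convention):
  at      1 1/s:  33.03 ->  28.02 cP  (17.89% lower, prints as 17%)
  at    300 1/s:   4.76 ->   4.29 cP  (11.09% lower, prints as 11%)
```

(One seeded n = 8 draw; across seeds the grand means match the
calibration anchors 33.64/28.40 and 5.02/4.51 cP.)

Run the isolated hemodilution contrast — one seeded geometry, one
waveform, only the Casson parameters switched between the published
before/after group means:

```bash
python analysis/05_headline_contrast.py --seed 0 --mesh-h 0.8
```

```
                region  WSS before  WSS after   lower  SR before  SR after
                 whole       1.596      1.468   8.70%      351.3     361.3
                   ica       2.178      2.053   6.08%      473.9     498.5
              ica_bulb       0.706      0.642   9.91%      140.8     145.0
 bifurcation_apex_zone       5.567      5.086   9.46%     1542.7    1578.3
                   cca       1.007      0.906  11.16%      198.6     199.2
                   eca       1.268      1.156   9.63%      266.8     273.3

bulb recirculation fraction: before 0.526, after 0.538
```

Reading it: time-averaged WSS (Pa) falls in every wall region after
saline — by 6–11%, the same order as the published group tables —
while the wall shear rate (s⁻¹) in the whole artery and the internal
carotid rises slightly; the carotid bulb recirculates (negative wall
shear over half its length-time extent) and carries far lower WSS than
the flow-divider apex.  Because the geometry is a 2-D planform rather
than a patient MRA lumen, magnitudes are indicative; directions and
relative changes are the reproducible content.

The full study replica (cohort → fits → 16 arteries × 2 conditions →
tables → percent differences) is one command:

```bash
python analysis/03_run_study.py --profile smoke   # minutes, coarse
python analysis/03_run_study.py --profile paper-scale --seed 0  # hours
python analysis/04_compare_conditions.py --dir results/smoke
```

Every run writes a `manifest.json` with a SHA-256 hash of each
artifact; identical config + seed reproduces identical hashes.

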