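# Methods

## Model overview

`cardiopbpk` implements a whole-body physiologically based pharmacokinetic
(PBPK) model of seventeen perfusion-limited compartments — arterial and
venous blood, lung, adipose, bone, brain, kidney, spleen, gut, liver,
muscle, skin, a lumped "rest of body", and a four-compartment heart — for
a single oral dose.  State variables are drug amounts A_T [mg]; volumes
are in L, flows in L/h, concentrations in mg/L, time in h.

Every non-eliminating tissue follows the well-stirred perfusion-limited
equation

    V_T dC_T/dt = Q_T (C_art − C_T·BP/Kp_T),

i.e. blood leaving tissue T is in instant equilibrium with the tissue at
the tissue:plasma partition coefficient Kp_T (converted to a blood basis
with the blood:plasma ratio BP).  The lung sits in series between the
venous and arterial pools at full cardiac output; the liver receives the
hepatic artery plus the gut and spleen outflows (hepatic-artery flow is
obtained by difference, so the venous return sums exactly to cardiac
output).

Absolute volumes are body-weight fractions × body weight; absolute flows
are cardiac-output fractions × cardiac output (108.33 mL/s for the 70 kg
reference adult, converted once to 389.988 L/h).

### Heart sub-model

The heart tissue volume (0.0047 L/kg → 0.329 L at 70 kg) is split
10/30/60% into epicardium, midmyocardium and endocardium (0.0329, 0.0987,
0.1974 L).  The three mural layers are perfused **serially** from the
outside in — arterial → epi → mid → endo → venous — at the mural flow
Q_he − Q_pf, where Q_he is 4% of cardiac output and Q_pf is a small
pericardial perfusion taken out of Q_he so total flow is conserved.  The
pericardial fluid (fixed 0.03 L, not scaled with body weight) is perfused
directly from arterial blood at Q_pf and exchanges passively with the
epicardium through a single lumped diffusion clearance P:

    J = P (C_epi − fu_pf·C_pf),   positive into the fluid.

Outward flux is driven by the total epicardial tissue concentration and
the return path by the unbound pericardial concentration (unbound
fraction fu_pf).  The exchange is exactly antisymmetric, so it conserves
mass.  This convention was a genuinely open choice: only a passive,
bidirectional, single-parameter process is specified by the model
structure.  The chosen form is the only simple one that lets the
pericardial fluid concentrate far above its partition coefficient
(Kp_pf = 2.6) — the behaviour the reference scenario exhibits, with a
pericardial:venous-blood ratio near 40 despite Kp_pf/BP ≈ 2.5 — because
at quasi-steady state C_pf ≈ (Q_pf·C_art + P·C_epi)/(Q_pf·BP/Kp_pf +
P·fu_pf) and the small fu_pf in the denominator dominates.

### Absorption

The bioavailable fraction of the dose (F_abs × dose) is placed in an oral
depot at t = 0 and transferred first-order (rate k_a) into the gut tissue
compartment, from which it passes through the liver (first-pass).  The
1 − F_abs remainder is never absorbed and is not tracked.

### Elimination

* **Hepatic** — Michaelis–Menten over seven CYP isoforms:
  rate = Σ_i Vmax_i·Cu/(Km_i + Cu).  Whole-liver Vmax_i [mg/h] is scaled
  from recombinant-enzyme activity [pmol/min/pmol CYP] via isoform
  abundance [pmol/mg microsomal protein], MPPGL (45 mg/g), liver mass
  (density 1 g/mL), an inter-system extrapolation factor (ISEF), and the
  molecular weight; Km is converted from µM to mg/L.  The driving
  concentration defaults to the unbound drug in liver-emergent plasma,
  Cu = fu_p·C_li/Kp_li — the standard well-stirred convention of the
  whole-body scaffold this model follows.  An alternative convention,
  Cu = fu_h·C_li (hepatocyte unbound fraction × total tissue
  concentration), is selectable via `drug.hepatic_driving:
  unbound_hepatocyte`.  The default was chosen because it reproduces the
  reference disposition surface (peak times of 1.32 h in venous plasma
  and 1.64 h in the heart, against the reported 1.3/1.7 h), whereas the
  hepatocyte convention makes first-pass and systemic clearance several
  times larger and pulls both peaks ~0.35 h too early.  Liver CYP
  abundances are not part of the scenario tables and ship as standard
  healthy-volunteer defaults (pmol/mg): 1A2 52, 2B6 17, 2C8 24, 2C9 73,
  2C19 14, 2D6 8, 3A4 137 — all config-overridable.
* **Renal** — a fixed clearance CL_renal applied to the blood-equivalent
  kidney concentration, CL_renal·C_ki·BP/Kp_ki.
* **Cardiac** — per-pmol intrinsic clearances for the heart-expressed
  CYPs (2C8, 2C9, 2J2) are scaled through their microsomal abundances and
  the microsomal protein content of the whole heart to an unbound
  intrinsic clearance CLu_int, then flow-corrected with the well-stirred
  form CLm_HT = Q_he·fu_b·CLu_int/(Q_he + fu_b·CLu_int), fu_b = fu_p/BP.
  CLm_HT is split equally across the three mural layers, each applied to
  the layer's blood-equivalent concentration.  The microsomal protein
  content per heart is not a measured input: the default 11,732 mg is a
  documented calibration back-solved so the scale-up reproduces the
  reference total cardiac clearance of 0.316 L/h from the per-mg value
  0.4489 µL/min/mg (0.316 / (0.4489 × 60 × 1e-6) ≈ 11,732).  Both
  CLu_int and CLm_HT are reported; "total cardiac clearance" in the
  package's reports refers to CLu_int.

Three cumulative elimination bins (hepatic, renal, cardiac) close the
mass balance: depot + Σ compartments + Σ bins = F_abs × dose at all
times, which the test suite verifies to 1e-6 relative.

## Numerical choices

* Integration: `scipy.integrate.solve_ivp` with the LSODA
  stiff/non-stiff switching method, rtol 1e-8, atol 1e-10, output on a
  regular 0.01 h grid over 0–48 h.  One reference simulation takes well
  under a second.
* T_max is reported at output-grid resolution; halving the grid step
  moves it by at most one step and changes C_max by < 0.1% (tested).
* AUC is trapezoidal on the output grid.
* Degenerate inputs: a zero dose yields the identically zero trajectory;
  a non-finite state aborts integration with the offending time; zero
  compartment volumes are rejected at construction.
* Fitting: Levenberg–Marquardt (`scipy.optimize.least_squares`,
  method="lm") on log-transformed parameters — an exact
  reparameterization of the (0, ∞) box that needs no explicit
  constraints.  Finite-difference Jacobians use a relative step of 1e-4
  on the log scale, kept well above the integrator error so the
  derivative estimates stay clean; the inner-loop simulations use the
  same tight tolerances as reporting runs.  Infeasible probes (e.g.
  Q_pf exceeding the heart blood flow) return a large finite cost so the
  optimizer retreats instead of aborting.  Standard errors come from
  SSR/(n−p)·(JᵀJ)⁻¹ at the optimum on the original scale (pseudo-inverse
  with a warning if singular); p-values from a two-sided t-test with
  n−p degrees of freedom.  Non-convergence is flagged on the result,
  not raised.
* Residuals follow res_i = (Mod_i − Obs_i)/error_i with unit weights by
  default; model values are linearly interpolated from the dense output
  grid at the observation times.  Fitting operates on concentrations
  (mg/L); observed values in ng/mL are numerically µg/L and converted by
  the provided unit helpers.

## Two-stage fitting protocol

Stage 1 fits the absorption rate k_a [1/h] and the rest-of-body
partition coefficient Kp_re to the venous-plasma series, with the
pericardial parameters held at their stage-2 starting values (Q_pf =
0.01 L/h, P = 0.40 L/h).  Stage 2 pins the stage-1 estimates and fits
Q_pf and P to the total-heart series.  The shipped reference parameter
set (k_a 0.80075, Kp_re 52.6095, Q_pf 0.01193, P 0.78230) is the default
simulation parameterization; it is not a fitting target, because the
plasma series it was originally derived from is external to this
package.

**Identifiability.**  With five heart observations, the stage-2
parameters are weakly identified: halving P changes the fitted
total-heart observable by under 5%, and a ten-fold change in Q_pf by
under 2% — below a 10% assay noise.  On noiseless synthetic data the
protocol recovers all four parameters to better than 3% (so the
estimator is consistent and bias → 0 with noise), but across 20 noisy
replicates at 10% CV the median recovery error is ~6% for k_a and ~9%
for Kp_re while Q_pf and P scatter widely, mirrored by their large
Jacobian-based standard errors and near-unity p-values.  This is a
property of the study design, documented rather than "solved".

## Synthetic data generator

No deposited observation data exist for the reference scenario, so the
generator emulates its data situation from the model itself:

* **Plasma series** — venous-plasma concentrations after the 22 mg oral
  dose (the free-base equivalent of a 25 mg salt dose), sampled densely
  over 0.5–12 h and sparsely to 48 h (14 points), with multiplicative
  lognormal noise (log-SD √log(1+CV²), default CV 10%, a typical PK
  assay error).
* **Heart series** — five points: a fixed literature anchor of
  114.35 ng/mL (0.11435 mg/L) at 3.5 h from pig heart tissue, plus two
  absorption-phase points (before the heart peak) and two
  elimination-phase points (after it) taken from the model total-heart
  trajectory rescaled to pass through the anchor.  The original four
  non-anchor values were never published, so their times (0.5, 1, 8,
  24 h) are the package's own design, recorded in each fixture's header.
  For parameter-recovery experiments the anchor pinning and rescaling
  can be disabled so the data are a pure noisy realization of the model.

All noise is drawn from seeded generators; identical specs produce
byte-identical fixture files.  The generator emulates sampling design
and assay noise only — it does not emulate inter-individual variability,
model misspecification, or assay limits of quantification, so passing
recovery tests demonstrate estimator correctness under the model's own
assumptions, not performance on real clinical data.

## Known limitations

* Single oral dose only: no IV route, multiple dosing, or enterohepatic
  recirculation; transporters and permeability limitation outside the
  pericardial exchange are not modeled.
* The exact published forms of the pericardial flux and of the cardiac
  elimination driving concentration are not recoverable from the model's
  prose description; the conventions here are explicit reconstructions
  validated against the reported disposition ratios (epicardium 2.77 vs
  2.89; midmyocardium 6.86 vs 7.13; endocardium 12.93 vs 13.41; total
  heart 10.09 vs 10.47; pericardial fluid 39.6 vs 42.65 — the last is
  the most convention-sensitive).
* The nortriptyline metabolite, pharmacodynamic coupling, and population
  variability are out of scope.
* Problem sizes used throughout the documentation and tests: 0–48 h at
  0.01 h output resolution (4801 grid points), 14-point plasma and
  5-point heart fixtures, 20-replicate recovery experiments.
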