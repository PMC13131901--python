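# Methods

## Model structure and assumptions

The simulator is a whole-body PBPK system with twelve perfused tissues
(lung, liver, kidney, gut, spleen, heart, brain, muscle, adipose, skin,
bone, rest-of-body) plus venous and arterial blood pools. The lung sits in
series with the entire cardiac output; the liver receives the hepatic
artery plus the portal venous outflow of gut and spleen. Every tissue is
divided into an extracellular (vascular + interstitial) sub-compartment,
flow-connected to arterial blood, and an intracellular sub-compartment.

Distribution is permeability-limited: the extracellular↔intracellular flux
is `fup · PS_t · (C_ec − C_ic/Kp_t)` with `PS_t = SpecPStc × V_ic,t`.
Two choices here deserve explanation:

* **Unbound-driven flux.** Passive transmembrane permeation is driven by
  the unbound aqueous concentration, so the exchange rate carries the
  plasma unbound fraction fup. This leaves the equilibrium
  intracellular:extracellular ratio (→ Kp), mass balance, dose linearity
  and the AUC(0–∞) = Dose/CL identity untouched — it only slows cellular
  uptake for highly bound compounds. For MTMSA-Trp (fup = 0.001) this is
  the dominant behaviour: over 24 h its tissues load almost exclusively
  into extracellular space, which is what produces its low liver partition
  and high plasma exposure. The total-concentration variant remains
  available (`permeability_driver="total"`), under which MTMSA-Trp would
  equilibrate intracellularly within hours and its projected plasma
  exposure would fall several-fold — inconsistent with the compound's
  binding-restricted disposition.
* **PS normalization.** SpecPStc (mL/s per mL cell volume) multiplies the
  intracellular volume of each tissue. The alternative (total tissue
  volume) is exposed via `ps_reference="total"`; the calibrated SpecPStc
  absorbs most of the difference.

Clearance is a single empirical systemic term acting on venous plasma
(`rate = CL_input × C_venous/BPR`), with `CL_input` the observed NCA
clearance in preclinical species and a projected value in humans. This is
an intentionally empirical ("middle-out") construct: the elimination
pathways of these compounds are not mechanistically resolved, so observed
clearance is injected rather than predicted. A consequence used throughout
the tests is the distribution-free identity AUC(0–∞) = Dose/CL.

Blood and plasma are related by `C_blood = BPR × C_plasma`; flow terms
carry blood-equivalent concentrations, and plasma is the reported sampling
matrix. All dosing is intravenous (bolus or zero-order infusion into venous
blood); there is no oral absorption, metabolite tracking, or saturable
elimination — the system is strictly linear.

## Partition coefficients

Kp values use the Poulin & Theil tissue-composition equation with
`P = 10^logP`, bundled neutral-lipid/phospholipid/water fractions, and the
tissue unbound fraction derived from fup through the extracellular protein
ratio `RA` (`fut = 1/(1 + RA(1−fup)/fup)`); adipose uses the method's
variant with negligible interstitial binding (fut = 1). `RA = 0.5` is used
uniformly — interstitial albumin is commonly reported near half the plasma
concentration — and is overridable per tissue in the composition data file.
Ionization is not modelled (logP, not logD; pKa values are provenance
metadata only).

## System (physiology) parameters

All physiology ships as unit-annotated YAML (one file per species), with
sources noted inline: organ-weight and regional-flow fractions from the
Brown et al. (1997) compilations, cardiac output and GFR from Davies &
Morris (1993) — mouse 0.28, rat 1.31, monkey 10.4 mL/min — and ICRP-based
fractions for the reference human, a 13-year-old 50-kg male (the
pediatric/adolescent Ewing sarcoma setting) with an absolute GFR of
100 mL/min. Any field can be overridden at load time, which is also the
supported route for replacing the human GFR. Body weights default to
0.025 / 0.25 / 5 / 50 kg.

## Drug parameters

Compound configs carry molecular weight, logP, solubility (metadata in an
IV-only model), pKa list, per-species fup and BPR maps, and the
mouse-calibrated SpecPStc. fup values below the bioanalytical
quantification limit (<1%) are entered as 0.001. The monkey BPR of
MTMSA-Trp (0.02) is a study-specific adjustment to observed monkey plasma
PK and is stored, not fitted, here; simulations fail loudly if a species
lacks an fup/BPR entry rather than substituting silently.

## Calibration, clearance scaling, evaluation

* SpecPStc is fitted by bounded scalar minimization on log10(SpecPStc) over
  [1e-6, 1] mL/s/mL, objective Σ(C_obs − C_pred)²/C_pred² (1/ŷ² weighting),
  clearance fixed at the NCA value. The log scale is required because the
  two compounds' optima differ by two orders of magnitude. Hitting a bound
  is flagged in the fit report.
* NCA uses the log-linear trapezoid (log rule on declining positive
  intervals, linear otherwise; duplicate timestamps rejected), and
  `CL_obs = Dose/AUC_obs`. Where a species has two monkey dose arms the
  higher-dose arm is used for clearance derivation.
* Method 1 floors zero %CL_add values at 0.1% inside the geometric mean
  (warning emitted) except in the all-zero limit, which returns the
  filtration-only clearance exactly. Method 2 fits absolute clearances
  (per-kg values converted via body weight), the standard convention for
  `CL = a·BW^b`; the fit is ordinary least squares on the log-log scale.
* Evaluation computes fold error, AFE (base-10, as the `10^mean(log10)`
  definition implies), log10-RMSE and the 0.5–2.0 AUC-ratio band.
  Predictions are generated directly at observed timestamps (the engine
  samples its exact solution on arbitrary grids), so time-matching is an
  exact join; zero observed concentrations are excluded with a count.

## Numerical approach

The assembled system is linear and time-invariant, so simulation uses
matrix-exponential propagation over the piecewise-constant dosing segments
rather than an adaptive stiff stepper: states are exact to machine
precision on any output grid, mass balance holds to rounding error, runs
are bit-reproducible, and there are no tolerance knobs to document beyond
the optimizer's (`xatol = 1e-4` log10 units for calibration; Brent's
method with default tolerances for target-AUC clearance solves).
Non-finite states abort with diagnostics.

One numerical caveat: after an IV bolus the venous pool (mL-scale in
rodents) mixes on a seconds timescale, so a trapezoidal AUC on a coarse
output grid (for example the 30-minute human protocol grid) overstates the
contribution of the first interval. Oracle tests therefore integrate on
log-spaced grids; reported protocol AUCs deliberately keep the protocol
grid, matching how simulated outputs are consumed in practice.

## Synthetic observed data

The raw concentration–time profiles behind the printed study summaries are
not public. The synthetic-data generator stands in for them: it simulates
each printed regimen with the compound's own parameters, solves (by
Brent's method on log10 CL) for the clearance whose noise-free log-trapezoid
AUC over the sampling window equals the printed observed AUC (to 0.5%),
then applies multiplicative log-normal noise — the standard LC-MS/MS error
model — with default CV 15% and optional LLOQ censoring. Default serial
sampling is 0.083–24 h (8 samples). What passing tests on these fixtures
show is self-consistency of the pipeline (calibration recovers generating
parameters; evaluation statistics behave correctly), not agreement with
the true unpublished raw data: only the printed AUC summaries are matched
by construction.

## Known limitations

* Liver-partition outputs are exploratory: they are conditional on the
  bundled Kp/RA constants (with RA = 0.5, the binding correction fup/fut is
  ≈0.5 for any fup) and on the blood-equivalent concentration convention in
  the extracellular space, and they are the least-identifiable outputs of
  the model — nothing in the calibration constrains them. Plasma-side
  projections are robust to this (they are pinned by the Dose/CL identity).
* Method-1 human clearance is dominated by the near-100% additional
  clearance of mouse and rat (their observed clearances are ~70-fold above
  fup×GFR), making the geometric-mean %CL_add insensitive to the monkey
  value; with open-literature GFRs it lands near 9.4 L/h for MTM. Results
  using proprietary physiology databases can differ ~2-fold.
* No population variability, ontogeny, nonlinear kinetics, unbound-exposure
  reporting, or oral absorption. The PSA is one-at-a-time and illustrative,
  run under the allometric-clearance scenario only.
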