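# Methods

## Scope and model structure

`acatpk` couples a compartmental absorption-and-transit (ACAT-style)
model of the gut lumen to one-compartment linear systemic disposition,
and adds the supporting analyses a PBPK study of an oral-vs-IV switch
needs: noncompartmental PK metrics, Caco-2 apparent-permeability
estimation, and synthetic-data generators for validation. The gut model
follows the classical published CAT/ACAT structure — a first-order
transit chain with per-compartment dissolution, precipitation and
permeability-limited absorption. It is a reconstruction of that class of
model from its public formulation, not a clone of any commercial
implementation; commercial tools layer proprietary absorption-scale
(ASF) models on top, which is why this package exposes ASF as plain
per-compartment configuration plus a one-shot calibration (below).

## Lumen model

State per compartment: solid mass, dissolved mass (mg), with constant
luminal volume; the fluid taken with a tablet (default 250 mL) augments
the stomach volume and drains with gastric transit. Processes:

- **Transit**: first-order between adjacent compartments at
  1/(mean transit time); applies to both pools. Mass exiting the
  ascending colon is excreted.
- **Dissolution** (Noyes–Whitney, mono-disperse particles):
  rate = (3D/ρr²)·m_solid·(Cs − C), floored at zero at saturation.
  Units are reconciled internally (D cm²/s, r µm, ρ g/mL, Cs mg/mL →
  mg/h).
- **Precipitation**: supersaturated excess (C − Cs)·V returns to the
  solid pool with a first-order time constant (default 900 s); the
  precipitate can redissolve downstream.
- **Absorption**: first-order in dissolved mass with
  kₐ = 2·Peff·ASF/R — the surface-to-volume relation of a cylindrical
  segment of radius R. The stomach has ASF 0; solubility is treated as
  pH-independent (a single measured Cs is used; no pKa model).

Fa is cumulative absorbed mass over administered mass at the end of the
horizon; FDp = Fa·(1 − E_gut); F = FDp·(1 − E_h). Both extraction ratios
default to 0: for the packaged study the clearance is entered as a
systemic value, so no separate first-pass loss is assigned (the
reference predictions show FDp ≈ Fa to four figures, consistent with
this choice). Hooks exist to set either ratio.

## Default parameters

Drug (gemcitabine): MW 263.2 g/mol, logP −1.32, Cs 5.01 mg/mL (pH 7.92),
precipitation time 900 s, particle density 1.2 g/mL, diffusion
coefficient 0.93e-5 cm²/s, blood/plasma ratio 1.12, Peff 0.59e-4 cm/s,
fup 0.846, Vc 1.45 L/kg, CL 120 L/h. Two values deserve comment:

- The diffusion coefficient circulates in some sources with a positive
  exponent (0.93e+5 cm²/s), which is physically impossible; 0.93e-5 is
  the standard magnitude for a small molecule in water and is used here.
- Particle radius is not part of the published parameter set; 25 µm is a
  conventional immediate-release default and is configurable. At this
  radius dissolution is fast (minutes), so predictions are insensitive
  to it except through the solubility ceiling.

Subject: 70 kg. The source predictions do not state body mass; 70 kg
makes V = 101.5 L, which reproduces the printed 0.59 h half-life
(ln2·101.5/120 = 0.586 h), and is configurable.

Physiology (fasted adult, 9 compartments): stomach 47 mL / R 9.67 cm /
0.25 h; duodenum 42/1.60/0.26; jejunum 154/1.53/0.95 and 122/1.45/0.76;
ileum 94/1.33/0.59, 71/1.21/0.43, 49/1.08/0.31; caecum 47/3.39/4.5;
ascending colon 50/2.41/13.5. Small-intestine transit sums to 3.30 h.
These are population defaults adapted from the published CAT/ACAT
literature, stored in an editable config — not constants.

## Calibration policy

Uncalibrated, the small intestine alone absorbs ~60% of a 1000 mg dose
and a fully absorbing colon would push Fa to ~92%. Since proprietary ASF
models are not public, the package fits a single colonic ASF multiplier
(small-intestine ASF fixed at 1) by root bracketing so that one
reference simulation — a single 1000 mg tablet — reproduces Fa = 68.026%
(achieved multiplier ≈ 0.103, |Fa error| < 1e-3). Every other regimen is
then a prediction. If a target exceeds the colon's full capacity, a
global multiplier is fitted instead; targets below the small-intestine
floor raise an error reporting the attainable range.

## Disposition and NCA

dA/dt = input − (CL/V)·A, Cp = A/V. IV infusions are integrated
piecewise at rtol 1e-11 and verified against the closed form
(R0/CL)(1 − e^(−kt)); oral regimens are integrated jointly with the
lumen so tablets co-mingle. Multi-dose handling restarts the solver at
each dosing time with a state jump (superposition of shifted single-dose
profiles is retained as a test oracle only).

NCA uses the linear trapezoid on the dense 0.01 h grid (exactly
additive; grid-halving changes AUC by < 0.01%), first-maximum tie-break
for Tmax, and log-linear regression over the last 2 h for λz. One
subtlety: at 24 h the colon is still delivering drug (ascending-colon
transit is 13.5 h), so for oral runs the measured tail slope reflects
that flux (~0.1/h), not elimination (1.18/h). The regimen summary
therefore extrapolates oral tails with the model constant CL/V — which
makes AUC0-inf equal the absorbed-mass identity F·Dose/CL — and uses the
measured λz only for IV, where the window is genuinely flux-free. The
extrapolated fraction is reported and stays below 1% for all packaged
regimens.

For IV runs the summary reports F = 100% exactly. (The reference
predictions print 99.929% for the IV row; a one-compartment model with
systemic clearance has no mechanism for sub-unity IV bioavailability,
so the 0.07% gap is treated as an artifact of the original tool.)

## Caco-2 permeability

Cumulative receiver amount with sampling correction
Q_n = C_n·V_r + Σ_{i<n} C_i·V_s; flux = free-intercept OLS slope over
all time points (robust to a lag phase; the choice of points is
otherwise arbitrary); Papp = flux/(C0·A) with A = 1.12 cm² (the nominal
growth area of a 12 mm insert). Replicates (n = 4) are reported as
mean ± SEM; a warning (not an error) is emitted if receiver
concentration exceeds 10% of donor. The Papp→Peff map is
log10 Peff = a + b·log10 Papp with the default a pure scale (b = 1)
anchored so 5.8e-6 cm/s → 0.59e-4 cm/s.

## Synthetic data

The transwell generator solves the exact two-chamber diffusion system
(matrix exponential between sampling events, exact bookkeeping of each
0.6 mL withdrawal/replacement), then applies multiplicative Gaussian
noise (CV configurable) to measured concentrations only; the latent
state conserves mass to machine precision. Protocol defaults: 60 µM
donor, 0.4/1.2 mL chambers, samples at 0–120 min every 30 min, n = 4.

Because the generator is exact while the estimator assumes a constant
donor concentration, the estimator's sink-condition bias is measurable:
at Papp 5.8e-6 cm/s the donor depletes by ~11% over 2 h and the
estimate is biased −6.6% (deterministic). With 5% CV noise the median
absolute relative error over 200 seeds is ~6.5%. The generator emulates
passive transcellular transport only — no efflux, paracellular leak,
monolayer variability or drift — so recovery results bound estimator
behaviour under the stated noise model, not under all real-assay
pathologies.

Virtual drugs draw Peff, solubility, CL and Vc log-uniformly from wide
ranges (other fields keep reference values), for property tests such as
"highly soluble doses behave like solutions".

## Numerical choices

LSODA with rtol 1e-8, atol 1e-10 mg, dense output on a 0.01 h grid;
lumen mass balance is checked at every output time and an error is
raised if drift exceeds 0.1% of the administered dose (observed drift is
orders of magnitude smaller). Transit-limit simulations agree with the
closed form Fa = 1 − (1 + kaT/n)^(−n) to better than 0.5% across
n ∈ {1,3,7}, kaT ∈ {0.1,1,10}. Each 24 h regimen simulation takes well
under a second on one CPU; the full six-regimen study including
calibration runs in ~2 s.

## Known limitations

- Dissolution makes tablet kinetics weakly nonlinear (driving force
  Cs − C): dose-doubling and dose-superposition hold only to ~0.5–1% of
  Cmax for tablets (exactly for solutions and IV). A related effect:
  later-dose peaks sit 2–3% above the first-dose peak because colonic
  absorption of earlier doses is still in progress — ongoing input, not
  plasma accumulation (the accumulation index at τ = 8 h is 1.00008).
- Constant luminal volumes (except gastric fluid) mean a large dose can
  transiently supersaturate the small duodenal volume and cycle through
  precipitation/redissolution; adequate at this solubility margin but
  crude for poorly soluble compounds.
- No enterocyte metabolism, transporter kinetics (relevant to nucleoside
  analogs), bile-salt solubilization, fed state, or controlled-release
  formulations; single fasted physiology; no population variability.
- One-compartment disposition only — no peripheral or liver compartment,
  so tissue concentrations are out of scope.
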