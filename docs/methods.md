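# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would want to know.

## Hydrodynamics of the stenotic channel

The assay channel is rectangular (width w = 200 µm, inlet height H = 50 µm)
with a smooth hump occluding a fraction φ of the height; the default is
φ = 0.8, leaving a 10-µm apex gap. The hump profile is a raised cosine of
axial extent 400 µm (a Gaussian profile is selectable); the profile shape
only affects the shoulders of the shear field — the apex value, which drives
the headline stress, depends only on the apex gap.

Flow is treated as locally fully developed (lubrication): at each axial
station the wall shear rate is the rectangular-section result

γ(x) = 6Q / (w·h(x)²) · 1/(1 − 0.63·h(x)/w),

and τ = µγ. Against the exact Fourier-series duct solution this is within
0.4% at aspect ratio w/h = 4 and better at higher aspect; at the apex the
local aspect ratio is 20. Lubrication neglects axial acceleration around the
hump; the inlet Reynolds number at the default perfusion (18 µL/min,
ρ = 1060 kg/m³) is ≈2.5, so inertial corrections are small and the
estimate agrees with full CFD of this geometry at the ~10% level. Defaults:
viscosity 1.0 mPa·s (Newtonian, plasma-like; configurable), density
1060 kg/m³ (whole blood; used only for Re). Stresses are reported in
dyn/cm² (1 Pa = 10 dyn/cm²) per vascular-biology convention.

`circular_equivalent` reports the same-cross-sectional-area Poiseuille tube
(r = √(wh/π), γ = 4Q/πr³). It deliberately does **not** attempt a circular
*stenosis*: that would require a specific unshown geometry.

Out of scope: 3-D Navier–Stokes, non-Newtonian rheology, cell margination,
thrombus-perturbed flow.

## Profile quantitation

Onset of thrombus formation is the first time the platelet signal exceeds
the pre-perfusion baseline mean + 3 s.d. for 3 consecutive frames (the
baseline is the first 5 frames by default). The onset rule is this package's
own operational definition — the readout time point (onset + 450 s) is
standard, the onset criterion itself is not.

The readout is a 3-frame local average centred on onset + 450 s, for
robustness to single-frame noise. Size is the platelet intensity; each other
dimension is biomarker intensity ÷ size, with the ~391-nm channel first
corrected by `max(raw − c·platelet, 0)` for the platelet autofluorescence
leak (coefficient c is configuration; the Fg channel is the ~391-nm channel
by default). The PS (Annexin V) channel is normalised identically to the
antibody channels.

Because an enrichment is a ratio of noisy channels it carries a second-order
Jensen bias of order cv² (≈0.3–0.5% relative at the default 5% frame
noise). It is unbiased to first order; tests assert the absence of material
bias (<1%) rather than exact unbiasedness.

Growth curves are fit with a three-parameter logistic
A/(1 + exp(−(t − t_half)/τ_g)) with zero baseline; the plateau-approach time
(95% of plateau) is t_half + 2.944·τ_g. Constant traces and non-convergent
fits raise explicit errors.

## Dose–response

Residue size follows R + (100 − R)/(1 + (C/IC50)^h) with bounds
0 ≤ R ≤ 100, IC50 > 0, h > 0. This is the descending Hill form; the textbook
(IC50/C)^HillSlope parameterisation is equivalent with a negative slope, and
h here is the slope magnitude. IC50 is fit on the log scale with a 7-point
log-spaced multistart spanning the observed concentrations ± one decade.
Monotonically non-decreasing data raise `NoInhibitionError` instead of
returning a meaningless fit. Biphasic dose dependencies (e.g.
negatively-charged-nanoparticle inhibition) are not Hill-shaped;
`half_effect_concentration` interpolates the descending branch to the
~50%-reduction concentration instead.

## Barcodes

Effect barcodes test each of the 7 dimensions two-sided — paired t-test for
within-subject drug designs, Welch's t-test for cohort comparisons — and
assign trit = sign(mean difference) when the adjusted p < α (default 0.05).
Multiplicity across the 7 dimensions uses Holm–Šidák by default ("none" is
selectable); cohort comparisons use Welch rather than an omnibus
ANOVA-plus-Tukey because the barcode is defined per dimension and the
directional conclusions coincide at these sample sizes (an ANOVA wrapper is
exposed separately in `stats`).

The addition rule is elementwise sign saturation, sign(a + b): −1 + −1 → −1
(required by the VWF-inhibition identity) and +1 + −1 → 0. The operation is
commutative but **not** associative once clamping occurs
((+ + −) groupings differ); tests document this with a counterexample.

Reference ranges are per-dimension Gaussian fits (sample mean ± 2 s.d.,
95.45% coverage) on healthy-young profiles, on the raw scale by default
(values are positive and moderately skewed; a log-scale fit is a one-line
transform by the caller). Personal-barcode classification is closed on
"normal": values exactly at a bound classify 0. The census reports distinct
canonical strings and per-dimension low/normal/high fractions.

## Cohort statistics

`correlate` cross-checks association three ways: OLS slope with its
two-sided t-test, Spearman's ρ, and Kendall's τ-b (tie-corrected). The best
separating threshold maximises Youden's J = sensitivity + specificity − 100
over midpoints between sorted unique pooled values, trying both
classification directions; ties break toward higher specificity. J is
rank-based, hence invariant under monotone transforms.
`classification_consistency` is the percentage of subjects classified
identically (above/below threshold) by two markers. `group_compare` wraps
one-way ANOVA + Tukey HSD and two-way fixed-effects OLS ANOVA with
interaction; the two-way model assumes variance homogeneity — under marked
heteroskedasticity prefer the per-dimension Welch route that the barcode
derivation uses.

Published sensitivity/specificity/consistency percentages for real cohorts
are descriptors of protected clinical data; the operations that produce such
numbers are validated here by construction on synthetic data instead.

## Single-molecule kinetics

Adhesion frequency P_a is successes/cycles over (default) 30 touch cycles
with binomial standard error. The Poisson bond-number model underlies both
the avidity/affinity inversion (λ = −ln(1 − P_a) = m_r·m_l·A_c·K_a) and the
single-bond probability P(N = 1 | N ≥ 1) = λe^{−λ}/(1 − e^{−λ}), which is
89.3% at the P_a = 0.2 working point — the quantitative basis for running
force-clamp assays at ~20% adhesion. P_a = 1 raises explicitly (infinite
affinity).

Lifetimes are binned over clamping force (default 10-pN bins from 0;
configurable — published bin edges are not stated); bins with ≥50 events are
flagged reportable. Phenotype classification uses the sign pattern of
successive bin-to-bin changes exceeding a noise margin (default 1 pooled
s.e.m.): monotone down = slip, interior peak = catch-slip (peak force and
lifetime reported), down-up-down = triphasic slip-catch-slip, none = flat.

Fura-2 traces are normalised as (i340/i380) ÷ mean of the first 10 frames;
ΔI_max is the peak increase above 1 over the post-baseline window, with no
smoothing before the peak (the raw maximum).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
the study's scale:

- **Cohorts**: healthy young n = 33, healthy older n = 14, hypertensive
  young n = 9, hypertensive older n = 13 (69 subjects). True profiles are
  baseline × cohort multipliers × unit-mean log-normal subject noise
  (CV 0.25 for size, 0.20 for enrichments; log-normal keeps intensities
  positive). Baseline: size 1000 AFU, enrichments (0.5, 0.3, 0.4, 0.2, 0.3,
  0.2) — plausible mid-scale values; absolute scale cancels in all
  normalised statistics.
- **Effect sizes**: hypertension and aging each multiply
  [size, Fg, E⁺, Act] by (1.8, 1.3, 1.6, 1.5) and act multiplicatively when
  combined. Published evidence fixes directions and significance, not
  magnitudes; these values are chosen so that at the study's n the derived
  effect barcode is `+ + 0 0 0 + +` with ~95% probability — i.e. the
  generator encodes the reported qualitative conclusion, and the recovery
  tests measure the pipeline's power to re-derive it.
- **Time courses**: platelet channel logistic after a 30-s perfusion onset
  delay; healthy (t_half, τ_g) = (200, 68) s and hypertensive (250, 85) s
  put the 95%-plateau times at ≈400 s and ≈500 s. Biomarker channels are
  enrichment × platelet × log-normal frame noise (CV 5%); the Fg channel
  also receives a 10% platelet autofluorescence leak; a small additive
  camera noise floor (0.5 AFU) makes baseline onset detection meaningful.
- **Kinetics**: two-pathway dissociation rate
  k(F) = k_c0·e^{−F/f_c} + k_s0·e^{F/f_s}; lifetimes are exponential at
  1/k(F). Healthy integrin parameters put the analytic catch-slip peak at
  15 pN / 5 s, hypertensive at 35 pN / 10 s (rate constants are calibrated
  to those peaks, not measured). A *triphasic* lifetime curve cannot arise
  from any positive sum of exponential pathways (k is strictly convex, so
  1/k has a single interior peak); the generator therefore covers slip /
  catch-slip / flat, and the triphasic classifier branch is exercised on
  directly constructed curves.
- **Calcium**: pulse amplitude proportional to mean bond lifetime at the
  clamping force (0.05 per second of lifetime), encoding the observation
  that the Ca²⁺ response mirrors the lifetime's force dependence.
- **MFIs**: only the E⁺ integrin level is elevated (2×) in hypertensive
  cohorts; total integrin, Act and P-selectin MFIs share one healthy scale.

Everything is deterministic under (design, seed); per-stage streams in the
pipeline are spawned from one `SeedSequence`.

**What the generator does not emulate** — and hence what passing tests do
not show about real blood: inter-channel optical crosstalk beyond the single
autofluorescence coefficient, heavy-tailed or bimodal subject distributions,
age as a continuous covariate (it is drawn but has no effect beyond the
cohort label), within-subject repeat-visit variability, hematocrit/platelet
count covariates, pharmacokinetics, and any image-level artefact. Recovery
rates measured here are power calculations under the stated model, not
clinical performance estimates.

## Problem sizes

Stochastic tests use 100-seed recovery runs (barcodes, IC50), 1000-seed
type-I-error runs, and 10⁴-series Monte-Carlo checks; the acceptance script
uses 2×10⁵ Gaussian draws for the coverage estimate and a 201-sample axial
grid for the shear field. These sizes put Monte-Carlo error well below each
test's tolerance while keeping the full suite fast.

## Known limitations

- Lubrication is a thin-gap approximation: the ±10% band against CFD is the
  accuracy contract at the apex; shoulder values are less constrained.
- The Hill fit reports a Gauss–Newton covariance on the internal
  (log-IC50) parameterisation; it is indicative, not a full profile
  likelihood.
- Barcode derivation treats dimensions independently; correlated dimensions
  (size with E⁺) make the 7 tests non-independent, which Holm–Šidák handles
  conservatively.
- `best_threshold` reports one operating point, not a full ROC curve.
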