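# Methods

## The remodeling model

Atherosclerotic coronary arteries change caliber as plaque accumulates:
expansive (Glagov) remodeling enlarges the external elastic membrane (EEM)
to preserve the lumen, while constrictive remodeling shrinks it. The ideal
comparator for quantifying that response is the same cross-section *before*
disease — unobservable in practice. The package's central quantity, the
fractional vessel remodeling index,

FVRI = EEM_actual / (EEM_predicted + P),

compares the measured vessel area against the size the vessel would have if
its inferred pre-disease area, EEM_predicted, had grown by exactly the
plaque + media area P. FVRI = 1 therefore means complete compensation; the
departure from 1 is a continuous measure of over- or under-compensation.

The FVRI algebra was published as a figure rather than a formula; the ratio
above is the only form consistent with the published constraints (an index
of exactly 1 at complete compensation, a strictly positive frame-level
distribution, and "negative" remodeling nesting inside FVRI < 0.83). An
algebraically different variant with the same fixed point,
`(EEM_actual − P) / EEM_predicted`, satisfies the same constraints and is
selectable (`formula_variant="lumen_ratio"`); the two agree exactly at 1 and
always agree on the sign of FVRI − 1, but the default compensation-ratio
form is bounded by 1/(1 + burden) for shrunken vessels, which is what ties
the 0.83 band edge (≈ 1/1.2) to the 20% burden cutoff.

### Classification

Frames with plaque burden < 20% are labelled `trivial_plaque` and not
classified (their index, when plaque is present, is still computed for
burden-profile summaries). For established plaque the four patterns are:

| pattern | rule |
|---|---|
| ectatic | FVRI > 1.17 |
| complete_compensatory | 0.83 ≤ FVRI ≤ 1.17 (inclusive) |
| incomplete_compensatory | FVRI < 0.83 and EEM_actual ≥ EEM_predicted |
| negative | FVRI < 0.83 and EEM_actual < EEM_predicted |

The band is one standard deviation of the published lesion-level FVRI
distribution (0.77 ± 0.17) around 1 and can be re-derived from any SD with
`derive_band_from_sd`. A boundary subtlety: the exact algebraic bound for a
shrunken vessel is FVRI < 1/(1 + burden/100) ≤ 1/1.2 = 0.8333, so frames
with burden just above 20% and EEM within a fraction of a percent of its
prediction can land in (0.83, 0.8333) and classify as complete rather than
negative; the published 0.83 is 1/1.2 rounded to two decimals and is used
verbatim.

### The normal-dimension model

EEM_predicted is a linear function of four deliberately simple covariates:
a binary dominance indicator (right = 0, left/balanced = 1), an ordinal
vessel code (LM 0, LAD 1, LCx 2, RCA 3), the natural logarithm of the
distance from the coronary ostium in mm (clamped at 1 mm so ostial frames
contribute a zero log term), and body surface area in m² (Mosteller by
default, Du Bois selectable; the source publication does not state its BSA
formula). The packaged `falcao2015-default` equation (intercept 12.20;
dominance −1.14; vessel −1.73; log-distance −1.28; BSA +2.60; adjusted
R² 0.46) ships with its published 95% confidence intervals. The covariate
*encodings* behind the published coefficients are unrecoverable from the
publication, so the codings above are package conventions: scoring is
internally consistent, but per-frame numeric agreement with the original
authors' predictions cannot be asserted.

Refitting uses frames assumed to retain normal lumen dimensions — plaque
burden < 20%, with the response (lumen area) restricted to 3.1–19.6 mm²
(vessel diameter 2.0–5.0 mm) — and a bootstrap: the final coefficients are
the means over resampled OLS replicates, CIs the 2.5/97.5 percentiles, and
the adjusted R² comes from the point fit on the full training set. The
default resampling unit is the patient, which is the conservative choice
for real pullbacks whose residuals are correlated within a patient;
frame-level resampling is available and is the matched choice when
residuals are frame-independent (as in the simulator — see below). A
caveat inherited from the method itself: restricting the *observed* lumen
to a window is selection on the response, which slightly attenuates the
vessel and distance coefficients for cohorts with many frames near the
window edges. The package keeps the operational filter as published; the
parameter-recovery experiment in the test suite instead windows on the
noise-free expected caliber (selection on covariates only) so that it
measures the estimator rather than this known selection artifact.

### Lesions and the classical comparator

A lesion is a maximal run of ≥ 3 consecutive frames with plaque burden
> 40%. Its representative cross-section is the minimal-lumen-area (MLA)
frame, ties broken proximally. The lesion's FVRI and FVRI class are those
of the MLA frame. The classical remodeling index divides the MLA-frame EEM
by the mean EEM of the two immediately adjacent out-of-run frames (burden
≤ 40% by maximality; no distance-window search is performed since adjacency
is the published rule); lesions touching a pullback boundary lack a
reference and are excluded from the classical analysis. Classical classes:
negative < 0.88, intermediate 0.88–1.00 (inclusive), positive > 1.00.
Lesions separated by a single sub-threshold frame are *not* merged.

Scheme agreement is summarized on the 4×3 cross-tabulation. Concordant
cells are negative/negative, incomplete/intermediate, complete/positive,
plus ectatic/positive (both denote expansion); the three named pairs alone
are also reported, since the published 38.1% concordance is the sum of the
printed one-decimal percentages of the named cells. Cohen's kappa — an
added diagnostic, not part of the published analysis — is computed on the
3×3 collapse with ectatic merged into complete. Composition differences
across classes use classic one-way ANOVA per virtual-histology tissue
percentage (fibrous, fibrolipidic, necrotic core, dense calcium, expressed
over the four-component sum); classes with fewer than two lesions are
excluded from the F-test.

## The synthetic cohort generator

No public IVUS pullback dataset accompanies the method, so the simulator is
a first-class package component. It emulates a catheterization cohort
(weight 72.0 ± 11.6 kg, height 161.6 ± 7.9 cm, 15% left/balanced dominance)
imaged with three-vessel IVUS plus the left main: LAD/LCx/RCA segments of
40–80 mm and a short LM, at 0.3 mm frame spacing (the acquisition protocol
fixes pullback speed, not frame spacing; 0.3 mm reproduces the published
per-patient frame volume).

Per frame, the true pre-disease EEM area is the packaged linear equation
plus biological scatter with standard deviation proportional to the
predictor (constant CV). The proportional form keeps areas positive, makes
large vessels vary more, and keeps the clinically motivated caliber window
from truncating small distal vessels' response distribution. The default
CV of 0.23 is calibrated by bisection (`calibrate_noise`) so that refitting
the model on the simulated near-normal frames reproduces an adjusted R² of
about 0.46.

Disease has two components: a diffuse background burden per artery (base ~
N(30, 8)% clipped to [0, 50], with a slow ±5% sinusoidal variation along
the vessel) and focal raised-cosine lesions (Poisson 2.4 per artery, width
3–12 mm, peak burden 50–80%, non-overlapping with 2 mm gaps). The diffuse
component is what reproduces the published cohort texture in which only
~11% of frames are near-normal; focal bumps alone cannot. A consequence is
that a zero lesion *rate* does not give a plaque-free artery — the
background must also be disabled.

Each lesion (and each artery background) draws a remodeling response θ from
a four-component Gaussian mixture spanning the patterns (defaults: means
−0.8, 0.35, 1.0, 1.6 with weights 0.22, 0.41, 0.35, 0.02, chosen to mirror
the published lesion-class mix). θ = 1 is perfect compensation (EEM grows
by exactly the plaque area), θ > 1 ectatic overshoot, θ < 0 shrinkage.
Because lumen is preserved in early disease, the *effective* per-frame
response ramps linearly from θ_eff = 1 at burden ≤ 20% to θ_eff = θ at
burden ≥ 40%. This embeds the method's own founding assumption — low-burden
frames genuinely exhibit their normal lumen — and makes the mean index
decline with plaque burden by construction, from ≈ 1 below 20% burden
downward, matching the published burden profile qualitatively. Plaque area
follows from the burden target b and θ_eff as p = b·N/(1 − b·θ_eff), with
the denominator floored at 0.15 so strongly ectatic lesions cannot demand
impossible burdens. Observed EEM adds θ_eff·p and Gaussian measurement
noise (default SD 0.25 mm², applied independently to EEM and plaque);
frames violating positivity have their noise redrawn (counted and logged).
VH composition is drawn from softmax logits shifted along θ (expansive
plaques richer in fibrolipidic/necrotic tissue, shrinking plaques more
calcified) — a deliberately simple effect model used only to give the
composition ANOVA a known signal.

Ground truth records, per frame, the noise-free expected caliber, the true
normal EEM, plaque area, θ, θ_eff, burden, FVRI = (N + θ_eff·p)/(N + p) and
class; per lesion, the spans/θ/class derived from the noise-free profiles
with the same run rule the pipeline uses. The same seed yields byte-identical
output files.

### What the simulator does and does not emulate

It reproduces the covariate structure, the tapering caliber, the diffuse +
focal disease texture, the low-burden frame fraction, a realistic lesion
count, and a controllable compensation spectrum — enough to give every
pipeline stage a known answer. It does **not** emulate spatially correlated
biological scatter (frame scatter is independent given the artery), catheter
or gating artefacts, bifurcation effects, or longitudinal progression. Two
consequences matter when reading test results. First, because the scatter
is iid per frame, selecting the minimal-lumen frame inside a lesion
preferentially picks negative scatter extremes, so simulated lesion-level
class mixes skew more "negative" than the published cohort's; real caliber
deviations vary smoothly along an artery and dilute this regression-to-the-
minimum. Second, passing the classification-fidelity experiments on
idealized cohorts (biological scatter off, measurement noise on) shows the
*pipeline machinery* is exact; on realistic cohorts the method's accuracy is
intrinsically bounded by the prediction model's R² ≈ 0.46, which is a
property of the method, not of this implementation.

## Numerical conventions and experiment sizes

- CSV artifacts serialize floats at 6 decimals; determinism tests compare
  bytes after one write→read round trip.
- OLS point fits use statsmodels; bootstrap replicates use the equivalent
  lstsq fast path (asserted equal to 1e-12 in tests). Rank-deficient
  designs raise, naming the collinear columns; rank-deficient bootstrap
  replicates are redrawn, and more than 10% redraws aborts.
- Percentile CIs are clipped to contain the coefficient mean so the model
  invariant ci_low ≤ coefficient ≤ ci_high holds even in degenerate
  single-replicate bootstraps.
- Out-of-window EEM predictions warn but are never clamped.
- MLA ties break to the most proximal frame; lesion length is the distance
  difference between the first and last in-run frames.
- The parameter-recovery experiment uses 100 independent 67-patient cohorts
  with 500-replicate frame-resampled bootstraps; cohorts whose near-normal
  frames carry a constant covariate (e.g. no left-dominant patient) are not
  estimable and are replaced deterministically from the seed stream. The
  classification-fidelity experiment uses 20-patient idealized cohorts
  (≥ 100 lesions); the composition power check uses 100 cohorts of 12
  patients. These sizes keep the full suite at a few minutes on one CPU
  while leaving the binomial margins of the pass thresholds comfortable.

## Known limitations

- The covariate encodings behind the packaged coefficients are conventions;
  absolute predicted values for real patients should be validated locally.
- The operational training-frame filter selects on the observed lumen and
  therefore carries a small truncation bias toward zero for the vessel and
  distance coefficients; refitted equations inherit it exactly as the
  published equation does.
- No per-frame uncertainty propagation from the model CIs into FVRI.
- Vessels other than LM/LAD/LCx/RCA (e.g. ramus intermedius) carry no
  vessel code and are dropped with a warning on read.
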