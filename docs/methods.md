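# Methods

This note documents the models, defaults and design choices behind
`hepamark`, and what the synthetic tests do and do not establish about
real ¹H-NMR data.

## Study design emulated by the generator

The pipeline targets the duck *foie gras* setting: male mule ducks
overfed on a corn diet, slaughtered on overfeeding days 6, 8, 10 and 12
(16 animals per day, n = 64), with liver weight (LW) spanning 302.3 to
914.9 g, technological yield (TY) 54.8 to 99.5 %, and a phenotypic
correlation corr(LW, TY) near −0.80 (the published account also quotes
−0.82 in a later section; the generator default is −0.80).

`generate_phenotypes` draws LW per day from normal distributions whose
means climb linearly through the LW range (fractions 0.19–0.68 of the
span, sd = 0.155 × span), clipped to the printed bounds. TY is generated
conditionally on LW — a single Gaussian-copula-style affine link
TY = a + b·LW + ε — with b and sd(ε) calibrated against the *drawn* LW
standard deviation so the expected sample correlation equals the target;
TY is then clipped to its range. The target sd of TY is span/5, so
clipping affects roughly 1 % of samples and the calibration error stays
within the ±0.05 tolerance the test suite asserts over 50 replicate
studies. Body weight is decorative and carries no signal. If clipping
ever pushes the achieved correlation more than 0.2 from the target (at
n ≥ 30), the generator raises a calibration error rather than returning
a silently miscalibrated table.

Concentrations follow
`c = baseline · (1 + sign · magnitude · z(trait)) · exp(ε)`,
with z the standardized trait, ε ~ N(0, cv_noise), truncated at zero.
Defaults: baseline 1.0 (arbitrary units), magnitude 0.4, cv_noise 0.1,
which yields metabolite–trait correlations around 0.9–0.96 — the scale
of the correlations reported for real fatty-liver biomarkers (0.6–0.98).
The default planted set mirrors the published correlation signs for
liver weight: lactate (+), glucose (−), taurine (−), alanine (−),
allantoin (−). Metabolites without a planted effect get pure
multiplicative noise around baseline; the seven decoy library entries
(valine, uracil, inosine, tyrosine, histidine, phenylalanine, formate —
real metabolites placed in shift regions otherwise empty in this study)
receive zero concentration and serve as negative controls.

## Spectrum model

Spectra are rendered in the frequency domain only (no FID, phasing or
baseline artifacts) on a 0–10.5 ppm grid with 0.001 ppm spacing. Each
fingerprint peak becomes a cluster of Lorentzian lines of half-width
0.002 ppm — the natural NMR line shape — whose total area equals
concentration × proton count. Doublets/triplets/quartets split at a
7 Hz coupling on the 600 MHz scale (0.0117 ppm) with binomial height
ratios 1:1, 1:2:1, 1:3:3:1; a "multiplet" renders as five equal lines
spanning its printed shift range. This reproduces realistic bucket-level
overlap without a full spin-system simulation. Each line is evaluated
within ±0.5 ppm of its center; the truncated tail holds ≈ 0.25 % of the
line area, well inside the 1 % accuracy the area tests assert.

Per-sample imperfections: a metabolite-level chemical-shift jitter
N(0, 0.002 ppm) applied uniformly to all of a metabolite's peaks
(sub-bucket calibration error), and additive Gaussian noise with
sd = 0.5 intensity units per grid point (peak heights for unit
concentration and one proton are ≈ 160, so planted signals sit far above
the floor, as concentrated liver metabolites do). All randomness flows
from one master seed through CRC32-keyed child streams, so any subset of
samples, metabolites or permutations is reproducible in isolation;
mixtures are exactly additive at zero noise because each metabolite owns
its jitter stream.

What the generator does **not** emulate: pH- and matrix-dependent shift
drift beyond one bucket, peak-shape distortions, baseline roll,
relaxation-weighted intensities, and a realistic crowd of hundreds of
co-occurring metabolites. Passing recovery tests therefore demonstrate
correctness of the statistical machinery under the stated assumptions,
not field performance on real spectra — in particular real shift drift
larger than a bucket would degrade both annotation and unmixing.

## Preprocessing

Buckets are half-open 0.01 ppm intervals [lo, lo + 0.01) from 0.5 to
10 ppm, integrated by the trapezoid rule. Buckets intersecting a solvent
window (water 4.5–5.1 ppm, methanol 3.2–3.35 ppm) are dropped entirely
— the conservative choice for partial overlaps at window edges. This
yields 875 retained buckets with the default windows; the bucket count
is configuration-dependent and deliberately not asserted anywhere.
Normalization divides each row by its own total over *retained* buckets,
so removed solvent signal cannot dominate the denominator; rows then sum
to one, which makes the data compositional (see Limitations). Pareto
scaling centers each column and divides by the square root of its sample
standard deviation (ddof = 1); zero-variance columns map to zeros and
are flagged.

## Chemometrics

All models use exactly one latent variable, matching the analysis the
pipeline re-implements. For one component NIPALS is closed-form:
w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt; R²X and R²Y are
the explained fractions of ‖X‖² and ‖y_c‖²; VIPⱼ = √p·|wⱼ| so that
mean VIP² = 1. Conventions that the source analysis never spells out and
that we therefore fix explicitly:

* **Cross-validation.** Samples are assigned to 7 folds round-robin
  after a seeded shuffle (the proprietary "venetian blinds" grouping of
  SIMCA-style software differs). Pareto scaling is refit inside each
  training fold. Q² = 1 − PRESS/SS with the test response centered on
  its training-fold mean (the SIMCA convention; a global-SS variant is
  exposed as configuration). RMSECv = √(PRESS/n).
* **RMSEE** uses n − 1 − A degrees of freedom with A = 1.
* **Permutation validation** permutes the response values (a
  permutation of values and of ranks coincide as multisets), refits the
  model and its cross-validated Q² for each of 500 permutations with the
  X block untouched, and reports the intercepts of least-squares lines
  through the (correlation, R²Y) and (correlation, Q²) point clouds,
  the original model included at correlation 1. A constant response is
  flagged degenerate rather than fitted.
* **PCA outlier screen**: Hotelling T² on the first two PCA scores
  against the (1 − α) F-ellipse, advisory only (samples are reported,
  never dropped automatically).

## Bucket method

Bucket-wise simple regressions are computed vectorized from the Pearson
correlation (t = r·√((n−2)/(1−r²)), two-sided p with n − 2 df); the
trait is regressed on the bucket, the orientation used in the published
tables (the p-value is symmetric in the orientation). One BH family
spans all retained buckets per trait; a second, separate family spans
the candidate metabolites' RCs ("BH p-value 2"). A bucket supports a
fingerprint peak when its interval, expanded by shift_tol = 0.005 ppm
(half a bucket, absorbing calibration jitter), intersects the peak's
shift range; a bucket may support several metabolites and no
unique-assignment heuristic is applied — crowded carbohydrate regions
genuinely share buckets. RC sums use *all* retained buckets of each
peak, not only the VIP-selected ones (the formula's "sum of the bucket
intensity of the peak"); peaks falling wholly inside solvent windows are
skipped, and a metabolite with no usable peak is refused with a
diagnostic rather than silently quantified.

The packaged fingerprint library transcribes the published peak tables
(21 metabolites; shift ranges and multiplicities as printed, with
obvious typographical artifacts normalized — reversed shift ranges,
"3.22.25" → 3.22–3.25 — and per-peak proton counts filled from standard
reference spectra, as the source tables do not print them). Proton
counts are a packaged data asset, not study ground truth; RC arithmetic
is therefore tested against a small synthetic library with known counts.

## Metabolite method

Templates are noiseless, jitter-free renders of each library metabolite,
bucketed identically to the samples and L1-normalized; a metabolite
whose retained signal falls below 5 % of its analytic area (peaks inside
solvent windows) is dropped with a warning. Unmixing solves
argmin_{c ≥ 0} ‖b − Tc‖² per sample (non-negative least squares);
coefficients below 10⁻⁶ of the row's total intensity are exactly zero
and count as "absent" for the presence filter (the published analysis
never defines presence numerically). The filter keeps metabolites
present in ≥ 50 % of samples of at least one day. Qualification then
mirrors the published rule: Pareto scaling, one-component PLS1, VIP > 1
*and* BH p < 0.05 jointly required.

This unmixing is a deliberately simple fingerprint-deconvolution
stand-in for full reference-library deconvolution tools: there is no
per-metabolite local realignment, so performance degrades when shift
jitter approaches one bucket width, and strongly overlapping
single-peak metabolites can trade intensity. In the default synthetic
study this shows up as allantoin (one singlet at 5.38 ppm, flanked by
glycogen at 5.39 and maltose at 5.40) keeping a highly significant
regression but a VIP just below 1 — the metabolite route then recovers
4 of the 5 planted biomarkers while the bucket route recovers all 5.

## Integration

Venn comparisons canonicalize names (case, whitespace, packaged synonym
table for variants like "guanidino acetic acid") before exact set
partition. Networks connect biomarker RC vectors (computed from bucket
data for every biomarker, whichever method found it) and the trait node
with Pearson edges kept at |r| ≥ 0.4 — the threshold is set so that the
weakest published network edge (0.46) would survive — with signed
weights; this simplifies the original PLS-similarity network to direct
correlations, which is how the published edges are interpreted
numerically. `run_pipeline` chains every stage, writes all tables plus
`summary.json`, and is byte-identical under a fixed config and seed.

## Statistical behavior under the null, and a caveat

With all planted effects zeroed, bucket candidates require a bucket to
clear both VIP > 1 and a BH-corrected p < 0.05 across 875 buckets; this
happens in ≈ 2 % of trait analyses, so the unconditional expected number
of false biomarkers per trait is ≈ 0.015 per study. However, the
two-stage design means that *conditional* on a null bucket surviving
stage one, the RC-level test of stage two usually confirms it (the two
statistics share the same buckets). The RC-level BH family is therefore
validated separately on fixed pure-noise candidate sets, where it
controls false biomarkers at ≈ 1–2 % of candidates (nominal 10 %
ceiling); the selection-biased conditional rate of the full cascade is a
property of the published procedure itself, not of this implementation.

## Problem sizes used in the test suite

Unit and property tests run on small matrices (up to 64 × 875). The
recovery experiment uses 20 replicate studies at the full n = 64 design
with 500-permutation validation on three of them; the null calibration
uses 100 zero-effect replicates (the metabolite route on 25 of them) and
a 200-permutation null placement check. These sizes were chosen to make
the stochastic assertions stable across reruns at fixed seeds.

## Known limitations

* Normalized buckets are compositional: a genuine increase in one
  abundant metabolite depresses every other normalized value, inducing
  trait correlations in unrelated regions. The synthetic recovery tests
  count only designated decoys as false positives for exactly this
  reason — non-planted but *present* metabolites can legitimately pick
  up compositional signal, as real studies' long biomarker lists show.
* One latent variable throughout; responses driven by two orthogonal
  spectral directions are out of scope by design.
* Published R²/Q²/VIP/correlation magnitudes from the original duck
  data are tied to spectra that are not deposited and are not
  reproduced here; only the rule arithmetic on the printed statistics
  and the qualitative validation patterns are.
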