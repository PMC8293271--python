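# hepamark

Hepatic biomarker discovery from ¹H-NMR spectra of fatty duck livers.

*Foie gras* production hinges on two quality traits measured after
slaughter: the liver weight (LW, g) and the technological yield at
cooking (TY, % — 100 minus the fat loss). The two are strongly
negatively correlated above ~600 g, and producers would like to predict
them from the crude liver. `hepamark` implements, as a reusable and
tested pipeline, a two-track ¹H-NMR metabolomics workflow that turns
frequency-domain liver spectra into lists of metabolite biomarkers of LW
and TY:

* **Bucket method.** Spectra are integrated into 0.01 ppm buckets from
  0.5 to 10 ppm (solvent windows 4.5–5.1 and 3.2–3.35 ppm excluded),
  each row normalized by its whole-spectrum integral, and Pareto-scaled.
  A one-component PLS1 model (NIPALS; the weight vector is the
  normalized covariance direction **w** ∝ Xᵀy) explains the trait;
  buckets with VIP > 1 that are also significant after a
  Benjamini–Hochberg (BH) correction of bucket-wise regression p-values
  are matched to a packaged metabolite fingerprint library. Candidate
  metabolites are then quantified by their relative concentration,
  RCⱼ = meanᵢ(peak-intensity sumᵢⱼ / proton countᵢⱼ), and a second BH
  family over the candidates ("BH p-value 2") declares them significant
  (p < 0.05), a tendency (0.05 ≤ p < 0.1), or rejected.
* **Metabolite method.** Each normalized spectrum is decomposed against
  library-rendered, L1-normalized fingerprint templates by non-negative
  least squares; metabolites present in ≥ 50 % of the samples of at
  least one overfeeding day are kept, and a metabolite qualifies when
  its PLS1 VIP exceeds 1 *and* its BH-corrected regression p-value is
  below 0.05.

Model quality is reported with the standard chemometrics suite (R²X,
R²Y, Q² from 7-fold cross-validation, RMSEE, RMSECv) and validated by
refitting on 500 response-permuted copies of the data: a valid model has
its original Q² above every permuted Q² and a negative Q²-intercept.
The two methods and the two traits are reconciled with Venn set logic,
and biomarker–trait Pearson correlation networks are built from the RC
vectors.

Because the original duck data are not publicly deposited, the package
ships a synthetic study generator that emulates the published design
(64 ducks over overfeeding days 6/8/10/12, LW ∈ [302.3, 914.9] g,
TY ∈ [54.8, 99.5] %, corr(LW, TY) ≈ −0.80) and renders spectra as noisy
Lorentzian-multiplet mixtures of the packaged fingerprints, with planted
concentration–trait effects. Every stage of the pipeline is tested
against this generator. See `docs/methods.md` for modeling details and
limitations.

## Worked example

Run the full pipeline on a synthetic study (default seed 0):

```bash
hepamark run --out demo/
```

prints the per-trait biomarker counts

```json
{
  "LW": {"bucket": 16, "metabolite": 5, "common": 5},
  "TY": {"bucket": 16, "metabolite": 5, "common": 5}
}
```

and writes per-bucket statistics, peak-evidence tables, biomarker
records, network edge lists and `summary.json` into `demo/`. In this
run the liver-weight bucket model reports R²X = 0.263, R²Y = 0.951,
Q² = 0.934, RMSEE = 35.0 g, RMSECv = 41.1 g with 105 VIP > 1 buckets:
one latent variable explains most of the trait because the five planted
metabolites (lactate up; glucose, taurine, alanine, allantoin down with
LW) dominate the spectral variation, exactly the regime the method is
designed for. The bucket list contains all five planted metabolites
plus shift-overlapping neighbors (e.g. threonine's doublet adjoins
lactate's at 1.32 ppm — the same ambiguity the annotation step preserves
on real spectra); none of the seven decoy metabolites placed in empty
shift regions qualifies.

The same analysis is available as a library:

```python
from hepamark import run_pipeline
result = run_pipeline({"seed": 0}, out_dir="demo")
result.traits["LW"].pls_summary          # R2X/R2Y/Q2/RMSEE/RMSECv
result.traits["LW"].bucket_records       # RC-level qualification table
result.trait_venn.common                 # biomarkers shared by LW and TY
```

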