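# lungscreen

A tested, reusable implementation of a lung-carcinoma screening pipeline for
2-D chest CT-like images, aimed at researchers who want an end-to-end,
fully reproducible reference chain they can probe stage by stage:

1. **Denoising** — an anisotropic diffusion filter whose diffusion-matrix
   eigenvalues α₁ = 1−C, α₂ = α₁ + 3/2(1−C_p), α₃ = α₂ + 3(1−C_l) derive
   from intra-class variance gains computed over window, planar and linear
   stencils of the structure-tensor frame (I-ADF);
2. **Lung-field extraction** — percentile contrast stretch, Otsu threshold,
   and per-component convex hulls of the two largest enclosed dark regions;
3. **Segmentation (B-RGS)** — a coati optimization algorithm with
   Bates-distributed random steps (ς = (1/φ)Σ U(0,1)) selects one seed
   pixel per lung quadrant; region growing with the adaptive threshold
   T = c·std₅ₓ₅(seed) + floor yields four disjoint parts;
4. **Features** — 21 named values per part (84 per image): gradient-histogram
   statistics, spectral flatness GM/AM of Fourier magnitudes, vertical
   profile statistics, on-rib evidence (centroid-to-rib distance vs
   inter-rib spacing), on-vessel evidence
   V₁ = (len₁·len₂)/(H·W), V₂ = 1/min dist, and the candidate blob radius;
5. **Selection (BD-CST)** — 2×2 Pearson chi-square
   χ² = e(WZ−YX)²/((W+Y)(X+Z)(W+X)(Y+Z)) at a significance level taken
   from a binomial pmf value R = C(e,ρ)gʳ(1−g)^(e−ρ);
6. **Classification (PResNet)** — a NumPy residual network with parametric
   ReLU (μ(x) = x if x>0 else J·x, J learnable) over the selected features;
7. **Risk screening** — abnormal predictions are graded high/low from the
   on-rib flag and blob radius of the most salient quadrant.

A synthetic chest-phantom generator (elliptical lung fields, curved rib
bands, vessel spokes, optional nodules, Gaussian/Poisson noise) supplies
images *with complete ground truth*, so every stage is testable without any
external dataset. See `docs/methods.md` for the models, assumptions, and
all parameter choices.

## Worked example

The one-command demo renders a seeded 60-phantom corpus (30 normal, 30
abnormal), runs the full chain, trains on a stratified 70 % split and
evaluates on the held-out 18 images:

```bash
lungscreen run --mode demo --seed 1 --out demo/
```

prints (abridged):

```json
{
 "mode": "demo",
 "n_images": 60,
 "n_train": 42,
 "n_test": 18,
 "n_selected_features": 50,
 "significance_rank": 0.37735360253530725,
 "critical_value": 0.7793055791030383,
 "mean_lung_dice": 0.995395084354861,
 "mean_quadrant_dice": 0.9953985063591513,
 "test": {
  "accuracy": 0.9444444444444444,
  "precision": 1.0,
  "recall": 0.8888888888888888,
  "specificity": 1.0,
  "f_score": 0.9411764705882353,
  "fnr": 0.1111111111111111,
  "fpr": 0.0
 },
 "risk_accuracy_abnormal_test": 0.7777777777777778
}
```

Reading the numbers: the convex-hull extraction recovers the true lung
fields almost exactly (Dice 0.995), the four optimizer-seeded regions cover
their quadrant ground truth equally well, feature selection keeps 50 of 84
features at the binomially derived significance level R ≈ 0.377 (critical
χ² ≈ 0.78), and the classifier reaches 94 % accuracy on the 18 held-out
phantoms with no false alarms (FPR 0, one missed abnormal). Risk grading of
the abnormal test images agrees with ground truth for 7 of 9 — the
rule-based screen is deliberately biased toward high risk.
Exact values for the error rates on an 18-image test set move in steps of
1/18 ≈ 5.6 points, so expect a few points of variation with other corpus
seeds. The run writes `demo/predictions.csv`, `demo/features.csv`,
`demo/labels.csv`, the model checkpoint and `demo/report.json`; re-running
with the same seed reproduces them byte for byte.

Individual stages are available as subcommands (`lungscreen phantom`,
`preprocess`, `segment`, `features`, `select`, `train`, `predict`,
`evaluate`, `evaluate-denoise`) and as plain library calls
(`lungscreen.iadf_denoise`, `lungscreen.segment_lungs`, ...).

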