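# melanomorph

Quantitative tools for studying melanosome morphology in bird feathers and
reconstructing plumage color in fossils.

Melanosomes — the melanin-bearing organelles preserved in exceptional
fossils — differ in size and shape between black, brown, grey and
iridescent plumage. Iridescent feathers additionally contain four derived
melanosome types (solid/hollow × cylindrical/flat) that have evolved
convergently in distant bird lineages. `melanomorph` implements the full
comparative workflow around these observations, for paleontologists and
evolutionary biologists working with per-melanosome measurement tables and
a time-calibrated phylogeny:

- **Morphometrics** — collapse per-melanosome length/width measurements to
  per-sample features: mean length L̄, mean width (diameter) W̄, aspect
  ratio (mean of per-melanosome L/W), CVs, and flatness/hollowness flags;
  quantify how unstable each statistic is at small n by subsampling.
- **Mixed ordination (PCAmix)** — a fused PCA/MCA for quantitative +
  qualitative variables: standardized quantitative columns and centered
  level indicators weighted n/nₛ are factored by a weighted SVD. Total
  inertia is p₁ + (m − p₂); fossils are projected with the training
  standardization. A phylogenetic PCA (eigendecomposition of the GLS
  evolutionary covariance **R** = (X−1a)ᵀ**C**⁻¹(X−1a)/(n−1)) checks that
  morphospace volumes are not phylogenetic artifacts.
- **Disparity** — convex hull and alpha-shape volumes per color category
  on the first three axes, a label-randomization test for the excess
  volume of iridescence-generating melanosomes, and sum-of-variances with
  bootstrap CIs.
- **Phylogenetic signal** — multivariate Blomberg K (K_mult, permutation
  test), per-axis K and Pagel's λ (ML), and Brownian ancestral states for
  phylomorphospaces.
- **Convergence** — the Wheatsheaf index w = mean phylogenetically
  penalized phenotypic distance among all species over that among the
  convergent focal species, with bootstrap CIs and a randomized-focal-set
  significance test.
- **Paleocolor classifiers** — QDA (closed-form class Gaussians) and
  multinomial logistic regression with exhaustive AIC variable selection,
  repeated stratified k-fold cross-validation, Cohen's κ, an exact
  binomial test against the no-information rate, and a *model decay*
  statistic: the fraction of predictions that flip when dimensions are
  shrunk 10–30% to mimic fossil maturation.
- **Synthetic data** — a generator producing trees (pure birth), species
  traits (Brownian motion plus convergent regime optima painted on
  disjoint clades) and lognormal per-melanosome measurements, so the whole
  pipeline is testable without any external download.

## Worked example

```sh
$ melanomorph simulate --seed 11 --n-species 96 --outdir demo
wrote 2400 measurements for 96 species to demo
$ melanomorph summarize demo/measurements.csv --out demo/summaries.csv
wrote 96 sample summaries to demo/summaries.csv
$ melanomorph ordinate demo/summaries.csv --model-out demo/ord.json --scores-out demo/scores.csv
5 axes; variance explained: PC1 53.9%, PC2 30.0%, PC3 12.6%, PC4 3.4%, PC5 0.1%
$ melanomorph train demo/summaries.csv --seed 11 --model-out demo/mlr.json
MLR: accuracy 86%, decay 42%, kappa 0.82, exact p 3.6e-135
$ melanomorph predict demo/mlr.json demo/summaries.csv --out demo/preds.csv
96/96 samples called at threshold 0.5
```

Reading the output: the mixed morphospace has exactly five
positive-inertia axes (three quantitative variables plus two binary
variables, each binary contributing one); the first two axes carry ~84% of
the inertia, dominated by size and the flat/hollow contrasts. The trained
multinomial model recovers the true color class of 86% of held-out samples
(chance-corrected agreement κ = 0.82, far above the no-information rate),
but 42% of its predictions flip under 30% linear shrinkage — the decay
figure to weigh when interpreting fossil calls. `demo/preds.csv` lists
per-sample posteriors over {black, brown, grey, iridescent} and a call
wherever the maximum posterior reaches 50%.

The same analyses are available as a library (`melanomorph.ordination`,
`.disparity`, `.phylo_signal`, `.convergence`, `.classifier`), and
`melanomorph all config.yaml` runs the complete pipeline (simulate or load
→ summarize → ordinate → disparity → signal → convergence → train →
predict) with a reproducibility manifest.

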