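# Methods

This note documents the models, estimators and numerical choices behind
`melanomorph`, what the synthetic data generator does and does not
emulate, and the design decisions taken where several defensible options
existed.

## Data model

The unit of observation is the *sample*: one feather patch from one
species, measured as dozens of individual melanosomes (length and width in
μm). All downstream analysis operates on per-sample summaries: mean
length, mean width ("diameter"), aspect ratio, CV of length and width,
and two binary flags (flat vs cylindrical, hollow vs solid) assessed from
imaging. Aspect ratio defaults to the mean of per-melanosome length/width
ratios; the ratio-of-means convention is available via a switch, since
the two differ for skewed data and the field's usage is ambiguous.
Standard deviations use the n−1 denominator throughout.

CV of length is computed but excluded from ordination and classification
defaults: subsampling (`morphometrics.subsample_stability`) shows the
across-draw CV of the sample mean at n = 10 melanosomes is ~6% (the
√n standard-error rate for 20% within-sample variation), whereas the CV
statistic itself varies by ~25% at the same n — too unstable for fossil
samples where n is small. Skew statistics are omitted entirely for the
same reason.

Species-level filters (e.g. dropping penguins, whose melanosome shape
tracks an aquatic lifestyle rather than color mechanism) remove rows;
small samples are only flagged by default (`min_n = 10`), because the
robust response to small n is dropping sensitive *statistics*, not
samples.

## Trees

Trees are rooted, ultrametric, with branch lengths in time units. Species
absent from a reference tree are grafted next to congeners: at the genus
MRCA as an extra (polytomy-forming) child when two or more congeners are
present, or by splitting the single congener's terminal branch at a
configurable fraction (default 0.5) otherwise. Both constructions keep an
ultrametric tree ultrametric; grafting is idempotent. The Brownian
covariance matrix C (Cᵢⱼ = root-to-MRCA path length) is computed once per
analysis and shared.

## Mixed ordination (PCAmix)

Quantitative columns are centered and scaled by their population standard
deviation; each qualitative variable enters as its centered level
indicator matrix with column weights n/nₛ (nₛ = level count). With
uniform row weights 1/n, the weighted matrix is factored by SVD.
Consequences used as invariants and tests: each quantitative variable
contributes inertia 1 and each qualitative variable mₛ − 1, so the
eigenvalue sum is p₁ + (m − p₂) (exactly 5 for the standard 3 + 2-binary
analysis); with no qualitative variables the method reduces to
correlation-matrix PCA; the squared loading of a variable on an axis is
its squared correlation (quantitative) or correlation ratio η²
(qualitative), and these sum per axis to the eigenvalue. New (fossil)
samples are projected with the *training* means, deviations and level
frequencies; projecting the training data reproduces the training scores.
Axis signs are canonicalized (largest-|entry| element of each axis
positive) so runs are reproducible. Eigenvalues below 1e−10 are treated
as null axes.

Species with multiple samples: every sample is a point in the sample
morphospace, but phylogenetic analyses need one value per tip, so samples
are averaged per species first (flags OR-ed). This choice is configurable
by passing your own per-species table.

Phylogenetic PCA eigendecomposes the evolutionary covariance
R = (X−1a)ᵀC⁻¹(X−1a)/(n−1) with GLS mean a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X; scores are
projections of the centered (not whitened) data on R's eigenvectors, so
ordinary and phylogenetic scores differ by an invertible linear map and
hull volumes computed from both agree closely — the package's check that
volumes are not phylogenetic artifacts. Only quantitative variables can
enter, which is also why pPCA volumes for the iridescent category run
lower than mixed-ordination volumes: the flat/hollow dimensions are
absent.

## Disparity

Convex hulls use the first three axes (3-D volumes; Qhull). Alpha-shape
volume is the total volume of Delaunay tetrahedra whose circumsphere
radius is ≤ α, the standard alpha-complex construction: it converges to
the hull for large α, vanishes as α → 0, is monotone in α, and does not
bridge well-separated clusters. Default α ∈ {1.3, 2, 5} on score axes.
Degenerate clouds (< 4 points, coplanar) raise in strict mode and report
volume 0 with a warning in pipeline mode.

The randomization test uses the statistic
volume(iridescent) / volume(pooled non-iridescent points) — pooling, not
summing per-category volumes, because the scientific claim is about the
iridescent cloud exceeding everything else combined. Labels are shuffled
preserving category sizes (default 5000 iterations) and
p = (1 + #{null ≥ observed})/(1 + n_iter). The published analyses fed a
related ratio to an exact goodness-of-fit test whose exact form is
ambiguous; alongside the permutation p we therefore also report a
one-sided exact binomial test of the count of null ≥ observed against
1/2. Neither mode is claimed to be the original computation; both support
the same directional conclusion.

Sum of variances (per category, across all axes, n−1 denominator) gets a
95% percentile bootstrap CI from 1000 stratified (within-category)
resamples.

## Phylogenetic signal

K_mult follows the distance-based multivariate generalization of
Blomberg's K:

K_mult = [Σᵢ d²(yᵢ, â) / Σᵢ d²(uᵢ, 0)] ÷ [(tr C − n(1ᵀC⁻¹1)⁻¹)/(n−1)],

with â the GLS phylogenetic mean and u = C^(−1/2)(Y − 1â). C^(−1/2) is
computed by eigendecomposition with an eigenvalue floor of 1e−12;
zero-length duplicate tips make C singular and raise with a suggestion to
jitter branch lengths. K = 1 is the Brownian expectation (the package
verifies a mean of ~1 over 500 Brownian simulations); significance comes
from permuting species across tips (default 999 permutations, +1
smoothing). With one axis the statistic reduces exactly to univariate
Blomberg K.

Pagel's λ multiplies the off-diagonal of C by λ ∈ [0, 1]; the mean and
rate are profiled analytically and λ maximized by bounded scalar search
(xatol 1e−8), with endpoints checked explicitly since the MLE is often at
a boundary. The reported p-value is a likelihood-ratio test against
λ = 0 (the star-tree/iid model).

Ancestral states are the Brownian ML (= GLS) conditional expectations at
internal nodes; the root estimate equals the phylogenetic mean, and the
whole vector equals the solution of the edge-wise penalized least-squares
problem (verified against that independent formulation in tests).

## Wheatsheaf index

Traits are z-standardized per axis; pairwise Euclidean distances dᵢⱼ are
inflated for close relatives by d′ᵢⱼ = dᵢⱼ(1 + sᵢⱼ), with sᵢⱼ the shared
root-to-MRCA path length divided by tree depth. This penalty was chosen
because it (i) discounts resemblance among close relatives, which is weak
evidence of convergence, and (ii) vanishes on a star tree; the original
published penalty is not restated in the source literature, so the
penalty function is a pluggable argument and published w values should be
read as directional, not numeric, references. w = mean(d′ all pairs) /
mean(d′ focal pairs); w = 1 exactly when the focal group is all species.
The focal group should hold one representative per independent origin.
CI: percentile bootstrap over species with focal membership attached to
each resampled species (1000 replicates). Significance: random focal sets
of the same size, because the hypothesis concerns focal-set membership;
p uses +1 smoothing.

## Classifiers

QDA is fitted in closed form (class means, covariances, frequencies as
priors) and cross-checked against scikit-learn's implementation in the
test suite; it accepts only quantitative variables. The flags can instead
act as a pre-filter (`flag_prefilter`): any flat or hollow sample is
assigned iridescent before the QDA runs, mirroring the situation where
sectioning evidence already settles the flags. MLR is a softmax-linear
model fitted by scikit-learn's multinomial logistic regression with a
negligible ridge (C = 1e8) for numerical stability.

Variable selection enumerates all 2ᵏ − 1 nonempty subsets of {length,
diameter, aspect ratio, flatness, hollowness} and ranks by AIC
(multinomial log-likelihood for MLR; class-conditional Gaussian joint
likelihood for QDA, qualitative candidates skipped with a note). Default
variable sets — MLR: diameter, aspect ratio, flatness, hollowness; QDA:
length, aspect ratio, diameter.

Cross-validation is repeated stratified k-fold with k = 10 and 5 repeats
(k shrinks with a warning if a class is smaller than k). Accuracy is the
mean held-out correct fraction; Cohen's κ = (p_o − p_e)/(1 − p_e) is
computed from the confusion matrix pooled over all folds and repeats; the
"exact test" is a one-sided binomial test of the pooled correct count
against the no-information rate (largest class frequency).

Model decay re-applies the *fixed* fitted model (no retraining) to data
whose length and width are shrunk by 10/20/30%; the reported decay is the
percent of predictions changed at 30%. Aspect ratio and flags are
invariant under uniform linear shrinkage, so models built purely on them
have decay 0 — the mechanism behind the robustness ranking of
shape+flag models over size-based ones. Fossil predictions report the
full posterior and call a class only when the maximum posterior reaches
the 50% threshold; otherwise "inconclusive".

## Synthetic data: what it emulates, and what it does not

The generator's defaults define the package's study conditions: 96
species on a unit-depth pure-birth tree; log length and log width evolving
by Brownian motion (rate 0.04 per unit depth) from a ~0.9 μm / 0.35 μm
root; color categories in proportions black 0.25 / brown 0.20 / grey
0.20 / iridescent 0.35 with distinct size optima (black long and narrow,
brown short, grey wide and low-aspect); four iridescent melanosome types
painted onto 2–3 disjoint clades each (solid cylindrical ~1.1 × 0.25 μm,
solid flat ~1.2 × 0.45, hollow cylindrical ~1.05 × 0.35, hollow flat
~2.2 × 0.9 — the hollow-flat type reaching the ~2.5 μm outliers seen in
hummingbirds against a ~1 μm overall average); species pulled a fraction
γ = 0.85 from their Brownian value toward their regime/category optimum;
25 melanosomes per sample drawn lognormally with within-species CV 20%
(lognormal guarantees positivity; width > length draws are swapped).
Category probabilities for unpainted species are renormalized per
replicate so the overall composition matches the configured proportions
in expectation. Everything is reproducible from one integer seed.

Deliberate simplifications, and hence limits on what passing tests show
about real data:

- Convergence is injected as a single displacement toward a shared
  optimum, not an Ornstein–Uhlenbeck process: sufficient to create
  Wheatsheaf-positive structure, but not a model of the generating
  process.
- Color categories of unpainted species are assigned independently of
  the tree, and the attraction to category optima is strong (γ = 0.85).
  Both choices erase most Brownian signal from the final morphospace, so
  K_mult on the synthetic species scores is low — real comparative data
  retain intermediate signal. K calibration is therefore tested on pure
  Brownian simulations, not on the generator's output.
- One sample per species; no measurement error beyond sampling; no
  fossil taphonomy other than uniform shrinkage; no optics, keratin or
  barbule geometry.

## Problem sizes

Simulation-heavy checks are sized to hold their statistical guarantees at
modest cost: 500 Brownian replicates for the K_mult calibration band
[0.9, 1.1], 200 replicates for λ recovery at each end, 200 null
experiments (199 permutations each) for the randomization-test type-I
rate, 5000 permutations for the power fixture, 1000 bootstrap replicates
for Wheatsheaf CIs and significance. The acceptance script runs the full
default conditions in well under a minute of compute per stage.
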