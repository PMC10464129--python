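# Methods

`depscreen` re-implements, as a tested library, a comparison framework for
gene-dependency screens obtained with two perturbation modalities: a
knockout-like modality ("A", full on-target efficacy, e.g. CRISPR-Cas9)
and a knockdown-like modality ("B", partial suppression, e.g. RNAi).  All
statistics operate on *gene-effect* matrices (cell lines x genes) scaled
so that the per-line median of nonessential genes is 0 and the per-line
median of core-essential genes is -1; more negative means stronger
dependency.  Because the real screen compendia are large external
deposits, the package ships a synthetic-data generator with planted
ground truth, and every downstream module is validated against that
truth.

## Synthetic screens

Each gene is planted with one archetype:

* **pan-dependent** — Normal(mu_pan, sigma) in every line, with
  mu_pan = -1 (the scaled core-essential anchor) and sigma = 0.15;
* **strongly selective** — Normal(0, sigma) in most lines; a 5% minority
  of lines is shifted by 1.5 * mu_pan (a two-component mixture rather
  than a literal skew-t draw — a harder detection problem, since the
  likelihood-ratio test must still recognise it);
* **high-variance** — a continuous gradient mu_pan * Beta(2, 4) per line
  plus noise, giving effects spanning [-1, 0] with negative skew;
* **weakly selective** — like strongly selective with a sub-threshold
  depth of 0.6 * mu_pan;
* **non-dependent** — Normal(0, sigma).

Archetypes are assigned per gene index by a golden-ratio (Weyl) sequence
binned by the configured fractions (default 10/10/10/10/60%): this keeps
every existing gene's archetype stable when the gene axis is extended,
while realised proportions stay within one gene of the configured
fractions.  Random draws use one root seed with per-purpose, per-gene
child streams; structural latents (dependent-line sets, high-variance
gradients, module profiles, missingness masks) are shared between
modalities, measurement noise is modality-specific.  A fixed seed
reproduces the bundle bitwise.

Modality B applies attenuation: pan-dependent means shrink by a factor
0.6 and their per-line standard deviation is inflated by +0.25 (pan
knockouts typically become variable, partially selective knockdowns);
selective shift depths shrink by the same factor.  This reproduces the
qualitative knockout-vs-knockdown pattern without claiming a mechanism.

Couplings for downstream modules:

* **Biomarkers** — per gene the generator emits an expression and a
  copy-number feature (plus hotspot-mutation flags for planted driver
  genes and lineage one-hots).  Planted mechanisms couple features to the
  realised effects: expression addiction (own expression = 4 - 3*effect +
  N(0, 0.5)), CYCLOPS (own copy number = 1 + 1.2*(effect - mean) +
  N(0, 0.08), on the gene's own chromosome-arm tag), paralog lethality
  (partner expression = 3 + 3*effect + N(0, 0.5)), genetic driver
  (mutation flag marks the dependent lines with 2% label noise).
  Coefficients were chosen so planted couplings give feature-effect
  correlations around 0.85-0.95 — strong but not deterministic, the
  regime where a random forest should succeed.
* **Drugs** — each drug targets a selective or high-variance gene.  Doses
  are indexed low to high: the lowest quarter is pure noise, the highest
  quarter is near-uniform toxicity (response -2, small variance), and
  mid-range doses carry the target's effect profile with a triangular
  weight peaking at the centre dose, plus N(0, 0.3) noise.  A shared
  growth-rate-like confound (0.5 * standard normal per line, weight 1)
  is added to all drugs, to be removed by PC1 regression downstream.
* **Networks** — planted modules (default 5 modules of 10 genes, drawn
  from high-variance genes) share a common Beta(2, 4) gradient with
  coupling weight 0.85, yielding within-module correlations ~0.6-0.7 in
  modality A and ~0.4-0.5 after attenuation in B.  Module co-membership
  and paralog pairs form the "known related" prior sets.
* A configurable fraction (default 40%) of the inert non-dependent genes
  is transcriptionally silent in every line (expression ~ |N(0.05,
  0.03)|, versus expressed means of 2-8): these are the per-line null
  controls and the high-variance negative-control set.

What the generator does **not** emulate: copy-number-driven cutting
artefacts, miRNA seed effects, batch structure, lineage-correlated
dependency, or realistic missingness mechanisms (missingness is MCAR with
mirrored masks).  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
real-data pathology.

## Screen quality

Reagent-level log fold-changes collapse to genes by simple per-line
averaging.  Control separation per line is the strictly standardised mean
difference, SSMD = (mean_pos - mean_neg) / sqrt(var_pos + var_neg), with
unpaired sample variances (the standard screening-literature two-group
form).  Reagent concordance first z-scores each cell line (batch-effect
reduction), then takes the median pairwise Pearson correlation among each
gene's reagents, alongside a percentile of the per-gene maximum reagent
variance (percentile = fraction strictly smaller, ties averaged).
Control ROC AUC per line ranks genes by effect (more depleted = more
positive) with midrank tie handling; it equals the normalised
Mann-Whitney U statistic and is tested against explicit pair counting.
Gene effects are scaled per line by subtracting the nonessential median
and dividing by |essential median - nonessential median|; the map is
idempotent and invariant to per-line affine transformations.  The
composite "unbiased essential" control set converts population constraint
metrics to percentiles (direction declared per metric), calls a gene
population-lethal when its median percentile over >= 3 observed metrics
exceeds 85, and requires gene-trap support plus one other source
(mouse-lethal or population-lethal).

## Dependency classification

**Normalised ranks.** Within each line, genes are ranked ascending by
effect (average ranks on ties) and divided by the number of non-missing
genes, giving values in (0, 1] that are invariant to strictly monotone
transformations.

**Pan-dependency.** Per gene, the 90th percentile of its normalised ranks
across lines is the rank of its most-dependent line among the 10% least
dependent.  That statistic is bimodal over genes; the threshold is the
kernel-density minimum isolating the depleted (left) mode.  Mode finding
uses a Gaussian KDE (Silverman bandwidth, 512-point grid) with a
prominence floor of 1% of the maximum density; the threshold is the
density argmin between the leftmost mode and the next mode to its right.
For a genuinely bimodal sample this is the unique valley; selecting modes
by prominence alone instead mis-pairs modes when an intermediate
subpopulation (e.g. a block of high-variance genes) forms a shoulder.
The percentile is configurable (80/90/95 give near-identical sets on
separated data).

**Probability of dependency.** Per line, gene effects are decomposed into
a null density f0 (that line's non-expressed genes) and a positive
density f1 (the dataset's pan-dependent genes), both Gaussian KDEs with
the Silverman rule.  The posterior is pi1*f1 / (pi0*f0 + pi1*f1) with
symmetric default weights pi0 = pi1 = 0.5, so the 0.5 decision boundary
is the equal-density point.  Beyond the control supports the posterior is
pinned (1 on the depleted side, 0 on the enriched side) to prevent
density-ratio tail artefacts, and an isotonic projection enforces
monotone non-increase in the effect within each line.  Both control sets
must have >= 20 members per line.  A line is "dependent" at probability
strictly greater than 0.5; a non-dependency has all lines below 0.5.

**Selectivity LRT.** Each gene's profile is fit by a Gaussian
(closed-form MLE) and an Azzalini skew-t with location, scale, slant
alpha, and degrees of freedom nu;

    LRT = 2 [ln L(skew-t) - ln L(Gaussian)],

with strongly selective dependencies at LRT >= 100 (the comparison
operator is configurable, since both >= and > appear in common usage).
Numerical choices: Nelder-Mead on (xi, log omega, alpha, log nu) from a
method-of-moments start, a heavy-tail start, and two "folded" starts
(location at a data extreme with strong slant) — the small-sample surface
is multimodal and the near-half-normal basin is otherwise missed.  On
failure (and always for n <= 50, where fits are cheap) a two-step ladder
fixes nu at (2, 5, 10, 25, 50, 100, 250, 500, 1000), fits the remaining
parameters, then refits freely from that solution.  The family is
restricted to nu >= 0.5 and |alpha| <= 50: outside, the unconstrained MLE
degenerates (density spikes on near-tied points; |alpha| beyond ~50 is
numerically identical to the folded limit), and the restriction keeps the
maximum attained.  The Gaussian is the boundary member (alpha = 0,
nu -> inf), so the fitted skew-t likelihood is floored at the Gaussian
likelihood and LRT >= 0 by construction.

**High variance.** Per-gene variance of the dependency probabilities is
compared with the 99th percentile of that variance over the non-expressed
(presumed inert) genes; the threshold is always derived from the data at
hand, never fixed a priori.

**Ordered classes.** Each gene receives exactly one of five labels by
sequential overwrite: (1) non-dependent if no line is dependent; (2)
weakly selective if any line is; (3) strongly selective if the LRT
exceeds the cutoff; (4) pan-dependent; (5) high-variance; (6) strongly
selective again if the LRT exceeds the cutoff *and* the slant is
negative.  Later rules overwrite earlier labels, so a gene that is
simultaneously pan, high-variance, and negatively-skew selective ends as
strongly selective.  A first-match variant is available behind a flag
because the double listing of the selective rule makes the intended
precedence genuinely ambiguous; sequential overwrite is the default
reading.

**Cross-dataset agreement.** Within a modality, two datasets agree on a
gene if it is pan-dependent in both, non-dependent in both, or its own
top cross-dataset correlate (its matching-gene correlation ranks first
among all pairings for that gene).  The high-confidence set is the
intersection of the per-modality agreement unions.  Class tables from the
two modalities are compared as a 5x5 contingency of per-gene label pairs.

## Biomarker models

Omics features are z-scored per feature (constant features dropped),
categorical features one-hot encoded, remaining missing values set to 0,
and a screen-quality confounder column carried along.  Each target gene's
effect profile is modelled by a random-forest regressor (100 trees, max
depth 8, min 5 lines per leaf) under two regimes: **related** (features
whose subject gene has a prior relation to the target, the target itself
included; confounders and lineage always included; an empty selection
falls back to confounders + lineage with a flag) and **unbiased** (top
1000 features by |Pearson correlation| with the target, screened inside
each training fold so no held-out information leaks).  Evaluation is
stratified 5-fold cross-validation with strata = dependent vs
non-dependent lines (probability 0.5); accuracy is the Pearson
correlation between observed effects and concatenated out-of-fold
predictions, and a gene's single reported accuracy is the maximum over
regimes.  Importances are mean-decrease-in-impurity, averaged over folds
and normalised to sum 1; "top feature" ties break by feature name for
determinism.

Accurate models (r > 0.5) are screened against a literal rule table
(genetic driver, expression addiction, paralog lethality, CYCLOPS,
oncogene addiction, synthetic lethality with an oncogene/TSG feature).
All correlation directions are evaluated on the gene-effect scale (more
negative = more dependent): a dependency-promoting feature — mutation
flag, amplified copy number, or overexpression — correlates negatively
with the effect, while the CYCLOPS rule requires *positive* correlation
with the target's own copy number (copy loss sensitises).  Skewness is
the sample third standardised moment of the effect profile; "negative
skew" means moment < 0.  "Same chromosome arm" is resolved from the
synthetic arm tags carried in feature metadata.

## Drug–target association

Each dose-level matrix (cell lines x drugs) is median-imputed per drug,
its first principal component computed across cell lines, and every drug
column residualised against the PC1 scores; imputed entries are re-masked
afterwards.  Residual profiles are correlated (pairwise-complete Pearson)
with dependency profiles of genes that are dependencies in >= 3 lines.
Both axes are "more negative = more killing", so a drug matching its
target gives positive r; the best dose per annotated (drug, target) pair
is the signed-r argmax (ties to the lowest dose), with an absolute-value
mode behind a flag.  Target recovery at rank k is the fraction of
drug-doses whose annotated target ranks in the drug's top k correlated
genes, reported per dose, overall, and stratified by the target's
dependency class.

## Co-dependency networks

Raw networks are all-pairs Pearson correlation over cell lines for the
filtered gene set.  Fusion adapts Similarity Network Fusion: affinities
are |r| (nonnegativity requirement; the sign is retained in the raw
networks for reporting), full kernels are row-normalised with the
diagonal set to 1/2 beforehand, sparse kernels keep each row's k = 7
nearest neighbours by |value| renormalised to sum 1 (k = round(ln n)
available as an auto mode), and the kernels cross-diffuse

    P_A <- S_A P_B S_A^T,   P_B <- S_B P_A_prev S_B^T

with row renormalisation for exactly 20 iterations (no convergence test),
after which the two kernels are averaged and symmetrised.  Prior-relation
recovery per query gene uses a one-sided two-sample KS test of whether
the |similarity| scores of known related genes are stochastically larger
than the rest, plus the best rank of any prior under |similarity|
ordering (self excluded).  Local neighbourhood graphs take the query plus
its top-10 co-dependencies, with a directed edge u -> v whenever v is in
u's top 10 and edge weights as z-scores over the full matrix.

## Benchmark problem sizes

The planted-truth benchmarks (`depscreen.benchmarks`, exercised by the
acceptance tests and `scripts/acceptance.py`) use: pan recovery on five
400 x 1000 bundles; LRT operating characteristics on 500 Gaussian null
and 200 planted selective profiles of 400 lines each; probability
calibration on a line with 150 + 150 control genes separated by ~6.7
pooled SD; rule-replay agreement on 200 random statistic vectors;
biomarker recovery on a 200 x 450 bundle with 50 planted genes per
mechanism and 50 uncoupled controls, evaluated through the Related regime
(which carries every planted mechanism's class signal) with an Unbiased
spot-check on 5 genes — the Unbiased regime over all 250 targets adds no
class information here and is costly at full scale; drug recovery on 50
drugs over a 400 x 1000 bundle; network fusion on the 400 x 1000 bundle's
five 10-gene modules.  These sizes are the package's standard desk-scale
study conditions; all thresholds and tolerances in the tests were fixed
by the statistical design described above.

## Known limitations

* The skew-t optimiser does not guarantee the global maximum; the
  multi-start design plus the nesting floor make under-estimation of the
  LRT the only failure mode, and the small-sample grid-search tests bound
  it to 0.5 log-likelihood units on n = 12 profiles.
* The posterior's isotonic projection can flatten genuinely non-monotone
  density ratios between overlapping controls; with well-separated
  controls the projection is a no-op.
* KDE-based thresholds (pan cut-off, expression threshold) depend on the
  Silverman bandwidth; the bandwidth rule is surfaced in the relevant
  function signatures.
* The high-confidence "top correlate" rule uses complete-case z-scored
  matrix products; with heavy missingness a pairwise-complete variant
  would be preferable.
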