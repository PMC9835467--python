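# Methods

This note documents the models and procedures `pairimpute` implements, the
defaults it ships, and the numerical conventions behind them. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## Problem setting

A *collection* is a set of studies $s = 1, \dots, S$ measuring overlapping
gene panels $G_s$ on disjoint cohorts, each with expression matrix $X_s$
($n_s \times p_s$) and, for training studies, a continuous outcome $Y_s$.
Missingness is structural: a gene is either measured for every sample in a
study or absent from the study entirely. The package assumes every study
pair shares at least one gene ($p_{sj} > 0$) and that genes are missing at
random with respect to the outcome; gene identity is exact string match on
IDs (probe-to-gene mapping, normalization and batch correction are upstream
concerns and out of scope — the reader rejects duplicate gene columns
rather than guessing how to collapse probes).

## Harmonization strategies

* **Omitting** restricts every study to the global intersection
  $\bigcap_s G_s$. No model is fitted; it is the baseline every comparison
  is anchored to.
* **Pairwise** fits, for each unordered pair and each gene unique to one
  member, a penalized regression of that gene on the pair intersection in
  the study observing it, and predicts the gene in the partner study. A
  (study, gene) cell imputed by several pairs is finalized as the unweighted
  arithmetic mean of its imputed vectors. Sample-size weighting across pairs
  is deliberately not implemented: plain averaging is the stated ensemble
  rule, and it keeps the result invariant to study enumeration order.
* **Merged** row-concatenates all studies observing a missing gene and fits
  a single model on the global intersection.
* **Subset-of-k** generalizes both: imputation within every size-$k$ study
  subset using the subset intersection, ledger-averaged across subsets.
  $k=2$ reproduces pairwise and $k=S$ reproduces merged *exactly* — the
  implementations are independent and the equalities are enforced
  elementwise by regression tests, not assumed.
* **Core / All** (incomplete validation study $V$, outcome unavailable):
  each training study is screened to its top-$q$ genes by magnitude of
  cross-validated lasso coefficient against the outcome. For a pair
  $(T_i, T_j)$ with screened sets $Q_i, Q_j$ and $Q_V$ the genes available
  in $V$: targets are $H_2 = (Q_i \cup Q_j) \setminus (Q_i \cap Q_j \cap
  Q_V)$; features are $H_1 = Q_i \cap Q_j \cap Q_V$ (Core) or
  $H_{\text{int}} = G_i \cap G_j \cap Q_V$ (All; $H_1 \subseteq
  H_{\text{int}}$ always). Per-gene routing: a gene screened by one training
  study is imputed into whichever other study structurally lacks it, and
  into $V$ only when $V$ lacks it; a gene held by both training studies but
  absent from $V$ gets a single model fitted on the pooled pair and is
  imputed into $V$ only; a gene observed somewhere always keeps its
  original values there. With $S > 2$ training studies, screening is
  computed once per study (it depends only on the study), all pairs share
  one ledger, and averages are taken at the end. The final prediction panel
  is the union of all screened sets — unscreened genes may serve as
  imputation features (All) but never enter the outcome model.

Two routing cases the scenario lists leave implicit are resolved as
follows: a gene in $Q_i \cap Q_j \cap Q_V$ is in $H_1$, hence never a
target (no-op); and a gene screened in one training study but present
*unscreened* in the other keeps its original values in that other study —
observed data always outrank imputations. Imputations are never chained:
imputed values in $V$ are not reused as features for other genes.

### Downstream model

The outcome model is a cross-validated lasso fitted on the
row-concatenation of the harmonized training studies over their (identical)
gene panel; the validation study is predicted on the same panel. The
validation outcome is used only for scoring.

## Imputation learners

The default learner is the lasso with linear terms; a polynomial variant
expands each feature into pure powers $x, x^2, \dots, x^d$ (default $d=2$,
no interaction terms — this keeps the design linear in the feature count
and is the conservative reading of "polynomial terms"). Random forest, RBF
support-vector regression and a chained-equations multiple-imputation
learner (5 posterior draws, averaged to one vector) satisfy the same
fit/predict contract for sensitivity analyses; scikit-learn provides all
estimators.

Numerical conventions, applied inside every learner:

* Features and target are standardized to zero mean / unit variance on the
  training rows; predictions are returned on the original target scale.
  Penalized regression is scale-sensitive, and standardization makes
  predictions invariant to per-gene rescaling (tested to 1e-8).
* The penalty weight is selected by 10-fold cross-validation minimizing
  mean squared error over a 50-point log-spaced grid, with the fold split
  seeded — identical seeds give bit-identical fits. The grid resolution is
  a numerical choice: on the benchmark designs, halving scikit-learn's
  100-point default changes the cross-validated fits imperceptibly while
  halving their cost. `lambda_policy="fixed"` pins the penalty for exact
  tests; a fixed penalty of 0 falls through to minimum-norm least squares.
* Degenerate inputs: a zero-variance target or a single training row falls
  back to an intercept-only model (predicting the training mean, with a
  warning); fewer rows than folds reduces the fold count with a warning.

### Screening ties and padding

When the cross-validated lasso retains fewer than $q$ genes, the
penalization path is descended to the largest penalty admitting at least
$q$ nonzero coefficients and the ranking is taken there; remaining ties
break lexicographically by gene ID. If no penalty yields any signal (e.g. a
zero-variance outcome) the fallback ranking is absolute marginal
correlation, again with lexicographic ties. A deterministic rule is
required because screened sets feed set algebra that must be reproducible.

## Determinism and order invariance

Every derived gene set iterates in lexicographic order; training
concatenations order studies by ID; ledger averages stack entries in
sorted-source order. Consequently every strategy's output is bit-identical
under permutation of the input study list, replicated runs with the same
seed are bit-identical, and serial and parallel experiment execution agree
exactly. Replicate seeds are `base_seed + index (mod 2^31)`, so any subset
of replicates is reproducible in isolation.

## Synthetic collections

The generators emulate multi-study expression collections with three
mechanisms (study sample size defaults to 100, four training studies plus
one validation study):

* **eq1** — 10 predictive genes ($X_1..X_5$, $Xs_1..Xs_5$) jointly
  multivariate normal, mean 0.1, unit variance, pairwise covariance 0.5;
  $Y = \sum_j \beta_j X_j + \sum_j \beta^*_j Xs_j + \varepsilon$. The
  benchmark sources state the gene law but not the coefficients or noise
  scale; the package fixes $\beta_j = \beta^*_j = 1$ and $\varepsilon \sim
  N(0, 1)$ as its study condition — signal spread evenly over all ten
  genes, so masking any of them costs real information. $X_1, X_2$ are
  anchored (never masked); the other eight genes are maskable. The
  validation study is complete.
* **eq2** — eq1 plus ten irrelevant genes $Z_1..Z_{10}$ (mean 0.1, unit
  variance, equicorrelation 0.2, zero coefficients), also maskable.
* **eq3** — sparse signal: 20 common predictive genes, 20 partner genes,
  120 irrelevant genes ($Z$: mean 0, unit variance, correlation 0.2, zero
  coefficients). Per study — validation included — 10 partner and 50
  irrelevant genes are masked, leaving 100 observed genes (20 + 10 + 70).
  Two coefficient presets: $\beta_X = 5$ with $\beta^*_{1..10} = 10$
  (partner genes dominant), and $\beta_X = 10$ with $\beta^* = 5$.
* **nonlinear** — eq1 layout with partner genes built as
  $\sin(Xw_j) + \cos(Xv_j)$ with fixed random projections; the exact
  published functional form of this supplementary mechanism is unavailable,
  so this map is explicitly non-canonical and off by default.

**Missingness.** The proportion design masks `round(p * pool)` genes per
training study, drawn uniformly without replacement, seeded. A pattern that
removes some gene from *every* training study is redrawn while a valid
pattern is feasible; at high proportions (where covering draws are
near-certain and the benchmark sweeps deliberately go) the draw stands and
fully masked genes simply drop out of the training union — they behave
exactly like omitted genes. Explicit user-fixed patterns that mask a gene
in every training study are rejected instead of silently degrading, and a
proportion of 1 is always an error. Masking counts, not wanting a
particular pattern, is what the benchmark varies; an explicit
`missing_design` override reproduces any fixed pattern.

**Heterogeneity.** With $\tau > 0$, eq1-style mechanisms replace the joint
partner draw by study-specific random slopes: $\gamma_k \sim N(0, \tau^2)$,
$\gamma_{k,j} \sim N(\gamma_k \mathbf{1}, I)$, $Xs_j = X\gamma_{k,j}$
(noiseless given the slopes; across-study slope variance is $1 + \tau^2$).
eq2/eq3 shift the $Z$-block mean by $\mu_k \sim N(0, \tau^2)$ per study.
$\tau = 0$ reproduces the homogeneous mechanisms bit-exactly.

**Truth record.** Pre-masking matrices, masks, all outcomes (including the
validation study's) and heterogeneity slopes are retained so imputation
error and prediction error can be scored exactly.

### What the generators do and do not emulate

They reproduce structural per-study missingness, correlated predictive
blocks, irrelevant-gene clutter, sparse signals, incomplete validation
panels and cross-study heterogeneity in inter-gene relationships. They do
not emulate platform-specific measurement noise, batch effects, count-data
distributions, outcome-dependent (non-MAR) missingness or non-Gaussian
expression marginals. Passing tests therefore demonstrate the strategies'
behavior under the stated generative laws, not performance on any
particular real collection; the CSV interfaces exist precisely so real
matrices can be run through the identical code path.

## Evaluation harness

Validation RMSE is the sole performance metric. Within a replicate every
method scores against the identical validation draw (paired design).
Comparisons use the paired two-sided Wilcoxon signed-rank test: zero
differences dropped, exact null for $n \le 25$ without ties in the absolute
differences, normal approximation with continuity correction otherwise
(the implementation is oracle-tested against exhaustive enumeration of all
$2^n$ sign assignments for $n \le 10$). P-values are Bonferroni-multiplied
by the number of method pairs in the displayed grid and capped at 1, and
each pair is annotated with the direction of the smaller median and a
significance band (<0.01, 0.01–0.05, >0.05). Proportion-best splits ties
equally so proportions always sum to 1. Log-RMSE ratios against a baseline
are reported as medians (negative favors the method).

The tests and the acceptance script run 50 replicates per experiment — the
package's desk-scale default, large enough for the signed-rank comparisons
to resolve the orderings of interest — with 100 samples per study, four
training studies for the 10-gene designs and two for the sparse-signal
design. The replicate count is a config knob for larger runs.

## Known limitations

* Under strong cross-study slope heterogeneity (the $\tau = 1$ random-slope
  mechanism), the partner-gene slopes of an unseen study are mean-zero and
  independent of every training study's, so the best cross-study imputation
  shrinks toward the mean. The merged strategy's pooled cross-validated
  lasso performs that shrinkage implicitly (pooled heterogeneous rows
  inflate the CV error and drive the penalty up), whereas the pairwise
  route fits each observer study's noiseless within-study map essentially
  exactly and pair-averaging does not shrink magnitudes. The benchmark
  experiments in `scripts/acceptance.py` accordingly show merged edging out
  pairwise at $\tau = 1$ while both still beat omitting; the pairwise
  advantage documented elsewhere in this note is a homogeneous-law and
  feature-pool phenomenon, not a heterogeneity cure.
* Neither Core nor All uses an optimal imputation feature set: Core ignores
  unscreened genes that may be informative for imputation; All admits noise
  features that dilute small-sample fits.
* The strategies assume genes are missing at random; outcome-dependent
  missingness can make imputation worse than omitting.
* Classification and survival outcomes, pair weighting, imputation
  chaining and multi-study stacking are out of scope.
* Continuous per-cell missingness (scattered NaNs) is rejected by design;
  the package models structural, per-gene-per-study absence only.
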