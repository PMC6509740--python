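# Methods

## The model

Snapshot scoring gives each *ideational pool* — everything one person
produced for one divergent-thinking task — a single holistic rating of
creative quality on an M-point Likert scale (M = 5 throughout, but nothing
downstream hard-codes it).  `treequal` treats such a rating as the outcome
of a walk through the **linear response tree**: M − 1 sequential binary
nodes, where node r asks "does this pool beat category r?".  A rating of m
passes nodes 1..m−1 and stops at node m; the top category passes every
node.  *Dendrification* (`treequal.treeify`) materializes this walk as one
binary sub-item row per reached node; nodes after the stop are structurally
missing and appear as absent rows, because the sequential likelihood
conditions only on nodes actually reached.

Each sub-item is Bernoulli with a logistic link:

    P(pass node r) = logistic(theta_{p, d(r)} + beta_{i r} + delta_k)

* `theta_p` — the person's latent creative-quality trait(s), multivariate
  normal with mean zero, free scales `sigma_d` and a free correlation
  matrix.  The dimension assignment d(r) encodes the competing hypotheses:
  - **unidimensional**: one trait for every node (the "ordinal hypothesis"
    that the whole scale measures one thing);
  - **node_multidimensional**: one trait per tree node; the posterior
    correlation matrix then *measures* how close the scale is to
    unidimensional;
  - **fluency_split**: one trait for low-fluency and one for high-fluency
    pools (labels from a median split, below).
* `beta_ir` — item-by-node easiness on the logit scale, *added* to theta
  (a larger beta makes the node easier to pass).  This is a Rasch-type
  tree: no discrimination parameters.
* `delta_k` — a global leniency offset per rater, reference rater fixed at
  0.  A single offset shared across items and nodes is the minimal model of
  rater central tendency; rater-by-node interactions are out of scope.

Identification comes from the zero latent means and the reference rater.
The category distribution implied by the node model
(`category_probabilities`) multiplies pass probabilities along the walk,
and the sub-item Bernoulli likelihood is algebraically identical to the
sequential categorical likelihood — a property the test suite checks to
1e−10 rather than assumes.

## Priors

The data contain thousands of sub-items per fitted parameter class, so the
priors are deliberately weak: normal(0, 2.5) on thresholds and rater
offsets, half-normal(0, 2) on latent scales, LKJ(1) (uniform over
correlation matrices) on the latent correlations.  All four scales are
configurable through `PriorConfig`.

## Posterior sampling

No probabilistic-programming backend is assumed; the sampler
(`treequal.inference`) is written directly on NumPy and is exact MCMC, not
an approximation:

1. **Polya-Gamma augmentation.**  With omega_i ~ PG(1, eta_i) attached to
   every sub-item, the logistic likelihood becomes conditionally Gaussian,
   so theta (per person, batched), beta (per item-node cell) and delta are
   exact conjugate Gibbs draws each sweep.  The PG(1, z) sampler
   (`treequal._polya_gamma`) implements the alternating-series rejection
   method (truncated inverse-Gaussian / exponential mixture proposal,
   Jacobi-theta partial-sum acceptance), fully vectorized; its moments are
   verified against the closed forms and a one-parameter Gibbs run is
   checked against quadrature in the test suite.
2. **Covariance sufficiency step.**  Given theta, the latent covariance is
   proposed from an inverse-Wishart matched to the latent scatter and
   accepted with a Metropolis-Hastings correction for the half-normal/LKJ
   prior (evaluated on Sigma with the (sigma, C) → Sigma Jacobian).
3. **Interweaved ancillary moves.**  Conditional updates alone mix the
   covariance poorly when a dimension has few observations per person (the
   familiar scale funnel: the latent scatter sticks to the current
   covariance and vice versa).  Holding the whitened residuals
   eps = L⁻¹ theta fixed, scalar moves rescale one sigma_d (theta column
   carried along) or perturb one correlation entry (theta re-rotated
   through the new Cholesky), accepted against the true Bernoulli
   likelihood.  Two rounds per sweep raised the worst-case correlation
   effective sample size from single digits to several dozen per 500 kept
   draws at the default study size.
4. **Translation moves.**  theta_d + c with the matching thresholds
   shifted by −c is likelihood-invariant and accepted on the prior ratio,
   removing the slow location trade-off between persons and items.

Proposal scales adapt by Robbins-Monro during warmup only; kept draws come
from a fixed kernel.  Defaults are desk-scale — 2 chains × 500 warmup +
500 kept — and reproduce bit-for-bit under a fixed `SamplerConfig.seed`.
Split-R-hat is computed for every scalar parameter (via arviz); any value
above 1.05 attaches a warning to the fit rather than aborting, since short
exploratory runs are legitimate.  Values around 1.05–1.1 on the latent
correlations are common at the default draw count; doubling `kept_draws`
typically clears them.

### Non-informative nodes

When an instruction produces (almost) no ratings in an extreme category,
the corresponding node has (almost) only one outcome class there: its item
thresholds are then determined by the prior, with unrealistically wide
uncertainties.  `detect_noninformative_nodes` flags any (instruction, node)
whose minority outcome class has fewer than `min_per_class` observations
(default 5 — the smallest count at which a logistic threshold stops being
prior-dominated; the choice is a floor, not a tuned value), and
`omit_nodes` drops exactly those rows.  A node flagged in *every*
instruction disappears from the model; a node flagged in one instruction
keeps its latent dimension, informed by the other instruction.  Fitting a
node with a single observed outcome class raises `IdentificationError`
instead of silently returning prior draws.

## Model comparison

PSIS-LOO (`treequal.comparison`, backed by arviz) approximates exact
leave-one-out cross-validation from the stored pointwise log-likelihood:
importance ratios per observation are tail-smoothed by a generalized
Pareto fit to the largest 20%, with Pareto k > 0.7 attached as a warning.
The **pointwise unit is one binary sub-item row** — the unit the fitted
likelihood factorizes over.  Results are reported on the deviance scale
(−2 × elpd).  `compare` refuses fits whose observation sets differ (no
silent alignment) and reports ΔLOO = LOO(a) − LOO(b) with a standard error
from the pointwise differences; by convention the unidimensional model is
passed first, so positive ΔLOO favors the multidimensional alternative and
|ΔLOO| > 2 SE is read as decisive.  The test suite validates PSIS-LOO
against exact leave-one-out computed by n refits on a small study.

## Study pipeline

* **Median splits** (`median_split`): a pool is `low` fluency iff its idea
  count is *strictly below* the median of its group — (person, instruction)
  for the within-person split, (item, instruction) for the within-item
  split.  Medians are computed over distinct pools (not rater rows), so
  both raters always agree on the label, and the strictly-below rule caps
  the low fraction at one half.  Even-sized groups use the conventional
  sample median (mean of the two central values).
* **ICC(2,2)** (`icc_2_k`): two-way random effects, absolute agreement,
  average measures, computed from the ANOVA mean squares of the pooled
  (person × item) × rater matrix; one pool = one target, pooled over all
  items so a single global reliability is reported.  Confidence intervals
  use the F-distribution method for absolute-agreement average measures
  (single-measure bounds with Satterthwaite degrees of freedom, stepped up
  by Spearman-Brown).  Cross-checked against pingouin and a from-scratch
  ANOVA decomposition in the tests.
* **Batteries**: `run_node_dimensionality_battery` fits unidimensional vs.
  node-multidimensional on identical rows for the full data and for each
  instruction, after detect/omit; correlation grids show NA for omitted
  nodes.  `run_fluency_split_battery` fits unidimensional vs. two-trait
  (low/high fluency) per instruction × split method and reports the
  low-high correlation with its credible interval and the shared variance
  r² (squared posterior-mean correlation, rounded to two decimals).  A
  failing block is logged and skipped; the battery continues.

## Synthetic studies

`treequal.synthetic_data` generates complete studies mirroring the design
the analysis assumes: N = 249 persons, 4 items per instruction, 2 raters,
5-point scale.  Defaults:

* **Latent traits**: multivariate normal, SD 1 per dimension, compound-
  symmetric correlation (`latent_corr`, default 0.7) for multidimensional
  structures.
* **Fluency**: 1 + Poisson(lambda), lambda = 10 under be-fluent and 6
  under be-creative — plausible alternate-uses magnitudes with the
  be-fluent > be-creative ordering; pools always contain at least one
  idea.  An optional coefficient couples the Poisson log-rate to the
  person's mean trait; it is 0 by default so the fluency-split analyses
  are not confounded by construction.
* **Thresholds**: per-instruction node profiles (0.8, −0.5, −1.8, −6.5)
  for be-fluent and (8.0, 1.5, 0.0, −1.5) for be-creative, plus small item
  offsets (±0.1, ±0.3).  The extreme values were chosen from the marginal
  category probabilities under theta ~ N(0, 1): they put ≈0.05% mass on a
  be-fluent 5 and on a be-creative 1, i.e. about one such rating per 1,992
  — below the `min_per_class` floor — which reproduces the typical
  instruction-dependent sparsity pattern (fluent pools rarely rated
  excellent, creative pools rarely rated poor) and makes the top be-fluent
  and bottom be-creative nodes non-informative in instruction-specific
  analyses.
* **Raters**: both raters score the same generated pool through the model
  with independent node-level noise and offsets (0, −0.3), which yields a
  realistic average-measures reliability (ICC(2,2) ≈ 0.7 at the defaults).
* A mandatory seed makes every study byte-reproducible;
  `make_fixture_suite` writes the four canonical fixtures (unidimensional;
  node-multidimensional r = 0.7; fluency-split r = 0.7; exaggerated sparse
  nodes) with their ground truth.

### What the generator does and does not emulate

It reproduces the design counts, instruction-dependent fluency and
sparsity, rater disagreement, and the latent correlation structures the
models posit.  It does **not** simulate idea texts, serial-order or
practice/exhaustion effects, administration order, rater-by-node
interactions, or any miscalibration of the logistic link — so passing
recovery tests demonstrates that the pipeline is correct and well
calibrated *under its own assumptions*, not that those assumptions hold
for any particular real data set.

## Numerical choices and edge cases

* Logistic probabilities via tanh and log-likelihoods via `logaddexp`;
  category probabilities sum to 1 within 1e−12 by construction.
* An empty sub-item table with an explicit design is a prior-only fit
  (used to verify the sampler reproduces its priors); an empty table
  without a design is an error.
* `collapse_from_subitems` validates the tree pattern (contiguous nodes,
  at most one terminal failure) and names the offending group.
* The perfect-agreement ICC case (zero error mean square) returns a
  degenerate interval instead of dividing by zero.
* LOO refuses fits with fewer than 25 total draws (unstable Pareto tail
  fit).
* Problem sizes in the tests are chosen for desk-scale runs: recovery at
  N = 300 persons with 5 replicates, model-selection behavior at 10
  replicates per condition, exact-refit LOO on a ≤ 60-observation study
  with a 3-point scale.

## Known limitations

* The sampler is specialized to Rasch-type sequential logistic trees; it
  would need new conjugate updates for discrimination parameters or
  non-linear trees (both out of scope).
* No maximum-likelihood path is provided.
* Latent correlations at the default draw counts carry Monte-Carlo error
  of a few hundredths; studies needing tighter summaries should raise
  `kept_draws`.
* Comparisons across different data subsets (e.g., between instructions)
  are deliberately unsupported: LOO differences are only defined on
  identical observation sets.
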