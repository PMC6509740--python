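# treequal

**IRTree dimensionality analysis of snapshot creativity ratings.**

Divergent-thinking tasks ("name unusual uses for a brick") are often scored
by *snapshot rating*: a rater reads a person's whole pool of ideas and
assigns one holistic creative-quality rating on a 5-point Likert scale.
That single number hides two dimensionality questions that decide whether
the scale measures what it claims to:

1. **Across scale points** — is the ability that lifts a pool from a 1 to a
   2 the same ability that lifts it from a 4 to a 5 (the *ordinal
   hypothesis*)?
2. **Across pool sizes** — do low-fluency and high-fluency pools reflect
   the same latent creative quality?

`treequal` answers both with **IRTree models**: the ordinal rating is
decomposed into the M−1 sequential binary nodes of a linear response tree
("does this pool beat category r?"), each node modeled as a Rasch-type
logistic sub-item,

    P(Y*_pir = 1 | theta_p) = exp(theta_pr + beta_ir) / (1 + exp(theta_pr + beta_ir))

with person traits `theta`, item-by-node thresholds `beta`, and a rater
fixed effect.  Fitting the same sub-items with different latent structures
— one trait for the whole scale, one trait per node, or separate
low/high-fluency traits — and comparing the fits with approximate
leave-one-out cross-validation (PSIS-LOO, deviance scale, ΔLOO =
LOO(uni) − LOO(multi)) turns each dimensionality question into a model
comparison.  The posterior correlations among node traits quantify *how*
unidimensional the scale is.

The package is aimed at psychometricians and creativity researchers.  It
contains the full pipeline: data types and CSV I/O, dendrification, the
sequential tree model, a Polya-Gamma Gibbs sampler (no external MCMC
backend required), PSIS-LOO comparison, ICC(2,2) inter-rater reliability,
fluency median splits, the two study batteries, and a synthetic-study
generator so every stage is testable without any data download.

## Worked example

```python
from treequal import SyntheticConfig, generate_study, icc_2_k
from treequal.study_pipeline import pooled_rating_matrix

table, truth = generate_study(SyntheticConfig(seed=7))
icc, (lo, hi) = icc_2_k(pooled_rating_matrix(table))
print(len(table), round(icc, 3))
```

Running `python examples/02_simulate_study.py` (the same computation with
commentary) prints:

```
3984 rating rows (249 persons x 8 items x 2 raters)

be_creative: mean fluency 7.0, rating distribution {1: 0.001, 2: 0.279, 3: 0.376, 4: 0.256, 5: 0.089}
be_fluent: mean fluency 11.1, rating distribution {1: 0.412, 2: 0.341, 3: 0.19, 4: 0.057}

inter-rater reliability ICC(2,2) = 0.669, 95%-CI [0.636, 0.699]
(absolute agreement of the two raters' averaged scores across pools)
```

Reading the numbers: the design is 249 × 8 × 2 = 3,984 rating rows;
be-fluent instructions produce larger pools (mean ≈ 11 ideas vs. 7) with
ratings squeezed toward the bottom of the scale (no 5s at all in this
draw), while be-creative pools almost never receive a 1 — the
instruction-dependent sparsity that later starves one tree node per
instruction.  The ICC(2,2) of ≈ 0.67 says the two simulated raters agree
well on averaged scores.

The other examples walk through the remaining capabilities, each printing
its result with a line of interpretation:

* `examples/01_dendrify.py` — ratings to binary sub-items and back,
* `examples/03_fit_and_recover.py` — node-multidimensional fit recovering
  generating correlations,
* `examples/04_model_comparison.py` — PSIS-LOO adjudication between
  latent structures,
* `examples/05_full_study.py` — both batteries end to end.

A thin CLI wraps the pipeline for shell use:

```bash
treequal simulate --out study.csv --seed 3
treequal icc --input study.csv
treequal run --input study.csv --battery all --seed 1 --out reports/
```

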