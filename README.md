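# prostasig

Tools for studying **converging prognostic gene signatures in prostate
cancer**. Expression-based prognostic signatures for prostate cancer rarely
share genes, yet a few — derived by entirely different routes (latent
admixture modelling, NMF of pathway activation, cell-cycle biology,
HES6/androgen-receptor biology) — overlap far beyond chance. This package
implements the analysis chain used to find and exploit such convergence:

* **Pathway activation scoring** — for a gene set *S* and sample *t*,

  ```
  Z(t,S) = ( mean_S(x_t) − mean(x_t) ) / ( sd(x_t) / √|S| )
  ```

  the one-sample z-statistic of the set mean against the sample-wide
  expression distribution.
* **Consensus-NMF subgrouping** — the pathways × samples z-score matrix is
  factorised (X ≈ WH, multiplicative Frobenius updates) from many random
  restarts; samples are co-clustered by their argmax H factor; the number of
  subgroups is the rank (2–6) whose consensus matrix has the highest
  cophenetic correlation. A bagged-tree classifier (5001 trees, per-tree
  down-sampling to the smallest class) transfers the labels to new cohorts.
* **Signature overlap statistics** — upper-tail hypergeometric tests of
  gene-set overlap in an explicit universe (log-space, safe far below
  p = 1e-300), moderated-t differential expression with an empirical-Bayes
  variance prior (FDR < 0.001 and fold change > 1.4), Benjamini–Hochberg
  adjustment, and a sample-level GSEA along a continuous ranking.
* **Composite risk stratification** — four high-risk calls per patient
  (DESNT: admixture proportion γ strictly maximal; NMF1 subgroup; Prolaris-
  style cell-cycle score top quartile; HES6-signature classifier), their
  16-cell intersection table, Kaplan–Meier curves, log-rank tests,
  time-to-25%-events, and Cox models with Gleason score as covariate.
* **Synthetic cohorts** — a generator that emulates the assumed structure
  (three pathway-activation subgroups, Dirichlet γ admixture with a
  DESNT-like component, subgroup-linked DE genes, exponential recurrence
  with independent censoring) so the whole pipeline is testable end to end
  without patient data.

## File formats

| file | schema |
| --- | --- |
| expression TSV | header = sample IDs, first column = gene IDs, tab-separated floats |
| GMT | per line: set name, description, tab-separated gene IDs |
| clinical TSV | sample_id, time (months to biochemical recurrence), event (0/1), gleason, cohort |
| gamma TSV | sample_id, one column per latent signature (rows sum to 1; one column named DESNT) |

## Worked example

```python
import pandas as pd
from sklearn.metrics import adjusted_rand_score
import prostasig as ps

cfg = ps.SimConfig(seed=1)                      # 2000 genes x 300 samples
expr, clinical, truth = ps.generate_cohort(cfg)

z = ps.score_pathways(expr, truth.pathway_sets) # 14 x 300 activation z-scores
X = ps.nonneg_transform(z)
best, coph = ps.select_rank(X.to_numpy(), ranks=range(2, 7), n_runs=30, seed=0)
print("cophenetic by rank:", dict(coph.round(3)))
print("selected rank:", best)

fit = ps.nmf(X.to_numpy(), rank=best, seed=0)
labels = ps.assign_subgroups(fit, sample_ids=list(z.columns))
print("ARI vs generative subgroups:",
      round(adjusted_rand_score(truth.subgroup, labels.labels), 3))

flags = pd.DataFrame({
    "desnt": ps.assign_desnt(truth.gamma_true),
    "nmf1": ps.align_labels(labels.labels, truth.subgroup) == 1,
    "prolaris": ps.prolaris_flag(ps.prolaris_score(
        expr, ps.GeneSet("CCP", frozenset(truth.de_genes[1][:31])))),
    "hes6": truth.subgroup == 1,
})
res = ps.stratify_interaction(flags, clinical)
print(res.strata_summary)
```

prints

```
cophenetic by rank: {2: 0.995, 3: 1.0, 4: 0.999, 5: 0.997, 6: 0.996}
selected rank: 3
ARI vs generative subgroups: 1.0
              n  events  time_to_25pct_events
stratum
neither     152      49             19.245816
desnt_only   48      23             11.266206
hes6_only    72      44              7.085802
both         28      19              3.792074
```

The cophenetic coefficient peaks at rank 3, recovering the three generative
subgroups exactly; patients flagged high-risk by both the DESNT rule and at
least one SIG-HES6-family biomarker reach 25% recurrences after 3.8 months,
against 19.2 months for patients flagged by neither — the interaction the
composite stratification is designed to expose. The accompanying Cox model
estimates a hazard ratio of 1.44 per additional positive biomarker with
Gleason score as covariate.

A CLI mirrors the library (`prostasig simulate | score | subgroup | overlap
| de | gsea | stratify`); see `prostasig --help`.

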