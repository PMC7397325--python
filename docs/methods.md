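# Methods

This note documents the statistical machinery implemented in `prostasig`,
the design decisions taken where conventions diverge, and what the
synthetic cohorts do and do not establish.

## Cohort assembly and normalisation

Expression matrices are assumed to arrive on a log-like scale with
platform-level preprocessing (RMA, loess, variance stabilisation, batch
correction) already applied; those steps are upstream of this package.
The assembly helpers implement the meta-analysis conventions:

* **Duplicate-probe collapse** keeps, per gene, the probe with the highest
  mean expression across samples; mean ties keep the probe earliest in
  input order (deterministic "keep first").
* **Median centring** subtracts each gene's across-sample median (standard
  mid-mean median for even n).
* **Quantile normalisation** maps each column onto the mean of the order
  statistics across columns; within-column ties receive the mean of their
  tied reference quantiles. The published pipelines this mirrors do not
  spell out tie handling; this is the convention of the standard algorithm.
  The order of operations is fixed as median-centre **then**
  quantile-normalise.
* **Cohort merging** intersects gene IDs and concatenates samples, logging
  per-input gene losses.

## Pathway activation score

For gene set S and sample t, with x_t the sample's expression vector over
all measured genes,

Z(t,S) = (mean of x_t over S − mean of x_t) · √|S| / sd(x_t).

Conventions: sd uses the n−1 divisor (configurable via `ddof`); the
sample-wide mean and sd include the genes of S; genes of S absent from the
matrix are dropped and |S| reduced accordingly — the only reading that
keeps the score defined after cross-platform merging. The score is
location- and scale-invariant per sample, so cohorts on different
intensity scales remain comparable.

## Consensus NMF and rank selection

Activation z-scores carry sign, but NMF needs nonnegative input. Each
pathway row r is split into max(r, 0) and max(−r, 0) (a 2P × N matrix);
this preserves sign information exactly and adds no arbitrary offset.

The factorisation X ≈ WH minimises the Frobenius loss with Lee–Seung
multiplicative updates (max 2000 iterations, relative-change tolerance
1e-6, uniform random initialisation scaled to the data magnitude). The
objective trace is recorded and is non-increasing by construction; the
test suite asserts it on every run. The multiplicative-update variant with
Frobenius loss was chosen over the Kullback–Leibler variant because its
monotonicity and rank-1 recovery make it directly testable against
closed-form oracles; the variant is a documented, configurable choice, not
a claim about which variant other implementations default to.

For each candidate rank (2–6 by default) the factorisation is repeated
from 30 random restarts; samples are assigned to their argmax H factor and
the consensus matrix records co-assignment frequencies. The cophenetic
coefficient is the Pearson correlation between the consensus distances
(1 − consensus) and the cophenetic distances of their average-linkage
hierarchical clustering; the selected rank maximises it, with ties broken
toward the smaller rank. A constant consensus-distance matrix (nothing to
mismatch) is defined to have coefficient 1. All argmax ties break toward
the lowest index for determinism.

## Subgroup and HES6 classifiers

Label transfer uses a random-forest-style ensemble of CART trees
(`sqrt`-feature subsampling). Each tree is grown on a bootstrap formed by
sampling, with replacement, min-class-size samples *from every class*, so
class imbalance never tilts the vote. The default ensemble size is 5001
trees. Out-of-bag votes give the accuracy estimate and per-class
one-vs-rest AUCs. The same machinery serves both the pathway-score
subgroup classifier (14 features) and the HES6-signature classifier
(expression features of the signature's genes, two classes).

## Overlap, differential expression, enrichment

* **Hypergeometric overlap**: both sets are intersected with an explicit
  universe (default: the genes of the analysis matrix) before testing;
  p = P(X ≥ k) for X ~ Hypergeom(N, m, n), evaluated via the log survival
  function. `log10_p` is reported alongside `p` because converging
  signatures can reach tail probabilities far below the smallest positive
  float. The universe matters: results are not comparable across different
  universes, which is why the CLI requires one explicitly.
* **Moderated t**: one-vs-rest per subgroup. Per-gene pooled variances are
  shrunk toward an empirical-Bayes prior whose degrees of freedom d0 and
  scale s0² are estimated by the method of moments on the log variances
  (inverse-trigamma solve; d0 floored at 1, capped at 1e6). The moderated
  statistic has d0 + n1 + n2 − 2 degrees of freedom. Setting the prior df
  to zero recovers the ordinary pooled t exactly; the suite also verifies
  the full estimator against limma's `eBayes` on a shared fixture
  (agreement to 1e-8). Significance requires BH-adjusted p below the FDR
  threshold **and** linear fold change above the cut (|Δlog2| >
  log2(1.4)); the FDR default is 0.001 and is a parameter, since published
  descriptions of this analysis vary between 0.001 and 0.0001.
* **GSEA (sample-level)**: samples are ranked by a continuous score (e.g.
  DESNT γ); the running sum gains |score|^w (w = 1 by default, w = 0 for
  the classic Kolmogorov–Smirnov form) at members and loses 1/(N − N_hit)
  elsewhere; ES is the signed extreme deviation. The permutation null
  redraws member sets of equal size (default 10,000 permutations, +1
  pseudo-count).

## Risk rules and survival analysis

* **DESNT**: flagged when the DESNT γ is *strictly* larger than every
  other latent signature's γ; ties and uniform rows are not DESNT.
* **Prolaris-style score**: mean within-sample z-score of the cell-cycle
  genes; exactly ⌈0.25·N⌉ samples are flagged, boundary ties resolved by
  score then sample ID (logged) so the count is reproducible.
* **Stratification**: DESNT × (any of NMF1 / Prolaris / HES6) defines four
  strata; which biomarkers count as the SIG-HES6 family is a parameter
  (default: all three). Pairwise log-rank tests between non-empty strata
  are BH-adjusted; each stratum reports the smallest event time at which
  the Kaplan–Meier curve drops to ≤ 0.75 ("time to 25% events"; undefined
  — NaN — if never reached). A parallel breakdown by number of positive
  flags (0–4) feeds a Cox model of that count with Gleason as covariate.
* Kaplan–Meier, log-rank and Cox fits are delegated to lifelines; Cox uses
  Efron tie handling and Wald 95% intervals. Months are the time unit
  throughout, with biochemical recurrence as the endpoint.

## Synthetic cohorts

`SimConfig` defaults define the reference study conditions: 2000 genes ×
300 samples; 14 disjoint 40-gene pathways; three near-balanced subgroups,
each over-activating its own block of pathways by 1.0 within-sample SD;
100 DE genes per subgroup shifted by 1.0 log2 unit; four latent admixture
signatures with Dirichlet(0.5) per-sample proportions γ (first designated
DESNT), each loading on a dedicated 50-gene block with effect γ × 1.0 SD;
exponential recurrence with log-hazard log(0.01/month) +
(1.2, 0.0, 0.3)[subgroup] + 1.5·γ_DESNT; independent exponential censoring
with its rate matched to the mean hazard so that roughly half of the
cohort is censored. Gleason grades 6–10 are drawn with a distribution
skewed toward high grade in the poor-prognosis subgroup. Gene/pathway
identifiers are fixed lexicographic fixtures (G000001…, PW01…). All draws
come from one seeded generator, so identical configurations are
bit-identical.

What the simulator deliberately omits: overlapping pathway memberships,
probe/batch artefacts, platform effects, correlated gene–gene noise,
non-proportional hazards, informative censoring, and any dependence
between γ and subgroup. Consequently, passing tests demonstrate that the
pipeline recovers structure *of the assumed form*; they are not evidence
about real prostate-cancer cohorts, where separation is weaker and the
listed complications all apply.

## Problem sizes used in checks

The end-to-end checks run at the reference conditions above: rank
selection with 30 restarts per rank on the 28 × 300 nonnegativised score
matrix; classifier evaluation with 5001 trees (201–501 where the
classifier is incidental to the property under test); Cox recovery at
n = 2000 over 20 replicates; permutation oracles at 10⁵ draws; exhaustive
hypergeometric enumeration for universes up to 15 genes. The
stratification-ordering property is evaluated over 20 independent cohorts;
at the reference conditions its weakest comparison (DESNT-only vs neither,
a hazard ratio near 2 at stratum size ≈ 45) inverts in roughly one cohort
in ten, so agreement counts near 18/20 are the expected behaviour, and
the shipped suite reports the observed count against that bar.

## Known limitations

* The 14 pathway definitions and published signature gene lists are not
  distributed; real-data use requires supplying them as GMT. Shipped
  fixtures are synthetic stand-ins.
* γ proportions are an input (produced upstream by admixture modelling);
  this package does not fit the admixture model itself.
* The hypergeometric universe is a modelling choice with large leverage on
  overlap p-values; no default can make cross-study p-values comparable.
* The Prolaris rule here is the population-quartile version; it cannot be
  applied to a single new sample without a reference cohort.
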