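# Methods

## Model and assumptions

The package treats a predicted functional-coupling network as a static
*backbone* of possible interactions and asks which of them are active under
which experimental condition.  Expression values are log10 sample/reference
ratios from a universal-reference two-channel design; the analysis assumes a
full factorial layout of 2 treatment arms × 5 days with ≥ 2 (nominally 4)
independent replicates per cell, and tolerates one missing array (the
canonical design drops one treated day-2 replicate, leaving 39 samples).
Replicates are assumed independent between weeks; within-array correlation
structure is not modeled.

Co-expression is measured by the Pearson correlation (PLC) of two genes'
profiles.  Condition-specific coupling is *defined* by the conjunction of a
correlation contrast (high in one condition, absent in the other) and mean
structure detectable by ANOVA: the GENE × TREATMENT (or the triple)
interaction requires the two genes' mean responses to the treatment to
differ.  A correlation change with perfectly parallel means is deliberately
not called enabled/sensitive — without the interaction evidence it cannot be
distinguished from shared nuisance variation.

## ANOVA implementation

Both the per-gene 2-way fit and the per-link 3-way fit are ordinary
fixed-effects least squares computed by projection: for each model in a
nested sequence the residual sum of squares is obtained from a precomputed
residual-maker matrix (I − X X⁺), and Type II sums of squares are
differences of RSS between models with and without the term of interest,
with F-tests against the full-model residual.  This reproduces
`statsmodels` `anova_lm(typ=2)` to machine precision (asserted in the test
suite) while being vectorizable across thousands of genes sharing one
design, and correct under the mild imbalance of the degraded replicate.
Per-day contrasts use the treated-vs-control cell-mean difference within the
day, with the pooled residual variance and df of the full model — the most
powerful option at n = 4 replicates.  Degenerate inputs follow documented
conventions: an all-constant profile reports F = 0, p = 1, variance
fractions 0; correlations over < 3 complete pairs (10 per condition for link
classification) or constant vectors return none, and such links fall into
the `none` class.

Missing values are dropped pairwise (correlations) or listwise per gene/link
(ANOVA, falling back to a per-profile design when a gene has gaps).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.01 | significance for gene contrasts and link interactions |
| `plc_high` | 0.75 | PLC floor for "co-expression present" (p < 0.01 at n = 39) |
| `plc_low` | 0.5 | PLC ceiling for "co-expression absent" |
| `fbs_min` | 3.0 | backbone confidence floor |
| `chi_min` | 6.64 | GO–GO χ² threshold = 1-df 0.99 quantile |
| `o_min`, `e_min` | 3, 0.5 | observed / expected count floors for GO–GO edges |
| `max_size` | 130 | module growth cap |

`plc_low` sits midway between the absent-side example value (~0.13) seen in
reference data and `plc_high`; it is deliberately conservative and exposed
as a parameter.  The PLC thresholds are on the correlation scale
(dimensionless); effect sizes throughout are log10 ratios.

## Module discovery

The clustering objective is the hypergeometric upper tail of the module's
DEL edge count among its induced backbone edges.  Growth is greedy from
every DEL seed edge, adding the neighbor that most decreases the p-value;
ties break to the lexicographically smallest gene id, making discovery
deterministic.  Adding a node with only non-DEL incident edges can only
increase the tail probability, so growth stops at locally coherent DEL
neighborhoods.  Candidates overlapping at node Jaccard > 0.5 merge (better
p wins) and survivors pass BH at q < 0.05.  The PN polarity additionally
requires at least one internal enabled and one internal sensitive link.
This is a from-scratch design chosen for determinism and testability; the
historical in-house tool it conceptually follows was never described, so no
equivalence is claimed, and real-data module counts from that tool are not
comparable.

## GO–GO expected counts

For a day pattern a→b the observed table O_ij counts links with one
endpoint first-DE on day a in category i and the other on day b in category
j (multi-annotated genes count once per category).  Marginals N_i(a),
N_j(b) and the total T are read off the observed table, giving the
independence expectation E_ij = N_i(a)·N_j(b)/T, which reproduces the
observed total in aggregate (ΣE = ΣO) by construction.  Same-day tables are
built ordered-and-symmetric then halved — off-diagonal E = N_i·N_j/(2T),
diagonal E = N_i²/(4T) — the one halving convention that preserves
ΣE = ΣO exactly; links between genes first-DE ≥ 2 days apart belong to no
pattern and are discarded.  GO assignment uses direct annotations by
default; an ancestor-propagation mode (true-path rule) is available when an
ontology graph is supplied.

## Synthetic data: what it emulates, and what it does not

`synthetic.simulate_dataset` generates
`value = baseline(g, day) + effect(g)·[treated ∧ day ≥ first_de_day(g)] +
λ·Z_set(sample)·[condition active] + noise`, with per-gene random-walk day
baselines (step sd 0.15) so developmental variance dominates, Gaussian
measurement noise (sd 0.05), and a shared per-sample latent factor
(λ = 0.15) switching on within one condition for each planted gene set —
giving within-condition PLC ≈ λ²/(λ² + σ²) ≈ 0.9 at the defaults.  Planted
co-expression genes carry damped baselines and effect sizes spread over
±[0.2, 1.6] log10 with alternating signs, so every planted pair genuinely
satisfies the enabled/sensitive definition (condition-specific correlation
*and* gene-specific response).  Propagation truth assigns dedicated GO
categories to flow genes of degree ≤ 3 with a diffuse background of randomly
scheduled genes, because meta-flow enrichment is measured against exactly
that background.

The generator does not emulate probe effects, dye bias, intensity-dependent
variance, correlated replicate batches, or hub-dependent co-expression; a
passing recovery test therefore demonstrates correctness of the inference
chain under the stated generative model, not performance on microarray data
with those artifacts.

## Problem sizes and numerical choices

Recovery and calibration experiments run at 300–600 backbone genes with 2–6
planted sets or 2 flows, sizes at which every planted structure is
identifiable yet each experiment completes in seconds; the acceptance script
uses 1000 genes for null calibration (5000 contrast tests).  All stochastic
stages take explicit integer seeds and are bit-reproducible; the pipeline
manifest records parameters, seeds, package versions, and input SHA-256
checksums.  Bootstrap CIs for variance fractions resample replicates within
design cells (default 1000 resamples).  Permutation FDR strata are
(day, replicate) pairs, preserving the day structure while exchanging
treatment labels; the permutation p for linkage statistics uses the
add-one estimator (1 + #null ≥ obs)/(1 + draws), so it is never zero.

## Known limitations

* Enabled/sensitive calls require the ANOVA interaction gate; condition-
  specific correlation with identical mean responses is intentionally
  invisible.
* The greedy module search is locally optimal only; a globally better
  module containing no improving single-node path will be missed.
* Gene-level p-values are uncorrected by design (downstream network
  statistics provide error control); the per-gene DE lists should not be
  interpreted marginally.
* The GO–GO expectation conditions on the observed pattern marginals; very
  sparse patterns (T close to the planted count) make E ≈ O and suppress
  detection, which is the correct conservative behavior but limits power in
  small studies.
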