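# Methods

This note documents the models and procedures implemented in `netmark`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## The two-cycle consensus design

The pipeline nominates a biomarker only when three independent lines of
evidence coincide: differential expression in the tumor, the same-
direction change in the patient's PBMCs, and topological centrality in a
network of established cancer-signature genes. The first cycle is purely
network-based and needs no expression data; the second is purely
expression-based; the intersection is what makes the call specific. An
empty intersection is a valid outcome and the orchestrator reports it as
such (downstream, seed-dependent stages are then skipped unless a seed
gene is forced).

## Differential expression (`netmark.dge`)

Per gene, a two-sided Welch t-test on log2 expression; logFC is the
difference of group means (so it is a log2 fold change for log2 input).
P-values are Benjamini–Hochberg adjusted across all genes, and a gene is
significant iff |logFC| > 0.5 (strict) and adjusted P < 0.05 — both
criteria jointly, the cut applied to both directions. Welch rather than a
moderated (empirical-Bayes) statistic is a deliberate, documented
substitution point: it is self-contained, assumption-light, and `test_gene`
is the single function to swap if variance shrinkage is wanted. Degenerate
input (zero variance in both groups) yields P = 1 for equal means and 0
otherwise.

## Network topology (`netmark.topology`)

Betweenness is the classic Brandes count: unnormalized, endpoints
excluded, each unordered source–target pair counted once; disconnected
graphs contribute per component. The fat-tail check fits
log(frequency) ~ log(degree) over observed positive degrees by least
squares and reports R²; an all-equal frequency vector (zero-variance
response) is defined as R² = 0, and fewer than 3 distinct positive
degrees is an error.

Central-gene selection unites two rules. The betweenness tier uses a
tail-inclusive quantile: the cutoff is the smallest value such that at
least ceil(q·n) nodes lie at or above it, and ties at the cutoff are
included — with one exception: nodes of betweenness exactly 0 are never
"high betweenness", since they mediate no shortest paths (otherwise any
star-like periphery would tie its way into the tier). The hub rule is
either top-k by degree (ties broken by symbol, deterministic) or a fixed
degree threshold, which may be fractional; a threshold that selects
nothing produces a warning and an empty hub set rather than an error.

## Consensus (`netmark.consensus`)

Shared DEGs are genes significant in both compartments; with several
datasets per compartment, significance-in-all (default) or -in-any is
supported. Direction agreement is required by default — a biomarker
claimed to be shared should move the same way in tumor and blood. The
intersection with the central set carries a per-gene provenance record
(significance, directions, hub / high-betweenness membership) so every
consensus decision is auditable from the output table alone.

## Co-expression module inference (`netmark.coexpr`)

The ARACNE recipe with a verifiable estimator:

- **MI estimator.** Plug-in MI on an equal-frequency B×B contingency
  table, ranks taken with a stable sort (deterministic tie handling).
  The automatic bin count is the Sturges rule B = floor(log2 n) + 1.
  The plug-in estimator is biased upward by roughly (B−1)²/(2n) nats;
  with B ~ sqrt(n) that bias is O(1) and overwhelms both the
  independence baseline and DPI's multiplicative tolerance, whereas with
  Sturges bins it vanishes as n grows. An explicit `n_bins` overrides the
  rule. Closed form for testing: a bijection maps to a diagonal table,
  MI = log B exactly when B divides n.
- **Threshold.** For up to `max_null_pairs` (default 30) randomly chosen
  gene pairs, sample labels of one member are permuted `n_permutations`
  times each; the threshold is the (1−alpha) quantile of the pooled null
  MIs, taken with the upper-bounding interpolation so the null pass rate
  stays at or below alpha. This is assumption-free and directly
  calibratable, unlike an analytic null fit.
- **DPI.** In every triangle, edge (i,j) is marked when
  MI(i,j) < min(MI(i,k), MI(j,k))·(1−ε), ε = 0.1 by default (within the
  commonly recommended 0–0.2 band). Marks are computed against the
  original weights and applied after the full scan, so the result is
  independent of edge order.
- **Module.** The seed gene plus its first neighbors in the pruned
  network. This definition is meaningful because DPI removes mediated
  edges: in a module driven by a regulator, member–member edges are
  exactly the indirect ones, leaving a star around the driver.

## Enrichment (`netmark.enrich`)

One-sided Fisher exact test: P(X ≥ k) for X hypergeometric with
(universe N, term size K, query size n). The universe defaults to the
union of all library genes — the only background reconstructible from a
GMT file; query genes outside the universe are dropped with a warning.
Rows are BH-adjusted across the library, filtered to adjusted P < alpha,
and ranked by adjusted P then overlap size descending (the joint
"significance and maximal overlap" criterion). Depletion and combined
scores are out of scope.

## Survival (`netmark.survival`)

Median dichotomy of the stratifying gene's expression: strictly above the
median is "high", ties at the median go "low" (deterministic). A horizon
(e.g. 3 or 5 years) administratively censors all later follow-up before
estimation. The Kaplan–Meier estimator is the standard product limit over
distinct event times; the group comparison is the log-rank test
(chi-square, 1 df) and the hazard ratio is summarised from its
observed/expected table as (O₁/E₁)/(O₂/E₂) — the appropriate univariate
summary for a single-gene stratification, with Cox regression left as an
external cross-check rather than part of the contract. Note the O/E ratio
is mildly conservative (the simulation study in the test suite estimates
~1.9 for a true HR of 2 under 20% censoring).

## qPCR (`netmark.qpcr`)

Classic ΔΔCt with amplification efficiency fixed at 2: per sample
ΔCt = Ct_target − Ct_housekeeping, ΔΔCt referenced to the calibrator
group's mean ΔCt, fold = 2^(−ΔΔCt). Group summaries use the geometric
mean of folds — identical to 2^(−mean ΔΔCt) — because folds are
log-scale quantities; dispersion is the geometric SD factor. The
calibrator is configurable; the demo expresses both contrasts relative to
the primary-stage group. Groups are compared by Kruskal–Wallis
(tie-corrected H, chi-square P); the all-identical degenerate case is
defined as H = 0, P = 1.

## Synthetic data (`netmark.synth`)

Each generator draws from an RNG stream keyed by (seed, call name), so
outputs are bit-reproducible and adding calls never perturbs earlier
ones.

- **Expression**: gene baselines uniform on [4, 12] log2 units (a typical
  post-normalisation microarray range) plus Normal(0, noise_sd) noise,
  default noise_sd 0.5 log2 units; planted DEGs are shifted by
  ±planted_logfc (default 2) in cases. Defaults of 20 cases / 20 controls
  reflect small GEO series.
- **Network**: Barabási–Albert preferential attachment (2 edges per new
  node by default); planted hubs are the top-k degrees with symbol
  tie-break, the same deterministic rule the topology stage uses.
- **Co-expression**: a per-sample latent factor z ~ N(0,1); the seed gene
  measures z at loading 1 with residual SD noise_sd/2, members load at
  `module_loading` (default 0.9) with residual SD noise_sd. The seed is
  deliberately the module *driver*: member–member dependence is then
  mediated by the seed, which is precisely the structure DPI prunes to a
  star and the first-neighbor module definition recovers. With equal
  loadings for all members including the seed, the pruned module is an
  arbitrary spanning tree and no neighborhood definition could recover
  it.
- **Survival**: exponential event times with hazard
  baseline·exp(beta·1[expression > median]); censoring is
  administrative-uniform on [0, 2/baseline] applied to a `censor_rate`
  fraction of subjects, the simplest mechanism satisfying independent
  censoring.
- **qPCR**: housekeeping Ct ~ N(20, 0.25) cycles and target Ct offset by
  the planted group shift, 0.25 cycles being the usual order of technical
  Ct variability. The demo shifts (primary +1.38, metastatic −3.25
  relative to healthy) plant fold changes of 2^4.63 ≈ 24.8 and
  2^1.38 ≈ 2.6 against the primary-stage calibrator.

What the generators do **not** emulate: probe-level artifacts,
normalisation residuals, batch effects, gene-length/GC bias, correlated
null genes, non-proportional hazards, or qPCR efficiency drift. Passing
tests therefore demonstrate the correctness and calibration of the
algorithms under their stated models, not robustness to every real-data
pathology.

## The bundled demo

`make_demo` builds a self-consistent dataset: a 200-gene scale-free
network; the top hub aliased to CCNB2 and planted as an up-regulated DEG
in both compartments (15 case / 15 control per compartment); a second
shared DEG aliased to PGK1 planted on a verified non-central node; ~8
extra compartment-specific DEGs each; a 40-gene co-expression matrix (120
samples) with a 10-gene module around CCNB2; a 160-subject survival table
with a planted HR of 2 on CCNB2; an 8-per-group three-group Ct table; and
a synthetic GMT library whose first term contains 90% of the planted
module. The gene aliases are cosmetic only — symbols, not biology.

## Numerical and degenerate-case conventions

- MI cell terms are summed in sorted order, making mi(x,y) and mi(y,x)
  bitwise equal; marginals come from per-vector bin counts for the same
  reason.
- BH adjustment validates inputs to [0,1] and clips at 1.
- Significance comparisons are strict (<, >) where the rule says
  "more than"/"less than".
- Problem sizes in the test suite and acceptance script (e.g. 500-node
  networks, 300-sample co-expression matrices, 200–500 simulation
  replicates) are chosen so each statistical check has comfortable power
  while the whole suite remains a desk-scale computation.

## Known limitations

- Welch t lacks the small-sample power of moderated statistics; at n < 5
  per group sensitivity drops accordingly.
- The MI permutation threshold is a global (not per-pair) null; strongly
  non-uniform marginal distributions across genes would make it
  conservative for some pairs.
- The O/E hazard-ratio summary attenuates toward 1 relative to a Cox
  estimate; confidence intervals are not provided.
- First-neighbor module extraction is one reasonable delimitation of a
  co-expression module; other definitions (communities, cliques) are out
  of scope.
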