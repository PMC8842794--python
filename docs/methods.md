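# Methods

## Scope and model of the analysis

pertnet implements the dry-lab chain of a drug-repositioning study: a small
treated/control expression experiment is screened for differentially
expressed genes (DEGs); DEGs are characterized by gene-set
over-representation and preranked GSEA; the tendency of a focal pathway
module's products to interact with the other DEGs is tested on a PPI
network against randomized networks; an independent tumor/normal cohort is
screened the same way and intersected with the drug signature; cohort
survival is regressed gene-by-gene with Cox models; and transcription
factors/cofactors are ranked and filtered into candidate upstream
regulators. Every stage is a pure function over explicit inputs, and every
stochastic stage takes one integer seed.

## Differential expression

**Intensity design.** The screen is the classical two-sample pooled-variance
Student *t* on log2 intensities, two-sided. Fold change is linear,
FC = 2^(mean_b − mean_a), with direction relative to the treated group. The
DEG filter is inclusive at both thresholds (p ≤ p_max, FC ≥ fc_min or
≤ 1/fc_min; defaults 0.05 and 1.5). The fold-change cutoff is interpreted on
the linear scale and applied symmetrically; a flag would let a user move it
to the log2 scale, but the linear reading is the default because both up-
and down-regulation are reported against the same 1.5× bar. Zero-variance
genes: equal group means give t = 0, p = 1; unequal means with zero pooled
variance are flagged `degenerate`, excluded from testing (NaN statistics)
and counted in the log — they can never become DEGs. Probe-level tables
collapse to one row per gene by smallest raw p, ties broken by larger
|log2 FC| then lexicographically smallest probe id, so output is
deterministic.

**Count design.** Cohort counts are normalized by median-of-ratios size
factors (geometric-mean reference over genes expressed in every sample),
rescaled to the raw library-size scale, then transformed to
log2 CPM + 0.5. Plain total-count CPM is deliberately not used: when a
sizeable fraction of genes truly changes in one group, total counts shift
and every unchanged gene acquires a spurious opposite shift (the
composition effect); the median ratio is robust to it, which is the same
reason count-GLM packages apply TMM-style effective library sizes. Testing
is per-gene Welch *t* with Satterthwaite degrees of freedom and
Benjamini–Hochberg adjustment; DEG at FDR ≤ 0.05 (inclusive). This
moderated-free procedure is adequate at cohort group sizes (tens to
hundreds); it is not meant for 3-vs-3 count designs.

**Multiple testing.** All FDR adjustment in the package is
Benjamini–Hochberg step-up, capped at 1 (delegated to statsmodels; an
independent step-up implementation verifies it in the tests).

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) with the universe N equal to the genes actually measured — not all
annotated genes — because the query can only ever be drawn from the
platform. Sets enter testing only with overlap ≥ 5 (filtering precedes
testing), and significance is either FDR < 0.05 or raw p < 0.05, selectable
per collection; both thresholds are strict, matching how such results are
conventionally reported.

Preranked GSEA ranks genes by log2 fold change (descending, gene name as a
deterministic tie-break). For a set S of K ranked genes out of N, walking
the ranking adds |r_i|^w / Σ_{S}|r|^w on a hit and subtracts 1/(N−K) on a
miss (w = 1 by default); ES is the signed maximum deviation of the running
sum, and the leading edge is the set members at or before (after, for
negative ES) the peak. The null is n_perm = 1,000 random same-size gene
sets — a gene-label permutation, the only option for a preranked input. NES
divides ES by the mean |null ES| of matching sign; the p-value is the
add-one tail proportion among matching-sign nulls, BH-adjusted across sets.
Sets with fewer than two ranked members, or spanning the entire ranking
(miss increment undefined), are skipped and logged. Note the permutation
floor: with ~500 matching-sign nulls the smallest attainable p is ~2×10⁻³,
so the BH-adjusted significance of even a perfect set depends on n_perm.

## Network module significance

Two statistics are computed with the node groups held fixed while the
network is the random object: (1) the number of edges running between the
focal (module) DEG group and the remaining DEGs, and (2) the order of the
largest connected component of the subgraph induced by the union of the two
groups. The default null is Maslov–Sneppen degree-preserving rewiring —
10×|E| attempted double-edge swaps per replicate, rejecting swaps that
would create self-loops or parallel edges — because module statistics must
be judged against graphs with the same degree sequence, not just the same
density; a uniform node-label shuffle is available for comparison, and the
result records which scheme produced it. Empirical p-values use the add-one
rule (1 + #{null ≥ observed}) / (1 + n_random): non-strict, so ties with
the null count against significance, and the smallest attainable p at
1,000 replicates is 1/1001. The swap loop is jit-compiled (numba) and
seeded per replicate from the master seed; the union-find LCC and the
vectorized cross-count make a 2,000-node, ~12,500-edge test with 1,000
replicates run in under a minute.

A caveat documented from the generator experiments: the union-LCC statistic
is informative only while the null's induced union subgraph stays below its
percolation threshold. A dense planted module inflates its nodes' degrees;
in degree-preserving nulls that degree mass is spread across the union, and
once the expected internal degree approaches ~2 the null LCC saturates near
the union size and ties erase significance. Concentrated excess wiring
inside a small union (the acceptance scenario) or low-density excess wiring
across the whole DEG set (the coherent study generator) both stay in the
informative regime; a dense island inside a large diluted union does not.

## Survival

The Cox screen is a univariate proportional-hazards fit per gene:
Newton–Raphson on the partial likelihood with the Efron correction for tied
event times, convergence at |Δβ| < 10⁻⁸ or 50 iterations, steps clipped to
±5 for stability. Monotone likelihoods (perfect separation) are flagged
non-converged and reported at the last iterate with a warning rather than
raised. The covariate enters as continuous expression standardized to unit
variance, so β is the log hazard ratio per SD; screening on the continuous
covariate and displaying a median split are kept distinct on purpose —
dichotomizing before testing discards information. "Survival-related" is a
strict Wald p < 0.05, in contrast to the inclusive DEG thresholds, because
that is how the classification is conventionally phrased. Kaplan–Meier
curves and the log-rank test are delegated to lifelines; the high group is
strictly above the median. An independent grid-search maximization of the
partial likelihood and lifelines' Efron fits verify the solver in the
tests.

## Integration

Cross-cohort concordance intersects the two direction-annotated DEG lists
and reports common-up, common-down, concordant and discordant sets under an
explicit mode: `same` counts genes moving in the same direction in both
contrasts (the bookkeeping convention for "common up/down" tallies),
`reversal` counts genes whose drug response opposes their tumor-vs-normal
direction (the signature-reversal reading). Both are first-class because a
drug study genuinely needs both views; the pipeline defaults to `same` and
always reports all four sets, taking no stance on the discordant genes.

The survival × drug-altered contingency is scored with a one-sided Fisher
exact test for over-representation of drug-altered genes among
survival-related ones; degenerate margins (empty or saturated sets) return
p = 1 with a warning instead of failing. The Fisher p equals the
hypergeometric upper tail on the matching urn, which the tests assert as a
cross-module consistency check.

Regulator nomination is a pure conjunction of four evidence rules — Cox
p < 0.05, hazard ratio > 1, up-regulated in the tumor table, down-regulated
in the drug table — with no invented scoring or weighting; a regulator
missing from any evidence table is excluded and logged as not evaluable.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of parameters and one integer seed.

* **Perturbation** (`simulate_perturbation`): per-gene baselines U(6, 12)
  log2 units, i.i.d. Gaussian noise (σ = 0.5 default), 3 vs 3 replicates,
  5% DE genes with lognormal fold-change magnitudes around 2 log2 units and
  a 76%/24% down/up sign split — the asymmetry typical of a
  growth-suppressing compound. It does not model probe effects, batch
  structure, or intensity-dependent variance.
* **Cohort** (`simulate_cohort`): negative-binomial counts (gamma–Poisson),
  lognormal gene base means, common dispersion 0.1, lognormal library-size
  factors (σ = 0.15), tumor multiplier 2^lfc on DE genes. An `lfc_of`
  override lets the study generator align cohort truth with drug truth. No
  gene–gene correlation, outlier samples, or clinical covariates.
* **Survival** (`simulate_survival`): exponential event times with rate
  base_hazard·exp(Σ β·z), administrative censoring at a fixed horizon —
  proportional hazards holds exactly, so recovery tests measure the
  estimator, not model misfit. Defaults (base hazard 0.1, horizon 20) give
  ~80–90% events.
* **Network** (`simulate_network`): Barabási–Albert preferential attachment
  plus a planted module wired to a target internal density. Real PPI data's
  annotation bias and hub correlations are not modeled.
* **Gene sets** (`simulate_gene_sets`): enriched sets draw a stated
  fraction of members from a designated DE list, the rest uniformly;
  background sets are uniform. Sizes ≥ 5 so the min-overlap rule is
  satisfiable.
* **Coherent study** (`simulate_study`): wires the five inputs into one
  scenario — cohort fold-changes follow the drug's for most genes and
  oppose it for a reversed fraction (default 30%) containing the planted
  regulator (tumor-up, drug-down, per-SD log hazard ratio 1.0); the two
  planted pathway sets draw from drug-down DE genes; excess network wiring
  is planted at low density (0.04) across all DE genes, keeping the
  degree-preserving null sub-critical (see the network caveat above);
  survival covers tumor samples only, since mixing normals would let the
  group contrast confound every DE gene into a survival signal.

Passing tests on these data demonstrate correctness of the statistics and
recovery under the stated generative assumptions; they do not certify
performance on real microarray or sequencing data, where normalization
artifacts, correlation structure and annotation bias dominate.

## Numerical and design choices

* Exact, case-sensitive gene-identifier matching everywhere; silent case
  folding hides mapping bugs.
* Directed interaction inputs are collapsed to an undirected simple graph
  before testing (both network statistics are orientation-free); dropped
  self-loops and merged duplicates are logged.
* Missing expression values fail fast naming the offending cell; no
  imputation.
* Probe-collapse, enrichment and regulator rankings all carry deterministic
  tie-breaks (documented above), so byte-identical outputs follow from
  identical config + seed; the pipeline writes all floats at fixed
  precision and verifies determinism by digest in the tests.
* The pipeline derives one sub-seed per stage from the master seed, so
  adding or removing a stage does not shift another stage's stream.
* Acceptance-scale problem sizes: the module-significance check runs a
  2,000-node background at mean degree ~12 (edges_per_node = 6, typical of
  curated interactomes) with 1,000 randomizations; calibration checks use
  200–300-node graphs and 99–200 randomizations, which already give the
  empirical-p resolution those checks need.

## Known limitations

* The count-DE stage has no dispersion moderation; very small cohort groups
  will be underpowered relative to GLM-based tools.
* GSEA significance is bounded by the permutation floor (~1/n_perm); deeply
  significant sets need larger n_perm, at linear cost.
* The union-LCC network statistic loses power outside the sub-critical
  regime described above; the cross-PPI count degrades more gracefully.
* No multivariable Cox, proportional-hazards diagnostics, or time-varying
  covariates; no GO-graph topology handling; no identifier conversion.
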