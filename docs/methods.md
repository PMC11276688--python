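# Methods

`ubipan` re-implements, as a tested pipeline, a pan-cancer multi-omics
workflow for characterizing ubiquitination regulation: differential
expression of E3 ligases and deubiquitinases (DUBs) across paired
tumor/normal proteomic cohorts, a cross-cohort regulatory atlas,
tissue-specificity clustering of samples, proteome-based E3–substrate
correlation analysis, a multi-omics screen for degradative ubiquitination,
topology-aware signaling pathway impact analysis (SPIA), and proteome-based
prognosis. Because the workflow is exercised on synthetic cohorts with
planted ground truth, every stage can be scored against known answers.

## Differential expression

Proteins missing in strictly more than 50% of samples are removed. The
remainder are completed by a three-method ensemble imputer — k-nearest
neighbour features (Euclidean distance over shared observed samples,
rescaled to the full sample count; k = 10), feature mean, and iterative
rank-5 SVD (50 iterations, tolerance 1e-4) — whose element-wise mean fills
each gap. Observed cells are never altered and imputing a complete matrix
is the identity. The ensemble is a deliberately small, dependency-free
design; a masking oracle in the test suite verifies it beats the row-mean
baseline on held-out cells whenever the data carry low-rank structure.
Imputation is performed jointly on tumor and normal samples of a cohort.

Paired cohorts are tested per feature with the Wilcoxon signed-rank test on
within-pair differences (exact for small n, normal approximation otherwise,
zeros dropped); unpaired designs use the Wilcoxon rank-sum test. log2FC is
the difference of group means on the log2 scale — the estimator is not
uniquely determined by convention, and means were chosen over medians.
Features with no variation yield p = 1 by convention. P-values are adjusted
with Benjamini–Hochberg step-up.

RNA counts are normalized by median-of-ratios size factors (the median over
all-positive features of the count over that feature's geometric mean) and
then tested with the same rank tests; log2FC uses pseudo-counted normalized
group means, log2((m_t + 0.5)/(m_n + 0.5)). This keeps the count layer
consistent with the nonparametric philosophy of the protein layer rather
than fitting a negative-binomial GLM; power and type-I oracles in the test
suite bound the cost of that substitution. Ubiquitination-site matrices are
assumed protein-corrected and are tested with the paired signed-rank test
only.

## Regulatory atlas

Per cohort, catalog enzymes are tallied as up (log2FC > 0) or down
(log2FC < 0); zero counts in neither. The enzymes × cohorts log2FC matrix
is signed column-scaled: positives divided by the column's maximum
positive, negatives by the magnitude of its minimum negative, so every
cohort's strongest movements map to ±1 while zeros and missing cells are
preserved. Rows are clustered by Ward linkage on Euclidean distances (the
"ward.D2" convention), with missing cells imputed to 0 for the distance
computation only; the default cut is k = 3 clusters, configurable. Cluster
membership is scored against gene sets by the hypergeometric upper tail
with BH adjustment; the default universe is the enzyme catalog rather than
the genome, since the queries are catalog subsets.

## Tissue-specificity clustering

Each cohort's tumor (or normal) samples are Z-scored per feature within the
cohort, removing batch offsets; zero-SD features are set to 0 and logged.
Only catalog enzymes present in every cohort are retained. PCA is computed
on the feature-centered sample matrix; component significance uses a
JackStraw permutation scheme: each replicate permutes a random 1–10% of
features across samples, re-runs PCA, and pools the permuted features'
loadings as the per-component null. Per-feature p-values (rank of the
observed |loading| in the null pool) are compared to uniform with a
one-sided Kolmogorov–Smirnov test; components with p < 0.05 are kept.
Samples are then clustered on the significant components by Louvain
modularity on a shared-nearest-neighbor graph (k = 20 neighbours including
self, Jaccard edge weights, pruning below 1/15) at a stated resolution.
Size-1 communities are merged into the nearest cluster by centroid
distance, and labels are deterministic given the seed. These choices mirror
the conventions of the common single-cell toolchain but make no claim of
bit-compatibility with it.

## E3–substrate correlations

Spearman correlations (average ranks) are computed per E3–substrate pair
over a condition's samples, requiring at least 10 complete observations;
constant vectors yield a missing coefficient. A background is drawn by
matching each pair with a random partner that is neither the E3 itself nor
any of its known substrates, without replacement within an E3 so the
background preserves the E3 multiset exactly. Distributions (tumor vs
normal, substrates vs background) are compared with the two-sample
Kolmogorov–Smirnov test; the caller adjusts across cohorts with BH.

## Degradative-ubiquitination screen

An E3–substrate interaction is **over-ubiquitinated** when

- (a) at least one ubiquitination site of the substrate is up
  (log2FC > 0, q < 0.05), and
- (b) the targeting E3 protein is up (log2FC ≥ 0.5, q < 0.01),

and **degradative** when additionally

- (c) the substrate protein is down (log2FC < 0, q < 0.01) while its mRNA
  is *not* significantly down, **or** the substrate protein shows no
  significant change (q ≥ 0.01) while its mRNA is significantly up
  (log2FC > 0, q < 0.01).

"Not significantly down" is the complement ¬(log2FC < 0 ∧ q < 0.01); "no
significant change" is q ≥ 0.01 with no fold-change condition. Criterion
(a) is satisfied by any single site (a minimum-count flag exists). All q
thresholds are strict; the single fold-change bound in (b) is inclusive,
whereas the stand-alone "significantly differential E3" selection uses a
strict |log2FC| > 0.5 — both readings of the underlying convention are
implemented where they apply, and the discrepancy at exactly 0.5 is
surfaced rather than silently resolved. Every call serializes the eight
statistics that produced it plus a per-layer reason code when skipped.
Degradative calls are nested in over-ubiquitinated calls by construction,
and tightening any threshold can only remove calls.

## Pathway impact analysis

For a signed topology, the influence matrix is B[i, j] = sign(j→i) /
outdegree(j). Perturbation factors solve PF = ΔE + B·PF, i.e.
PF = (I − B)⁻¹ΔE, with a 0.99 dampening of B as a logged fallback for
singular cyclic systems. Net accumulation Acc = PF − ΔE sums to the pathway
statistic tA; its sign labels the pathway Activated or Inhibited. Because
tA is linear in ΔE (tA = wᵀΔE with w = ((I−B)⁻ᵀ − I)·1), the bootstrap null
assigns the observed ΔE values to uniformly random pathway nodes cheaply;
pPERT is two-tailed around the null median with add-one smoothing. The
over-representation evidence pNDE is the hypergeometric upper tail of the
pathway's DE-node count. Evidence combines by Fisher's product method,
pG = c − c·ln c with c = pNDE·pPERT (identical to the χ²₄ tail of
−2 ln c), with BH and Bonferroni adjustments across pathways. Edge
semantics are collapsed to ±1 activation/inhibition; per-relation weight
tables are out of scope. Any signed per-gene score may serve as ΔE — the
prognosis workflow passes robust correlations and group log2FCs.

## Prognosis

Cox proportional-hazards fits are univariate with Efron tie handling and
Wald p-values. The cutpoint model computes, for every candidate split of
the marker inside a quantile window (default 10–90%, ≥ 5 samples per
side), the standardized two-group log-rank statistic built from log-rank
(Nelson–Aalen) scores a_i = δ_i − Λ̂(t_i); the cutpoint maximizes |z|
(smallest value on ties) and its p-value permutes marker labels and
recomputes the maximum (add-one smoothing). The permutation approach was
chosen over the improved-Bonferroni approximation for exactness at the
problem sizes used here; being rank-based, the cutpoint is invariant to
monotone marker transformations. Group differences are tested with the
unpaired rank-sum machinery (significant: q < 0.05; pronounced:
additionally |log2FC| ≥ 2, inclusive and applied to the magnitude).
Biweight midcorrelation uses the standard Tukey weights
u = (x − med)/(9·MAD), w = (1 − u²)²·1[|u| < 1], with a logged Pearson
fallback when the MAD vanishes. Substrate-mediated association ranks all
other proteins by |bicor| (ties by symbol), truncates to the top 500, and
feeds the signed correlations to the pathway engine as ΔE.

## Synthetic cohorts and what they do (not) show

The generator emulates paired tumor/NAT proteogenomic cohorts on the log2
scale: per-protein baselines ~ N(0, 1), a subject random effect (SD 0.3)
shared within a pair so paired tests gain power, planted tumor shifts, and
i.i.d. residual noise (SD 0.5). RNA is negative-binomial (dispersion 0.1)
with means tied to protein baselines and log-normal library-size factors.
Each interaction-network substrate carries 1–3 ubiquitination sites,
generated as already protein-corrected. Missingness is MCAR by default or
intensity-dependent (logistic in abundance, rescaled to the target rate).
Planted degradative pairs set the substrate's sites up (+effect), protein
down (−effect) and mRNA flat or up, with the targeting E3 among the
up-regulated E3s; the recorded ground truth contains every interaction
edge pairing an up-regulated E3 with a degradative substrate, since all
such edges carry the pattern by construction. Optional E3–substrate noise
coupling (with a tumor-decoupling switch), a multi-cohort tissue panel
with cohort-specific versus shared latent factors, and a protective-marker
cohort whose planted pathway is suppressed in high-marker samples provide
the structural mirrors used in acceptance testing. Default study
conditions: 40 pairs, 800 proteins (60 E3, 20 DUB), 5 substrates per E3,
10% degradative edges, effect 1.0, 10% missingness; the screen-recovery
check uses 80 pairs and effect 2.0 with 30 seeded degradative edges among
300.

The generator does not model mass-spectrometer peak-level noise, TMT batch
structure, isoform ambiguity, or identifier mapping; passing tests
demonstrate the correctness and calibration of the algorithms under the
stated statistical structure, not performance on any real cohort.

## Numerical choices and limitations

Randomness flows exclusively through explicit integer seeds
(`numpy.random.default_rng`); every stochastic stage is byte-reproducible.
Problem sizes in the test and acceptance workloads (hundreds of features,
tens of pairs, hundreds of bootstrap/permutation replicates) were chosen so
the whole synthetic pipeline and its checks run in minutes on one CPU; all
statistical procedures accept larger inputs unchanged. Discrete test
statistics (hypergeometric tails, small-sample rank tests) produce
super-uniform null p-values; calibration checks therefore assert validity
(P(p ≤ α) ≤ α) where literal uniformity cannot hold. Ties in Ward
clustering and Louvain are broken by index order; cluster labels are
ordered by decreasing size. The Cox fit requires at least two events and a
non-constant covariate and reports non-convergence (e.g. separation) as an
error rather than a coefficient.
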