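# Methods

This note records the statistical model behind `epigseq`, the semantics and
defaults of its tunable parameters, the design of the synthetic study used
throughout the test suite, and the numerical choices made where the procedure
admitted more than one reasonable reading.

## Model and procedure

### CY similarity on raw counts

Gene profiles are compared on raw counts, not normalised expression. For
profiles *x*, *y* over the samples where at least one has reads, the observed
dissimilarity is

    observed CY_d = Σ_j [ (x_j + y_j) ln((x_j + y_j)/2)
                          − x_j ln y_j − y_j ln x_j ] / (x_j + y_j),

with natural logarithms, and the similarity is
`CY_s = 1 − observed CY_d / maximum CY_d`. Two conventions complete the
definition:

* **Zero substitution.** The formula contains `ln x` with counts that may be
  0. Zeros whose partner is nonzero are replaced by 0.1 before evaluation
  (`zero_sub`, configurable), the convention of the species-abundance
  literature the index comes from. Samples where *both* profiles are zero are
  excluded from the sum entirely, which also makes CY_s invariant to
  appending mutually silent samples.
* **Maximisation.** The maximum dissimilarity given the data is taken
  per sample as the total-preserving reallocation `(t_j, zero_sub)` with
  `t_j = x_j + y_j`: all of the sample's reads on one side. This is the
  "completely dissimilar" standardisation of the CY index; it yields exactly
  CY_s = 0 for disjoint-support profiles and CY_s = 1 for identical ones.
  The construction is isolated in one function (`similarity.max_cy_d`) so an
  alternative standardisation can be swapped in.

Values within 1e−12 of 0 or 1 are snapped to the exact bound; accumulated
rounding otherwise leaves, e.g., 2⁻⁵² instead of 0 for disjoint profiles.

Two properties of CY_s matter for interpretation. First, it is *per-sample
comparative*: both profiles are measured in the same sample, so unequal
sequencing depth across samples cancels and no library-size normalisation is
needed (or performed) for clustering. Second, it is *abundance-sensitive*:
two flat profiles at 10-fold different levels score ≈ 0.8 no matter how
parallel their responses. Co-expression patterns found by this method are
therefore groups of genes with similar shapes *and* similar expression
levels; this is inherent to the index, not an implementation artifact.
Because CY_s cannot distinguish correlation from anticorrelation, the signs
of the per-group magnitude statistics are used as a compatibility constraint
in every neighbour count and assignment: two genes conflict iff some treated
group has strictly opposite nonzero signs (zeros are compatible with
anything).

### Magnitude of change

Per treated group versus control:

* **Wilcoxon rank-sum Z** (default with ≥ 4 replicates per group): normal
  approximation with midranks, tie-corrected variance and a 0.5 continuity
  correction (count data are tie-heavy). Values are ranked on the
  reads-per-million scale so that unequal library sizes cannot masquerade as
  group effects; ranks are invariant to any monotone per-sample scaling, so
  this choice only matters when depths differ. On the standard-normal scale
  the default threshold St = 2 corresponds to a two-sided tail probability
  of ≈ 0.05.
* **Hodges–Lehmann shift** (when any group has < 4 replicates,
  `small_n_cutoff`): the median of all pairwise treated-minus-control
  differences, computed on log2(RPM + 1) so the statistic reads as an
  approximate log2 fold change and is library-size invariant. In this mode
  St is interpreted on the log2 scale (St = 2 ≈ 4-fold change). The cutoff
  of 4 reflects where the rank-sum normal approximation becomes unreliable.

### Dispersion and per-gene significance

Each gene is modelled by a quasi-Poisson GLM: Poisson likelihood, log link,
group factor, log library-size offset, variance V(Y) = μ·θ. For a single
saturated factor the IRLS solution is closed-form — the fitted rate of a
group is its summed counts over its summed library sizes — so fitted means,
the Pearson estimate θ = X²/(n − G), deviances, and the dispersion-adjusted
F test of the group factor (F = ΔD/(G−1)/θ on (G−1, n−G) df) are computed
directly and vectorised across all genes. The test suite verifies the closed
form against statsmodels' IRLS fit to 8 significant digits, and verifies
calibration: θ is recovered within ±20 % at n = 200 for θ ∈ {1, 2, 5}, and
the F test's type-I error at α = 0.05 is within binomial error over 2,000
simulated null genes. The offset is included because a per-gene model
without it would confound sequencing depth with group effect. Degenerate
fits are defined explicitly: θ = 0 with zero between-group deviance gives
p = 1 (e.g. identical counts everywhere); θ = 0 with a group effect gives
p → 0. BH-adjusted p-values are reported alongside raw ones; no adjustment
is applied to the pattern-level bootstrap p-values (pattern counts are
small).

### Two-step clustering

*Step 1 (extraction).* Candidate seeds must (a) be responsive,
|magnitude| ≥ St1 in at least one treated group; (b) have dispersion inside
the central [pct, 100−pct] percentile band of the empirical θ distribution
(default pct = 5, trimming both tails); and (c) have ≥ Mt − 1 neighbours,
i.e. sign-compatible genes with CY_s ≥ Rt1. Candidates are ordered by
neighbour count, then median neighbour CY_s, then input order — a fixed
tie-break chain that makes runs deterministic — and greedily weeded: a
candidate with CY_s ≥ `weed_r` to an already selected seed is redundant.
Selection order defines pattern numbering. `weed_r = 1.0` disables weeding.

*Step 2 (clustering).* All non-all-zero genes with |magnitude| ≥ St2
participate (the dispersion band applies to pattern *extraction* only).
Each is assigned to the sign-compatible representative with the highest
CY_s provided that reaches Rt2, ties to the lower pattern number. After each
pass, each pattern's representative is recomputed as the member with the
highest median CY_s to the other members (PCS; ties to the lower gene
index). Iteration stops when the fraction of genes changing assignment drops
below 1e−4 — the only scale on which that printed threshold is meaningful
for gene counts in this problem's range — or after 100 iterations, whichever
comes first. Patterns that lose every member are dropped, not re-seeded
(no re-seeding rule exists for the procedure). A pattern reduced to one gene
is retained with PCS defined as 1 and flagged as degenerate. Sign
compatibility during reassignment uses the *current* representative's
signature. The fixed point is stable: re-running the clustering from its own
output representatives reproduces it in one iteration.

*Significance.* For each pattern of size P, B (default 500) random sets of P
distinct profiles are drawn without replacement from the analysed
(non-all-zero) genes and their PCS computed; p = (# sets with PCS strictly
greater than observed)/B, so p lies on the lattice {0, 1/B, …, 1} and p = 0
is attainable — the strict inequality is kept exactly as the estimator is
defined, with no +1 correction. Drawing *sets* of distinct profiles mirrors
what a real pattern is; the pool defaults to all analysed genes
(configurable). Each pattern's draws come from a substream keyed on its
pattern number under one master seed, so p-values are reproducible and
independent of evaluation order and thread count.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| Rt1, Rt2 | 0.8 | CY_s thresholds for neighbouring (step 1) and assignment (step 2) |
| St1, St2 | 2 | magnitude thresholds; Z-scale (tail ≈ 0.05) or log2-scale in small-sample mode |
| Mt | 5 | minimum genes to make a pattern (so ≥ Mt − 1 = 4 neighbours) |
| weed_r | 0.9 | CY_s above which two candidate seeds are redundant |
| pct | 5 | percent trimmed from each dispersion tail for seed eligibility |
| B | 500 | bootstrap draws per pattern |
| zero_sub | 0.1 | zero replacement inside CY log terms |
| small_n_cutoff | 4 | below this many replicates per group, Hodges–Lehmann mode |
| pseudocount | 1 RPM | visualisation-only, in the log2 RPM-ratio matrix |

Mt = 5 and weed_r = 0.9 are this package's defaults (reasonable for the
pattern sizes the method targets); correlation 0.8, St ∈ {1, 2} and pct = 5
are the settings the method is typically run at. The pseudocount never
touches clustering: ratios are computed only for plots and output tables.
The group-count rule is enforced as ≥ 4 distinct groups with an explicit
override (`--allow-few-groups`), and an optional minimum-total-count filter
(default off) can remove very low-count genes beyond the always-excluded
all-zero rows, which are retained in the matrix with a "filtered" flag for
auditability but take part in no statistic.

## The synthetic study

`synthetic_data` is first-class, tested code and defines the conditions
under which the package's recovery claims are evaluated: 6 groups (1 control
+ 5 treated) × 3 replicates; five planted 40-gene patterns; one 40-gene
correlated-but-non-responsive cluster; 1,000 flat background genes; θ = 2;
5 % zero inflation; library sizes log-uniform on [5·10⁶, 2·10⁷].

* **Counts** are gamma–Poisson: λ ~ Gamma(μ/(θ−1), θ−1), Y ~ Poisson(λ),
  moment-matched so Var = μθ exactly as the quasi-Poisson variance function
  specifies (which is a variance assumption, not a generative law; the
  gamma mixture is the standard generative completion). θ = 1 is pure
  Poisson.
* **Zero inflation** is mean-dependent dropout: a count is zeroed with
  probability `0.05 · exp(−μ/20)`. Inflated zeros in real RNA-Seq
  concentrate in low-abundance genes — a technical zero at an expected count
  of several hundred does not occur — so dropout is parameterised by a
  maximum rate (the headline 5 %) decaying with the expected count.
* **Signatures.** The five response vectors (log2 fold changes across the
  treated groups, entries in {0, ±2, ±3, ±4}) were designed analytically
  from noiseless templates before any end-to-end run, under three
  constraints. (1) Every signature carries a ±2 (4-fold) entry as its
  minimum planted responsiveness, and at least one stronger entry: a planted
  effect exactly equal to the St = 2 threshold would sit on a knife edge and
  be recovered only about half the time, which no simulation designer would
  plant. (2) Pairwise template CY_s ≤ 0.85, so no two *distinct* patterns
  are ever weeded as mutually redundant at weed_r = 0.9. The CY index is
  compressive — even opposite 8-fold responses in two of six groups leave
  CY_s near 0.9 — and a binary-code bound (five length-5 sign vectors cannot
  all be pairwise Hamming-distance ≥ 3) forces two signature pairs to differ
  in only two groups, where the strongest (16-fold) oppositions are placed.
  (3) Every pair of signatures conflicts in sign somewhere, exercising the
  directionality constraint. Measured worst-case pairwise CY_s is 0.849 at
  equal baselines.
* **Baselines.** Pattern and noise-cluster genes draw baselines log-uniform
  on 100–300 RPM: because CY_s is abundance-sensitive, a co-expression block
  must share similar levels to be a block (a 3-fold within-block offset
  costs ≈ 0.045 of similarity; 10-fold would destroy the block). Background
  genes span 0.5–1,000 RPM.
* **The noisy cluster** shares a per-sample log2-normal jitter (σ = 0.5):
  its members are strongly mutually correlated under CY_s (median pairwise
  ≈ 0.95) yet no group is responsive, so it specifically probes the
  magnitude filter — the mechanism by which correlated-but-unresponsive
  structure must be rejected.

With 3 replicates per group the study runs in Hodges–Lehmann mode, so the
small-sample path — the harder regime — is what the end-to-end recovery
tests exercise. What passing shows: under these conditions the pipeline at
default parameters recovers exactly the five planted patterns with adjusted
Rand agreement ≥ 0.9 (observed: 1.0 across seeds), rejects the noisy
cluster, and assigns bootstrap p = 0 to every real pattern. What it does not
show: performance under biological replicate correlation, batch effects,
isoform-level ambiguity, or patterns whose members span wide abundance
ranges — real-data regimes the generator deliberately does not model.

## Numerical and engineering choices

* Pairwise CY_s is computed in vectorised row blocks, optionally in
  parallel; rows are partitioned deterministically and reassembled in order,
  so the result is bit-identical for any thread count. The matrix is
  symmetrised and given an exact unit diagonal.
* The problem sizes in the test suite (1,240 genes × 18 samples end-to-end;
  B = 200–500 bootstrap draws; 2,000-gene calibration panels) keep the full
  suite under two minutes while leaving every statistical check adequately
  powered.
* The sample embedding (classical scaling of the double-centred
  sample × sample CY_s matrix over clustered genes) is one reading of a
  "PCA on the CY_s measures of the clustered genes"; the alternative — PCA
  of the log2-ratio matrix — is one function swap away
  (`plots.sample_coordinates`). Eigenvector signs are solver-dependent, so
  tests compare inter-sample distances, not raw coordinates.
* Monotonicity facts asserted on the fixed synthetic dataset — stricter Rt1,
  Rt2 or Mt never yield more patterns/genes; a laxer weed-out never yields
  fewer seeds — are empirical properties of block-structured data, not
  theorems: greedy weeding admits adversarial similarity tables where seed
  counts move non-monotonically with the threshold.

## Known limitations

* CY_s couples shape and abundance; genes co-regulated at very different
  expression levels will not cluster together.
* The quasi-Poisson F test assumes the variance is proportional to the mean;
  strongly gene-wise-varying overdispersion within groups is absorbed into
  θ but not modelled (no negative-binomial or zero-inflated likelihoods by
  design).
* One gene, one pattern: no soft assignment.
* The bootstrap null (random gene sets from the analysed pool) is
  conservative for patterns resembling the pool's dominant abundance band,
  since CY_s between random same-level flat genes is already high.
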