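# Methods

## Scope and data model

The package analyses bulk expression cohorts on the log2 scale, probes ×
samples, with a probe→gene annotation table. Normalisation (MAS5, RMA,
…) is upstream; only an elementwise `log2(x + offset)` is offered for
raw-scale inputs. Expression matrices are pandas DataFrames validated
for unique identifiers and finite values; when a gene is measured by
several probes, the per-sample **median** over its probes is the gene's
value.

## Variance filtering

Unsupervised analysis uses the `ceil(fraction · P)` most variable probes
(default fraction 0.05), with the unbiased (n−1) sample variance. Ties
break by ascending probe id and the retained probes keep their original
row order, so the filter is deterministic and idempotent. On a full
54,675-probe array the 5% filter keeps exactly 2,734 probes.

## Fuzzy clustering

Patients are compared by the centred-Pearson dissimilarity
d(i,j) = 1 − ρ(i,j) over the filtered probes (range [0, 2]; the
monotonically equivalent (1 − ρ)/2 is available). The clustering
minimises the FANNY criterion

    F(u) = Σ_k  [ Σ_{i,j} u(i,k)^r u(j,k)^r d(i,j) ]  /  [ 2 Σ_j u(j,k)^r ]

subject to row sums of 1, by alternating closed-form updates derived
from the stationarity conditions: u(i,k) ∝ a(i,k)^{−1/(r−1)} with
a(i,k) the partial-derivative coefficient
(Σ_j u(j,k)^r d(i,j)) / S_k − W_k / (2 S_k²), where S_k = Σ_j u(j,k)^r
and W_k is the membership-weighted within-cluster dissimilarity sum. A
non-positive coefficient sends the full membership to that cluster. A
guard rejects any sweep that fails to decrease the objective, so the
objective sequence is non-increasing by construction. Initialisation is
deterministic (memberships concentrated on the k most mutually distant
samples by greedy max-min selection) plus seeded Dirichlet restarts
(default 2); the best objective wins. Convergence: relative objective
change < 1e−9 or 500 sweeps.

**Fuzziness index.** The default is r = 1.2, not the textbook 2, and the
reason is structural: at the uniform membership u ≡ 1/k the criterion
equals n·d̄/(2k) (d̄ the mean pairwise dissimilarity), which is *below*
the value of any crisp partition unless within-cluster dissimilarities
are far smaller than d̄. On correlation distances between expression
profiles — where within-cluster d rarely drops much below ~0.3 — the
r = 2 optimum is therefore complete fuzziness; the reference R
implementation (`cluster::fanny`) returns the identical uniform collapse
and warns to decrease the membership exponent. At r = 1.2 the optimiser
matches the reference objective to five digits on the same inputs and
produces the crisp membership profile (winning memberships mostly
> 0.9) expected of a stable molecular partition. The index remains
configurable, and a complete-fuzziness warning fires whenever the
returned memberships are all near 1/k.

**Cluster number.** For k = 2…10 the pipeline reports the Dunn index in
its original form (minimum single-linkage separation over maximum
cluster diameter, computed on the dissimilarity; undefined denominators
are reported absent) and the Calinski–Harabasz pseudo-F
([tr B/(k−1)] / [tr W/(n−k)]) computed on the filtered profiles in
Euclidean geometry with crisp labels, since the statistic needs
centroids. Crisp assignment is argmax membership with ties to the lowest
cluster index. The cluster count itself is a configuration choice
(default 3); the indices are reported for the whole range rather than
selecting automatically. Membership diagnostics summarise per-cluster
minimum/median winning memberships, counts above a threshold, and the
per-sample membership gap for a designated cluster pair; barycentric
coordinates (Σ_k u(i,k)·vertex_k) place patients inside the membership
simplex for plotting.

## SAM and the signed M2/M1 metagene

Two-class unpaired SAM: d_i = (x̄₂ − x̄₁) / (s_i + s₀) with s_i the
pooled two-sample standard error and s₀ the Tusher fudge factor — the
percentile of s (grid 0, 5, …, 100) minimising the coefficient of
variation of window-wise MADs of d across the range of s. The null
distribution comes from label permutations (default 300, seeded); each
permutation enters the pool in both class orientations, which makes
q-values exactly invariant to class relabelling in balanced designs.
For each threshold delta, cut points are the outermost observed
d-values whose deviation from their expected order statistics reaches
delta; the FDR at delta is π₀ times the 90th percentile of per-permutation
false-call counts over the number called, and a probe's q-value is the
smallest FDR among deltas at which it is called. The 90th percentile is
the conservative of the two summaries the SAM literature uses; with the
median, the top observed order statistic beats the median permutation
maximum about half the time, so pure-null data would regularly yield
spurious q = 0% calls — incompatible with a gene-selection rule that
keys on q = 0% exactly. π₀ is estimated from the fraction of observed d
inside the permutation interquartile range.

A gene enters the signed signature only if **all** its probes reach
q = 0%; its weight is +1 if its mean expression in M2 exceeds that in
M1, −1 otherwise (equal means drop the gene; genes with
significant probes of conflicting sign are excluded). The score of a
tumour is the weighted mean over the measured signature genes; missing
genes are dropped, never imputed, with the measured fraction logged.
Module scores (the seven immune metagenes, proliferation, VEGF,
glycolysis) are unweighted means of gene-collapsed expression.
Centroid subtyping assigns each sample to the class of highest Pearson
(or Spearman) correlation with user-supplied centroids over the
intersected genes, with an "unclassified" outcome below a correlation
floor (default 0.1) and a minimum-gene floor (default 10). Published
centroid matrices and module lists are user-supplied files; the
synthetic generator ships its own planted versions.

## Immune dissection

On the samples of the two basal-enriched clusters, the seven immune
metagenes are z-scored per module (they span different ranges, and
unstandardized Euclidean distance would let one module dominate) and
Ward-clustered; the tree is cut at k = 2 and the group with the higher
grand mean of metagene scores is labelled HIR, the other LIR — an
explicit, testable version of "high immune response". The M2/M1 score
is computed alongside but by default does not enter the clustering
(an option includes it as an eighth feature). Metagene differences
between clusters are reported with Welch t-tests.

## Survival statistics

Kaplan–Meier estimation, the k-sample logrank test and Cox fits are
delegated to lifelines (Efron tie handling). Cox covariates are scaled
per standard deviation by default — the natural scale for metagene
scores, on which hazard ratios around 0.6 are plausible — with per-unit
available. Perfect separation is reported as a non-converged fit. Group
comparisons: one-way ANOVA with Tukey HSD (statsmodels), Fisher's exact
test (scipy for 2×2; an own exact enumeration over tables with fixed
margins for r×c, feasible at cohort-annotation sizes), Pearson
correlation. P-values are unadjusted by default, as is conventional for
cohort annotation; Benjamini–Hochberg is available.

## PAM transfer

Nearest-shrunken-centroid classification in the Tibshirani
parameterisation: standardized deviations
d_kg = (x̄_kg − x̄_g) / (m_k (s_g + s₀)), with m_k = √(1/n_k − 1/n),
s_g the pooled within-class standard deviation and s₀ its median, are
soft-thresholded by delta; the discriminant is the squared standardized
distance to the shrunken centroid minus 2·log prior (priors default to
training frequencies, matching the clusters' imbalance). Delta is chosen
by stratified cross-validation (default 5 folds, seeded) as the largest
value whose error lies within one standard error of the minimum, the SE
taken across folds. The feature space is the same top-variance probe set
used for clustering; external genes missing from it are dropped from all
centroids symmetrically, with an 80% overlap floor. The model serialises
to a single JSON document.

## Synthetic cohorts

`generate_tnbc_cohort` draws a 107-patient cohort with three latent
clusters at proportions (0.224, 0.449, 0.327) — sizes 24/48/35 by the
largest-remainder rule — carrying a luminal-AR axis (up in cluster 1),
a proliferation axis (up in cluster 2, half-strength in cluster 3) and
an immune axis (up in cluster 3), plus a claudin-low-like subpopulation
(26% of cluster 3) with the luminal/adhesion block down and an EMT
block up. Gene baselines are N(8, 1) on the log2 scale (matching the
6–14 range of MAS5/log2 summaries), active blocks shift by 1.5 log2
units, per-sample gene noise is N(0, 0.7), and genes expand to 1–3
probes with N(0, 0.25) probe noise. The probe layout derives from a
separate platform seed, so cohorts generated on the same "platform"
share probe identifiers — as two cohorts profiled on the same chip
would. The background gene count (4,800) is sized so the 5% variance
filter is dominated by the planted axes, mirroring real arrays where
the differential probe clusters sit inside the retained top-variance
set. Ages are N(cluster mean, 12) with means (64.6, 56.8, 51.9) years;
event-free survival is exponential with cluster hazards
(0.10, 0.10, 0.04)/year — hazard ratio 0.4 for the good-outcome third
cluster — under independent exponential censoring (0.05/year).
`generate_macrophage_reference` draws a two-class (M1/M2) gene-level
reference, 10 samples per class, 1,000 genes with 100 planted
differential genes at 3 log2 units (3σ at the default noise), 60% up in
M2, with a truth table of directions. Passing the cohort generator the
reference's truth table plants those genes in the cohort (M2-up genes
high in cluster 2, M1-up in cluster 3), linking the macrophage score to
the immune phenotype. All outputs are deterministic functions of
(spec, seed).

**What the generator does not emulate:** batch effects, array spatial
artefacts, probe cross-hybridisation, non-Gaussian heavy tails,
correlated gene-gene noise within blocks beyond the shared shift, and
informative censoring. Tests passing on these cohorts demonstrate that
the pipeline recovers structure of the assumed form at the stated
signal-to-noise; they do not certify performance on real arrays.

## Numerical choices and degenerate inputs

Convergence tolerances: fuzzy clustering 1e−9 relative objective
change; membership row sums validated to 1e−9. Dunn and
Calinski–Harabasz report absent values (NaN) for empty crisp clusters,
zero diameters or zero within-scatter rather than raising mid-scan.
Fisher enumeration sums tables with probability ≤ the observed (within
1e−9 log-tolerance). Equal class means drop a gene from the signed
signature; membership ties in crisp assignment go to the lowest cluster
index; variance ties to the ascending probe id; identical samples under
Ward resolve by scipy's deterministic observation ordering. The
analysis drivers use problem sizes (107 patients, ~7,000 probes, 300
permutations, 10–20 seed replicates) chosen to exercise the cohort
scale the generator emulates while keeping any single stage under a few
seconds.

## Known limitations

The FANNY optimiser is a local method; restarts mitigate but do not
eliminate local optima on weakly separated data. SAM q-values depend on
the sampled permutation set below the exhaustive-enumeration regime.
The exact r×c Fisher enumeration is exponential in table size and
intended only for small annotation tables. PAM assumes the external
cohort shares the training platform's probe universe up to the overlap
floor; cross-platform transfer (different chip families) needs upstream
id mapping the package does not provide.
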