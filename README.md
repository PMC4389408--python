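# tnbcsub — fuzzy molecular subtyping of triple-negative breast cancer cohorts

Triple-negative breast cancer (TNBC) — tumours lacking ER, PR and HER2
expression — is clinically defined by what it is not, yet molecularly
heterogeneous: luminal androgen-receptor (LAR), basal-like and
claudin-low programmes coexist under one label, with different outcomes.
`tnbcsub` implements an unsupervised subtyping pipeline for log2
expression cohorts of such tumours, together with a synthetic-cohort
generator that reproduces the statistical structure every stage assumes,
so the whole workflow runs and is tested without any data download.

The pipeline:

1. **Variance filtering** — keep the top 5% most variable probes
   (2,734 probes on a full 54,675-probe array).
2. **Fuzzy clustering** — minimise the FANNY criterion over membership
   matrices *u* on the centred-Pearson dissimilarity
   d(i,j) = 1 − ρ(i,j) between patient profiles:

   minimise over u:  Σₖ [ Σᵢⱼ u(i,k)ʳ u(j,k)ʳ d(i,j) ] / [ 2 Σⱼ u(j,k)ʳ ]

   with each patient's memberships summing to 1; Dunn and
   Calinski–Harabasz indices over k = 2…10 guide the cluster number, and
   barycentric coordinates place each patient inside the membership
   simplex.
3. **SAM + signed macrophage metagene** — two-class Significance Analysis
   of Microarrays (moderated d-statistic, Tusher fudge factor s₀,
   permutation q-values) on an M1-vs-M2 macrophage reference; genes whose
   probes all reach q = 0% get a weight of +1 or −1 by their M2-vs-M1
   contrast, and the M2/M1 score of a tumour is the weighted mean of
   those genes.
4. **Immune dissection** — seven immune metagenes (HCK, LCK, IgG, STAT1,
   Interferon, MHC-I, MHC-II) scored as module means; Ward clustering of
   the standardized metagenes splits the basal clusters into high/low
   immune response (HIR/LIR).
5. **Survival statistics** — Kaplan–Meier / logrank, univariate Cox
   (Efron ties, per-SD covariates), ANOVA + Tukey HSD, exact Fisher
   tests, Pearson correlations.
6. **PAM transfer** — a nearest-shrunken-centroid classifier trained on
   the fuzzy clusters carries the partition to an external cohort on the
   same platform.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
cohorts and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_cluster.py
python analysis/03_macrophage_signature.py
python analysis/04_immune_dissection.py
python analysis/05_survival.py
python analysis/06_external_transfer.py
```

`02_cluster.py` prints, for the default 107-patient cohort:

```
retained 357 probes; fanny objective 13.7026 (7 iterations)
Calinski-Harabasz favours k=3; partition taken at k=3
cluster  n      min   median  n_above_threshold
     C1 24 0.992705 0.996002                 24
     C2 35 0.991144 0.997074                 35
     C3 48 0.993406 0.996857                 48
cluster sizes: [24, 35, 48]; ARI vs planted clusters: 1.000
```

— three clusters at the planted 24/48/35 proportions, each patient with
a winning membership above 0.99 (the partition is essentially crisp),
and perfect agreement with the generative labels.  `04_immune_dissection.py`
then splits the two basal clusters into a pure HIR group (all 35
immune-high patients) and a pure LIR group, with the M2/M1 macrophage
score lower in HIR (1.10 vs 2.60) — high immune response goes with an
M1-skewed, tumour-suppressive macrophage profile.  `05_survival.py`
reports per-SD hazard ratios around 0.5 for every immune metagene
(higher immune expression, better event-free survival) and above 2 for
the M2/M1 score, and `06_external_transfer.py` closes the loop: the PAM
classifier trained on the discovery clusters and the external cohort's
own fuzzy clustering disagree on 0/107 samples.

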