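# gutmwas

Case-control association analysis of gut shotgun metagenomes: a reusable,
tested implementation of the full analysis arc of a metagenome-wide
association study (MWAS) — feature aggregation from gene-level profiles,
alpha/beta diversity, enterotyping, differential abundance, reporter-score
functional enrichment, virulence-factor/PHI quantification, random-forest
marker selection with ROC evaluation, and clinical-index association — plus
a synthetic cohort generator with known ground truth so every stage can be
validated without access to raw sequencing data.

It is written for microbiome researchers who want the standard MWAS recipe
as a library of statsmodels-style model objects and a thin CLI, rather than
a collection of one-off R scripts.

## The analysis in brief

Profiles are relative abundances. A taxon's (or KO's, or virulence
factor's) abundance is the sum of the relative abundances of the genes
annotated to it; VF/PHI annotations come from blast tabular hits filtered
to identity > 40% and bit score > 60, keeping each query's best hit.

* **Diversity** — richness, Shannon index H = −Σ pᵢ ln pᵢ, Chao1
  S_obs + F₁²/(2F₂), and the Jensen–Shannon divergence
  JSD(p,q) = H(m) − (H(p)+H(q))/2, m = (p+q)/2, with the per-sample mean
  within-group JSD as the beta-diversity statistic.
* **Enterotypes** — PAM (partitioning around medoids, BUILD + SWAP) on the
  genus-level JSD matrix; the cluster number maximizes the
  Calinski–Harabasz index computed from the distance-based sum-of-squares
  decomposition; enterotype–phenotype association by Fisher's exact test.
* **Differential abundance** — per-feature two-sided Wilcoxon rank-sum with
  Benjamini–Hochberg FDR (q < 0.05), reported with group means/sds and
  direction; PERMANOVA pseudo-F on the JSD matrix for whole-community
  effects.
* **Functional enrichment** — per-KO p-values are inverse-normal
  transformed to signed Z scores; a module's reporter score is
  (Σ Z)/√k, background-corrected against random size-k KO sets;
  |Z_adj| > 1.6 calls a module differentially enriched.
* **Markers** — random-forest feature elimination over a halving grid with
  5-fold CV and the one-SE rule; out-of-fold case probabilities from
  repeated 10-fold CV; AUC by the Mann–Whitney identity with a DeLong 95%
  CI; three-way Case / Uncertain / NotCase calls at probability cutoffs
  0.50 / 0.35.
* **Clinical association** — Spearman rank correlation with pairwise
  deletion of missing values.

## Worked example

```python
from gutmwas import (CohortConfig, simulate_cohort,
                     DifferentialAbundanceModel, EnterotypeModel)

cohort = simulate_cohort(CohortConfig(seed=1))   # 44 cases vs 46 controls
res = DifferentialAbundanceModel(cohort.species, cohort.metadata).fit()
print(res.summary())
ent = EnterotypeModel(cohort.species, k_max=5).fit()
print(ent.summary())
```

prints (abridged):

```
Differential abundance (Wilcoxon rank-sum + Benjamini-Hochberg)
  features tested      200
  cases / controls     44 / 46
  significant (q<0.05)  49  (43 enriched in cases, 6 in controls)

Enterotyping (PAM on JSD, CH model selection)
  optimal k        2
  CH(k=2)        807.42 *
  CH(k=3)        565.51
  CH(k=4)        521.75
  CH(k=5)        519.03
  cluster 0: n=29, top taxa Prevotella, sp_0062, sp_0123
  cluster 1: n=61, top taxa Bacteroides, sp_0062, sp_0123
```

The cohort was generated with 45 species spiked (38 enriched in cases, 7
depleted) and a two-component Bacteroides/Prevotella enterotype structure;
the model recovers a significant-species count near the designed 45 with
the designed direction skew, and the two enterotypes with their driver
taxa. The same analysis runs from the shell:

```bash
gutmwas simulate --seed 1 --out fixtures/
gutmwas diff --matrix fixtures/species.tsv --metadata fixtures/metadata.tsv --out diff.tsv
gutmwas run --config pipeline.yaml        # full multi-stage report
```

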