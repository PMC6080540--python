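# Methods

This note records the models, the synthetic-data design, the numerical
choices, and what the validation experiments do and do not establish.

## Profiles and aggregation

All quantities are relative abundances: non-negative feature × sample
matrices whose per-sample sums never exceed 1. IO is lossless — columns may
sum below 1 (e.g. after unannotated mass is dropped) and nothing is
renormalized implicitly; stages that need a composition (Shannon, JSD)
renormalize internally.

A parent feature's abundance is the sum of its annotated children's
abundances. Genes without annotation are excluded from the sum rather than
pooled into an "unclassified" feature; the dropped per-sample fraction is
logged so the loss is auditable. For virulence-factor and
pathogen–host-interaction profiles the gene→feature map comes from
12-column blast tabular hits: a hit survives only with identity strictly
above 40% and bit score strictly above 60 bits, and each query keeps its
single best surviving hit (highest bit score, ties broken by higher
identity, then lexicographically smaller subject id, so output is
deterministic). Whether a study sums all surviving hits or only best hits
per query is rarely stated in publications; best-hit-per-query is the
choice here because it avoids double-counting a gene's mass across
features.

## Diversity

Shannon entropy and the Jensen–Shannon divergence use the natural
logarithm (nats), the convention of the enterotype literature; a `base`
argument converts. JSD is used directly (not its square root) both for the
beta-diversity statistic and for enterotyping; `sqrt=True` is available
where a proper metric is needed. The beta-diversity statistic is each
sample's mean JSD to the other members of its own group; group contrasts of
these values use the Wilcoxon rank-sum test.

Chao1 is defined on counts only. Relative-abundance profiles are converted
by seeded multinomial resampling at a stated depth
(`simulate.multinomial_counts`, default depth 10⁵ in the pipeline); this is
a documented modeling choice, since richness estimators are undefined on
proportions. The bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)) is used
when no doubletons exist. Rarefaction subsamples without replacement and
reports the exact observed richness at full depth (no resampling noise at
the endpoint).

## Enterotyping

PAM is the classical BUILD + SWAP algorithm run directly on the
dissimilarity matrix: BUILD seeds greedily, SWAP applies the single best
improving medoid/non-medoid exchange until none exists. All tie-breaks are
by smallest index, so the algorithm is deterministic; the `seed` parameter
exists for interface symmetry only. The Calinski–Harabasz index uses the
distance-based decomposition T = (1/n)Σ_{i<j}d²ᵢⱼ,
W = Σ_c (1/n_c)Σ_{i<j∈c}d²ᵢⱼ, CH = [(T−W)/(k−1)]/[W/(n−k)], which
coincides with the centroid form on Euclidean embeddings (asserted in the
tests); whether published pipelines computed CH on the dissimilarities or
on an embedding is usually unstated, so the embedding form is provided as a
cross-check utility. k is scanned over 2..10 by default and ties in the CH
argmax resolve to the smallest k. A best CH below a configurable threshold
(default 200, chosen between the scores observed for one- and
two-component synthetic communities) flags "weak structure" without
changing the reported optimum.

## Hypothesis testing

The Wilcoxon rank-sum test enumerates exactly for combined n ≤ 12 without
ties and otherwise uses the normal approximation with tie and continuity
correction — the same switchover R's `wilcox.test` applies, which matters
when comparing against R-based pipelines. BH is the only multiple-testing
correction; pipelines that used a pi0-estimating q-value package are
approximated by BH (the difference is a constant factor π₀ ≤ 1, i.e. BH is
the conservative end). PERMANOVA permutes labels freely (no strata) and
reports p = (#{F* ≥ F} + 1)/(n_perm + 1). Direction of a differential
feature is the sign of the group-mean difference — nothing more; a feature
whose mean and median disagree is reported by its mean. The
summary-statistic t-test offers pooled and Welch variants because
published demographic tables rarely state which was used per row.

## Reporter-score enrichment

Z = Φ⁻¹(1−p) per KO, clipped to |Z| ≤ 8, signed positive for
case-enrichment. A module's raw score is (ΣZ)/√k over its k scored member
KOs. Because the KO Z's are not standard normal in real data, the raw
score is background-corrected: for each distinct k, 1000 seeded random KO
sets of size k give μ_k and σ_k, and Z_adj = (Z_raw − μ_k)/σ_k; under a
null cohort Z_adj is standard normal (KS-tested in the suite). The
enrichment call |Z_adj| > 1.6 is one-sided per direction, matching the
convention of reporter-feature analyses. All scored KOs contribute by
default; `significant_only=True` implements the stricter literal reading
(only q < 0.05 KOs), which is noisier because it conditions the background
on significance.

## Marker selection and evaluation

Random forests use 500 trees by default and mean-decrease-in-impurity
importance. Feature elimination ranks features once on the full data per
run, then measures stratified 5-fold CV error at halving feature counts
(n, n/2, …, 1), averaged over 5 repeats; the selected panel size is the
smallest count whose mean error is at most (minimum mean error + SD at the
minimizer) — the one-SE rule with the SD taken across repeats. Per-sample
case probabilities are out-of-fold forest vote fractions from repeated
stratified 10-fold CV, averaged across repeats. AUC is the Mann–Whitney
pair statistic (ties ½) and the CI is DeLong's; both are reported in
percent. Three-way calls use strict inequalities (probability > 0.50 →
Case, < 0.35 → NotCase, boundary values → Uncertain). The validation
experiments use 200 trees and 3 CV repeats; forest AUC is stable beyond
~100 trees, so this changes runtime, not conclusions.

## The synthetic cohort generator

The generator emulates the structure of a two-arm gut-metagenome
case-control study, with defaults fixed at the postmenopausal-arm scale:
44 cases vs 46 controls, 200 species, 45 differentially abundant species
of which 84% are case-enriched, per-sample log-normal dispersion σ = 1.

* **Species model.** Species base log-abundances are N(0, 2); each sample
  draws one of two mixture components (Prevotella-like with probability
  0.3) whose driver taxon is up-weighted by 8 log-units, which puts the
  driver at roughly half of its component's community — the dominance level
  real Bacteroides/Prevotella enterotypes show, and enough for PAM/CH to
  recover the components (ARI > 0.95 across seeds). Spiked species are
  drawn from the rarer half of the community, as in real cohorts where
  disease-associated species are predominantly low-abundance; this also
  keeps the mass moved by a spike small, so closure barely disturbs
  non-spiked species. (Spiking abundant species 8-fold instead makes every
  species differential through closure — a compositional effect worth
  knowing about, not a bug.) Effects multiply the mean on the log scale
  before closure, because additive effects are ill-defined under closure.
* **Population vs sample seed.** Population-level draws (base abundances,
  spiked set, gene splits) come from `population_seed` (default: the
  sampling seed), so two cohorts sharing a population seed are independent
  samples of one population — the setting in which marker transfer between
  cohorts is meaningful.
* **Genes and modules.** Each species splits over its genes by one fixed
  Dirichlet(1) draw, so aggregation recovers the species profile exactly at
  full annotation. Each annotated gene carries one KO; KOs partition
  evenly into modules; the designed differential modules contain only KOs
  fed by genes of spiked species of one direction.
* **Clinical indices.** For target Spearman ρ, the index is built from a
  latent bivariate-normal pair with Pearson r = 2 sin(πρ/6) against the
  species' normal scores, exponentiated to a positive scale; |ρ| = 1 is an
  exact monotone map. Realized ρ at n = 90 tracks the target within
  sampling noise (~0.1).
* **"Moderate effect"** for the classifier regime is fixed at a 2.25-fold
  spike on 14 markers, which yields mean cross-validated AUC ≈ 84% — a
  mid-80s regime typical of species-marker panels at this cohort size.

What the generator does **not** emulate: read-count noise (profiles are
exact compositions plus log-normal variation), taxonomic correlation
structure beyond the two drivers, gene-length or copy-number effects,
covariates such as age or BMI, and batch effects. Passing the validation
suite therefore shows the statistics are implemented correctly and behave
as designed under a realistic compositional model — it does not certify
performance on any real cohort.

## Validation experiment sizes

The acceptance script and acceptance tests run: 50 seeds for differential
recovery (40 vs 40, 8-fold), 20 seeds for enterotype recovery, 50 seeds
for reporter recovery, 20 seeds for classifier AUC (200 trees, 3 repeats),
20 null cohorts for type-I calibration (with reporter nulls pooled over
10), and 25 seeds for clinical-correlation recovery. These sizes put
Monte-Carlo error well inside the asserted margins while keeping a full
run in minutes on one CPU.

## Known limitations

* PERMANOVA offers no strata/covariate adjustment.
* The r×c (beyond 2×2) enterotype–phenotype test is a seeded Monte-Carlo
  permutation test, not the exact network algorithm.
* Chao1 on resampled proportions inherits the chosen resampling depth;
  report the depth with the estimate.
* The degenerate reporter background (a constant KO universe) only defines
  the exactly-null score; anything else raises.
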