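"""Synthetic case-control metagenome cohorts with known ground truth.

The generator emulates the structure of a shotgun-metagenome case-control
study of the gut microbiome so that every downstream stage (diversity,
enterotyping, differential abundance, module enrichment, marker selection,
clinical association) can be exercised against a known answer:

* **Species profiles** follow a log-normal compositional model.  Each sample
  is drawn from one of two mixture components mimicking the two classical
  enterotypes, each dominated by a single driver taxon (Bacteroides-like in
  component 0, Prevotella-like in component 1).  A configurable set of
  species is spiked with a multiplicative fold-change on the log scale in
  cases (a configurable fraction enriched, the rest depleted; the default
  mirrors the skew typical of dysbiosis, ~84% enriched) before per-sample
  closure to 1.
* **Gene profiles** split every species' abundance over its genes by a fixed
  Dirichlet draw, so summing annotated genes recovers the species profile
  exactly; each annotated gene carries one KO, and KOs partition into
  modules.  Designed differential modules contain only KOs fed by genes of
  spiked species, giving module-level enrichment with known direction.
* **Clinical indices** are generated by blending the normal scores of a
  target species' abundance ranks with independent noise, calibrated so the
  population Spearman correlation equals the requested value.

Sizes default to the postmenopausal arm of a typical cohort (44 cases vs 46
controls, 200 species).  Everything is deterministic under the configured
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import (
    CohortMetadata,
    CountMatrix,
    FeatureMap,
    RelAbundanceMatrix,
)

__all__ = [
    "CohortConfig",
    "TruthSpec",
    "SyntheticCohort",
    "simulate_species_profiles",
    "simulate_gene_and_ko_profiles",
    "simulate_clinical_indices",
    "multinomial_counts",
    "simulate_cohort",
]

DRIVER_TAXA = ("Bacteroides", "Prevotella")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``effect_size`` is the multiplicative fold-change applied to spiked
    species' mean abundance (on the log scale, before closure) in cases;
    ``dispersion`` is the per-sample log-normal sigma; ``enterotype_fraction``
    is the probability that a sample comes from the Prevotella-like
    component; ``driver_boost`` is the log-scale up-weighting of the
    component's driver taxon.
    """

    seed: int
    n_case: int = 44
    n_control: int = 46
    n_species: int = 200
    n_genes_per_species: int = 10
    n_diff_species: int = 45
    fraction_enriched: float = 38 / 45
    effect_size: float = 4.0
    enterotype_fraction: float = 0.3
    dispersion: float = 1.0
    driver_boost: float = 8.0
    n_ko: int = 400
    n_modules: int = 40
    n_diff_modules: int = 6
    annotation_fraction: float = 1.0
    stratum: str = "postmenopausal"
    clinical_targets: tuple[tuple[str, str, float], ...] = ()
    population_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("n_case and n_control must be positive")
        if self.n_species < 3:
            raise ValueError("need at least 3 species (2 drivers + 1)")
        if not 0 <= self.n_diff_species <= self.n_species - len(DRIVER_TAXA):
            raise ValueError("n_diff_species out of range")
        if self.effect_size <= 0 or self.dispersion <= 0:
            raise ValueError("effect_size and dispersion must be positive")
        if not 0.0 <= self.enterotype_fraction <= 1.0:
            raise ValueError("enterotype_fraction must lie in [0, 1]")
        if not 0.0 <= self.fraction_enriched <= 1.0:
            raise ValueError("fraction_enriched must lie in [0, 1]")
        if self.n_ko < self.n_modules:
            raise ValueError("n_ko must be at least n_modules")
        if not 0 <= self.n_diff_modules <= self.n_modules:
            raise ValueError("n_diff_modules out of range")
        if not 0.0 <= self.annotation_fraction <= 1.0:
            raise ValueError("annotation_fraction must lie in [0, 1]")
        for _, _, rho in self.clinical_targets:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"target Spearman rho {rho} outside [-1, 1]")


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth of one simulated cohort."""

    diff_species: dict[str, int]  # species -> +1 (case-enriched) / -1 (depleted)
    diff_modules: dict[str, int]
    enterotype_assignment: pd.Series  # sample -> component (0/1)
    clinical_rho: dict[tuple[str, str], float]
    driver_species: tuple[str, str] = DRIVER_TAXA


@dataclass(frozen=True)
class SyntheticCohort:
    """Full fixture set produced by :func:`simulate_cohort`."""

    species: RelAbundanceMatrix
    genes: RelAbundanceMatrix
    gene_to_species: FeatureMap
    gene_to_ko: FeatureMap
    ko_to_module: FeatureMap
    metadata: CohortMetadata
    truth: TruthSpec
    config: CohortConfig


def _species_ids(n: int) -> list[str]:
    ids = list(DRIVER_TAXA)
    ids += [f"sp_{i:04d}" for i in range(n - len(DRIVER_TAXA))]
    return ids


def simulate_species_profiles(
    config: CohortConfig,
) -> tuple[RelAbundanceMatrix, CohortMetadata, TruthSpec]:
    """Draw the species x sample relative-abundance matrix plus metadata/truth.

    Population-level parameters (species base abundances, which species are
    spiked) are drawn from ``population_seed`` (defaulting to ``seed``), so
    two cohorts sharing a population seed are independent samples from the
    same synthetic population -- the setting for train/test transfer.
    """
    pop_seed = config.seed if config.population_seed is None else config.population_seed
    rng_pop = np.random.default_rng(np.random.SeedSequence((pop_seed, 10)))
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 11)))
    n = config.n_case + config.n_control
    species = _species_ids(config.n_species)
    sample_ids = [f"case_{i:03d}" for i in range(config.n_case)] + [
        f"ctrl_{i:03d}" for i in range(config.n_control)
    ]
    is_case = np.array([1] * config.n_case + [0] * config.n_control, dtype=bool)

    base_mu = rng_pop.normal(0.0, 2.0, size=config.n_species)
    # drivers start from a fixed baseline so the component boost, not the
    # random draw, determines their dominance
    base_mu[: len(DRIVER_TAXA)] = 0.0
    component = (rng.random(n) < config.enterotype_fraction).astype(int)

    # spiked species are drawn from the rarer half of the community, as in
    # real case-control studies where disease-associated species are
    # predominantly low-abundance; this also keeps the mass moved by the
    # spike small, so closure barely perturbs non-spiked species
    non_driver = np.arange(len(DRIVER_TAXA), config.n_species)
    n_eligible = max(config.n_diff_species, non_driver.size // 2)
    eligible = non_driver[np.argsort(base_mu[non_driver], kind="stable")][:n_eligible]
    spiked = rng_pop.choice(eligible, size=config.n_diff_species, replace=False)
    n_up = int(round(config.fraction_enriched * config.n_diff_species))
    directions = np.array([1] * n_up + [-1] * (config.n_diff_species - n_up))

    log_effect = np.log(config.effect_size)
    mu = np.tile(base_mu[:, None], (1, n))
    for c in (0, 1):
        mu[c, component == c] += config.driver_boost
    for idx, d in zip(spiked, directions):
        mu[idx, is_case] += d * log_effect

    log_abund = mu + rng.normal(0.0, config.dispersion, size=(config.n_species, n))
    raw = np.exp(log_abund)
    values = raw / raw.sum(axis=0)

    matrix = RelAbundanceMatrix.from_arrays(values, species, sample_ids)
    meta = CohortMetadata(
        pd.DataFrame(
            {
                "group": np.where(is_case, "case", "control"),
                "stratum": config.stratum,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = TruthSpec(
        diff_species={species[i]: int(d) for i, d in zip(spiked, directions)},
        diff_modules={},
        enterotype_assignment=pd.Series(component, index=sample_ids,
                                        name="enterotype"),
        clinical_rho={},
    )
    return matrix, meta, truth


def simulate_gene_and_ko_profiles(
    species_matrix: RelAbundanceMatrix,
    config: CohortConfig,
    truth: TruthSpec | None = None,
) -> tuple[RelAbundanceMatrix, FeatureMap, FeatureMap, FeatureMap, dict[str, int]]:
    """Split species over genes (fixed Dirichlet weights) and annotate KOs/modules.

    Returns (gene matrix, gene->species, gene->KO, KO->module,
    diff-module directions).  Designed differential modules draw their KOs
    exclusively from genes of spiked species of one direction, so their
    member-KO profiles inherit the species-level case/control shift.
    """
    pop_seed = config.seed if config.population_seed is None else config.population_seed
    rng = np.random.default_rng(np.random.SeedSequence((pop_seed, 1)))
    species = species_matrix.feature_ids
    g = config.n_genes_per_species

    gene_ids: list[str] = []
    gene_species: list[str] = []
    gene_values = np.empty((len(species) * g, species_matrix.n_samples))
    for si, sp in enumerate(species):
        w = rng.dirichlet(np.ones(g))
        rows = species_matrix.values[si][None, :] * w[:, None]
        gene_values[si * g:(si + 1) * g] = rows
        for gi in range(g):
            gene_ids.append(f"gene_{sp}_{gi:02d}")
            gene_species.append(sp)
    genes = RelAbundanceMatrix.from_arrays(gene_values, gene_ids,
                                           species_matrix.sample_ids)

    n_genes = len(gene_ids)
    n_annot = int(round(config.annotation_fraction * n_genes))
    annotated = set(rng.choice(n_genes, size=n_annot, replace=False).tolist())
    gene_to_species = FeatureMap(
        {gene_ids[i]: gene_species[i] for i in sorted(annotated)}
    )

    diff_species = dict(truth.diff_species) if truth is not None else {}
    pool_up = [i for i in sorted(annotated) if diff_species.get(gene_species[i]) == 1]
    pool_down = [i for i in sorted(annotated) if diff_species.get(gene_species[i]) == -1]
    pool_rest = [i for i in sorted(annotated)
                 if gene_species[i] not in diff_species]

    ko_ids = [f"K{i:05d}" for i in range(config.n_ko)]
    module_ids = [f"M{i:05d}" for i in range(config.n_modules)]
    ko_to_module = FeatureMap(
        {ko_ids[i]: module_ids[i % config.n_modules] for i in range(config.n_ko)}
    )
    module_kos: dict[str, list[str]] = {m: [] for m in module_ids}
    for ko, m in ko_to_module.items():
        module_kos[m].append(ko)

    n_dm = config.n_diff_modules
    n_dm_up = (n_dm + 1) // 2
    diff_modules = {}
    for j, m in enumerate(module_ids[:n_dm]):
        diff_modules[m] = 1 if j < n_dm_up else -1
    if not pool_up:
        diff_modules = {m: d for m, d in diff_modules.items() if d != 1}
    if not pool_down:
        diff_modules = {m: d for m, d in diff_modules.items() if d != -1}

    up_kos = [ko for m, d in diff_modules.items() if d == 1 for ko in module_kos[m]]
    down_kos = [ko for m, d in diff_modules.items() if d == -1 for ko in module_kos[m]]
    rest_kos = [ko for m in module_ids if m not in diff_modules
                for ko in module_kos[m]]
    if not diff_modules:
        pool_rest = sorted(annotated)
        pool_up, pool_down = [], []
        rest_kos = ko_ids

    gene_to_ko: dict[str, str] = {}
    for pool, kos in ((pool_up, up_kos), (pool_down, down_kos),
                      (pool_rest, rest_kos)):
        for j, gi in enumerate(pool):
            if kos:
                gene_to_ko[gene_ids[gi]] = kos[j % len(kos)]
    return genes, gene_to_species, FeatureMap(gene_to_ko), ko_to_module, diff_modules


def simulate_clinical_indices(
    species_matrix: RelAbundanceMatrix,
    metadata: CohortMetadata,
    clinical_targets: Sequence[tuple[str, str, float]],
    seed: int,
) -> CohortMetadata:
    """Add clinical index columns with designed Spearman correlations.

    For a target correlation rho with a species' abundance, the index is
    built from a bivariate-normal latent pair whose Pearson correlation
    r = 2 sin(pi rho / 6) yields population Spearman rho; |rho| = 1 maps the
    species ranks through a monotone function exactly.  Values are mapped to
    a positive scale by exponentiation.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    table = metadata.table.copy()
    known = set(species_matrix.feature_ids)
    n = len(metadata.sample_ids)
    for species_id, index_name, rho in clinical_targets:
        if species_id not in known:
            raise ValueError(f"unknown species id {species_id!r}")
        x = species_matrix.data.loc[species_id, metadata.sample_ids].to_numpy()
        u = sps.rankdata(x, method="average") / (n + 1)
        zx = sps.norm.ppf(u)
        if abs(rho) == 1.0:
            latent = np.sign(rho) * zx
        else:
            r = 2.0 * np.sin(np.pi * rho / 6.0)
            latent = r * zx + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
        table[index_name] = np.exp(0.5 * latent + 1.0)
    return CohortMetadata(table)


def multinomial_counts(
    matrix: RelAbundanceMatrix, depth: int, seed: int
) -> CountMatrix:
    """Seeded multinomial resampling of relative abundances to integer counts.

    This is the documented route from proportion profiles to the count data
    Chao1 and rarefaction require.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    values = matrix.values
    sums = values.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("a sample has zero total abundance")
    counts = np.column_stack(
        [rng.multinomial(depth, values[:, j] / sums[j])
         for j in range(values.shape[1])]
    )
    return CountMatrix(
        pd.DataFrame(counts, index=matrix.feature_ids, columns=matrix.sample_ids)
    )


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the complete fixture set for one cohort."""
    species, meta, truth = simulate_species_profiles(config)
    genes, g2s, g2k, k2m, diff_modules = simulate_gene_and_ko_profiles(
        species, config, truth
    )
    if config.clinical_targets:
        meta = simulate_clinical_indices(
            species, meta, config.clinical_targets, config.seed
        )
    truth = TruthSpec(
        diff_species=truth.diff_species,
        diff_modules=diff_modules,
        enterotype_assignment=truth.enterotype_assignment,
        clinical_rho={(s, i): r for s, i, r in config.clinical_targets},
        driver_species=truth.driver_species,
    )
    return SyntheticCohort(
        species=species, genes=genes, gene_to_species=g2s, gene_to_ko=g2k,
        ko_to_module=k2m, metadata=meta, truth=truth, config=config,
    )
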