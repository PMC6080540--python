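"""End-to-end orchestration: diversity -> enterotypes -> differential abundance
-> markers -> functional enrichment -> clinical associations.

The pipeline is driven by a YAML/JSON config that either names input tables
or contains a ``simulate`` block; menopause strata are analyzed
independently throughout.  Every stage writes its TSV outputs into the
report directory and contributes to a machine-readable ``summary.json``
whose content is fully determined by the config (fixed seeds everywhere).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import diversity as dv
from . import io as gio
from .containers import CohortMetadata, RelAbundanceMatrix
from .enrichment import ReporterScoreModel
from .enterotype import EnterotypeModel, enterotype_phenotype_test
from .markers import MarkerSelectionModel, transfer_test
from .profiling import aggregate_abundance
from .simulate import CohortConfig, SyntheticCohort, multinomial_counts, simulate_cohort
from .stats import DifferentialAbundanceModel, permanova, spearman, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config"]

DEFAULT_THRESHOLDS = {
    "q": 0.05,
    "reporter_z": 1.6,
    "hi_cutoff": 0.50,
    "lo_cutoff": 0.35,
    "chao1_depth": 100_000,
}


def load_config(config_path) -> dict:
    with open(config_path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _load_inputs(cfg: dict) -> SyntheticCohort | dict:
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", cfg.get("seed", 0))
        if "clinical_targets" in sim:
            sim["clinical_targets"] = tuple(
                tuple(t) for t in sim["clinical_targets"]
            )
        return simulate_cohort(CohortConfig(**sim))
    inputs = cfg["inputs"]
    out = {
        "species": gio.read_abundance_table(
            inputs["species"], inputs.get("orientation", "features_in_rows")
        ),
        "metadata": gio.read_metadata(inputs["metadata"]),
    }
    if "genes" in inputs:
        out["genes"] = gio.read_abundance_table(inputs["genes"])
        out["gene_to_ko"] = gio.read_feature_map(inputs["gene_to_ko"])
        out["ko_to_module"] = gio.read_feature_map(inputs["ko_to_module"])
    return out


def _strata(metadata: CohortMetadata) -> list[str]:
    return sorted(metadata.stratum.unique())


def run_pipeline(config_path, output_dir=None) -> Path:
    """Run the full analysis described by a config file; returns the report dir."""
    cfg = load_config(config_path)
    outdir = Path(output_dir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    seed = int(cfg.get("seed", 0))
    n_trees = int(cfg.get("n_trees", 500))
    summary: dict = {"seed": seed, "thresholds": thresholds, "stages": {}}

    data = _load_inputs(cfg)
    if isinstance(data, SyntheticCohort):
        species, metadata = data.species, data.metadata
        genes, g2k, k2m = data.genes, data.gene_to_ko, data.ko_to_module
        gio.write_abundance_table(species, outdir / "species.tsv")
        gio.write_metadata(metadata, outdir / "metadata.tsv")
        truth = {
            "diff_species": data.truth.diff_species,
            "diff_modules": data.truth.diff_modules,
            "enterotype": data.truth.enterotype_assignment.to_dict(),
        }
        (outdir / "truth.json").write_text(json.dumps(truth, sort_keys=True, indent=1))
    else:
        species, metadata = data["species"], data["metadata"]
        genes, g2k, k2m = data.get("genes"), data.get("gene_to_ko"), data.get("ko_to_module")
    strata = _strata(metadata)

    def stage(name):
        logger.info("stage: %s", name)
        return summary["stages"].setdefault(name, {})

    # --- diversity -------------------------------------------------------
    try:
        s = stage("diversity")
        counts = multinomial_counts(species, int(thresholds["chao1_depth"]), seed)
        alpha = dv.alpha_diversity_table(species, counts)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        dist = dv.jsd_matrix(species)
        gio.write_distance_matrix(dist, outdir / "jsd.tsv")
        for st in strata:
            ids = metadata.samples_in(stratum=st)
            sub = metadata.subset(ids)
            beta = dv.mean_within_group_jsd(dist.subset(ids), sub.group)
            beta.to_csv(outdir / f"beta_diversity_{st}.tsv", sep="\t")
            case = alpha.loc[sub.samples_in(group="case")]
            ctrl = alpha.loc[sub.samples_in(group="control")]
            s[st] = {
                "richness_p": wilcoxon_rank_sum(case["richness"], ctrl["richness"]),
                "shannon_p": wilcoxon_rank_sum(case["shannon"], ctrl["shannon"]),
                "chao1_p": wilcoxon_rank_sum(case["chao1"], ctrl["chao1"]),
                "beta_p": wilcoxon_rank_sum(
                    beta.loc[case.index, "mean_within_group_jsd"],
                    beta.loc[ctrl.index, "mean_within_group_jsd"],
                ),
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'diversity' failed: {exc}") from exc

    # --- enterotyping ----------------------------------------------------
    try:
        s = stage("enterotype")
        k_max = min(int(cfg.get("k_max", 10)), species.n_samples - 1)
        model = EnterotypeModel(species, k_max=k_max)
        ent = model.fit(seed=seed)
        ent.assignment.to_frame().to_csv(outdir / "enterotypes.tsv", sep="\t")
        pd.Series(ent.ch_by_k, name="ch_index").rename_axis("k").to_csv(
            outdir / "ch_by_k.tsv", sep="\t"
        )
        s["k_optimal"] = int(ent.k_optimal)
        s["weak_structure"] = bool(ent.weak_structure)
        s["driver_taxa"] = {str(c): t for c, t in ent.driver_taxa.items()}
        s["phenotype_p"] = {}
        for st in strata:
            try:
                s["phenotype_p"][st] = enterotype_phenotype_test(
                    ent.assignment, metadata, stratum=st, seed=seed
                )
            except ValueError:
                s["phenotype_p"][st] = None  # degenerate table in tiny cohorts
    except Exception as exc:
        raise RuntimeError(f"stage 'enterotype' failed: {exc}") from exc

    # --- differential abundance + PERMANOVA -----------------------------
    try:
        s = stage("differential")
        for st in strata:
            res = DifferentialAbundanceModel(species, metadata, stratum=st).fit(
                alpha=thresholds["q"]
            )
            res.table.to_csv(outdir / f"differential_{st}.tsv", sep="\t")
            sig = res.significant
            ids = metadata.samples_in(stratum=st)
            perm = permanova(
                dv.jsd_matrix(species.select_samples(ids)),
                metadata.group.loc[ids].to_numpy(),
                n_perm=int(cfg.get("n_perm", 999)),
                seed=seed,
            )
            s[st] = {
                "n_significant": int(len(sig)),
                "n_enriched_in_case": int(
                    (sig["direction"] == "enriched_in_case").sum()
                ),
                "n_enriched_in_control": int(
                    (sig["direction"] == "enriched_in_control").sum()
                ),
                "permanova_p": perm.p_value,
                "permanova_R2": perm.R2,
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'differential' failed: {exc}") from exc

    # --- marker selection ------------------------------------------------
    try:
        s = stage("classifier")
        train_stratum = cfg.get("train_stratum", strata[-1])
        model = MarkerSelectionModel(species, metadata, stratum=train_stratum)
        res = model.fit(seed=seed, n_trees=n_trees,
                        hi=thresholds["hi_cutoff"], lo=thresholds["lo_cutoff"])
        res.error_curve.to_csv(outdir / "error_curve.tsv", sep="\t", index=False)
        res.probabilities.to_frame().join(res.calls["call"]).to_csv(
            outdir / "case_probabilities.tsv", sep="\t"
        )
        s["train_stratum"] = train_stratum
        s["n_markers"] = int(res.n_optimal)
        s["markers"] = list(res.selected_features)
        s["auc"] = res.auc
        s["auc_ci"] = list(res.auc_ci)
        others = [st for st in strata if st != train_stratum]
        if others:
            test_ids = metadata.samples_in(stratum=others[0])
            _, auc_t, ci_t = transfer_test(
                res.selected_features,
                model.matrix, model.labels,
                species.select_samples(test_ids),
                metadata.group.loc[test_ids].to_numpy(),
                seed=seed, n_trees=n_trees,
            )
            s["transfer_stratum"] = others[0]
            s["transfer_auc"] = auc_t
            s["transfer_auc_ci"] = list(ci_t)
    except Exception as exc:
        raise RuntimeError(f"stage 'classifier' failed: {exc}") from exc

    # --- functional enrichment -------------------------------------------
    if genes is not None and g2k is not None and k2m is not None:
        try:
            s = stage("enrichment")
            ko_matrix = aggregate_abundance(genes, g2k)
            gio.write_abundance_table(ko_matrix, outdir / "ko_profile.tsv")
            for st in strata:
                res = ReporterScoreModel(ko_matrix, metadata, k2m, stratum=st).fit(
                    seed=seed, threshold=thresholds["reporter_z"]
                )
                res.modules.to_csv(outdir / f"reporter_{st}.tsv", sep="\t")
                enr = res.enriched
                s[st] = {
                    "n_modules_scored": int(len(res.modules)),
                    "n_enriched": int(len(enr)),
                    "enriched_modules": sorted(enr.index),
                }
        except Exception as exc:
            raise RuntimeError(f"stage 'enrichment' failed: {exc}") from exc

    # --- clinical associations -------------------------------------------
    clinical = metadata.clinical_indices
    if clinical.shape[1] > 0:
        try:
            s = stage("association")
            rows = []
            for st in strata:
                table = pd.read_csv(outdir / f"differential_{st}.tsv", sep="\t",
                                    index_col=0)
                feats = table[table["q_value"] < thresholds["q"]].index
                ids = metadata.samples_in(stratum=st, group="case")
                for feat in feats:
                    x = species.data.loc[feat, ids].to_numpy()
                    for col in clinical.columns:
                        y = clinical.loc[ids, col].to_numpy(dtype=float)
                        try:
                            rho, p = spearman(x, y)
                        except ValueError:
                            continue
                        rows.append((st, feat, col, rho, p))
            assoc = pd.DataFrame(
                rows, columns=["stratum", "species", "index", "rho", "p_value"]
            )
            assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)
            s["n_tested"] = int(len(assoc))
            s["n_nominal"] = int((assoc["p_value"] < 0.05).sum())
        except Exception as exc:
            raise RuntimeError(f"stage 'association' failed: {exc}") from exc

    (outdir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1, default=float)
    )
    return outdir
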