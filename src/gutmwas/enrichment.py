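"""Reporter-score enrichment of KEGG modules from per-KO differential statistics.

Each KO's two-sided Wilcoxon p-value is inverse-normal transformed to a Z
score, Z = Phi^-1(1 - p), signed positive when the KO is enriched in cases.
A module's raw reporter score aggregates its k member KOs as
z_raw = (sum Z) / sqrt(k).  Because modules of different sizes have different
null scales once the KO Z's deviate from standard normal, the score is
background-corrected: for every distinct k, random KO sets of size k drawn
from all scored KOs give a mean mu_k and sd sigma_k, and
z_adjusted = (z_raw - mu_k) / sigma_k.  Modules with z_adjusted beyond the
enrichment threshold (|Z| > 1.6, evaluated one-sided per direction) are
called differentially enriched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CohortMetadata, FeatureMap, RelAbundanceMatrix
from .stats import DifferentialAbundanceModel, DifferentialAbundanceResults

logger = logging.getLogger(__name__)

__all__ = [
    "ko_z_scores",
    "reporter_score",
    "ReporterScoreModel",
    "ReporterScoreResults",
    "DEFAULT_REPORTER_THRESHOLD",
]

DEFAULT_REPORTER_THRESHOLD = 1.6
#: cap on |Z| so p-values of exactly 0 (or numerically tiny) stay finite
DEFAULT_Z_CLIP = 8.0


def ko_z_scores(
    p_values: Sequence[float],
    directions: Sequence[str],
    z_clip: float = DEFAULT_Z_CLIP,
) -> np.ndarray:
    """Signed inverse-normal Z scores from per-KO p-values.

    ``directions`` holds ``"enriched_in_case"`` / ``"enriched_in_control"``
    per KO; case enrichment is signed positive.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    dirs = np.asarray(directions)
    if dirs.size != p.size:
        raise ValueError("one direction per p-value required")
    if (p == 0).any():
        logger.warning("p-values of exactly 0 clipped to Z = %g", z_clip)
    z = sps.norm.ppf(1.0 - p)
    z = np.clip(z, -z_clip, z_clip)
    sign = np.where(dirs == "enriched_in_case", 1.0, -1.0)
    return z * sign


def reporter_score(
    z: Sequence[float],
    ko_ids: Sequence[str],
    ko_to_module: FeatureMap,
    n_background: int = 1000,
    seed: int | None = 0,
    threshold: float = DEFAULT_REPORTER_THRESHOLD,
) -> pd.DataFrame:
    """Background-corrected reporter scores per module.

    Returns a DataFrame indexed by module id with columns ``k``, ``z_raw``,
    ``z_adjusted``, ``direction`` and ``enriched``, sorted by descending
    ``|z_adjusted|``.
    """
    z = np.asarray(z, dtype=float)
    ko_ids = list(ko_ids)
    if len(ko_ids) != z.size:
        raise ValueError("one KO id per Z score required")
    z_by_ko = dict(zip(ko_ids, z))
    members: dict[str, list[float]] = {}
    for ko, module in ko_to_module.items():
        if ko in z_by_ko:
            members.setdefault(module, []).append(z_by_ko[ko])
    if not members:
        raise ValueError("no module has a scored member KO")
    rng = np.random.default_rng(seed)
    mu_sigma: dict[int, tuple[float, float]] = {}
    for k in sorted({len(v) for v in members.values()}):
        if k >= z.size:
            raise ValueError(
                f"module size {k} is not smaller than the KO universe ({z.size}); "
                "background sampling needs a larger universe"
            )
        draws = np.empty(n_background)
        for b in range(n_background):
            sel = rng.choice(z.size, size=k, replace=False)
            draws[b] = z[sel].sum() / np.sqrt(k)
        mu_sigma[k] = (float(draws.mean()), float(draws.std(ddof=1)))
    rows = []
    for module in sorted(members):
        zs = np.asarray(members[module])
        k = zs.size
        z_raw = zs.sum() / np.sqrt(k)
        mu, sigma = mu_sigma[k]
        if sigma <= 0:
            # a constant universe gives a flat background; only the exactly
            # null score is well-defined there
            if abs(z_raw - mu) < 1e-12:
                z_adj = 0.0
            else:
                raise ValueError(
                    f"degenerate background for module size {k}; "
                    "use a larger or more variable KO universe"
                )
        else:
            z_adj = (z_raw - mu) / sigma
        direction = "case" if z_adj >= 0 else "control"
        rows.append(
            {
                "module_id": module,
                "k": k,
                "z_raw": z_raw,
                "z_adjusted": z_adj,
                "direction": direction,
                "enriched": abs(z_adj) > threshold,
            }
        )
    out = pd.DataFrame(rows).set_index("module_id")
    return out.iloc[np.argsort(-out["z_adjusted"].abs().to_numpy(), kind="stable")]


@dataclass(frozen=True)
class ReporterScoreResults:
    """Per-KO differential table plus per-module reporter scores."""

    ko_results: DifferentialAbundanceResults
    modules: pd.DataFrame
    threshold: float

    @property
    def enriched(self) -> pd.DataFrame:
        return self.modules[self.modules["enriched"]]

    def summary(self) -> str:
        enr = self.enriched
        case = (enr["direction"] == "case").sum()
        ctrl = (enr["direction"] == "control").sum()
        return (
            "Reporter-score module enrichment\n"
            f"  KOs tested             {len(self.ko_results.table)}\n"
            f"  modules scored         {len(self.modules)}\n"
            f"  enriched (|Z|>{self.threshold:g})   {len(enr)}"
            f"  ({case} toward cases, {ctrl} toward controls)\n"
        )


class ReporterScoreModel:
    """Module enrichment from a KO profile and case/control metadata.

    Runs the per-KO Wilcoxon comparison, converts p-values to signed Z
    scores, and aggregates them per KEGG module with background correction.

    ``significant_only=True`` restricts the aggregation to KOs significant at
    q < 0.05 (a stricter literal reading); the default uses every scored KO,
    following the reporter-feature method the score derives from.
    """

    def __init__(
        self,
        ko_matrix: RelAbundanceMatrix,
        metadata: CohortMetadata,
        ko_to_module: FeatureMap,
        stratum: str | None = None,
        significant_only: bool = False,
    ) -> None:
        self.ko_matrix = ko_matrix
        self.metadata = metadata
        self.ko_to_module = ko_to_module
        self.stratum = stratum
        self.significant_only = significant_only

    def fit(
        self,
        n_background: int = 1000,
        seed: int | None = 0,
        threshold: float = DEFAULT_REPORTER_THRESHOLD,
    ) -> ReporterScoreResults:
        ko_res = DifferentialAbundanceModel(
            self.ko_matrix, self.metadata, stratum=self.stratum
        ).fit()
        table = ko_res.table
        if self.significant_only:
            table = table[table["q_value"] < 0.05]
            if table.empty:
                raise ValueError("no KO significant at q < 0.05")
        z = ko_z_scores(table["p_value"].to_numpy(), table["direction"].to_numpy())
        modules = reporter_score(
            z, list(table.index), self.ko_to_module,
            n_background=n_background, seed=seed, threshold=threshold,
        )
        return ReporterScoreResults(ko_results=ko_res, modules=modules,
                                    threshold=threshold)
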