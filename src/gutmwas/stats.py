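"""Hypothesis tests and multiple-testing correction for profile comparisons.

The differential-abundance workflow is exposed statsmodels-style: build a
:class:`DifferentialAbundanceModel` from a profile matrix plus cohort
metadata, call :meth:`~DifferentialAbundanceModel.fit`, and read the
per-feature table off the returned results object.  The primitive tests
(Wilcoxon rank-sum, BH adjustment, PERMANOVA, Spearman, summary t, chi-square,
Fisher exact) are plain functions delegating to scipy/statsmodels where those
implement the standard form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import CohortMetadata, DistanceMatrix, RelAbundanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "wilcoxon_rank_sum",
    "bh_adjust",
    "DifferentialAbundanceModel",
    "DifferentialAbundanceResults",
    "differential_abundance",
    "permanova",
    "PermanovaResult",
    "spearman",
    "t_test_from_summary",
    "chi_square_test",
    "fisher_exact_2x2",
]

#: exact Wilcoxon enumeration is used at or below this combined sample size
EXACT_WILCOXON_MAX_N = 12


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["auto", "exact", "approx"] = "auto",
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``auto`` enumerates exactly when ``len(x)+len(y) <= 12`` and there are no
    ties, matching R's ``wilcox.test`` switchover for small samples; otherwise
    the normal approximation with tie and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if mode == "exact" or (
        mode == "auto" and x.size + y.size <= EXACT_WILCOXON_MAX_N and not has_ties
    ):
        method = "exact"
    else:
        method = "asymptotic"
    if method == "exact" and has_ties:
        # exact null distribution is undefined under ties; scipy falls back
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order kept."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class PermanovaResult:
    """Distance-based pseudo-F test of a grouping factor."""

    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int

    def summary(self) -> str:
        return (
            "PERMANOVA\n"
            f"  pseudo-F       {self.pseudo_F:.4f}\n"
            f"  R2             {self.R2:.4f}\n"
            f"  p-value        {self.p_value:.4g}\n"
            f"  permutations   {self.n_permutations}\n"
        )


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size < 1:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss_total, ss_within


def permanova(
    dist: DistanceMatrix,
    labels: Sequence[str],
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F = [SS_between/(k-1)] / [SS_within/(n-k)] with the distance-based
    sum-of-squares partition; the p-value is (#{F_perm >= F_obs} + 1)/(n_perm + 1)
    under free permutation of sample labels.
    """
    labels = np.asarray(labels)
    n = dist.n_samples
    if labels.size != n:
        raise ValueError(f"got {labels.size} labels for {n} samples")
    uniq, codes = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValueError("need at least two groups")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    d2 = dist.values ** 2

    def f_stat(c: np.ndarray) -> float:
        ss_total, ss_within = _permanova_ss(d2, c, k)
        ss_between = ss_total - ss_within
        if ss_within <= 0:
            return np.inf if ss_between > 0 else 0.0
        return (ss_between / (k - 1)) / (ss_within / (n - k))

    f_obs = f_stat(codes)
    ss_total, ss_within = _permanova_ss(d2, codes, k)
    r2 = (ss_total - ss_within) / ss_total if ss_total > 0 else 0.0
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if f_stat(rng.permutation(codes)) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with pairwise deletion of missing values.

    Mid-ranks handle ties; the p-value uses the t approximation.  Requires at
    least 4 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 4:
        raise ValueError(f"need >= 4 complete pairs, got {int(mask.sum())}")
    rho, p = sps.spearmanr(x[mask], y[mask])
    return float(rho), float(p)


def t_test_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: Literal["pooled", "welch"] = "pooled",
) -> float:
    """Two-sided two-sample t-test p-value from group summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    return float(res.pvalue)


def chi_square_test(table: Sequence[Sequence[int]]) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c contingency table, no continuity correction.

    Returns (statistic, df, p).
    """
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("negative cell counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table (sum of tables no more probable)."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if table.sum() == 0:
        raise ValueError("empty table")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


@dataclass(frozen=True)
class DifferentialAbundanceResults:
    """Per-feature Wilcoxon + BH table in the control/case summary layout."""

    table: pd.DataFrame  # indexed by feature_id
    n_case: int
    n_control: int
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        """Features at q < alpha, most significant first."""
        sig = self.table[self.table["q_value"] < self.alpha]
        return sig.sort_values("q_value")

    def summary(self) -> str:
        sig = self.significant
        up = (sig["direction"] == "enriched_in_case").sum()
        down = (sig["direction"] == "enriched_in_control").sum()
        lines = [
            "Differential abundance (Wilcoxon rank-sum + Benjamini-Hochberg)",
            f"  features tested      {len(self.table)}",
            f"  cases / controls     {self.n_case} / {self.n_control}",
            f"  significant (q<{self.alpha:g})  {len(sig)}"
            f"  ({up} enriched in cases, {down} in controls)",
        ]
        return "\n".join(lines) + "\n"


class DifferentialAbundanceModel:
    """Feature-wise case/control comparison of a relative-abundance profile.

    Parameters
    ----------
    matrix :
        Feature profile (species, genus, KO, VF ...), features x samples.
    metadata :
        Cohort metadata supplying the case/control labels.
    stratum :
        Optional menopause stratum; when given, only samples of that stratum
        enter the comparison (the two strata are always analyzed separately).
    min_prevalence :
        Minimum fraction of samples in which a feature must be detected
        (abundance > 0) to be tested.  Default 0 tests everything.
    """

    def __init__(
        self,
        matrix: RelAbundanceMatrix,
        metadata: CohortMetadata,
        stratum: str | None = None,
        min_prevalence: float = 0.0,
    ) -> None:
        samples = metadata.samples_in(stratum=stratum)
        samples = [s for s in samples if s in set(matrix.sample_ids)]
        if not samples:
            raise ValueError("no overlap between matrix samples and metadata")
        self.matrix = matrix.select_samples(samples)
        self.metadata = metadata.subset(samples)
        self.min_prevalence = float(min_prevalence)
        groups = self.metadata.group
        self.case_ids = [s for s in samples if groups[s] == "case"]
        self.control_ids = [s for s in samples if groups[s] == "control"]
        if not self.case_ids or not self.control_ids:
            raise ValueError("both case and control samples are required")

    def fit(self, alpha: float = 0.05) -> DifferentialAbundanceResults:
        df = self.matrix.data
        case = df[self.case_ids].to_numpy()
        ctrl = df[self.control_ids].to_numpy()
        n_samples = case.shape[1] + ctrl.shape[1]
        prevalence = (np.concatenate([case, ctrl], axis=1) > 0).sum(axis=1) / n_samples
        keep = prevalence >= self.min_prevalence
        dropped = int((~keep).sum())
        if dropped:
            logger.info("prevalence filter removed %d features", dropped)
        features = df.index[keep]
        rows = []
        for i, feat in zip(np.flatnonzero(keep), features):
            p = wilcoxon_rank_sum(case[i], ctrl[i])
            mc, mk = case[i].mean(), ctrl[i].mean()
            rows.append(
                {
                    "feature_id": feat,
                    "p_value": p,
                    "mean_control": mk,
                    "sd_control": ctrl[i].std(ddof=1),
                    "mean_case": mc,
                    "sd_case": case[i].std(ddof=1),
                    "direction": "enriched_in_case" if mc >= mk else "enriched_in_control",
                }
            )
        table = pd.DataFrame(rows).set_index("feature_id")
        table.insert(1, "q_value", bh_adjust(table["p_value"].to_numpy()))
        return DifferentialAbundanceResults(
            table, n_case=len(self.case_ids), n_control=len(self.control_ids),
            alpha=alpha,
        )


def differential_abundance(
    matrix: RelAbundanceMatrix,
    metadata: CohortMetadata,
    stratum: str | None = None,
    min_prevalence: float = 0.0,
    alpha: float = 0.05,
) -> DifferentialAbundanceResults:
    """Functional shortcut for :class:`DifferentialAbundanceModel`."""
    return DifferentialAbundanceModel(
        matrix, metadata, stratum=stratum, min_prevalence=min_prevalence
    ).fit(alpha=alpha)
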