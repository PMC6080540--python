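"""Random-forest microbial marker selection and evaluation.

The protocol mirrors the common metagenomic-marker recipe: (1) rank species
by random-forest importance and estimate cross-validated error over a
halving grid of feature counts; (2) pick the smallest marker panel whose mean
CV error stays within one standard deviation of the minimum (the one-SE
rule); (3) score every sample with its out-of-fold case probability from
repeated stratified CV; (4) evaluate with the ROC AUC (Mann-Whitney identity)
and a DeLong 95% confidence interval; (5) call samples Case / Uncertain /
NotCase with two probability cutoffs (default: case above 50%, not-case
below 35%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .containers import CohortMetadata, RelAbundanceMatrix

__all__ = [
    "cv_feature_elimination",
    "cv_case_probabilities",
    "roc_auc",
    "assign_case_status",
    "transfer_test",
    "MarkerSelectionModel",
    "MarkerSelectionResults",
]

DEFAULT_N_TREES = 500
HI_CUTOFF = 0.50
LO_CUTOFF = 0.35


def _binary_labels(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "SUO":
        return (y == "case").astype(int)
    return y.astype(int)


def _forest(seed: int, n_trees: int = DEFAULT_N_TREES) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )


def _halving_grid(n_features: int) -> list[int]:
    grid = []
    n = n_features
    while n >= 1:
        grid.append(n)
        n //= 2
    return grid


def cv_feature_elimination(
    matrix: RelAbundanceMatrix,
    labels: Sequence,
    n_folds: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> tuple[pd.DataFrame, int, list[str]]:
    """Cross-validated error over a halving grid of top-ranked feature counts.

    Features are ranked by mean-decrease-in-impurity importance of a forest
    fitted to the full data; per repeat, stratified k-fold CV error is
    measured at each grid size using the top-ranked features.  The optimal
    count is the smallest whose mean error does not exceed the minimum mean
    error plus the between-repeat SD at the minimizing count.

    Returns (error curve DataFrame with columns n_features/mean_error/sd_error,
    n_optimal, ranked feature ids).
    """
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = matrix.values.T  # samples x features
    rng = np.random.SeedSequence(seed)
    rank_seed, *rep_seeds = [int(s.generate_state(1)[0] % 2**31)
                             for s in rng.spawn(n_repeats + 1)]
    ranker = _forest(rank_seed, n_trees).fit(X, y)
    order = np.argsort(-ranker.feature_importances_, kind="stable")
    ranked = [matrix.feature_ids[i] for i in order]
    grid = _halving_grid(X.shape[1])
    errors = np.zeros((n_repeats, len(grid)))
    for r, rs in enumerate(rep_seeds):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
        folds = list(skf.split(X, y))
        for gi, m in enumerate(grid):
            cols = order[:m]
            wrong = 0
            for fi, (tr, te) in enumerate(folds):
                clf = _forest(rs + 7919 * fi + m, n_trees)
                clf.fit(X[np.ix_(tr, cols)], y[tr])
                wrong += (clf.predict(X[np.ix_(te, cols)]) != y[te]).sum()
            errors[r, gi] = wrong / len(y)
    mean_err = errors.mean(axis=0)
    sd_err = errors.std(axis=0, ddof=1) if n_repeats > 1 else errors.std(axis=0)
    curve = pd.DataFrame(
        {"n_features": grid, "mean_error": mean_err, "sd_error": sd_err}
    )
    i_min = int(np.argmin(mean_err))
    cutoff = mean_err[i_min] + sd_err[i_min]
    admissible = [g for g, e in zip(grid, mean_err) if e <= cutoff + 1e-12]
    n_optimal = min(admissible)
    return curve, n_optimal, ranked


def cv_case_probabilities(
    matrix: RelAbundanceMatrix,
    labels: Sequence,
    selected_features: Sequence[str] | None = None,
    n_folds: int = 10,
    n_repeats: int = 5,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> pd.Series:
    """Out-of-fold case probability per sample, averaged over CV repeats.

    Each repeat runs stratified k-fold CV; a sample's probability is the
    forest vote fraction for the case class from the fold in which it was
    held out, averaged across repeats.
    """
    y = _binary_labels(labels)
    if selected_features is not None:
        missing = [f for f in selected_features if f not in set(matrix.feature_ids)]
        if missing:
            raise ValueError(f"selected features absent from matrix: {missing[:10]}")
        matrix = matrix.select_features(selected_features)
    X = matrix.values.T
    n_folds = min(n_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        raise ValueError("too few samples per class for cross-validation")
    rep_seeds = [int(s.generate_state(1)[0] % 2**31)
                 for s in np.random.SeedSequence(seed).spawn(n_repeats)]
    probs = np.zeros((n_repeats, len(y)))
    for r, rs in enumerate(rep_seeds):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
        for fi, (tr, te) in enumerate(skf.split(X, y)):
            clf = _forest(rs + 7919 * fi, n_trees)
            clf.fit(X[tr], y[tr])
            case_col = list(clf.classes_).index(1)
            probs[r, te] = clf.predict_proba(X[te])[:, case_col]
    return pd.Series(probs.mean(axis=0), index=matrix.sample_ids,
                     name="case_probability")


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the AUC estimate from case and control scores."""
    m, n = pos.size, neg.size

    def midrank(x: np.ndarray) -> np.ndarray:
        return sps.rankdata(x, method="average")

    all_scores = np.concatenate([pos, neg])
    r_all = midrank(all_scores)
    r_pos = midrank(pos)
    r_neg = midrank(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r_all[:m] - r_pos) / n - auc + 0.5  # placements of cases
    v01 = 1.0 - (r_all[m:] - r_neg) / m - auc + 0.5
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(
    probabilities: Sequence[float],
    labels: Sequence,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """ROC AUC (percent) with a DeLong confidence interval (percent).

    The AUC is the Mann-Whitney probability that a random case scores above
    a random control, ties counted one half.
    """
    y = _binary_labels(labels)
    p = np.asarray(probabilities, dtype=float)
    pos = p[y == 1]
    neg = p[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * equal) / (pos.size * neg.size)
    se = np.sqrt(_delong_variance(pos, neg))
    zq = sps.norm.ppf(0.5 + ci_level / 2)
    lo = max(0.0, auc - zq * se)
    hi = min(1.0, auc + zq * se)
    return 100.0 * auc, (100.0 * lo, 100.0 * hi)


def assign_case_status(
    probabilities: pd.Series | Sequence[float],
    hi: float = HI_CUTOFF,
    lo: float = LO_CUTOFF,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Three-way Case / Uncertain / NotCase calls from case probabilities.

    Strictly above ``hi`` -> Case; strictly below ``lo`` -> NotCase;
    anything else, including exact boundary values, -> Uncertain.
    """
    if isinstance(probabilities, pd.Series):
        ids = list(probabilities.index)
        p = probabilities.to_numpy(dtype=float)
    else:
        p = np.asarray(probabilities, dtype=float)
        ids = list(sample_ids) if sample_ids is not None else list(range(p.size))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    calls = np.where(p > hi, "Case", np.where(p < lo, "NotCase", "Uncertain"))
    return pd.DataFrame({"probability": p, "call": calls}, index=ids)


def transfer_test(
    selected_features: Sequence[str],
    train_matrix: RelAbundanceMatrix,
    train_labels: Sequence,
    test_matrix: RelAbundanceMatrix,
    test_labels: Sequence,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> tuple[pd.Series, float, tuple[float, float]]:
    """Evaluate trained markers on an independent cohort.

    A forest is fitted on the full training cohort restricted to the marker
    panel and applied to the held-out cohort.  Returns (test case
    probabilities, test AUC %, CI %).
    """
    missing = [f for f in selected_features
               if f not in set(test_matrix.feature_ids)]
    if missing:
        raise ValueError(f"markers missing from test matrix: {missing[:10]}")
    Xtr = train_matrix.select_features(selected_features).values.T
    Xte = test_matrix.select_features(selected_features).values.T
    ytr = _binary_labels(train_labels)
    clf = _forest(seed, n_trees).fit(Xtr, ytr)
    case_col = list(clf.classes_).index(1)
    p = clf.predict_proba(Xte)[:, case_col]
    probs = pd.Series(p, index=test_matrix.sample_ids, name="case_probability")
    auc, ci = roc_auc(p, test_labels)
    return probs, auc, ci


@dataclass(frozen=True)
class MarkerSelectionResults:
    """Selected marker panel, CV error curve, per-sample probabilities, AUC."""

    error_curve: pd.DataFrame
    n_optimal: int
    ranked_features: list[str] = field(repr=False)
    selected_features: list[str]
    probabilities: pd.Series = field(repr=False)
    auc: float
    auc_ci: tuple[float, float]
    calls: pd.DataFrame = field(repr=False)

    def summary(self) -> str:
        n_case_calls = (self.calls["call"] == "Case").sum()
        n_not = (self.calls["call"] == "NotCase").sum()
        n_unc = (self.calls["call"] == "Uncertain").sum()
        return (
            "Random-forest marker selection\n"
            f"  markers selected   {self.n_optimal}: "
            f"{', '.join(self.selected_features[:5])}"
            f"{' ...' if self.n_optimal > 5 else ''}\n"
            f"  CV AUC             {self.auc:.2f}% "
            f"(95% CI {self.auc_ci[0]:.2f}-{self.auc_ci[1]:.2f}%)\n"
            f"  calls              {n_case_calls} Case, {n_unc} Uncertain, "
            f"{n_not} NotCase\n"
        )


class MarkerSelectionModel:
    """End-to-end marker discovery on a species profile.

    Parameters
    ----------
    matrix :
        Species x sample relative abundances.
    metadata :
        Cohort metadata (labels taken as case vs control), optionally
        restricted to one menopause stratum.
    """

    def __init__(
        self,
        matrix: RelAbundanceMatrix,
        metadata: CohortMetadata,
        stratum: str | None = None,
    ) -> None:
        samples = [s for s in metadata.samples_in(stratum=stratum)
                   if s in set(matrix.sample_ids)]
        if not samples:
            raise ValueError("no overlap between matrix samples and metadata")
        self.matrix = matrix.select_samples(samples)
        self.labels = metadata.group.loc[samples].to_numpy()

    def fit(
        self,
        elim_folds: int = 5,
        elim_repeats: int = 5,
        prob_folds: int = 10,
        prob_repeats: int = 5,
        seed: int = 0,
        n_trees: int = DEFAULT_N_TREES,
        hi: float = HI_CUTOFF,
        lo: float = LO_CUTOFF,
    ) -> MarkerSelectionResults:
        curve, n_opt, ranked = cv_feature_elimination(
            self.matrix, self.labels, n_folds=elim_folds,
            n_repeats=elim_repeats, seed=seed, n_trees=n_trees,
        )
        selected = ranked[:n_opt]
        probs = cv_case_probabilities(
            self.matrix, self.labels, selected_features=selected,
            n_folds=prob_folds, n_repeats=prob_repeats, seed=seed + 1,
            n_trees=n_trees,
        )
        auc, ci = roc_auc(probs.to_numpy(), self.labels)
        calls = assign_case_status(probs, hi=hi, lo=lo)
        return MarkerSelectionResults(
            error_curve=curve, n_optimal=n_opt, ranked_features=ranked,
            selected_features=selected, probabilities=probs,
            auc=auc, auc_ci=ci, calls=calls,
        )
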