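"""Enterotype discovery: PAM clustering on Jensen-Shannon dissimilarities with
Calinski-Harabasz model selection.

Gut communities recur in a small number of compositional configurations
("enterotypes"), classically a Bacteroides-dominated and a
Prevotella-dominated type.  :class:`EnterotypeModel` reproduces the standard
recipe: genus-level JSD matrix -> partitioning around medoids for k = 2..k_max
-> Calinski-Harabasz index per k -> optimum at the argmax (smallest k on
ties).  The PAM implementation is the classical BUILD + SWAP algorithm
operating directly on the dissimilarity matrix, and the CH index uses the
distance-based sum-of-squares decomposition, which coincides with the
familiar centroid form on Euclidean embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CohortMetadata, DistanceMatrix, RelAbundanceMatrix
from .diversity import jsd_matrix
from .stats import fisher_exact_2x2

__all__ = [
    "pam",
    "calinski_harabasz",
    "calinski_harabasz_euclidean",
    "EnterotypeModel",
    "EnterotypeResults",
    "enterotype_phenotype_test",
]


def _total_cost(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def pam(
    dist: DistanceMatrix,
    k: int,
    seed: int | None = None,
    max_iter: int = 300,
) -> tuple[np.ndarray, list[int]]:
    """Partitioning around medoids on a dissimilarity matrix.

    BUILD greedily seeds k medoids, then SWAP exchanges a medoid and a
    non-medoid while any exchange lowers the total distance of samples to
    their nearest medoid.  Ties are broken by smallest sample index, making
    the result deterministic; ``seed`` is accepted for interface symmetry but
    the algorithm has no stochastic step.

    Returns (assignment codes aligned with ``dist.sample_ids``, medoid indices).
    """
    d = dist.values
    n = d.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    # BUILD: first medoid minimizes total distance; then best marginal gain
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, -1
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(current - d[:, j], 0.0).sum()
            if gain > best_gain + 1e-15:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    # SWAP until no exchange improves the configuration
    cost = _total_cost(d, medoids)
    for _ in range(max_iter):
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1:]
                delta = cost - _total_cost(d, trial)
                if delta > best[0] + 1e-12:
                    best = (delta, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        cost -= best[0]
    medoids = sorted(medoids)
    assignment = np.argmin(d[:, medoids], axis=1)
    # medoids belong to their own cluster even under distance ties
    for ci, m in enumerate(medoids):
        assignment[m] = ci
    return assignment, medoids


def calinski_harabasz(dist: DistanceMatrix, assignment: Sequence[int]) -> float:
    """Calinski-Harabasz index from pairwise dissimilarities.

    Uses the sum-of-squares decomposition T = (1/n) sum_{i<j} d_ij^2,
    W = sum_clusters (1/n_c) sum_{i<j in c} d_ij^2, B = T - W,
    CH = [B/(k-1)] / [W/(n-k)].
    """
    codes = np.asarray(assignment)
    d2 = dist.values ** 2
    n = d2.shape[0]
    if codes.size != n:
        raise ValueError("one assignment per sample required")
    clusters = np.unique(codes)
    k = clusters.size
    if k < 2:
        raise ValueError("need at least two clusters")
    iu = np.triu_indices(n, k=1)
    total = d2[iu].sum() / n
    within = 0.0
    for c in clusters:
        idx = np.flatnonzero(codes == c)
        if idx.size == 0:
            raise ValueError(f"cluster {c} is empty")
        sub = d2[np.ix_(idx, idx)]
        within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    between = total - within
    if within <= 0:
        return 0.0 if between <= 0 else np.inf
    return float((between / (k - 1)) / (within / (n - k)))


def calinski_harabasz_euclidean(points: np.ndarray, assignment: Sequence[int]) -> float:
    """Centroid-form CH index on a Euclidean embedding (cross-check form)."""
    x = np.atleast_2d(np.asarray(points, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    codes = np.asarray(assignment)
    n = x.shape[0]
    clusters = np.unique(codes)
    k = clusters.size
    grand = x.mean(axis=0)
    between = 0.0
    within = 0.0
    for c in clusters:
        sub = x[codes == c]
        cen = sub.mean(axis=0)
        between += sub.shape[0] * ((cen - grand) ** 2).sum()
        within += ((sub - cen) ** 2).sum()
    if within <= 0:
        return 0.0 if between <= 0 else np.inf
    return float((between / (k - 1)) / (within / (n - k)))


@dataclass(frozen=True)
class EnterotypeResults:
    """PAM/CH enterotyping of a genus profile."""

    k_optimal: int
    ch_by_k: dict[int, float]
    assignment: pd.Series  # sample_id -> cluster id (int, 0-based)
    medoids: list[str]
    driver_taxa: dict[int, list[str]]
    weak_structure: bool
    distance: DistanceMatrix = field(repr=False)

    def summary(self) -> str:
        lines = ["Enterotyping (PAM on JSD, CH model selection)"]
        lines.append(f"  optimal k        {self.k_optimal}"
                     + ("  [weak structure]" if self.weak_structure else ""))
        for k in sorted(self.ch_by_k):
            mark = " *" if k == self.k_optimal else ""
            lines.append(f"  CH(k={k})        {self.ch_by_k[k]:.2f}{mark}")
        for c, taxa in sorted(self.driver_taxa.items()):
            sizes = int((self.assignment == c).sum())
            lines.append(f"  cluster {c}: n={sizes}, top taxa {', '.join(taxa)}")
        return "\n".join(lines) + "\n"


class EnterotypeModel:
    """Cluster samples into enterotypes from a genus-level abundance profile.

    Parameters
    ----------
    genus_matrix :
        Genus x sample relative abundances.
    k_max :
        Largest cluster number scanned (CH computed for k = 2..k_max).
    weak_structure_threshold :
        When the best CH score falls below this value the result is flagged
        as weak clustering structure (single-component communities).
    """

    def __init__(
        self,
        genus_matrix: RelAbundanceMatrix,
        k_max: int = 10,
        weak_structure_threshold: float = 200.0,
    ) -> None:
        if genus_matrix.n_samples <= k_max:
            raise ValueError(
                f"k_max={k_max} too large for n={genus_matrix.n_samples} samples"
            )
        self.matrix = genus_matrix
        self.k_max = int(k_max)
        self.weak_structure_threshold = float(weak_structure_threshold)

    def fit(self, seed: int | None = None, n_driver_taxa: int = 3) -> EnterotypeResults:
        dist = jsd_matrix(self.matrix)
        ch_by_k: dict[int, float] = {}
        assignments: dict[int, tuple[np.ndarray, list[int]]] = {}
        for k in range(2, self.k_max + 1):
            assign, medoids = pam(dist, k, seed=seed)
            assignments[k] = (assign, medoids)
            ch_by_k[k] = calinski_harabasz(dist, assign)
        # argmax of CH; ties resolved toward the smallest (most parsimonious) k
        k_opt = max(sorted(ch_by_k), key=lambda k: (ch_by_k[k], -k))
        assign, medoids = assignments[k_opt]
        series = pd.Series(assign, index=self.matrix.sample_ids, name="enterotype")
        drivers = {}
        for c in range(k_opt):
            cols = series.index[series == c]
            means = self.matrix.data[cols].mean(axis=1).sort_values(ascending=False)
            drivers[c] = list(means.index[:n_driver_taxa])
        return EnterotypeResults(
            k_optimal=k_opt,
            ch_by_k=ch_by_k,
            assignment=series,
            medoids=[self.matrix.sample_ids[m] for m in medoids],
            driver_taxa=drivers,
            weak_structure=max(ch_by_k.values()) < self.weak_structure_threshold,
            distance=dist,
        )


def enterotype_phenotype_test(
    assignment: pd.Series,
    metadata: CohortMetadata,
    stratum: str | None = None,
    n_perm: int = 100_000,
    seed: int | None = 0,
) -> float:
    """Fisher exact p for association between enterotype and case status.

    Exact for the 2x2 case; an r x c table is handled by Monte-Carlo
    permutation of the sample labels (seeded), comparing the table
    probability under fixed margins.
    """
    samples = [s for s in metadata.samples_in(stratum=stratum) if s in assignment.index]
    if not samples:
        raise ValueError("no samples shared between assignment and metadata")
    groups = metadata.group.loc[samples]
    clusters = assignment.loc[samples]
    table = pd.crosstab(clusters, groups)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate enterotype x phenotype table")
    if table.shape == (2, 2):
        return fisher_exact_2x2(table.to_numpy())
    # Monte-Carlo generalization: permute group labels, compare chi-square stat
    from .stats import chi_square_test

    obs = chi_square_test(table.to_numpy())[0]
    rng = np.random.default_rng(seed)
    labels = groups.to_numpy()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        t = pd.crosstab(clusters, pd.Series(perm, index=clusters.index))
        if chi_square_test(t.to_numpy())[0] >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
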