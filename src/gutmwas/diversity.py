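"""Alpha diversity (richness, Shannon, Chao1, rarefaction) and Jensen-Shannon
beta diversity.

Shannon entropy and the JSD use the natural logarithm by default (so JSD lies
in [0, ln 2]); a ``base`` argument converts where another convention is
wanted.  Chao1 is defined on counts only — relative abundances must first be
turned into counts by seeded multinomial resampling
(:func:`gutmwas.simulate.multinomial_counts`).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, DistanceMatrix, RelAbundanceMatrix

__all__ = [
    "shannon_index",
    "richness",
    "chao1",
    "rarefaction_curve",
    "jsd",
    "jsd_matrix",
    "mean_within_group_jsd",
    "alpha_diversity_table",
]


def _as_composition(p: Sequence[float]) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundances")
    total = p.sum()
    if total <= 0:
        raise ValueError("abundance vector sums to zero")
    return p / total


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def shannon_index(p: Sequence[float], base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i of a renormalized abundance vector."""
    h = _entropy(_as_composition(p))
    return h / np.log(base) if base is not None else h


def richness(p: Sequence[float], detection_threshold: float = 0.0) -> int:
    """Number of features with abundance strictly above the detection threshold."""
    p = np.asarray(p, dtype=float)
    return int((p > detection_threshold).sum())


def chao1(counts: Sequence[int]) -> float:
    """Chao1 richness estimate from integer counts.

    S_obs + F1^2/(2 F2) with singletons F1 and doubletons F2; the
    bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) is used when F2 = 0.
    """
    counts = np.asarray(counts)
    as_float = counts.astype(float)
    if not np.allclose(as_float, np.round(as_float)):
        raise ValueError(
            "chao1 requires integer counts; resample relative abundances with "
            "simulate.multinomial_counts first"
        )
    counts = np.round(as_float).astype(np.int64)
    if (counts < 0).any():
        raise ValueError("negative counts")
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def rarefaction_curve(
    counts: Sequence[int],
    depths: Sequence[int],
    n_repeats: int = 10,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Mean detected-feature count after subsampling without replacement.

    Returns a DataFrame with columns ``depth`` and ``mean_features``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("negative counts")
    total = int(counts.sum())
    depths = [int(d) for d in depths]
    if any(d > total for d in depths):
        raise ValueError(f"depth exceeds total count {total}")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(counts.size), counts)
    rows = []
    for depth in depths:
        if depth == total:
            # exhaustive draw: exactly the observed richness, no resampling noise
            rows.append((depth, float((counts > 0).sum())))
            continue
        detected = [
            np.unique(rng.choice(pool, size=depth, replace=False)).size
            for _ in range(n_repeats)
        ]
        rows.append((depth, float(np.mean(detected))))
    return pd.DataFrame(rows, columns=["depth", "mean_features"])


def jsd(p: Sequence[float], q: Sequence[float], base: float | None = None) -> float:
    """Jensen-Shannon divergence between two abundance profiles.

    JSD(p, q) = H(m) - (H(p) + H(q))/2 with m = (p+q)/2, natural log, so the
    value is bounded by ln 2.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("profiles must have equal length")
    p = _as_composition(p)
    q = _as_composition(q)
    m = (p + q) / 2.0
    val = _entropy(m) - (_entropy(p) + _entropy(q)) / 2.0
    val = float(min(max(val, 0.0), np.log(2)))  # clamp fp noise at the bounds
    return val / np.log(base) if base is not None else val


def jsd_matrix(matrix: RelAbundanceMatrix, sqrt: bool = False) -> DistanceMatrix:
    """All pairwise JSDs between samples (columns) of a profile.

    ``sqrt=True`` returns the square root of the JSD, which is a proper
    metric.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    cols = matrix.values
    sums = cols.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("a sample has zero total abundance")
    comp = cols / sums
    n = comp.shape[1]
    out = np.zeros((n, n))
    # entropy per column once; pairwise mixture entropy in a loop
    ent = np.array([_entropy(comp[:, j]) for j in range(n)])
    for i in range(n):
        for j in range(i + 1, n):
            m = (comp[:, i] + comp[:, j]) / 2.0
            val = _entropy(m) - (ent[i] + ent[j]) / 2.0
            out[i, j] = out[j, i] = min(max(val, 0.0), np.log(2))
    if sqrt:
        out = np.sqrt(out)
    return DistanceMatrix(pd.DataFrame(out, index=matrix.sample_ids,
                                       columns=matrix.sample_ids))


def mean_within_group_jsd(
    dist: DistanceMatrix, groups: Sequence[str] | pd.Series
) -> pd.DataFrame:
    """Per-sample mean JSD to the other samples of its own group.

    A sample with a high mean indicates an atypical community within its
    group; group-level comparison of these values measures between-sample
    variability (beta diversity).  Returns a DataFrame with columns
    ``group`` and ``mean_within_group_jsd`` indexed by sample id.
    """
    if isinstance(groups, pd.Series):
        groups = groups.loc[dist.sample_ids]
        labels = groups.to_numpy()
    else:
        labels = np.asarray(groups)
    if labels.size != dist.n_samples:
        raise ValueError("one group label per sample required")
    values = dist.values
    rows = []
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        sub = values[np.ix_(idx, idx)]
        means = (sub.sum(axis=1)) / (idx.size - 1)
        for pos, m in zip(idx, means):
            rows.append((dist.sample_ids[pos], g, float(m)))
    out = pd.DataFrame(rows, columns=["sample_id", "group", "mean_within_group_jsd"])
    return out.set_index("sample_id").loc[dist.sample_ids]


def alpha_diversity_table(
    matrix: RelAbundanceMatrix,
    counts: CountMatrix | None = None,
    detection_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-sample richness and Shannon index, plus Chao1 when counts are given."""
    rows = {}
    for sid in matrix.sample_ids:
        col = matrix.data[sid].to_numpy()
        rows[sid] = {
            "richness": richness(col, detection_threshold),
            "shannon": shannon_index(col) if col.sum() > 0 else 0.0,
        }
    if counts is not None:
        for sid in counts.sample_ids:
            if sid in rows:
                rows[sid]["chao1"] = chao1(counts.data[sid].to_numpy())
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
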