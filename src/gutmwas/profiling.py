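"""Gene-level profiles -> taxon / KO / virulence-factor / PHI feature profiles.

A feature's relative abundance is the sum of the relative abundances of the
genes annotated to it; genes lacking annotation are excluded from the sum
(their dropped mass is logged per sample for auditability, never silently
re-assigned).  Virulence-factor and pathogen-host-interaction annotations come
from blast tabular hits filtered to identity > 40% and bit score > 60 (strict
inequalities), keeping each query's single highest-scoring surviving hit.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import AlignmentHit, FeatureMap, RelAbundanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "aggregate_abundance",
    "best_hit_filter",
    "profile_functional_features",
    "DEFAULT_MIN_IDENTITY",
    "DEFAULT_MIN_BITS",
]

DEFAULT_MIN_IDENTITY = 40.0
DEFAULT_MIN_BITS = 60.0


def aggregate_abundance(
    gene_matrix: RelAbundanceMatrix, fmap: FeatureMap
) -> RelAbundanceMatrix:
    """Sum gene abundances over their annotated parent features.

    Parents are emitted in lexicographic order.  The per-sample fraction of
    abundance lost to unannotated genes is logged.
    """
    df = gene_matrix.data
    annotated = [g for g in df.index if g in fmap]
    if not annotated:
        raise ValueError("no gene in the matrix carries an annotation in the map")
    parents = pd.Series({g: fmap[g] for g in annotated})
    agg = df.loc[annotated].groupby(parents).sum()
    agg = agg.sort_index()
    in_sums = df.sum(axis=0)
    out_sums = agg.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dropped = 1.0 - np.where(in_sums > 0, out_sums / in_sums, 1.0)
    logger.info(
        "aggregation dropped unannotated mass: mean %.3g, max %.3g over %d samples",
        float(np.mean(dropped)), float(np.max(dropped)), len(in_sums),
    )
    return RelAbundanceMatrix(agg)


def best_hit_filter(
    hits: Sequence[AlignmentHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_bits: float = DEFAULT_MIN_BITS,
) -> FeatureMap:
    """Map each query to the subject of its best surviving hit.

    Hits must exceed both thresholds strictly (identity > ``min_identity``
    and bit score > ``min_bits``).  Among survivors the highest bit score
    wins; ties break by higher identity, then lexicographically smaller
    subject id.  Queries with no surviving hit are absent from the map.
    """
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        if not (hit.percent_identity > min_identity and hit.bit_score > min_bits):
            continue
        cur = best.get(hit.query_id)
        if cur is None or _better_hit(hit, cur):
            best[hit.query_id] = hit
    return FeatureMap({q: h.subject_id for q, h in best.items()})


def _better_hit(a: AlignmentHit, b: AlignmentHit) -> bool:
    """True if *a* beats *b*: higher bits, then higher identity, then smaller subject id."""
    if a.bit_score != b.bit_score:
        return a.bit_score > b.bit_score
    if a.percent_identity != b.percent_identity:
        return a.percent_identity > b.percent_identity
    return a.subject_id < b.subject_id


def profile_functional_features(
    gene_matrix: RelAbundanceMatrix,
    hit_map: FeatureMap,
    subject_to_feature: FeatureMap | None = None,
) -> RelAbundanceMatrix:
    """Quantify functional features (VF/PHI) from a best-hit gene map.

    ``hit_map`` maps genes to database subjects (from
    :func:`best_hit_filter`); an optional ``subject_to_feature`` map rolls
    subjects up to named features before summation.
    """
    if subject_to_feature is not None:
        composed = {}
        for gene, subject in hit_map.items():
            feat = subject_to_feature.get(subject)
            if feat is not None:
                composed[gene] = feat
        hit_map = FeatureMap(composed)
    return aggregate_abundance(gene_matrix, hit_map)
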