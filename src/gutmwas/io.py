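"""Readers and writers for the TSV tables the pipeline consumes and emits.

Everything is plain UTF-8 TSV (gzip-transparent via pandas); abundance tables
are features-in-rows by default with an orientation flag for samples-in-rows
supplements.  IO is lossless: no renormalization, no filtering.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .containers import (
    BLAST_M8_FIELDS,
    AlignmentHit,
    CohortMetadata,
    CountMatrix,
    DistanceMatrix,
    FeatureMap,
    RelAbundanceMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

Orientation = Literal["features_in_rows", "samples_in_rows"]

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_count_table",
    "read_feature_map",
    "write_feature_map",
    "read_alignment_hits",
    "read_metadata",
    "write_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
]


def _read_matrix(path, orientation: Orientation) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if orientation == "samples_in_rows":
        df = df.T
    non_numeric = df.columns[df.dtypes == object]
    for col in non_numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"malformed numeric cell in {path} at row {bad[0]!r}, column {col!r}"
            )
        df[col] = coerced
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_abundance_table(
    path, orientation: Orientation = "features_in_rows"
) -> RelAbundanceMatrix:
    """Read a relative-abundance TSV (header = sample ids, first column = feature ids)."""
    return RelAbundanceMatrix(_read_matrix(path, orientation))


def read_count_table(
    path, orientation: Orientation = "features_in_rows"
) -> CountMatrix:
    """Read an integer count TSV in the same layout as abundance tables."""
    return CountMatrix(_read_matrix(path, orientation))


def write_abundance_table(matrix: RelAbundanceMatrix | CountMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id")


def read_feature_map(path) -> FeatureMap:
    """Read a two-column child<TAB>parent TSV (no header) into a FeatureMap."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            pairs.append((parts[0], parts[1]))
    if not pairs:
        logger.warning("feature map %s is empty", path)
    return FeatureMap.from_pairs(pairs)


def write_feature_map(fmap: FeatureMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for child, parent in sorted(fmap.items()):
            fh.write(f"{child}\t{parent}\n")


def read_alignment_hits(path) -> list[AlignmentHit]:
    """Parse a legacy 12-column blast tabular (-m 8) hit file, preserving order."""
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(BLAST_M8_FIELDS):
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(BLAST_M8_FIELDS)} columns, "
                    f"got {len(parts)}"
                )
            try:
                hits.append(
                    AlignmentHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        percent_identity=float(parts[2]),
                        alignment_length=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        q_start=int(parts[6]),
                        q_end=int(parts[7]),
                        s_start=int(parts[8]),
                        s_end=int(parts[9]),
                        e_value=float(parts[10]),
                        bit_score=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return hits


def read_metadata(path) -> CohortMetadata:
    """Read a sample metadata TSV (sample_id, group, stratum, clinical indices).

    Empty cells and "NA" both denote missing clinical values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    return CohortMetadata(df)


def write_metadata(metadata: CohortMetadata, path) -> None:
    metadata.table.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DistanceMatrix(df)


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    dist.data.to_csv(path, sep="\t", index_label="sample_id")
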