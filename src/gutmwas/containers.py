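"""Core data containers for metagenomic profile analysis.

All abundance-style tables are features-in-rows pandas DataFrames wrapped in
thin validating containers.  Relative abundances are treated as unnormalized
non-negative weights whose per-sample sums may not exceed 1; IO and
construction never renormalize (downstream stages renormalize explicitly
where a method requires a composition).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RelAbundanceMatrix",
    "CountMatrix",
    "FeatureMap",
    "CohortMetadata",
    "DistanceMatrix",
    "AlignmentHit",
    "ValidationError",
]

#: absolute slack on the "column sums <= 1" invariant
SUM_TOL = 1e-9


class ValidationError(ValueError):
    """An input table violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass(frozen=True)
class RelAbundanceMatrix:
    """A features x samples matrix of non-negative relative abundances.

    Per-sample column sums must not exceed 1 (up to ``SUM_TOL``); they may be
    below 1, e.g. after unannotated gene mass has been dropped during
    aggregation.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        _check_unique(list(df.index), "feature ids")
        _check_unique(list(df.columns), "sample ids")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("non-finite abundance values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at feature {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        sums = values.sum(axis=0)
        if (sums > 1 + SUM_TOL).any():
            j = int(np.argmax(sums))
            raise ValidationError(
                f"column sum {sums[j]:.6g} > 1 for sample {df.columns[j]!r}"
            )
        object.__setattr__(self, "data", df.astype(float))

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def normalized(self) -> "RelAbundanceMatrix":
        """Return a copy with every column rescaled to sum to 1.

        Columns summing to zero are left at zero.
        """
        sums = self.data.sum(axis=0)
        safe = sums.replace(0.0, 1.0)
        return RelAbundanceMatrix(self.data.div(safe, axis=1))

    def select_samples(self, sample_ids: Iterable[str]) -> "RelAbundanceMatrix":
        return RelAbundanceMatrix(self.data.loc[:, list(sample_ids)])

    def select_features(self, feature_ids: Iterable[str]) -> "RelAbundanceMatrix":
        return RelAbundanceMatrix(self.data.loc[list(feature_ids), :])

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        feature_ids: Sequence[str],
        sample_ids: Sequence[str],
    ) -> "RelAbundanceMatrix":
        return cls(pd.DataFrame(np.asarray(values, dtype=float),
                                index=list(feature_ids), columns=list(sample_ids)))


@dataclass(frozen=True)
class CountMatrix:
    """A features x samples matrix of non-negative integer counts."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(list(df.index), "feature ids")
        _check_unique(list(df.columns), "sample ids")
        values = df.to_numpy()
        if not np.all(np.isfinite(values.astype(float))):
            raise ValidationError("non-finite counts")
        as_float = values.astype(float)
        if (as_float < 0).any():
            raise ValidationError("negative counts")
        if not np.allclose(as_float, np.round(as_float)):
            raise ValidationError(
                "counts must be integers; for relative abundances use "
                "multinomial resampling (simulate.multinomial_counts)"
            )
        object.__setattr__(self, "data", df.astype(np.int64))

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass(frozen=True)
class FeatureMap:
    """Many-to-one child -> parent feature mapping (gene->taxon, gene->KO, KO->module).

    Children lacking annotation are simply absent from the map.  A child may
    appear on several rows only if every row names the same parent.
    """

    mapping: dict[str, str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "FeatureMap":
        mapping: dict[str, str] = {}
        conflicts = []
        for child, parent in pairs:
            prev = mapping.get(child)
            if prev is not None and prev != parent:
                conflicts.append(child)
            mapping[child] = parent
        if conflicts:
            raise ValidationError(
                f"children mapped to conflicting parents: {sorted(set(conflicts))[:10]}"
            )
        return cls(mapping)

    @property
    def children(self) -> list[str]:
        return list(self.mapping)

    @property
    def parents(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def __len__(self) -> int:
        return len(self.mapping)

    def __getitem__(self, child: str) -> str:
        return self.mapping[child]

    def __contains__(self, child: str) -> bool:
        return child in self.mapping

    def get(self, child: str, default=None):
        return self.mapping.get(child, default)

    def items(self):
        return self.mapping.items()


@dataclass(frozen=True)
class CohortMetadata:
    """Per-sample group labels, menopause stratum and clinical indices.

    ``table`` is indexed by sample id with mandatory columns ``group``
    (``case``/``control``) and ``stratum`` (``premenopausal``/
    ``postmenopausal``); any further numeric columns are clinical indices
    (missing values allowed, encoded as NaN).
    """

    table: pd.DataFrame

    GROUPS = ("case", "control")
    STRATA = ("premenopausal", "postmenopausal")

    def __post_init__(self) -> None:
        df = self.table
        _check_unique(list(df.index), "sample ids")
        for col in ("group", "stratum"):
            if col not in df.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
            if df[col].isna().any():
                raise ValidationError(f"metadata column {col!r} has missing values")
        bad = set(df["group"]) - set(self.GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        bad = set(df["stratum"]) - set(self.STRATA)
        if bad:
            raise ValidationError(f"unknown stratum labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def group(self) -> pd.Series:
        return self.table["group"]

    @property
    def stratum(self) -> pd.Series:
        return self.table["stratum"]

    @property
    def clinical_indices(self) -> pd.DataFrame:
        cols = [c for c in self.table.columns if c not in ("group", "stratum")]
        return self.table[cols]

    def subset(self, sample_ids: Iterable[str]) -> "CohortMetadata":
        return CohortMetadata(self.table.loc[list(sample_ids)])

    def samples_in(self, *, group: str | None = None, stratum: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if group is not None:
            mask &= self.table["group"] == group
        if stratum is not None:
            mask &= self.table["stratum"] == stratum
        return list(self.table.index[mask])


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric, zero-diagonal pairwise sample dissimilarities."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if list(df.index) != list(df.columns):
            raise ValidationError("distance matrix index and columns must match")
        _check_unique(list(df.index), "sample ids")
        values = df.to_numpy(dtype=float)
        if (values < -SUM_TOL).any():
            raise ValidationError("negative distances")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-10):
            raise ValidationError("distance matrix diagonal not zero")
        object.__setattr__(self, "data", df.astype(float))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def subset(self, sample_ids: Iterable[str]) -> "DistanceMatrix":
        ids = list(sample_ids)
        return DistanceMatrix(self.data.loc[ids, ids])


#: field order of the legacy 12-column blast tabular (-m 8) layout
BLAST_M8_FIELDS = (
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "e_value", "bit_score",
)


@dataclass(frozen=True)
class AlignmentHit:
    """One row of 12-column blast tabular output."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )
        if self.bit_score < 0:
            raise ValidationError(f"negative bit score {self.bit_score}")

    def as_tuple(self) -> tuple:
        return dataclasses.astuple(self)
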