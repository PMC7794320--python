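"""Shared data containers for the mycobiome analysis pipeline.

The central object is :class:`FeatureTable`, a sample-by-feature matrix
carrying a ``units`` tag so that downstream transforms can refuse inputs on
the wrong scale (e.g. a logit transform applied to raw counts).  Tables also
carry a ``provenance`` tuple recording the processing steps applied so far,
which the pipeline writes into its run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised units for a feature table.
VALID_UNITS = frozenset(
    {"counts", "relative", "logit", "log10", "hellinger", "intensity", "per_week"}
)

_ROW_TOL = 1e-9


class FeatureTableError(ValueError):
    """Raised when a feature table violates its unit invariants."""


@dataclass(frozen=True)
class FeatureTable:
    """A sample-by-feature abundance matrix with a units tag.

    Parameters
    ----------
    data:
        DataFrame with sample IDs as the index and feature IDs as columns.
        No missing values are allowed.
    units:
        One of ``counts``, ``relative``, ``logit``, ``log10``, ``hellinger``,
        ``intensity`` or ``per_week``.
    provenance:
        Ordered tuple of processing-step descriptions already applied.

    Notes
    -----
    ``counts`` tables must hold non-negative integers.  ``relative`` tables
    must have row sums in ``(0, 1]``: a freshly normalised table sums to one
    per sample, while a table from which features were removed after
    normalisation (the pipeline does not renormalise after filtering, so the
    retained values keep their original meaning) sums to less than one.
    ``hellinger`` rows have unit Euclidean norm at construction.
    """

    data: pd.DataFrame
    units: str
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.units not in VALID_UNITS:
            raise FeatureTableError(
                f"unknown units {self.units!r}; expected one of {sorted(VALID_UNITS)}"
            )
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise FeatureTableError("data must be a pandas DataFrame")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate sample IDs: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate feature IDs: {dupes}")
        values = df.to_numpy()
        if values.size and not np.isfinite(values.astype(float)).all():
            raise FeatureTableError("table contains missing or non-finite entries")
        if self.units == "counts":
            v = values.astype(float)
            if v.size and ((v < 0).any() or not np.allclose(v, np.round(v))):
                raise FeatureTableError("counts must be non-negative integers")
        elif self.units == "relative":
            sums = values.astype(float).sum(axis=1)
            if values.size and ((sums <= 0).any() or (sums > 1 + _ROW_TOL).any()):
                bad = df.index[(sums <= 0) | (sums > 1 + _ROW_TOL)].tolist()
                raise FeatureTableError(
                    f"relative-abundance rows must sum to (0, 1]; offending samples: {bad}"
                )
        elif self.units == "hellinger":
            norms = np.sqrt((values.astype(float) ** 2).sum(axis=1))
            if values.size and not np.allclose(norms, 1.0, atol=1e-6):
                raise FeatureTableError("hellinger rows must have unit Euclidean norm")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def derive(
        self, data: pd.DataFrame, units: str | None = None, step: str | None = None
    ) -> "FeatureTable":
        """Return a new table inheriting provenance, with ``step`` appended."""
        prov = self.provenance + ((step,) if step else ())
        return FeatureTable(data=data, units=units or self.units, provenance=prov)

    def subset_samples(self, sample_ids: list[str]) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return self.derive(self.data.loc[sample_ids], step=f"subset_samples(n={len(sample_ids)})")


@dataclass(frozen=True)
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix.

    ``coordinates`` holds one column per retained (positive-eigenvalue) axis,
    scaled by the square root of the eigenvalue.  ``eigenvalues`` keeps the
    full spectrum, including any negative values arising from non-Euclidean
    dissimilarities such as Bray-Curtis; ``proportion_explained`` is computed
    over the positive part of the spectrum only.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


@dataclass(frozen=True)
class PermanovaResult:
    """Pseudo-F and permutation p-value from a PERMANOVA test."""

    statistic: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        lo = 1.0 / (self.n_permutations + 1)
        if not (lo - 1e-12 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"permutation p-value {self.p_value} outside [{lo}, 1]")


@dataclass(frozen=True)
class GroupTestResult:
    """Result of a nonparametric group-difference test."""

    statistic: float
    p_value: float
    test: str  # "wilcoxon-rank-sum" or "kruskal-wallis"
    group_sizes: dict[str, int] = field(default_factory=dict)
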