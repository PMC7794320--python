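"""Co-inertia analysis and the RV coefficient for paired omic tables.

Co-inertia analysis measures the concordance of two data tables observed on
the same samples.  Each table is wrapped as a duality-diagram *triplet*
(data matrix, uniform row weights, unit column weights) after column
centering; the analysis is then the singular value decomposition of the
weighted cross-covariance ``X^T D Y`` (D = diag of row weights).  Squared
singular values are the co-inertia eigenvalues, their sum is the total
co-inertia, and the paired row scores along axis k co-vary with weight
``sqrt(eigenvalue_k)``.

The global strength of association is the RV coefficient::

    RV = tr(X^T D Y  Y^T D X) / sqrt( tr((X^T D X)^2) * tr((Y^T D Y)^2) )

which lies in [0, 1] and is invariant to rotation and positive scaling of
either table.  Significance is assessed by Monte-Carlo permutation of the
rows of one table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureTable


@dataclass(frozen=True)
class Triplet:
    """A centred (optionally standardised) table with uniform row weights."""

    data: pd.DataFrame  # samples x features, already centred
    row_weights: np.ndarray  # sums to 1
    column_means: np.ndarray
    column_scales: np.ndarray  # ones when scale=False

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass(frozen=True)
class CoinertiaResult:
    """Decomposition of the cross-covariance between two paired tables."""

    eigenvalues: np.ndarray
    x_loadings: pd.DataFrame
    y_loadings: pd.DataFrame
    x_scores: pd.DataFrame
    y_scores: pd.DataFrame
    total_coinertia: float
    rv: float
    p_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class PermutationTestResult:
    """Monte-Carlo permutation test of the RV coefficient."""

    observed_rv: float
    p_value: float
    n_permutations: int
    seed: int


def build_triplet(table: FeatureTable, center: bool = True, scale: bool = False) -> Triplet:
    """Wrap a processed table as a PCA-style triplet with uniform row weights."""
    n = table.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    x = table.values
    weights = np.full(n, 1.0 / n)
    means = weights @ x if center else np.zeros(x.shape[1])
    centred = x - means
    if scale:
        var = weights @ centred**2
        zero = np.asarray(table.data.columns)[var <= 0].tolist()
        if zero:
            raise ValueError(f"zero-variance columns cannot be scaled: {zero}")
        scales = np.sqrt(var)
    else:
        scales = np.ones(x.shape[1])
    data = pd.DataFrame(
        centred / scales, index=table.data.index, columns=table.data.columns
    )
    return Triplet(data=data, row_weights=weights, column_means=np.asarray(means),
                   column_scales=scales)


def _check_paired(x: Triplet, y: Triplet) -> None:
    if x.sample_ids != y.sample_ids:
        only_x = sorted(set(x.sample_ids) - set(y.sample_ids))
        only_y = sorted(set(y.sample_ids) - set(x.sample_ids))
        raise ValueError(
            "triplets are not paired on identical samples in identical order; "
            f"only in x: {only_x[:5]}, only in y: {only_y[:5]}"
        )


def _cross(x: Triplet, y: Triplet) -> np.ndarray:
    return x.values.T @ (x.row_weights[:, None] * y.values)


def coinertia(x: Triplet, y: Triplet, n_axes: int | None = None) -> CoinertiaResult:
    """Co-inertia decomposition of two paired triplets.

    Returns eigenvalues (squared singular values of ``X^T D Y``), column
    loadings for both tables, paired row scores (projections of each table
    onto its loadings), total co-inertia and the RV coefficient.  Axis signs
    are canonicalised (largest-magnitude x-loading positive per axis).
    """
    _check_paired(x, y)
    cross = _cross(x, y)  # p x q
    u, s, vt = np.linalg.svd(cross, full_matrices=False)
    eigenvalues = s**2
    k = len(s) if n_axes is None else min(n_axes, len(s))
    u, s, v = u[:, :k], s[:k], vt[:k].T
    for a in range(k):  # canonical sign per axis
        if u[np.argmax(np.abs(u[:, a])), a] < 0:
            u[:, a] = -u[:, a]
            v[:, a] = -v[:, a]
    axes = [f"CoI{a + 1}" for a in range(k)]
    return CoinertiaResult(
        eigenvalues=eigenvalues,
        x_loadings=pd.DataFrame(u, index=x.data.columns, columns=axes),
        y_loadings=pd.DataFrame(v, index=y.data.columns, columns=axes),
        x_scores=pd.DataFrame(x.values @ u, index=x.data.index, columns=axes),
        y_scores=pd.DataFrame(y.values @ v, index=y.data.index, columns=axes),
        total_coinertia=float(eigenvalues.sum()),
        rv=rv_coefficient(x, y),
    )


def rv_coefficient(x: Triplet, y: Triplet) -> float:
    """Matrix correlation RV between two paired, centred triplets."""
    _check_paired(x, y)
    sxy = _cross(x, y)
    sxx = _cross(x, x)
    syy = _cross(y, y)
    denom2 = np.sum(sxx * sxx) * np.sum(syy * syy)
    if denom2 <= 0:
        raise ValueError("RV is undefined for an all-zero centred table")
    return float(np.sum(sxy * sxy) / np.sqrt(denom2))


def coinertia_permutation_test(
    x: Triplet, y: Triplet, n_permutations: int = 999, seed: int = 0
) -> PermutationTestResult:
    """Monte-Carlo significance of the RV coefficient.

    Rows of ``x`` are permuted each round (equivalent to permuting ``y``
    under uniform row weights); p = (1 + #{RV_perm >= RV_obs}) /
    (1 + n_permutations).
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    _check_paired(x, y)
    xv = x.values
    yv = y.values
    w = x.row_weights[:, None]
    sxx = xv.T @ (w * xv)
    syy = yv.T @ (w * yv)
    denom = np.sqrt(np.sum(sxx * sxx) * np.sum(syy * syy))
    if denom <= 0:
        raise ValueError("RV is undefined for an all-zero centred table")

    def rv_of(xm: np.ndarray) -> float:
        sxy = xm.T @ (w * yv)
        return float(np.sum(sxy * sxy) / denom)

    observed = rv_of(xv)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if rv_of(xv[rng.permutation(len(xv))]) >= observed - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermutationTestResult(
        observed_rv=observed, p_value=p, n_permutations=n_permutations, seed=seed
    )
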