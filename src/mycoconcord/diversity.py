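"""Alpha/beta diversity, principal coordinates, PERMANOVA and group tests.

Beta diversity uses Bray-Curtis dissimilarity.  PCoA is the classical
Gower-centred eigendecomposition; because Bray-Curtis is non-Euclidean, the
spectrum may contain negative eigenvalues, which are kept in the eigenvalue
list but excluded from the proportion-explained denominator, and coordinates
are reported for positive-eigenvalue axes only.  PERMANOVA follows the
standard distance-based pseudo-F with label permutations driven by an
explicit seed, so p-values are exactly reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .containers import (
    FeatureTable,
    GroupTestResult,
    OrdinationResult,
    PermanovaResult,
)


def richness(table: FeatureTable) -> pd.Series:
    """Number of features with non-zero abundance per sample."""
    return (table.data > 0).sum(axis=1).rename("richness")


def shannon(table: FeatureTable) -> pd.Series:
    """Shannon diversity index H = -sum p_i ln p_i (natural log) per sample."""
    if table.units not in {"counts", "relative"}:
        raise ValueError(f"shannon expects counts or relative abundances, got {table.units!r}")
    x = table.values
    sums = x.sum(axis=1)
    if (sums <= 0).any():
        bad = np.asarray(table.data.index)[sums <= 0].tolist()
        raise ValueError(f"samples with zero total abundance: {bad}")
    p = x / sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-terms.sum(axis=1), index=table.data.index, name="shannon")


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d(a,b) = sum|a-b| / sum(a+b)."""
    x = table.values
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    zero_rows = np.asarray(table.data.index)[x.sum(axis=1) == 0].tolist()
    if len(zero_rows) >= 2:
        raise ValueError(
            f"Bray-Curtis is undefined between all-zero samples: {zero_rows}"
        )
    condensed = pdist(x, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Principal-coordinate analysis of a distance matrix.

    Eigendecomposition of the Gower-centred matrix ``-1/2 J D^2 J``;
    coordinates are eigenvectors scaled by sqrt(eigenvalue), reported for
    positive-eigenvalue axes.  Axis signs are canonicalised so the
    largest-magnitude coordinate on each axis is positive, making results
    run-to-run stable.
    """
    d2 = np.asarray(dist.data, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    pos = eigvals > max(eigvals.max(), 0) * 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    # Canonical sign: largest-|coordinate| entry positive on each axis.
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    positive_sum = eigvals[pos].sum()
    prop = eigvals[pos] / positive_sum if positive_sum > 0 else eigvals[pos]
    coordinates = pd.DataFrame(
        coords,
        index=pd.Index(dist.ids, name="sample_id"),
        columns=[f"PCo{k + 1}" for k in range(coords.shape[1])],
    )
    return OrdinationResult(
        coordinates=coordinates, eigenvalues=eigvals, proportion_explained=prop
    )


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """PERMANOVA pseudo-F from a squared-distance matrix and group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        mask = (codes == g).astype(float)
        ss_within += (mask @ d2 @ mask) / (2 * mask.sum())
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    dist: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA (Adonis-style) on a distance matrix.

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations).
    """
    labels = np.asarray(list(labels))
    if len(labels) != dist.shape[0]:
        raise ValueError("labels length must match the distance matrix")
    groups, codes = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = groups[sizes < 2].tolist()
        raise ValueError(f"each group needs at least 2 samples; too small: {small}")
    d2 = np.asarray(dist.data, dtype=float) ** 2
    observed = _pseudo_f(d2, codes, len(groups))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if _pseudo_f(d2, rng.permutation(codes), len(groups)) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        statistic=float(observed), p_value=p, n_permutations=n_permutations, seed=seed
    )


def axis_feature_correlation(
    table: FeatureTable,
    ordination: OrdinationResult,
    axis_index: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of each feature against one PCoA axis.

    ``axis_index`` is zero-based (1 selects the secondary axis, the one that
    separates cases from controls in the motivating analysis).  P-values are
    Benjamini-Hochberg adjusted across features; constant features have an
    undefined rho and are excluded from the adjustment family.

    Returns a DataFrame with columns ``rho``, ``p``, ``p_adj``,
    ``significant``, indexed by feature ID.
    """
    if not 0 <= axis_index < ordination.coordinates.shape[1]:
        raise IndexError(f"axis_index {axis_index} out of range")
    scores = ordination.coordinates.iloc[:, axis_index]
    data = table.data.loc[scores.index]
    rows = []
    for fid in data.columns:
        col = data[fid].to_numpy()
        if np.all(col == col[0]):
            rows.append((fid, np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(col, scores.to_numpy())
        rows.append((fid, rho, p))
    out = pd.DataFrame(rows, columns=["feature_id", "rho", "p"]).set_index("feature_id")
    out["p_adj"] = np.nan
    testable = out["p"].notna()
    if testable.any():
        out.loc[testable, "p_adj"] = multipletests(
            out.loc[testable, "p"], method="fdr_bh"
        )[1]
    out["significant"] = out["p_adj"] < alpha
    return out


def group_tests(values, labels) -> GroupTestResult:
    """Nonparametric location test across groups.

    Two groups: two-sided Wilcoxon rank-sum (Mann-Whitney U; exact p when
    sample sizes are small and there are no ties).  Three or more groups:
    Kruskal-Wallis H.
    """
    values = np.asarray(list(values), dtype=float)
    labels = np.asarray(list(labels))
    if len(values) != len(labels):
        raise ValueError("values and labels must have equal length")
    groups, codes = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("group_tests needs at least 2 groups")
    samples = [values[codes == g] for g in range(len(groups))]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must contain at least one sample")
    sizes = {str(g): int(len(s)) for g, s in zip(groups, samples)}
    if len(groups) == 2:
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return GroupTestResult(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            test="wilcoxon-rank-sum",
            group_sizes=sizes,
        )
    res = stats.kruskal(*samples)
    return GroupTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test="kruskal-wallis",
        group_sizes=sizes,
    )
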