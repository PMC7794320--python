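"""Permutation-null significance for cross-validated linear-SVM biomarkers.

The procedure asks whether a microbial community carries predictive signal
for a binary phenotype, and which features drive it, without assuming any
parametric model of the data:

1. Run stratified tenfold cross-validation of a class-weighted linear SVM
   for many iterations (default 100), each iteration with a fresh fold split.
   Per iteration, record the mean held-out AUC across folds and the mean of
   the fold-level coefficient vectors.
2. Repeat with class labels shuffled anew each iteration.  The shuffled runs
   give an empirical null distribution both for the AUC and, per feature,
   for the SVM coefficient.
3. For each feature, a single-sample z-test compares the mean true-label
   coefficient against the shuffled-coefficient null; p-values are
   Benjamini-Hochberg adjusted across features.

Coefficient signs follow the SVM decision function: positive coefficients
push towards the positive class (by convention the control group), so
negative coefficients mark case-associated features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable, GroupTestResult

_MAX_FOLD_REDRAWS = 100


@dataclass(frozen=True)
class CVConfig:
    """Configuration of the repeated cross-validation experiment."""

    n_folds: int = 10
    n_iterations: int = 100
    class_weighting: bool = True
    shuffle_labels: bool = False
    C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass(frozen=True)
class MLExperimentResult:
    """Per-iteration AUC / sensitivity / specificity and coefficient vectors."""

    auc: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    coefficients: np.ndarray  # (n_iterations, n_features)
    feature_ids: tuple[str, ...]
    positive_label: str
    config: CVConfig

    def __post_init__(self) -> None:
        if self.coefficients.shape != (len(self.auc), len(self.feature_ids)):
            raise ValueError("coefficient matrix shape mismatch")
        if ((self.auc < 0) | (self.auc > 1)).any():
            raise ValueError("AUC values must lie in [0, 1]")


def run_repeated_cv(
    table: FeatureTable, labels, config: CVConfig, positive_label: str | None = None
) -> MLExperimentResult:
    """Repeated stratified k-fold CV of a class-weighted linear SVM.

    Parameters
    ----------
    table:
        Logit-transformed abundance table (samples x features).
    labels:
        Binary class label per sample, aligned with the table rows.
    config:
        Folds, iterations, weighting, label shuffling and seed.
    positive_label:
        Class treated as positive by the decision function (default: the
        lexicographically larger label, matching scikit-learn).  Sensitivity
        is the recall of the *other* (case) class, specificity the recall of
        the positive class.

    Notes
    -----
    Each iteration draws a fresh stratified fold split (re-drawn if a test
    fold ends up single-class); with ``shuffle_labels`` the labels are
    permuted once per iteration before splitting.  The iteration AUC is the
    mean of fold-level held-out AUCs and the iteration coefficient vector is
    the mean of the fold-level SVM coefficient vectors.  All randomness
    derives from ``config.seed``.
    """
    y_raw = np.asarray(list(labels))
    if len(y_raw) != table.shape[0]:
        raise ValueError("labels must align with table samples")
    classes = np.unique(y_raw)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    if positive_label is None:
        positive_label = str(classes[-1])
    elif positive_label not in classes:
        raise ValueError(f"positive_label {positive_label!r} not among classes {classes}")
    if table.shape[0] < 2 * config.n_folds:
        raise ValueError("need at least 2 * n_folds samples")

    X = table.values
    y = (y_raw == positive_label).astype(int)  # 1 = positive (control) class
    rng = np.random.default_rng(config.seed)
    n_iter = config.n_iterations
    aucs = np.empty(n_iter)
    sens = np.empty(n_iter)
    spec = np.empty(n_iter)
    coefs = np.empty((n_iter, table.shape[1]))

    for it in range(n_iter):
        y_it = rng.permutation(y) if config.shuffle_labels else y
        splits = _stratified_splits(y_it, config.n_folds, rng)
        fold_aucs = []
        fold_coefs = []
        pred = np.empty_like(y_it)
        for train_idx, test_idx in splits:
            # Features are standardised within the training fold (the common
            # default of linear-SVM front-ends), so the margin is not
            # dominated by high-variance rare features.
            clf = make_pipeline(
                StandardScaler(),
                SVC(
                    kernel="linear",
                    C=config.C,
                    class_weight="balanced" if config.class_weighting else None,
                ),
            )
            clf.fit(X[train_idx], y_it[train_idx])
            scores = clf.decision_function(X[test_idx])
            fold_aucs.append(roc_auc_score(y_it[test_idx], scores))
            fold_coefs.append(np.ravel(clf[-1].coef_))
            pred[test_idx] = (scores > 0).astype(int)
        aucs[it] = np.mean(fold_aucs)
        coefs[it] = np.mean(fold_coefs, axis=0)
        case = y_it == 0
        sens[it] = (pred[case] == 0).mean()
        spec[it] = (pred[~case] == 1).mean()

    return MLExperimentResult(
        auc=aucs,
        sensitivity=sens,
        specificity=spec,
        coefficients=coefs,
        feature_ids=tuple(table.feature_ids),
        positive_label=positive_label,
        config=config,
    )


def _stratified_splits(y: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Stratified fold split; re-drawn until every test fold holds both classes."""
    for _ in range(_MAX_FOLD_REDRAWS):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        splits = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[test])) == 2 for _, test in splits):
            return splits
    raise ValueError(
        f"could not draw a stratified {n_folds}-fold split with both classes per fold"
    )


def coefficient_significance(
    true_result: MLExperimentResult,
    null_result: MLExperimentResult,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Single-sample z-test of true coefficients against the shuffled null.

    Per feature, ``z = (mean true coefficient - mean null coefficient) /
    SD(null coefficients)`` with a two-sided normal p-value, BH-adjusted
    across features.  Features whose null SD is zero have an undefined z and
    are excluded from the adjustment family (``z`` reported as NaN).

    Returns a DataFrame indexed by feature ID with columns ``true_mean``,
    ``null_mean``, ``null_sd``, ``z``, ``p``, ``p_adj``, ``direction``
    (``case-associated`` / ``control-associated``) and ``significant``.
    """
    if true_result.feature_ids != null_result.feature_ids:
        raise ValueError("true and null results must share the same feature set")
    if not null_result.config.shuffle_labels:
        raise ValueError("null_result must come from a shuffled-label run")
    true_mean = true_result.coefficients.mean(axis=0)
    null_mean = null_result.coefficients.mean(axis=0)
    null_sd = null_result.coefficients.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0, (true_mean - null_mean) / null_sd, np.nan)
    p = 2 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "true_mean": true_mean,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "p": p,
        },
        index=pd.Index(true_result.feature_ids, name="feature_id"),
    )
    out["p_adj"] = np.nan
    testable = np.isfinite(z)
    if testable.any():
        out.loc[testable, "p_adj"] = multipletests(out.loc[testable, "p"], method="fdr_bh")[1]
    out["direction"] = np.where(
        true_mean >= 0, "control-associated", "case-associated"
    )
    out["significant"] = out["p_adj"] < alpha
    return out


def compare_auc_distributions(
    true_result: MLExperimentResult, null_result: MLExperimentResult
) -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum test between true and shuffled AUC samples."""
    if len(true_result.auc) < 2 or len(null_result.auc) < 2:
        raise ValueError("need at least 2 iterations in each result")
    res = stats.mannwhitneyu(
        true_result.auc, null_result.auc, alternative="two-sided"
    )
    return GroupTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test="wilcoxon-rank-sum",
        group_sizes={"true": len(true_result.auc), "null": len(null_result.auc)},
    )
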