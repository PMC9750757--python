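"""Bootstrap LASSO -> linear-SVM outcome prediction with out-of-bag AUROC.

Each iteration draws a bootstrap sample (with replacement) from the patient
pool, standardizes features on the in-bag statistics, selects features with
an L1-penalized logistic model (penalty tuned by inner 5-fold CV on in-bag
AUROC), trains a linear-kernel SVM (C=1) on the selected features, and
scores the out-of-bag patients — those with zero in-bag draws — by the SVM
decision values.  Repeating B times yields an AUROC distribution summarized
as median and 2.5/97.5 percentile interval, a permuted-null control
ensemble for significance, and per-feature importance as the quadratic mean
of SVM weights across all iterations rescaled so the maximum is 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVC

__all__ = [
    "IterationResult",
    "ModelSummary",
    "auroc",
    "run_iteration",
    "bootstrap_ensemble",
    "importance_scores",
    "model_significance",
    "augment_covariates",
    "plsda_scores",
]

DEFAULT_DRAW_SIZE = 112
DEFAULT_B = 1000
MAX_REDRAWS = 10
LASSO_CS = np.logspace(-2, 1, 7)
SVM_C = 1.0


@dataclass
class IterationResult:
    index: int
    in_bag: np.ndarray  # multiset of pool indices
    oob: np.ndarray  # indices with zero in-bag draws
    selected: np.ndarray  # boolean mask over features
    weights: np.ndarray  # full-length SVM weight vector (zeros unselected)
    oob_auroc: float
    redraws: int = 0
    degenerate: bool = False  # no features selected


@dataclass
class ModelSummary:
    aurocs: np.ndarray
    median: float
    ci_low: float
    ci_high: float
    importance: pd.Series  # feature -> score in [0, 100]
    comparison_p: Optional[float] = None
    skipped: int = 0
    degenerate_iterations: int = 0
    permuted: bool = False

    def to_dict(self) -> dict:
        return {
            "median_auroc": self.median,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_iterations": int(len(self.aurocs)),
            "skipped": self.skipped,
            "degenerate_iterations": self.degenerate_iterations,
            "permuted": self.permuted,
            "comparison_p": self.comparison_p,
            "importance": self.importance.round(4).to_dict(),
        }


def auroc(labels, scores) -> float:
    """AUROC as Mann-Whitney concordance: the fraction of (negative,
    positive) pairs ranked correctly, ties counted one half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("auroc: both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def run_iteration(
    X: np.ndarray,
    y: np.ndarray,
    draw_size: int = DEFAULT_DRAW_SIZE,
    rng: Optional[np.random.Generator] = None,
    index: int = 0,
    permute_labels: bool = False,
    strict_positive: bool = False,
    lasso_cs=LASSO_CS,
    svm_c: float = SVM_C,
) -> Optional[IterationResult]:
    """One bootstrap iteration; returns None if no class-complete draw is
    found in MAX_REDRAWS attempts.

    ``strict_positive`` restricts selection to strictly positive L1
    coefficients (a literal reading of selecting weights above zero); the
    default keeps any nonzero coefficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("run_iteration: pool must contain both classes")
    rng = rng or np.random.default_rng()
    n = len(y)
    redraws = 0
    while True:
        in_bag = rng.integers(0, n, size=draw_size)
        oob = np.setdiff1d(np.arange(n), in_bag)
        if len(np.unique(y[in_bag])) == 2 and len(np.unique(y[oob])) == 2:
            break
        redraws += 1
        if redraws >= MAX_REDRAWS:
            warnings.warn(f"iteration {index}: redraw limit reached, skipped")
            return None

    y_train = y[in_bag]
    if permute_labels:
        y_train = rng.permutation(y_train)
    Xtr, Xte = _standardize(X[in_bag], X[oob])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        lasso = LogisticRegressionCV(
            Cs=lasso_cs,
            l1_ratios=(1.0,),
            solver="liblinear",
            cv=5,
            scoring="roc_auc",
            max_iter=200,
            use_legacy_attributes=False,
        )
        try:
            lasso.fit(Xtr, y_train)
        except ValueError:  # an inner fold lost a class on a degenerate draw
            return IterationResult(index, in_bag, oob, np.zeros(X.shape[1], bool),
                                   np.zeros(X.shape[1]), 0.5, redraws, True)
    coefs = lasso.coef_.ravel()
    selected = coefs > 0 if strict_positive else coefs != 0
    weights = np.zeros(X.shape[1])
    if not selected.any():
        # Constant score rule: no discrimination.
        return IterationResult(index, in_bag, oob, selected, weights, 0.5,
                               redraws, True)
    svm = SVC(kernel="linear", C=svm_c)
    svm.fit(Xtr[:, selected], y_train)
    weights[selected] = svm.coef_.ravel()
    scores = svm.decision_function(Xte[:, selected])
    return IterationResult(
        index, in_bag, oob, selected, weights, auroc(y[oob], scores), redraws
    )


def importance_scores(iterations: list, feature_names=None) -> pd.Series:
    """Quadratic-mean (root-mean-square) of each feature's SVM weights over
    all iterations, zeros included for unselected features, rescaled so the
    maximum score is 100."""
    if not iterations:
        raise ValueError("importance_scores: need at least one iteration")
    W = np.stack([it.weights for it in iterations])
    rms = np.sqrt(np.mean(W**2, axis=0))
    top = rms.max()
    if top == 0:
        warnings.warn("importance_scores: all weights zero")
        scores = rms
    else:
        scores = 100.0 * rms / top
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(len(scores))]
    return pd.Series(scores, index=feature_names).sort_values(ascending=False)


def bootstrap_ensemble(
    X,
    y,
    B: int = DEFAULT_B,
    draw_size: int = DEFAULT_DRAW_SIZE,
    seed: int = 0,
    permute_labels: bool = False,
    feature_names=None,
    strict_positive: bool = False,
) -> ModelSummary:
    """Run B bootstrap iterations and summarize the OOB AUROC distribution.

    Each iteration gets its own RNG stream spawned from ``seed``, so a real
    and a permuted-control ensemble built with the same seed share bootstrap
    draws pair-for-pair (the permutation happens after the draw)."""
    if B < 1:
        raise ValueError("bootstrap_ensemble: B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if isinstance(feature_names, pd.Index):
        feature_names = list(feature_names)
    streams = np.random.SeedSequence(seed).spawn(B)
    results, skipped = [], 0
    for i, child in enumerate(streams):
        res = run_iteration(
            X, y, draw_size=draw_size, rng=np.random.default_rng(child),
            index=i, permute_labels=permute_labels,
            strict_positive=strict_positive,
        )
        if res is None:
            skipped += 1
        else:
            results.append(res)
    if not results:
        raise RuntimeError("bootstrap_ensemble: every iteration was skipped")
    aurocs = np.array([r.oob_auroc for r in results])
    return ModelSummary(
        aurocs=aurocs,
        median=float(np.median(aurocs)),
        ci_low=float(np.percentile(aurocs, 2.5)),
        ci_high=float(np.percentile(aurocs, 97.5)),
        importance=importance_scores(results, feature_names),
        skipped=skipped,
        degenerate_iterations=sum(r.degenerate for r in results),
        permuted=permute_labels,
    )


def model_significance(
    real: ModelSummary, control: ModelSummary, mode: str = "paired"
) -> float:
    """One-sided p that the real model outperforms the permuted control.

    ``paired``: Wilcoxon signed-rank on per-iteration AUROC differences
    (iterations share bootstrap draws through the seed scheme).
    ``two_sample``: Mann-Whitney U between the two AUROC distributions.
    """
    a, b = real.aurocs, control.aurocs
    if mode == "paired":
        if len(a) != len(b):
            raise ValueError("model_significance: paired mode needs equal B")
        if len(a) < 10:
            warnings.warn("model_significance: few iterations; test underpowered")
        diff = a - b
        if np.all(diff == 0):
            return 1.0
        return float(stats.wilcoxon(diff, alternative="greater").pvalue)
    if mode == "two_sample":
        return float(stats.mannwhitneyu(a, b, alternative="greater").pvalue)
    raise ValueError(f"model_significance: unknown mode {mode!r}")


def augment_covariates(X: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Append ISS, age and sex (M=0, F=1) columns to a samples x features
    matrix; downstream standardization treats them as ordinary features."""
    for col in ("iss", "age", "sex"):
        if col in X.columns:
            raise ValueError(f"augment_covariates: column {col!r} already present")
    out = X.copy()
    for sample in X.index:
        if sample not in patients.index:
            raise KeyError(f"augment_covariates: no covariates for {sample!r}")
    sub = patients.loc[X.index]
    if sub[["iss", "age", "sex"]].isna().any().any():
        bad = sub.index[sub[["iss", "age", "sex"]].isna().any(axis=1)][0]
        raise ValueError(f"augment_covariates: missing covariate for {bad!r}")
    out["iss"] = sub["iss"].astype(float)
    out["age"] = sub["age"].astype(float)
    out["sex"] = (sub["sex"] == "F").astype(float)
    return out


def plsda_scores(X, y, n_components: int = 2):
    """PLS-DA projection: PLS regression of the 0/1 outcome on standardized
    features.  Returns (scores, explained X-variance fraction per component).
    Constant features are dropped with a warning."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("plsda_scores: both classes must be present")
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"plsda_scores: dropping {int((sd == 0).sum())} constant features")
        X = X[:, sd > 0]
        sd = sd[sd > 0]
    Xs = (X - X.mean(axis=0)) / sd
    rank = np.linalg.matrix_rank(Xs)
    if n_components > rank:
        raise ValueError(f"plsda_scores: n_components {n_components} > rank {rank}")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, y)
    scores = pls.x_scores_
    total_var = np.sum(Xs**2)
    explained = np.array([
        np.sum(np.outer(scores[:, k], pls.x_loadings_[:, k]) ** 2) / total_var
        for k in range(n_components)
    ])
    return scores, explained
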