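"""Monte Carlo cross-validated L1-penalized logistic classification.

Each iteration stratifies samples into 70/30 train/test splits, selects the
L1 penalty by stratified inner cross-validation maximizing held-out AUC
(ties toward the sparser, larger penalty), refits on the full training set,
and records the test AUC, the selected penalty, and the non-zero
coefficients.  Feature-recurrence summaries aggregate how often each
transcript is selected across iterations.

The penalty is parameterized as lambda multiplying the L1 norm in the
per-sample-mean negative log-likelihood; the solver is scikit-learn's
liblinear (C = 1 / (n * lambda)), with the intercept effectively
unpenalized via a large intercept scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io import GeneSet
from .normalize import NormalizedMatrix

_INTERCEPT_SCALING = 1000.0


def _default_lambda_grid() -> tuple[float, ...]:
    return tuple(np.logspace(-3, 2, 30))


@dataclass(frozen=True)
class CVConfig:
    n_iterations: int = 101
    train_fraction: float = 0.70
    inner_folds: int = 5
    lambda_grid: tuple[float, ...] = field(default_factory=_default_lambda_grid)
    standardize: bool = True
    seed: int = 0
    min_detection_fraction: float = 0.25  # for the all-transcripts feature set

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda grid must be positive")


@dataclass
class CVIterationResult:
    iteration: int
    auc: float
    selected_lambda: float
    coefficients: dict[str, float]  # non-zero only, on the standardized scale
    test_scores: pd.Series
    valid: bool = True
    message: str = ""


@dataclass
class FeatureRecurrence:
    feature: str
    selection_frequency: float
    median_coef: float
    iqr: tuple[float, float]
    sign_consistency: float  # fraction of selections sharing the majority sign


def stratified_split(labels, train_fraction: float, rng: np.random.Generator):
    """Class-stratified train/test split with round-half-up train counts."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    train_idx, test_idx = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} too small to appear in both partitions")
        n_train = int(np.floor(train_fraction * idx.size + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)  # both partitions keep each class
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return np.sort(train_idx), np.sort(test_idx)


def fit_lasso_logistic(features: np.ndarray, labels: np.ndarray, lam: float, tol: float = 1e-8):
    """L1-penalized logistic fit minimizing mean log-loss + lam * ||beta||_1.

    Returns ``(coefficients, intercept)``.  The intercept is unpenalized
    (up to the solver's large intercept scaling).
    """
    features = np.asarray(features, dtype=float)
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    n = features.shape[0]
    model = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (n * lam),
        solver="liblinear",
        intercept_scaling=_INTERCEPT_SCALING,
        tol=tol,
        max_iter=10_000,
        random_state=0,  # liblinear's internal coordinate shuffle
    )
    model.fit(features, labels)
    return model.coef_[0].copy(), float(model.intercept_[0])


def kkt_violation(features, labels, lam, coef, intercept) -> float:
    """Max violation of the L1 KKT conditions at a candidate solution.

    For the per-sample-mean loss, zero coefficients require |gradient| <= lam
    and non-zero ones gradient = -lam * sign(beta); returns the largest
    absolute slack.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    eta = intercept + x @ coef
    p = 1.0 / (1.0 + np.exp(-eta))
    grad = x.T @ (p - y) / len(y)
    viol = np.where(
        coef == 0,
        np.maximum(np.abs(grad) - lam, 0.0),
        np.abs(grad + lam * np.sign(coef)),
    )
    return float(np.max(np.append(viol, abs((p - y).mean()))))


def auc(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U: probability a random positive
    outranks a random negative, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def inner_cv_select_lambda(
    features: np.ndarray,
    labels: np.ndarray,
    config: CVConfig,
    rng: np.random.Generator,
) -> float:
    """Pick lambda maximizing mean held-out AUC over stratified inner folds.

    Ties break toward the larger lambda (the sparser model).  A fold whose
    held-out part lacks a class is an error, per the stratification contract.
    """
    grid = sorted(config.lambda_grid)
    if len(grid) == 1:
        return grid[0]
    skf = StratifiedKFold(
        n_splits=config.inner_folds,
        shuffle=True,
        random_state=int(rng.integers(2**31)),
    )
    mean_auc = np.zeros(len(grid))
    for tr, te in skf.split(features, labels):
        if len(np.unique(labels[te])) < 2:
            raise ValueError("inner fold without both classes")
        x_tr, x_te = features[tr], features[te]
        if config.standardize:
            x_tr, x_te = _standardize(x_tr, x_te)
        for k, lam in enumerate(grid):
            # the inner loop only ranks lambdas by held-out AUC; a loose
            # solver tolerance is sufficient and much cheaper
            coef, intercept = fit_lasso_logistic(x_tr, labels[tr], lam, tol=1e-4)
            mean_auc[k] += auc(x_te @ coef + intercept, labels[te])
    best = np.flatnonzero(mean_auc == mean_auc.max())
    return grid[best[-1]]  # largest lambda among ties


def features_from_norm(
    norm: NormalizedMatrix,
    feature_set: GeneSet | str,
) -> pd.DataFrame:
    """Samples-by-genes feature table for a gene set or ``"all"`` transcripts."""
    if isinstance(feature_set, str):
        if feature_set != "all":
            raise ValueError(f"unknown feature set {feature_set!r}")
        return norm.logcpm.T
    present = [g for g in feature_set.members if g in norm.genes]
    if not present:
        raise ValueError(f"feature set {feature_set.name!r} shares no genes with the matrix")
    return norm.logcpm.loc[present].T


def monte_carlo_cv(
    norm: NormalizedMatrix,
    labels,
    feature_set: GeneSet | str,
    config: CVConfig | None = None,
) -> list[CVIterationResult]:
    """Run the full Monte Carlo CV loop for one feature set.

    Per-iteration RNG substreams derive from ``(seed, iteration)``, so
    results are reproducible and independent of execution order.  For the
    ``"all"`` feature set, genes must be detected (count > 0) in at least
    ``min_detection_fraction`` of the *training* samples of that iteration.
    """
    config = config or CVConfig()
    labels = np.asarray(labels).astype(bool)
    x_all = features_from_norm(norm, feature_set)
    if len(x_all) != labels.size:
        raise ValueError("labels do not match the sample dimension")
    detection = norm.detection_mask().T if feature_set == "all" else None

    results: list[CVIterationResult] = []
    for i in range(config.n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i]))
        try:
            tr, te = stratified_split(labels, config.train_fraction, rng)
            cols = x_all.columns
            if detection is not None:
                det_frac = detection.iloc[tr].mean(axis=0)
                cols = cols[det_frac.to_numpy() >= config.min_detection_fraction]
                if len(cols) == 0:
                    raise ValueError("no features pass the detection filter")
            x_tr = x_all.iloc[tr][cols].to_numpy(dtype=float)
            x_te = x_all.iloc[te][cols].to_numpy(dtype=float)
            lam = inner_cv_select_lambda(x_tr, labels[tr], config, rng)
            if config.standardize:
                x_tr, x_te = _standardize(x_tr, x_te)
            coef, intercept = fit_lasso_logistic(x_tr, labels[tr], lam)
            test_scores = pd.Series(x_te @ coef + intercept, index=x_all.index[te])
            iteration_auc = auc(test_scores.to_numpy(), labels[te])
            nonzero = {g: float(c) for g, c in zip(cols, coef) if c != 0.0}
            results.append(
                CVIterationResult(
                    iteration=i,
                    auc=iteration_auc,
                    selected_lambda=float(lam),
                    coefficients=nonzero,
                    test_scores=test_scores,
                )
            )
        except ValueError as exc:
            results.append(
                CVIterationResult(
                    iteration=i,
                    auc=float("nan"),
                    selected_lambda=float("nan"),
                    coefficients={},
                    test_scores=pd.Series(dtype=float),
                    valid=False,
                    message=str(exc),
                )
            )
    return results


def feature_recurrence(results: list[CVIterationResult]) -> list[FeatureRecurrence]:
    """Selection frequency and coefficient stability per feature.

    Frequencies are over valid iterations; sorted by decreasing frequency,
    ties by feature identifier.
    """
    valid = [r for r in results if r.valid]
    if not valid:
        raise ValueError("no valid iterations")
    coefs: dict[str, list[float]] = {}
    for r in valid:
        for feat, c in r.coefficients.items():
            coefs.setdefault(feat, []).append(c)
    out = []
    for feat, values in coefs.items():
        arr = np.array(values)
        signs = np.sign(arr)
        majority = max((signs > 0).mean(), (signs < 0).mean())
        out.append(
            FeatureRecurrence(
                feature=feat,
                selection_frequency=len(values) / len(valid),
                median_coef=float(np.median(arr)),
                iqr=(float(np.percentile(arr, 25)), float(np.percentile(arr, 75))),
                sign_consistency=float(majority),
            )
        )
    out.sort(key=lambda f: (-f.selection_frequency, f.feature))
    return out


def recurrence_table(recurrence: list[FeatureRecurrence]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature for r in recurrence],
            "selection_frequency": [r.selection_frequency for r in recurrence],
            "median_coef": [r.median_coef for r in recurrence],
            "iqr_low": [r.iqr[0] for r in recurrence],
            "iqr_high": [r.iqr[1] for r in recurrence],
            "sign_consistency": [r.sign_consistency for r in recurrence],
        }
    )


def auc_summary(results: list[CVIterationResult]) -> dict:
    """Median / quartiles of test AUC over valid iterations."""
    aucs = np.array([r.auc for r in results if r.valid])
    if aucs.size == 0:
        raise ValueError("no valid iterations")
    return {
        "n_valid": int(aucs.size),
        "n_invalid": int(len(results) - aucs.size),
        "median_auc": float(np.median(aucs)),
        "q1_auc": float(np.percentile(aucs, 25)),
        "q3_auc": float(np.percentile(aucs, 75)),
    }
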