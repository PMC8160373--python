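"""Depression screening: MRMR feature selection and logistic regression.

The screening model is an unpenalized logistic regression

    log(p / (1 - p)) = b0 + b1 x1 + ... + bm xm,

with the decision rule logit >= 0 => suspected depressive, logit < 0 =>
healthy.  Candidate features are ranked by a greedy quotient-scheme
minimum-redundancy-maximum-relevance (MRMR) criterion using mutual
information on equal-frequency quartile bins, the model size is picked by
5-fold cross-validated accuracy (mean of sensitivity, specificity, PPV and
NPV), and the shipped :func:`published_model` carries the clinically fitted
four-variable equation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit
from sklearn.metrics import mutual_info_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import SeparationError

__all__ = [
    "ScreeningModel",
    "ScreeningResult",
    "CvMetrics",
    "mrmr_rank",
    "select_model_size",
    "fit_lra",
    "published_model",
    "score",
    "evaluate_cv",
    "roc_analysis",
    "PUBLISHED_FEATURES",
]

#: Feature names of the published four-variable model, in equation order.
PUBLISHED_FEATURES = ("HF_MT", "pctLF_PreR_MT", "pctHF_PreR_MT", "pctHF_MT_PostR")


@dataclass
class ScreeningModel:
    intercept: float
    coefficients: np.ndarray
    feature_names: tuple[str, ...]
    meta: dict = field(default_factory=dict)
    standard_errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, float)
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("coefficient count must match feature names")
        if not np.all(np.isfinite(self.coefficients)) or not np.isfinite(
            self.intercept
        ):
            raise ValueError("model parameters must be finite")

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(zip(self.feature_names, map(float, self.coefficients))),
            "meta": self.meta,
        }


@dataclass(frozen=True)
class ScreeningResult:
    logit: float
    p: float
    label: str  # "suspected_mdd" | "healthy"


@dataclass
class CvMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float
    optimal_cutoff: float
    fold_assignment: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        """The model-size criterion: mean of the four proportions."""
        return float(
            np.mean([self.sensitivity, self.specificity, self.ppv, self.npv])
        )


def _quartile_bins(x: np.ndarray) -> np.ndarray:
    """Equal-frequency quartile discretization; returns integer bin labels."""
    edges = np.quantile(x, [0.25, 0.5, 0.75])
    return np.searchsorted(edges, x, side="right")


def mrmr_rank(
    X: np.ndarray,
    y: np.ndarray,
    k: int | None = None,
    feature_names: Sequence[str] | None = None,
    eps: float = 1e-12,
) -> list[tuple[int, float]]:
    """Greedy quotient-scheme MRMR ranking.

    The first pick maximizes relevance MI(f; y); subsequent picks maximize
    MI(f; y) / (mean MI(f; selected) + eps).  Mutual information is computed
    on equal-frequency quartile bins.  Ties break by higher relevance, then
    input order.  Constant (zero-entropy) features are excluded with a
    warning.  Returns ``[(feature_index, score), ...]`` in rank order.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if np.isnan(X).any():
        raise ValueError("features contain missing values")
    n, m = X.shape
    if k is None:
        k = m

    binned = np.empty((m, n), dtype=int)
    usable = []
    for j in range(m):
        binned[j] = _quartile_bins(X[:, j])
        if len(np.unique(binned[j])) < 2:
            name = feature_names[j] if feature_names else str(j)
            warnings.warn(f"feature {name} is constant; excluded from MRMR",
                          stacklevel=2)
        else:
            usable.append(j)

    relevance = {j: mutual_info_score(binned[j], y) for j in usable}
    pair_mi: dict[tuple[int, int], float] = {}

    def redundancy(j: int, selected: list[int]) -> float:
        vals = []
        for s in selected:
            key = (min(j, s), max(j, s))
            if key not in pair_mi:
                pair_mi[key] = mutual_info_score(binned[j], binned[s])
            vals.append(pair_mi[key])
        return float(np.mean(vals))

    ranking: list[tuple[int, float]] = []
    selected: list[int] = []
    remaining = list(usable)
    while remaining and len(ranking) < k:
        best_j, best_key = None, None
        for j in remaining:
            s = (
                relevance[j]
                if not selected
                else relevance[j] / (redundancy(j, selected) + eps)
            )
            key = (s, relevance[j], -j)  # ties: higher relevance, then order
            if best_key is None or key > best_key:
                best_j, best_key = j, key
        ranking.append((best_j, best_key[0]))
        selected.append(best_j)
        remaining.remove(best_j)
    return ranking


def fit_lra(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_bound: float = 50.0,
) -> ScreeningModel:
    """Maximum-likelihood logistic fit via iteratively reweighted least
    squares, no penalty.

    Convergence when the largest coefficient update falls below ``tol``.
    Complete (quasi-)separation is reported as :class:`SeparationError`
    when any coefficient magnitude exceeds ``separation_bound`` during the
    iterations, rather than silently diverging.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, m) with one label per row")
    n, m = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(m + 1)
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        grad = Xd.T @ (y - mu)
        hess = (Xd * w[:, None]).T @ Xd
        try:
            delta = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular Fisher information: {exc}") from exc
        beta = beta + delta
        if np.max(np.abs(beta)) > separation_bound:
            raise SeparationError(
                "coefficients diverging; data are completely separated"
            )
        if np.max(np.abs(delta)) < tol:
            break
    cov = np.linalg.inv((Xd * np.maximum(expit(Xd @ beta) * (1 - expit(Xd @ beta)), 1e-10)[:, None]).T @ Xd)
    se = np.sqrt(np.diag(cov))
    names = tuple(feature_names) if feature_names else tuple(f"x{i+1}" for i in range(m))
    return ScreeningModel(
        intercept=float(beta[0]),
        coefficients=beta[1:],
        feature_names=names,
        standard_errors=se,
        meta={"n": n, "fit": "irls"},
    )


def published_model() -> ScreeningModel:
    """The clinically fitted four-variable screening equation.

    HF_MT is in ms^2; the three percent-change features are dimensionless
    percentages.
    """
    return ScreeningModel(
        intercept=-1.2895,
        coefficients=np.array([0.0013, 0.0051, -0.0001, -0.0004]),
        feature_names=PUBLISHED_FEATURES,
        meta={"source": "published clinical fit", "n": 53},
    )


def score(model: ScreeningModel, features: Mapping[str, float]) -> ScreeningResult:
    """Apply a screening model to a named feature mapping."""
    getter = features.as_dict() if hasattr(features, "as_dict") else features
    try:
        x = np.array([getter[name] for name in model.feature_names], float)
    except KeyError as exc:
        raise KeyError(
            f"missing feature {exc} (model needs {model.feature_names})"
        ) from exc
    logit = float(model.intercept + model.coefficients @ x)
    return ScreeningResult(
        logit=logit,
        p=float(expit(logit)),
        label="suspected_mdd" if logit >= 0 else "healthy",
    )


def evaluate_cv(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> CvMetrics:
    """Stratified k-fold cross-validation with a pooled confusion matrix.

    Out-of-fold logits are pooled and thresholded at 0; sensitivity,
    specificity, PPV and NPV come from the pooled counts, AUC and the
    Youden-optimal cutoff from the pooled logits.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    if counts.min() < folds:
        raise ValueError(
            f"minority class has {counts.min()} members; cannot stratify "
            f"{folds} folds with both classes present"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    logits = np.empty(len(y))
    fold_of = np.empty(len(y), dtype=int)
    for f, (train, test) in enumerate(skf.split(X, y)):
        model = fit_lra(X[train], y[train], feature_names=feature_names)
        logits[test] = model.intercept + X[test] @ model.coefficients
        fold_of[test] = f
    pred = (logits >= 0).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    auc, cutoff = roc_analysis(logits, y)
    return CvMetrics(
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        ppv=tp / (tp + fp) if tp + fp else np.nan,
        npv=tn / (tn + fn) if tn + fn else np.nan,
        tp=tp, fp=fp, tn=tn, fn=fn,
        auc=auc,
        optimal_cutoff=cutoff,
        fold_assignment=fold_of,
        seed=seed,
    )


def select_model_size(
    X: np.ndarray,
    y: np.ndarray,
    max_k: int | None = None,
    folds: int = 5,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> tuple[int, np.ndarray, list[tuple[int, float]]]:
    """Cross-validated model-size selection over the MRMR ranking.

    For k = 1..max_k, fit logistic models on the top-k MRMR features and
    record CV accuracy (mean of sensitivity, specificity, PPV, NPV).  A k
    whose folds hit complete separation is marked NaN (ineligible).
    Returns ``(k_star, accuracy_curve, ranking)`` with the smallest k on
    accuracy ties.
    """
    X = np.asarray(X, float)
    if max_k is None:
        max_k = min(X.shape[1], max(1, len(y) // 10))
    if max_k > X.shape[1]:
        raise ValueError("max_k exceeds the feature count")
    ranking = mrmr_rank(X, y, feature_names=feature_names)
    order = [j for j, _ in ranking]
    curve = np.full(max_k, np.nan)
    for k in range(1, max_k + 1):
        cols = order[:k]
        try:
            curve[k - 1] = evaluate_cv(
                X[:, cols], y, folds=folds, seed=seed,
                feature_names=[feature_names[c] for c in cols] if feature_names else None,
            ).accuracy
        except SeparationError:
            continue
    if np.all(np.isnan(curve)):
        raise SeparationError("every candidate model size hit separation")
    k_star = int(np.nanargmax(curve)) + 1
    return k_star, curve, ranking


def roc_analysis(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """ROC AUC (trapezoidal; equals the tie-corrected concordance
    probability) and the Youden-optimal cutoff (lowest threshold on ties)."""
    logits = np.asarray(logits, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(labels, logits, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = np.nonzero(j == j.max())[0][-1]  # thresholds descend: last = lowest
    cutoff = float(thresholds[best])
    if np.isinf(cutoff):
        cutoff = float(logits.max())
    return auc, cutoff
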