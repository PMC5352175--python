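"""Leave-one-out cross-validation, one-vs-rest ROC/AUC and diagnostic metrics.

Predictive accuracy of the grade model is assessed by refitting on every
leave-one-out training set and scoring the held-out tumor, then treating
each grade in turn as the positive class: the AUC is the Mann-Whitney rank
statistic of the predicted positive-class probability (midrank ties), with
a DeLong 95% CI.  Argmax classification yields per-grade sensitivity,
specificity, PPV and NPV with Wilson score CIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .errors import InvalidConfigError
from .model import fit_multinomial, predict_proba, stepwise_select

Z_95 = stats.norm.ppf(0.975)


@dataclass
class LoocvResult:
    """Held-out class probabilities per tumor.

    ``probabilities`` has one column per class (reference first); rows with
    a non-converged fold are NaN and listed in ``failed_folds``.
    """

    probabilities: pd.DataFrame
    y: np.ndarray
    classes: list
    mode: str
    failed_folds: list[int] = field(default_factory=list)
    per_fold_selected: list[list[str]] | None = None


def loocv_predict(
    X,
    y,
    selected_features: list[str] | None = None,
    mode: str = "fixed-selection",
    reference=1,
    alpha: float = 0.05,
) -> LoocvResult:
    """Leave-one-out class-probability predictions from the multinomial model.

    ``fixed-selection`` refits the model on the given feature set in every
    fold (mirroring selection reported once on the full data);
    ``per-fold-selection`` reruns stepwise selection inside each training
    fold, which removes the selection optimism but may pick different
    features per fold.
    """
    if mode not in ("fixed-selection", "per-fold-selection"):
        raise InvalidConfigError(f"unknown LOOCV mode {mode!r}")
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float),
                         columns=[f"x{j + 1}" for j in range(np.asarray(X).shape[1])])
    y = np.asarray(y)
    n = len(y)
    observed = sorted(pd.unique(y).tolist())
    classes = [reference] + [c for c in observed if c != reference]

    probs = np.full((n, len(classes)), np.nan)
    failed: list[int] = []
    per_fold: list[list[str]] = []
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        Xtr, ytr = X.iloc[train], y[train]
        if mode == "per-fold-selection":
            cols, _ = stepwise_select(Xtr, ytr, alpha_enter=alpha,
                                      alpha_remove=alpha, reference=reference)
        else:
            cols = list(selected_features or [])
        per_fold.append(cols)
        try:
            fit = fit_multinomial(
                Xtr[cols] if cols else np.empty((train.sum(), 0)),
                ytr, reference=reference, feature_names=cols, classes=classes,
                raise_on_nonconvergence=False,
            )
            if not fit.converged:
                failed.append(i)
                continue
            row = X.iloc[[i]][cols].to_numpy() if cols else np.empty((1, 0))
            probs[i] = predict_proba(fit, row).to_numpy()[0]
        except Exception:
            failed.append(i)

    prob_df = pd.DataFrame(probs, columns=classes)
    return LoocvResult(probabilities=prob_df, y=y, classes=classes, mode=mode,
                       failed_folds=failed,
                       per_fold_selected=per_fold if mode == "per-fold-selection" else None)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci: tuple[float, float]
    auc_variance: float
    n_positive: int
    n_negative: int


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic with midrank ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise InvalidConfigError("AUC needs both positive and negative examples")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the AUC via placement values."""
    pos = scores[labels]
    neg = scores[~labels]
    n1, n0 = len(pos), len(neg)
    # V10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i), via midranks
    v10 = np.array([
        (np.sum(neg < x) + 0.5 * np.sum(neg == x)) / n0 for x in pos
    ])
    v01 = np.array([
        (np.sum(pos > x) + 0.5 * np.sum(pos == x)) / n1 for x in neg
    ])
    s10 = np.var(v10, ddof=1) if n1 > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n0 > 1 else 0.0
    return float(s10 / n1 + s01 / n0)


def roc_auc_ovr(probabilities: pd.DataFrame, y, target_grade) -> RocResult:
    """One-vs-rest ROC curve and AUC for one grade with a DeLong 95% CI.

    Scores are the predicted probability of ``target_grade``; rows with
    missing predictions are dropped.
    """
    y = np.asarray(y)
    scores = probabilities[target_grade].to_numpy(dtype=float)
    keep = ~np.isnan(scores)
    scores, y = scores[keep], y[keep]
    labels = y == target_grade
    if labels.all() or not labels.any():
        raise InvalidConfigError(
            f"grade {target_grade!r} needs both positive and negative examples"
        )
    auc = auc_mann_whitney(scores, labels)
    var = _delong_variance(scores, labels)
    half = Z_95 * np.sqrt(var)
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), scores)
    return RocResult(
        fpr=fpr, tpr=tpr, auc=auc,
        ci=(max(0.0, auc - half), min(1.0, auc + half)),
        auc_variance=var,
        n_positive=int(labels.sum()), n_negative=int((~labels).sum()),
    )


# ---------------------------------------------------------------------------
# Diagnostic metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricValue:
    """A percentage metric with a Wilson 95% CI, or undefined with a reason."""

    percent: float | None
    ci: tuple[float, float] | None
    numerator: int
    denominator: int
    reason: str = ""

    @property
    def defined(self) -> bool:
        return self.percent is not None


def _proportion_metric(num: int, den: int, undefined_reason: str) -> MetricValue:
    if den == 0:
        return MetricValue(percent=None, ci=None, numerator=num, denominator=0,
                           reason=undefined_reason)
    low, high = proportion_confint(num, den, alpha=0.05, method="wilson")
    return MetricValue(percent=100.0 * num / den,
                       ci=(100.0 * float(low), 100.0 * float(high)),
                       numerator=num, denominator=den)


def diagnostic_metrics(probabilities: pd.DataFrame, y) -> dict:
    """Per-grade sensitivity, specificity, PPV and NPV from argmax assignment.

    Each tumor is assigned its highest-probability grade; metrics are
    one-vs-rest per grade, in percent, with Wilson score 95% CIs.  Ratios
    with empty denominators (e.g. PPV of a never-predicted grade) are
    reported as undefined with a reason rather than as numbers.
    """
    y = np.asarray(y)
    probs = probabilities.to_numpy(dtype=float)
    keep = ~np.isnan(probs).any(axis=1)
    probs, y = probs[keep], y[keep]
    classes = list(probabilities.columns)
    assigned = np.array([classes[k] for k in probs.argmax(axis=1)])

    out = {}
    for g in classes:
        if not np.any(y == g):
            raise InvalidConfigError(f"no true observations of grade {g!r}")
        tp = int(np.sum((assigned == g) & (y == g)))
        fp = int(np.sum((assigned == g) & (y != g)))
        fn = int(np.sum((assigned != g) & (y == g)))
        tn = int(np.sum((assigned != g) & (y != g)))
        out[g] = {
            "sensitivity": _proportion_metric(tp, tp + fn, "no true positives or false negatives"),
            "specificity": _proportion_metric(tn, tn + fp, "no true negatives or false positives"),
            "ppv": _proportion_metric(tp, tp + fp, f"grade {g!r} never predicted"),
            "npv": _proportion_metric(tn, tn + fn, f"grade {g!r} always predicted"),
        }
    out["assignments"] = assigned
    return out
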