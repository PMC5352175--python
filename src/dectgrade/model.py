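"""Grade-stratification statistics: univariate screening, multinomial fit,
stepwise selection and collinearity checks.

The central model is a baseline-category (multinomial) logistic regression
with grade 1 as the reference class: for classes g != 1,
``log P(g)/P(1) = a_g + x' b_g``.  It is fit by Newton-Raphson with step
halving on internally standardized covariates; coefficients, Wald
standard errors, odds ratios and 95% CIs are reported on the original
covariate scale.  Stepwise selection adds/removes one feature at a time
(as a block over both non-reference classes) using likelihood-ratio test
p-values at two-sided alpha 5% for both insertion and deletion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, InvalidConfigError

MAX_ITER = 100
LL_RTOL = 1e-10
#: |linear predictor| beyond which the fit is flagged as (quasi-)separated.
SEPARATION_ETA = 30.0
Z_95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# Univariate screening
# ---------------------------------------------------------------------------

def anova_bonferroni(feature: np.ndarray, grades: np.ndarray) -> dict:
    """One-way ANOVA across grades with Bonferroni-adjusted pairwise t-tests.

    Returns the omnibus F and p plus a dict of pairwise adjusted p-values
    (raw two-sample pooled-variance t-test p multiplied by the number of
    pairs, capped at 1).
    """
    feature = np.asarray(feature, dtype=float)
    grades = np.asarray(grades)
    levels = sorted(pd.unique(grades))
    groups = [feature[grades == g] for g in levels]
    if len(groups) < 2:
        raise InvalidConfigError("ANOVA needs at least 2 groups")
    for g, arr in zip(levels, groups):
        if arr.size < 2:
            raise InvalidConfigError(f"group {g} has fewer than 2 observations")

    grand = feature.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in groups)
    if ss_between <= 1e-300:
        f_stat, p_omni = 0.0, 1.0
    else:
        f_stat, p_omni = stats.f_oneway(*groups)

    n_pairs = len(levels) * (len(levels) - 1) // 2
    pairwise = {}
    for (ga, a), (gb, b) in itertools.combinations(zip(levels, groups), 2):
        if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
            p_raw = 1.0
        else:
            p_raw = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        pairwise[(ga, gb)] = min(1.0, p_raw * n_pairs)
    return {"F": float(f_stat), "omnibus_p": float(p_omni),
            "pairwise_adjusted_p": pairwise}


# ---------------------------------------------------------------------------
# Multinomial baseline-category logit
# ---------------------------------------------------------------------------

@dataclass
class GradeModelFit:
    """Fitted baseline-category logit.

    ``coef`` has one row per non-reference class (order ``classes[1:]``)
    and columns ``[intercept, features...]`` on the original covariate
    scale; ``cov`` is the Wald covariance of the flattened (class-major)
    coefficient vector.
    """

    classes: list
    reference: object
    feature_names: list[str]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_history: list[float]
    converged: bool
    n_iter: int
    separation: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov)).reshape(self.coef.shape)

    def summary(self) -> pd.DataFrame:
        """Per-coefficient OR, Wald 95% CI and p-value table."""
        rows = []
        terms = ["(intercept)"] + list(self.feature_names)
        se = self.se
        for k, cls in enumerate(self.classes[1:]):
            for j, term in enumerate(terms):
                b, s = self.coef[k, j], se[k, j]
                z = b / s if s > 0 else np.inf * np.sign(b)
                with np.errstate(over="ignore"):
                    or_point, or_lo, or_hi = (
                        float(np.exp(b)),
                        float(np.exp(b - Z_95 * s)),
                        float(np.exp(b + Z_95 * s)),
                    )
                rows.append({
                    "class": cls, "term": term, "coef": b, "se": s,
                    "odds_ratio": or_point,
                    "or_ci_low": or_lo,
                    "or_ci_high": or_hi,
                    "p_value": 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0,
                })
        return pd.DataFrame(rows)


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def p1_eta_max(xd: np.ndarray, beta: np.ndarray) -> float:
    """Largest |linear predictor| over observations and classes."""
    return float(np.abs(xd @ beta.T).max()) if beta.size else 0.0


def _loglik_grad_info(xd: np.ndarray, y_idx: np.ndarray, beta: np.ndarray):
    """Log-likelihood, score and Fisher information of the flattened model."""
    n, p1 = xd.shape
    km1 = beta.shape[0]
    eta = xd @ beta.T                                  # (n, K-1)
    m = np.maximum(0.0, eta.max(axis=1))               # log-sum-exp guard
    denom = np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1)
    log_denom = m + np.log(denom)
    probs = np.exp(eta - log_denom[:, None])           # (n, K-1)

    rows = y_idx > 0
    ll = -log_denom.sum() + eta[rows, y_idx[rows] - 1].sum()

    indic = np.zeros((n, km1))
    indic[np.nonzero(rows)[0], y_idx[rows] - 1] = 1.0
    grad = ((indic - probs).T @ xd).ravel()            # class-major blocks

    info = np.empty((km1 * p1, km1 * p1))
    for k in range(km1):
        for l in range(km1):
            w = probs[:, k] * ((1.0 if k == l else 0.0) - probs[:, l])
            info[k * p1:(k + 1) * p1, l * p1:(l + 1) * p1] = -(xd * w[:, None]).T @ xd
    info = -info  # negative Hessian = Fisher information
    return float(ll), grad, info, probs


def fit_multinomial(
    X,
    y,
    reference=1,
    feature_names: list[str] | None = None,
    classes: list | None = None,
    max_iter: int = MAX_ITER,
    tol: float = LL_RTOL,
    raise_on_nonconvergence: bool = True,
) -> GradeModelFit:
    """Maximum-likelihood baseline-category logit with Wald inference.

    Covariates are standardized internally for Newton stability and the
    coefficients back-transformed, so reported ORs are per original unit
    (e.g. per HU).  Raises :class:`ConvergenceError` after ``max_iter``
    Newton iterations unless ``raise_on_nonconvergence`` is False, in which
    case the partial fit is returned with ``converged=False``.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y)
    n, p = X.shape
    feature_names = feature_names or [f"x{j + 1}" for j in range(p)]

    if classes is None:
        observed = sorted(pd.unique(y).tolist())
        if reference not in observed:
            raise InvalidConfigError(f"reference class {reference!r} not present in y")
        classes = [reference] + [c for c in observed if c != reference]
    km1 = len(classes) - 1
    n_params = km1 * (p + 1)
    if n <= n_params:
        raise InvalidConfigError(
            f"n={n} must exceed the number of parameters ({n_params})"
        )
    if np.isnan(X).any():
        raise InvalidConfigError("X contains missing values")

    class_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_index[v] for v in y])

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    xs = (X - mu) / sd
    xd = _design(xs)

    beta = np.zeros((km1, p + 1))
    ll, grad, info, _ = _loglik_grad_info(xd, y_idx, beta)
    history = [ll]
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info + 1e-10 * np.eye(len(info)), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        scale = 1.0
        while scale > 1e-8:
            cand = beta + scale * step.reshape(km1, p + 1)
            ll_new, grad_new, info_new, _ = _loglik_grad_info(xd, y_idx, cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, grad, info = cand, grad_new, info_new
        history.append(ll_new)
        if abs(ll_new - ll) <= tol * (abs(ll) + 1e-12):
            ll = ll_new
            converged = True
            break
        ll = ll_new
        if km1 > 0 and p1_eta_max(xd, beta) > SEPARATION_ETA:
            # (Quasi-)separation: coefficients diverge while the likelihood
            # plateaus; stop here and flag, as GLM fitters conventionally do.
            separation = True
            converged = True
            break

    if not converged and raise_on_nonconvergence:
        raise ConvergenceError(
            f"multinomial fit did not converge in {max_iter} iterations "
            f"(log-likelihood trace tail: {history[-3:]})"
        )

    eta = xd @ beta.T
    separation = separation or bool(np.abs(eta).max() > SEPARATION_ETA)

    # Back-transform to the original covariate scale.
    coef = np.empty_like(beta)
    coef[:, 1:] = beta[:, 1:] / sd
    coef[:, 0] = beta[:, 0] - (beta[:, 1:] * mu / sd).sum(axis=1)

    # Wald covariance from the information matrix on the original design.
    xd_orig = _design(X)
    _, _, info_orig, _ = _loglik_grad_info(xd_orig, y_idx, coef)
    try:
        cov = np.linalg.inv(info_orig)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info_orig)

    return GradeModelFit(
        classes=list(classes), reference=reference, feature_names=feature_names,
        coef=coef, cov=cov, loglik=float(ll), loglik_history=history,
        converged=converged, n_iter=it, separation=separation,
    )


def predict_proba(fit: GradeModelFit, X) -> pd.DataFrame:
    """Class-probability predictions, columns ordered as ``fit.classes``."""
    if isinstance(X, pd.DataFrame):
        X = X[fit.feature_names].to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    xd = _design(X)
    eta = xd @ fit.coef.T
    full = np.column_stack([np.zeros(len(xd)), eta])
    full -= full.max(axis=1, keepdims=True)
    ex = np.exp(full)
    probs = ex / ex.sum(axis=1, keepdims=True)
    return pd.DataFrame(probs, columns=fit.classes)


# ---------------------------------------------------------------------------
# Stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseTrace:
    """Ordered record of stepwise actions ``(step, action, feature, p)``."""

    steps: list[tuple[int, str, str, float]] = field(default_factory=list)

    def record(self, action: str, feature: str, p: float) -> None:
        self.steps.append((len(self.steps) + 1, action, feature, float(p)))


def _fit_subset(X: pd.DataFrame, y, cols: list[str], reference):
    if cols:
        return fit_multinomial(
            X[cols], y, reference=reference, feature_names=cols,
            raise_on_nonconvergence=False,
        )
    return fit_multinomial(
        np.empty((len(X), 0)), y, reference=reference, feature_names=[],
        raise_on_nonconvergence=False,
    )


def stepwise_select(
    X,
    y,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
    reference=1,
    max_steps: int = 100,
) -> tuple[list[str], StepwiseTrace]:
    """Forward-backward stepwise selection on likelihood-ratio p-values.

    A feature enters or leaves as a block of one coefficient per
    non-reference class (2 df for three grades).  At each cycle the best
    enterable feature (smallest LRT p < ``alpha_enter``) is added, then
    removable features (largest LRT p > ``alpha_remove``) are dropped until
    none qualifies.  Ties break toward earlier column order.  Terminates
    when no action qualifies or a state repeats.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float),
                         columns=[f"x{j + 1}" for j in range(np.asarray(X).shape[1])])
    all_features = list(X.columns)
    km1 = len(pd.unique(np.asarray(y))) - 1
    current: list[str] = []
    trace = StepwiseTrace()
    seen = {tuple(current)}

    for _ in range(max_steps):
        changed = False
        ll_cur = _fit_subset(X, y, current, reference).loglik

        best_p, best_feat, best_ll = None, None, None
        for feat in all_features:
            if feat in current:
                continue
            fit1 = _fit_subset(X, y, current + [feat], reference)
            lr = max(0.0, 2.0 * (fit1.loglik - ll_cur))
            p = float(stats.chi2.sf(lr, df=km1))
            if best_p is None or p < best_p - 1e-15:
                best_p, best_feat, best_ll = p, feat, fit1.loglik
        if best_p is not None and best_p < alpha_enter:
            current = current + [best_feat]
            trace.record("add", best_feat, best_p)
            ll_cur = best_ll
            changed = True

        while current:
            worst_p, worst_feat = None, None
            for feat in current:
                rest = [f for f in current if f != feat]
                ll0 = _fit_subset(X, y, rest, reference).loglik
                lr = max(0.0, 2.0 * (ll_cur - ll0))
                p = float(stats.chi2.sf(lr, df=km1))
                if worst_p is None or p > worst_p + 1e-15:
                    worst_p, worst_feat = p, feat
            if worst_p is not None and worst_p > alpha_remove:
                current = [f for f in current if f != worst_feat]
                trace.record("remove", worst_feat, worst_p)
                ll_cur = _fit_subset(X, y, current, reference).loglik
                changed = True
            else:
                break

        state = tuple(sorted(current))
        if not changed or state in seen:
            break
        seen.add(state)

    return current, trace


# ---------------------------------------------------------------------------
# Collinearity and sample size
# ---------------------------------------------------------------------------

def vif_screen(X, threshold: float = 10.0) -> tuple[dict[str, float], list[str]]:
    """Variance inflation factors ``1 / (1 - R^2_j)`` with flags above 10.

    Each feature is regressed (with intercept) on all others; exact
    collinearity yields an infinite VIF.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float),
                         columns=[f"x{j + 1}" for j in range(np.asarray(X).shape[1])])
    names = list(X.columns)
    arr = X.to_numpy(dtype=float)
    n, p = arr.shape
    if p < 2:
        raise InvalidConfigError("VIF needs at least 2 features")
    if n <= p:
        raise InvalidConfigError(f"VIF needs n > number of features ({n} <= {p})")
    vifs: dict[str, float] = {}
    for j, name in enumerate(names):
        target = arr[:, j]
        others = np.column_stack(
            [np.ones(n), np.delete(arr, j, axis=1)]
        )
        fitted = others @ np.linalg.lstsq(others, target, rcond=None)[0]
        ss_tot = float(np.sum((target - target.mean()) ** 2))
        ss_res = float(np.sum((target - fitted) ** 2))
        if ss_tot == 0.0:
            vifs[name] = float("inf")
            continue
        r2 = 1.0 - ss_res / ss_tot
        vifs[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    flagged = [name for name, v in vifs.items() if v > threshold]
    return vifs, flagged


def sample_size(p: float, z_crit: float = 1.960, ci_width: float = 0.20) -> int:
    """Minimum n for estimating an accuracy ``p``: ``4 z^2 p(1-p) / D^2``.

    ``ci_width`` (D) is the total width of the desired confidence interval;
    the result is rounded up.
    """
    if not 0.0 < p < 1.0:
        raise InvalidConfigError(f"p must be in (0, 1), got {p}")
    if ci_width <= 0:
        raise InvalidConfigError(f"ci_width must be positive, got {ci_width}")
    return math.ceil(4.0 * z_crit**2 * p * (1.0 - p) / ci_width**2 - 1e-12)
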