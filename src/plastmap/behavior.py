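"""Learning-curve fitting and dispersion→behavior regression.

Learning rate is the slope b of the logarithmic learning curve
accuracy = a + b·ln(t) fitted per subject over training sessions. Regression
models relate per-subject dispersion changes (VN-within, FPN-within,
VN-FPN-between for one modality) to learning rate or accuracy improvement,
with permutation-based significance, a baseline/pre specificity permutation,
and leave-one-out cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class RegressionResult:
    """OLS summary on z-scored outcome and predictors."""

    betas: np.ndarray          # standardized coefficients (no intercept)
    t_values: np.ndarray
    coef_p: np.ndarray
    f_stat: float
    df_model: int
    df_resid: int
    f_p: float
    r2: float
    adj_r2: float
    n: int
    permutation_p: float | None = None
    loocv_r: float | None = None
    loocv_predictions: np.ndarray | None = None


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0)
    if np.any(sd <= 1e-12):
        raise ValueError("zero-variance variable cannot be standardized")
    return (x - x.mean(axis=0)) / sd


def _f_stat(y: np.ndarray, Q: np.ndarray, p: int) -> tuple[float, float]:
    """Overall F and parametric p from the thin-QR basis Q of [1, X].

    Algebraically identical to the OLS F in :func:`regress`; used by the
    permutation loops where refitting a full model object per draw would
    dominate the runtime.
    """
    n = y.size
    yc = y - y.mean()
    tss = yc @ yc
    proj = Q.T @ y
    ess = proj @ proj - n * y.mean() ** 2  # model SS beyond the intercept
    r2 = ess / tss
    df_resid = n - p - 1
    F = (r2 / p) / ((1 - r2) / df_resid)
    return F, float(stats.f.sf(F, p, df_resid))


def fit_learning_rate(accuracy: np.ndarray, t: np.ndarray | None = None) -> tuple[float, float]:
    """Least-squares fit of accuracy = a + b·ln(t); returns (a, b)."""
    acc = np.asarray(accuracy, dtype=float)
    if t is None:
        t = np.arange(1, acc.size + 1, dtype=float)
    t = np.asarray(t, dtype=float)
    if acc.size < 3 or np.unique(t).size < 3:
        raise ValueError("need >= 3 distinct training sessions to fit a log curve")
    X = np.column_stack([np.ones_like(t), np.log(t)])
    coef, *_ = np.linalg.lstsq(X, acc, rcond=None)
    return float(coef[0]), float(coef[1])


def regress(outcome: np.ndarray, predictors: np.ndarray) -> RegressionResult:
    """Multiple OLS regression on z-scored outcome and predictors."""
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("outcome and predictors must have the same number of subjects")
    if n <= p + 1:
        raise ValueError(f"need more subjects ({n}) than predictors + 1 ({p + 1})")
    Xz = _zscore(X)
    rank = np.linalg.matrix_rank(Xz, tol=1e-8)
    if rank < p:
        corr = np.corrcoef(Xz.T)
        pairs = [(i, j) for i in range(p) for j in range(i + 1, p)
                 if abs(corr[i, j]) > 1 - 1e-6]
        raise ValueError(f"singular design; collinear predictor pairs: {pairs}")
    yz = _zscore(y)
    model = sm.OLS(yz, sm.add_constant(Xz)).fit()
    return RegressionResult(
        betas=np.asarray(model.params[1:]),
        t_values=np.asarray(model.tvalues[1:]),
        coef_p=np.asarray(model.pvalues[1:]),
        f_stat=float(model.fvalue),
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        f_p=float(model.f_pvalue),
        r2=float(model.rsquared),
        adj_r2=float(model.rsquared_adj),
        n=n,
    )


def permutation_regression_p(outcome: np.ndarray, predictors: np.ndarray,
                             n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation p for the overall model F: p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    y = np.asarray(outcome, dtype=float)
    regress(y, predictors)  # validate design (collinearity, sizes)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Q = np.linalg.qr(np.column_stack([np.ones(y.size), X]))[0]
    obs = _f_stat(y, Q, X.shape[1])[0]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _f_stat(rng.permutation(y), Q, X.shape[1])[0] >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)


def loocv(outcome: np.ndarray, predictors: np.ndarray) -> tuple[np.ndarray, float]:
    """Leave-one-out cross-validation of the OLS model.

    Refits the (unstandardized, intercept-included) model per left-out subject
    and predicts it; returns (predictions, predicted-vs-observed correlation).
    Singular folds are skipped with NaN predictions.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n < p + 2:
        raise ValueError("need >= predictors + 2 subjects for leave-one-out")
    Xc = np.column_stack([np.ones(n), X])
    preds = np.full(n, np.nan)
    for i in range(n):
        mask = np.arange(n) != i
        Xi, yi = Xc[mask], y[mask]
        if np.linalg.matrix_rank(Xi, tol=1e-10) < Xi.shape[1]:
            continue  # singular fold: leave prediction NaN
        coef, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
        preds[i] = Xc[i] @ coef
    ok = np.isfinite(preds)
    r = float(np.corrcoef(preds[ok], y[ok])[0, 1]) if ok.sum() >= 3 else float("nan")
    return preds, r


def specificity_permutation(baseline: pd.DataFrame, pre: pd.DataFrame,
                            outcome: np.ndarray, n_iter: int = 1000,
                            seed: int = 0, alpha: float = 0.05) -> tuple[float, float]:
    """Specificity check: do baseline↔pre pseudo-changes predict behavior?

    Per iteration, each subject's baseline and pre-training dispersion rows are
    randomly ordered into a pseudo pre/post pair; the pseudo-change predictors
    are regressed on the outcome and models with parametric F-test p < alpha
    are counted. Returns (significant fraction, complementary p = 1 − fraction),
    matching the k-of-n reporting convention for this null.
    """
    if not baseline.index.equals(pre.index):
        raise ValueError("baseline and pre tables must cover the same subjects in order")
    B = baseline.to_numpy(dtype=float)
    P = pre.to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=float)
    if y.shape[0] != B.shape[0]:
        raise ValueError("outcome length must match the subject count")
    rng = np.random.default_rng(seed)
    n, p = B.shape
    sig = 0
    for _ in range(n_iter):
        flip = rng.integers(0, 2, size=n).astype(bool)
        pseudo = np.where(flip[:, None], B - P, P - B)
        D = np.column_stack([np.ones(n), pseudo])
        if np.linalg.matrix_rank(D, tol=1e-10) < D.shape[1]:
            continue  # degenerate pairing: no testable model
        Q = np.linalg.qr(D)[0]
        if _f_stat(y, Q, p)[1] < alpha:
            sig += 1
    frac = sig / n_iter
    return frac, 1.0 - frac
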