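"""NIPALS partial least squares regression (single response) with
cross-validated choice of the number of latent components.

Predictors and response are autoscaled (centered, unit variance, ddof=1)
before factorization; the stored regression vector maps a raw spectrum to a
raw response prediction.  Cross-validation refits on every training fold,
pools held-out predictions across folds, and picks the first RMSE minimizer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PLSRModel",
    "CVResult",
    "fit_plsr",
    "predict",
    "cross_validate",
    "loo_splits",
    "kfold_splits",
    "default_max_ncomp",
    "PLSRError",
]

_ZERO_VAR_TOL = 1e-12


class PLSRError(ValueError):
    pass


@dataclass
class PLSRModel:
    """Centered/scaled NIPALS factorization and its raw-scale linear form."""

    x_mean: np.ndarray          # [p] over all input channels
    x_sd: np.ndarray            # [p]; 1.0 at dropped (zero-variance) channels
    y_mean: float
    y_sd: float
    weights: np.ndarray         # W [p_kept, ncomp]
    x_loadings: np.ndarray      # P [p_kept, ncomp]
    y_loadings: np.ndarray      # q [ncomp]
    regression_vector: np.ndarray  # [p], raw scale; 0 at dropped channels
    intercept: float
    ncomp: int
    kept: np.ndarray            # [p] bool, channels retained after variance filter

    @property
    def n_channels(self) -> int:
        return self.regression_vector.size

    def to_json(self, path: str | Path, wavelengths_nm: np.ndarray | None = None) -> None:
        payload = {
            "ncomp": int(self.ncomp),
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "regression_vector": self.regression_vector.tolist(),
            "intercept": self.intercept,
            "kept": self.kept.astype(int).tolist(),
        }
        if wavelengths_nm is not None:
            payload["wavelengths_nm"] = np.asarray(wavelengths_nm, float).tolist()
        Path(path).write_text(json.dumps(payload) + "\n")


@dataclass
class CVResult:
    rmse_cv_by_ncomp: np.ndarray  # [max_ncomp], response units
    chosen_ncomp: int             # 1-based; first minimizer (parsimony on ties)
    r2_cv: float
    rmse_cv: float = field(init=False)

    def __post_init__(self) -> None:
        self.rmse_cv_by_ncomp = np.asarray(self.rmse_cv_by_ncomp, float)
        self.rmse_cv = float(self.rmse_cv_by_ncomp[self.chosen_ncomp - 1])


def default_max_ncomp(n: int, p: int | None = None) -> int:
    """Conventional ceiling on latent components: min(10, n-2[, p])."""
    m = min(10, n - 2)
    if p is not None:
        m = min(m, p)
    return max(1, m)


# --------------------------------------------------------------------------
# fitting / prediction
# --------------------------------------------------------------------------


def _autoscale(X: np.ndarray, y: np.ndarray):
    x_mean = X.mean(axis=0)
    x_sd_all = X.std(axis=0, ddof=1)
    kept = x_sd_all > _ZERO_VAR_TOL
    x_sd = np.where(kept, x_sd_all, 1.0)
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=1))
    return x_mean, x_sd, kept, y_mean, y_sd


def _nipals(Xc: np.ndarray, yc: np.ndarray, ncomp: int):
    """PLS1 NIPALS with X- and y-deflation on autoscaled data."""
    n, p = Xc.shape
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    q = np.zeros(ncomp)
    T = np.zeros((n, ncomp))
    X = Xc.copy()
    y = yc.copy()
    for a in range(ncomp):
        w = X.T @ y
        wn = np.linalg.norm(w)
        if wn < 1e-14:
            raise PLSRError(
                f"residual covariance vanished at component {a + 1}; "
                "reduce ncomp"
            )
        w /= wn
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-14:
            raise PLSRError(f"degenerate score at component {a + 1}")
        p_vec = X.T @ t / tt
        q_a = float(y @ t) / tt
        X -= np.outer(t, p_vec)
        y = y - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_vec, q_a, t
    return W, P, q, T


def fit_plsr(X: np.ndarray, y: np.ndarray, ncomp: int) -> PLSRModel:
    """Fit a PLS1 model with ``ncomp`` latent components.

    Zero-variance columns are dropped with a warning before scaling; their
    regression coefficients are zero so the model still accepts full-width
    spectra.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if n < 3:
        raise PLSRError("need at least 3 samples")
    if y.size != n:
        raise PLSRError("X/y length mismatch")
    if y.std(ddof=1) < _ZERO_VAR_TOL:
        raise PLSRError("response is constant")
    if not 1 <= ncomp <= min(n - 1, p):
        raise PLSRError(f"ncomp={ncomp} out of range [1, {min(n - 1, p)}]")

    x_mean, x_sd, kept, y_mean, y_sd = _autoscale(X, y)
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} zero-variance channel(s) before scaling",
            stacklevel=2,
        )
    if kept.sum() < ncomp:
        raise PLSRError("ncomp exceeds number of non-constant channels")

    Xc = (X[:, kept] - x_mean[kept]) / x_sd[kept]
    yc = (y - y_mean) / y_sd
    W, P, q, _T = _nipals(Xc, yc, ncomp)

    b_scaled = W @ np.linalg.solve(P.T @ W, q)
    coef = np.zeros(p)
    coef[kept] = y_sd * b_scaled / x_sd[kept]
    intercept = y_mean - float(x_mean @ coef)

    return PLSRModel(
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
        weights=W, x_loadings=P, y_loadings=q,
        regression_vector=coef, intercept=intercept,
        ncomp=ncomp, kept=kept,
    )


def predict(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Raw-scale prediction through the regression vector plus intercept."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.n_channels:
        raise PLSRError(
            f"channel count {X.shape[1]} does not match model ({model.n_channels})"
        )
    return X @ model.regression_vector + model.intercept


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------


def loo_splits(n: int) -> list[tuple[np.ndarray, np.ndarray]]:
    idx = np.arange(n)
    return [(np.delete(idx, i), np.array([i])) for i in range(n)]


def kfold_splits(n: int, k: int, seed: int | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    if not 2 <= k <= n:
        raise PLSRError("k must be in [2, n]")
    idx = np.arange(n)
    if seed is not None:
        idx = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(idx, k)
    return [(np.setdiff1d(idx, f, assume_unique=False), np.sort(f)) for f in folds]


def _resolve_scheme(scheme, n: int) -> list[tuple[np.ndarray, np.ndarray]]:
    if scheme is None or scheme == "loo":
        return loo_splits(n)
    if isinstance(scheme, str) and scheme.startswith("kfold"):
        k = int(scheme.split(":")[1]) if ":" in scheme else 5
        return kfold_splits(n, k)
    splits = [(np.asarray(tr, int), np.asarray(te, int)) for tr, te in scheme]
    held = np.sort(np.concatenate([te for _, te in splits]))
    if not np.array_equal(held, np.arange(n)):
        raise PLSRError("scheme must partition all samples exactly once")
    return splits


def _cv_pred_batch(Xtr, ytr, Xte, max_ncomp) -> np.ndarray:
    """Held-out predictions for ncomp=1..max_ncomp on a batch of folds.

    Shapes: Xtr [f, ntr, p], ytr [f, ntr], Xte [f, nte, p].
    Per-fold autoscaling, then NIPALS with cumulative test predictions; once
    the residual covariance vanishes in a fold, further components leave its
    predictions unchanged.  Returns [max_ncomp, f, nte] raw-scale predictions.
    """
    f, ntr, p = Xtr.shape
    xm = Xtr.mean(axis=1, keepdims=True)
    X = Xtr - xm
    xs = np.sqrt(np.einsum("fnp,fnp->fp", X, X) / (ntr - 1))[:, None, :]
    xs = np.where(xs > _ZERO_VAR_TOL, xs, 1.0)
    ym = ytr.mean(axis=1, keepdims=True)
    y = ytr - ym
    ys = np.sqrt(np.einsum("fn,fn->f", y, y) / (ntr - 1))[:, None]
    ys = np.where(ys > _ZERO_VAR_TOL, ys, 1.0)

    X = X / xs
    y = y / ys
    Xt = (Xte - xm) / xs

    preds = np.empty((max_ncomp, f, Xte.shape[1]))
    yhat = np.zeros((f, Xte.shape[1]))
    for a in range(max_ncomp):
        w = np.einsum("fnp,fn->fp", X, y)
        wn = np.sqrt(np.einsum("fp,fp->f", w, w))[:, None]
        w = np.where(wn > 1e-14, w / np.where(wn > 0, wn, 1.0), 0.0)
        t = np.einsum("fnp,fp->fn", X, w)
        tt = np.einsum("fn,fn->f", t, t)
        live = tt > 1e-14
        safe = np.where(live, tt, 1.0)
        p_vec = np.einsum("fnp,fn->fp", X, t) / safe[:, None]
        q = np.where(live, np.einsum("fn,fn->f", y, t) / safe, 0.0)
        X -= t[:, :, None] * p_vec[:, None, :]
        y -= q[:, None] * t
        t_te = np.einsum("fsp,fp->fs", Xt, w)
        yhat += q[:, None] * t_te
        Xt -= t_te[:, :, None] * p_vec[:, None, :]
        preds[a] = ym + ys * yhat
    return preds


try:  # optional JIT for the leave-one-out hot loop (GA fitness evaluations)
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in supported envs
    _HAVE_NUMBA = False

if _HAVE_NUMBA:

    @_njit(cache=False)
    def _loo_kernel(X, y, max_ncomp):  # pragma: no cover - exercised via tests
        n, p = X.shape
        ntr = n - 1
        preds = np.empty((max_ncomp, n))
        Xtr = np.empty((ntr, p))
        ytr = np.empty(ntr)
        w = np.empty(p)
        pv = np.empty(p)
        t = np.empty(ntr)
        xt = np.empty(p)
        for i in range(n):
            k = 0
            for j in range(n):
                if j != i:
                    for c in range(p):
                        Xtr[k, c] = X[j, c]
                    ytr[k] = y[j]
                    k += 1
            ym = 0.0
            for j in range(ntr):
                ym += ytr[j]
            ym /= ntr
            ys = 0.0
            for j in range(ntr):
                ytr[j] -= ym
                ys += ytr[j] * ytr[j]
            ys = np.sqrt(ys / (ntr - 1))
            if ys <= 1e-12:
                ys = 1.0
            for j in range(ntr):
                ytr[j] /= ys
            for c in range(p):
                m = 0.0
                for j in range(ntr):
                    m += Xtr[j, c]
                m /= ntr
                v = 0.0
                for j in range(ntr):
                    Xtr[j, c] -= m
                    v += Xtr[j, c] * Xtr[j, c]
                s = np.sqrt(v / (ntr - 1))
                if s <= 1e-12:
                    s = 1.0
                for j in range(ntr):
                    Xtr[j, c] /= s
                xt[c] = (X[i, c] - m) / s
            yhat = 0.0
            for a in range(max_ncomp):
                wn = 0.0
                for c in range(p):
                    acc = 0.0
                    for j in range(ntr):
                        acc += Xtr[j, c] * ytr[j]
                    w[c] = acc
                    wn += acc * acc
                wn = np.sqrt(wn)
                if wn > 1e-14:
                    for c in range(p):
                        w[c] /= wn
                    tt = 0.0
                    for j in range(ntr):
                        acc = 0.0
                        for c in range(p):
                            acc += Xtr[j, c] * w[c]
                        t[j] = acc
                        tt += acc * acc
                    if tt > 1e-14:
                        q = 0.0
                        for j in range(ntr):
                            q += ytr[j] * t[j]
                        q /= tt
                        for c in range(p):
                            acc = 0.0
                            for j in range(ntr):
                                acc += Xtr[j, c] * t[j]
                            pv[c] = acc / tt
                        for j in range(ntr):
                            for c in range(p):
                                Xtr[j, c] -= t[j] * pv[c]
                            ytr[j] -= q * t[j]
                        tte = 0.0
                        for c in range(p):
                            tte += xt[c] * w[c]
                        yhat += q * tte
                        for c in range(p):
                            xt[c] -= tte * pv[c]
                preds[a, i] = ym + ys * yhat
        return preds


def _loo_pred(X: np.ndarray, y: np.ndarray, max_ncomp: int) -> np.ndarray:
    """Pooled held-out predictions [max_ncomp, n] under leave-one-out."""
    if _HAVE_NUMBA:
        return _loo_kernel(np.ascontiguousarray(X), np.ascontiguousarray(y),
                           max_ncomp)
    n = len(y)
    rot = (np.arange(1, n)[None, :] + np.arange(n)[:, None]) % n
    return _cv_pred_batch(X[rot], y[rot], X[:, None, :], max_ncomp)[:, :, 0]


def cross_validate(X: np.ndarray, y: np.ndarray, max_ncomp: int,
                   scheme="loo") -> CVResult:
    """Pooled cross-validation over component counts 1..max_ncomp.

    RMSEcv pools held-out squared errors across all folds; R2cv is
    1 - SSE_pooled/SST(y) at the chosen component count; the chosen count is
    the first RMSEcv minimizer (ties resolved toward fewer components).
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, p = X.shape

    if scheme is None or scheme == "loo":
        # fast path: all n leave-one-out folds batched via an index matrix
        if max_ncomp < 1 or max_ncomp > min(n - 2, p):
            raise PLSRError(
                f"max_ncomp={max_ncomp} infeasible for smallest fold "
                f"(limit {min(n - 2, p)})"
            )
        pooled = _loo_pred(X, y, max_ncomp)
    else:
        splits = _resolve_scheme(scheme, n)
        min_train = min(len(tr) for tr, _ in splits)
        if max_ncomp < 1 or max_ncomp > min(min_train - 1, p):
            raise PLSRError(
                f"max_ncomp={max_ncomp} infeasible for smallest fold "
                f"(limit {min(min_train - 1, p)})"
            )
        pooled = np.empty((max_ncomp, n))
        # batch folds of equal (train, test) size through the vectorized kernel
        by_shape: dict[tuple[int, int], list[int]] = {}
        for i, (tr, te) in enumerate(splits):
            by_shape.setdefault((len(tr), len(te)), []).append(i)
        for (ntr, nte), fold_idx in by_shape.items():
            Xtr = np.stack([X[splits[i][0]] for i in fold_idx])
            ytr = np.stack([y[splits[i][0]] for i in fold_idx])
            Xte = np.stack([X[splits[i][1]] for i in fold_idx])
            preds = _cv_pred_batch(Xtr, ytr, Xte, max_ncomp)
            for j, i in enumerate(fold_idx):
                pooled[:, splits[i][1]] = preds[:, j, :]

    err = pooled - y[None, :]
    rmse = np.sqrt(np.mean(err**2, axis=1))
    chosen = int(np.argmin(rmse)) + 1
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst < _ZERO_VAR_TOL:
        raise PLSRError("response is constant")
    sse = float(np.sum(err[chosen - 1] ** 2))
    return CVResult(rmse_cv_by_ncomp=rmse, chosen_ncomp=chosen, r2_cv=1.0 - sse / sst)
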