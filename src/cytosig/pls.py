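"""Partial least squares regression and discriminant analysis.

Implements mean-centered, unit-variance-scaled PLS (NIPALS), a
prediction-preserving post-hoc orthogonalization that concentrates all
response-predictive covariance on the first latent variable, and variable
importance in projection (VIP) scores.

The model is deliberately deterministic: NIPALS inner loops are initialized
from the response column of maximal variance, and every latent variable is
sign-fixed so that its largest-magnitude weight entry is positive.  Two
fits of the same data therefore produce bit-identical models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FitError

__all__ = [
    "PlsModel",
    "autoscale",
    "encode_response",
    "fit_pls",
    "fit_model",
    "predict",
    "orthogonalize",
    "vip_scores",
]

_EPS = 1e-12


def autoscale(
    X,
    *,
    drop_constant: bool = False,
    ddof: int = 1,
):
    """Mean-center and unit-variance scale each column.

    Parameters
    ----------
    X : array-like or DataFrame, shape (n_samples, n_predictors)
    drop_constant : bool
        If True, zero-variance columns are silently dropped (indices
        reported in the returned mask); otherwise they raise ``FitError``.
    ddof : int
        Degrees-of-freedom correction for the standard deviation
        (``1`` gives the sample SD, the convention used throughout).

    Returns
    -------
    Xs : ndarray — scaled matrix
    mean, sd : ndarray — per-column scaling parameters (for reuse on test data)
    kept : ndarray of int — column indices retained (all, unless dropping)
    """
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
    A = np.asarray(X, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if not np.all(np.isfinite(A)):
        raise FitError("autoscale: input contains non-finite values")
    mean = A.mean(axis=0)
    sd = A.std(axis=0, ddof=ddof)
    const = sd <= _EPS
    if const.any():
        names = (
            [cols[i] for i in np.flatnonzero(const)]
            if cols is not None
            else np.flatnonzero(const).tolist()
        )
        if not drop_constant:
            raise FitError(f"autoscale: constant column(s) {names}")
        kept = np.flatnonzero(~const)
        A, mean, sd = A[:, kept], mean[kept], sd[kept]
    else:
        kept = np.arange(A.shape[1])
    return (A - mean) / sd, mean, sd, kept


@dataclass
class ResponseCoding:
    """How a response was turned into the (scaled) Y matrix fed to NIPALS."""

    kind: str  # "numeric" | "classes"
    classes: Optional[list] = None
    y_mean: np.ndarray = None
    y_sd: np.ndarray = None

    def encode(self, values) -> np.ndarray:
        """Raw response -> unscaled Y matrix (dummy columns for classes)."""
        values = np.asarray(values)
        if self.kind == "numeric":
            return values.astype(float)[:, None]
        Y = np.zeros((len(values), len(self.classes)))
        for j, c in enumerate(self.classes):
            Y[values == c, j] = 1.0
        return Y


def encode_response(values):
    """Build the scaled response matrix for PLSR (numeric) or PLS-DA (labels).

    Class labels become one 1/0 dummy column per class (classes in sorted
    order), then every column is autoscaled; a numeric response becomes a
    single autoscaled column.

    Returns ``(Ys, coding)`` where ``coding`` is a :class:`ResponseCoding`.
    """
    arr = np.asarray(values)
    if arr.dtype.kind in "fiu" and arr.ndim == 1:
        coding = ResponseCoding(kind="numeric")
    else:
        classes = sorted(pd.unique(arr).tolist())
        if len(classes) < 2:
            raise FitError("encode_response: need at least 2 distinct classes")
        coding = ResponseCoding(kind="classes", classes=classes)
    Y = coding.encode(arr)
    if not np.all(np.isfinite(Y)):
        raise FitError("encode_response: non-finite response values")
    Ys, coding.y_mean, coding.y_sd, _ = autoscale(Y)
    return Ys, coding


@dataclass
class PlsModel:
    """A fitted (optionally orthogonalized) PLS model.

    All matrices live on the autoscaled space.  ``coef`` maps scaled X to
    scaled Y; :func:`predict` applies the stored scaling parameters to new
    raw data and back-transforms.
    """

    n_lv: int
    weights: np.ndarray  # p x A ("W*"-style: scores = Xs @ weights)
    x_loadings: np.ndarray  # p x A
    scores: np.ndarray  # n x A (training scores)
    y_loadings: np.ndarray  # r x A
    coef: np.ndarray  # p x r
    x_mean: np.ndarray
    x_sd: np.ndarray
    coding: ResponseCoding
    predictors: list
    orthogonalized: bool = False
    ss_y: np.ndarray = None  # per-LV explained Y sum of squares (scaled space)
    nipals_weights: np.ndarray = None  # raw unit-norm NIPALS weights (p x A)
    tie_log: list = field(default_factory=list)

    @property
    def response_kind(self) -> str:
        return self.coding.kind

    def to_json(self, path) -> None:
        def enc(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        d = asdict(self)
        d["coding"] = {k: enc(v) for k, v in asdict(self.coding).items()}
        with open(path, "w") as fh:
            json.dump({k: enc(v) for k, v in d.items()}, fh, indent=1)


def _nipals(Xs, Ys, n_lv, tol=1e-10, max_iter=500):
    """Standard NIPALS with X- and Y-deflation. Returns W, P, T, Q (raw weights)."""
    X = np.array(Xs, dtype=float, copy=True)
    Y = np.array(Ys, dtype=float, copy=True)
    n, p = X.shape
    r = Y.shape[1]
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    T = np.empty((n, n_lv))
    Q = np.empty((r, n_lv))
    for a in range(n_lv):
        if r == 1:
            w = X.T @ Y[:, 0]
            nw = np.linalg.norm(w)
            if nw < _EPS:
                raise FitError(
                    f"NIPALS: X/Y residual exhausted at component {a + 1}; "
                    f"reduce the number of latent variables"
                )
            w /= nw
            t = X @ w
        else:
            u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
            t_old = None
            for _ in range(max_iter):
                w = X.T @ u
                nw = np.linalg.norm(w)
                if nw < _EPS:
                    raise FitError(
                        f"NIPALS: X residual exhausted at component {a + 1}"
                    )
                w /= nw
                t = X @ w
                tt = t @ t
                if tt < _EPS:
                    raise FitError(f"NIPALS: degenerate score at component {a + 1}")
                q = Y.T @ t / tt
                nq = np.linalg.norm(q)
                if nq < _EPS:
                    raise FitError(
                        f"NIPALS: Y residual exhausted at component {a + 1}"
                    )
                u = Y @ q / (q @ q)
                if t_old is not None and np.linalg.norm(t - t_old) <= tol * (
                    np.linalg.norm(t) + _EPS
                ):
                    break
                t_old = t
            else:
                raise FitError(
                    f"NIPALS inner loop failed to converge in {max_iter} "
                    f"iterations at component {a + 1} "
                    f"(last delta {np.linalg.norm(t - t_old):.3e})"
                )
        # deterministic sign: largest-|w| entry positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w, t = -w, -t
        tt = t @ t
        if tt < _EPS:
            raise FitError(f"NIPALS: degenerate score at component {a + 1}")
        pv = X.T @ t / tt
        qv = Y.T @ t / tt
        X -= np.outer(t, pv)
        Y -= np.outer(t, qv)
        W[:, a], P[:, a], T[:, a], Q[:, a] = w, pv, t, qv
    return W, P, T, Q


def fit_pls(Xs, Ys, n_lv, *, coding=None, x_mean=None, x_sd=None,
            predictors=None, tol=1e-10, max_iter=500) -> PlsModel:
    """Fit a PLS model on pre-autoscaled predictor and response matrices.

    ``n_lv`` must not exceed ``min(n_samples - 1, n_predictors)``.  The
    returned model stores score-generating weights ``W* = W (PᵀW)⁻¹`` so
    that ``scores = Xs @ weights`` holds exactly, the regression
    coefficients ``B = W* Qᵀ``, and the per-component explained response
    sum of squares used by VIP.
    """
    Xs = np.asarray(Xs, dtype=float)
    Ys = np.asarray(Ys, dtype=float)
    if Ys.ndim == 1:
        Ys = Ys[:, None]
    n, p = Xs.shape
    if n_lv < 1 or n_lv > min(n - 1, p):
        raise FitError(
            f"n_lv={n_lv} outside valid range 1..{min(n - 1, p)} "
            f"for n={n}, p={p}"
        )
    W, P, T, Q = _nipals(Xs, Ys, n_lv, tol=tol, max_iter=max_iter)
    # W* maps Xs directly to scores (Manne / de Jong identity)
    Wstar = W @ np.linalg.inv(P.T @ W)
    B = Wstar @ Q.T
    ss_y = (T * T).sum(axis=0) * (Q * Q).sum(axis=0)
    if coding is None:
        coding = ResponseCoding(
            kind="numeric",
            y_mean=np.zeros(Ys.shape[1]),
            y_sd=np.ones(Ys.shape[1]),
        )
    return PlsModel(
        n_lv=n_lv,
        weights=Wstar,
        x_loadings=P,
        scores=T,
        y_loadings=Q,
        coef=B,
        x_mean=np.zeros(p) if x_mean is None else np.asarray(x_mean, float),
        x_sd=np.ones(p) if x_sd is None else np.asarray(x_sd, float),
        coding=coding,
        predictors=list(predictors) if predictors is not None
        else list(range(p)),
        nipals_weights=W,
    )


def fit_model(X, response, n_lv, **kw) -> PlsModel:
    """Convenience wrapper: autoscale ``X``, encode ``response``, fit.

    ``X`` may be a DataFrame (column names become predictor names) or an
    array.  ``response`` is numeric (PLSR) or labels (PLS-DA).
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xs, mean, sd, kept = autoscale(X)
    if names is not None:
        names = [names[i] for i in kept]
    Ys, coding = encode_response(response)
    return fit_pls(
        Xs, Ys, n_lv, coding=coding, x_mean=mean, x_sd=sd,
        predictors=names, **kw,
    )


def predict(model: PlsModel, Xnew, *, return_labels=None):
    """Predict the response for new samples.

    ``Xnew`` is raw (unscaled) data with the model's predictor columns; it
    is scaled with the *training* parameters.  For numeric models returns
    the back-transformed prediction vector.  For class models returns
    ``(scores_per_class, labels)``: the dummy-space predictions and the
    argmax class, ties broken by class order (logged on the model).
    """
    if isinstance(Xnew, pd.DataFrame):
        missing = [c for c in model.predictors if c not in Xnew.columns]
        if missing:
            raise FitError(f"predict: missing predictor columns {missing}")
        Xnew = Xnew[model.predictors].to_numpy(dtype=float)
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != len(model.x_mean):
        raise FitError(
            f"predict: expected {len(model.x_mean)} predictors, "
            f"got {Xnew.shape[1]}"
        )
    Xs = (Xnew - model.x_mean) / model.x_sd
    Yhat_s = Xs @ model.coef
    Yhat = Yhat_s * model.coding.y_sd + model.coding.y_mean
    if model.coding.kind == "numeric":
        return Yhat[:, 0]
    ties = np.sum(Yhat == Yhat.max(axis=1, keepdims=True), axis=1) > 1
    if ties.any():
        model.tie_log.append(
            {"n_ties": int(ties.sum()), "rule": "first class in sorted order"}
        )
    idx = np.argmax(Yhat, axis=1)
    labels = np.asarray(model.coding.classes, dtype=object)[idx]
    return Yhat, labels


def fitted_values(model: PlsModel):
    """Training-set predictions (same back-transform as :func:`predict`)."""
    Yhat_s = model.scores @ model.y_loadings.T
    return Yhat_s * model.coding.y_sd + model.coding.y_mean


def orthogonalize(model: PlsModel, *, positive_class=None) -> PlsModel:
    """Rotate a fitted model so LV1 carries all response-predictive covariance.

    This is a target-projection style post-rotation: the score subspace and
    therefore the predictions are untouched; only the basis changes.  The
    first rotated score direction is aligned with the fitted response
    (dominant left singular direction of Ŷ within the score space), so the
    remaining components' scores are uncorrelated with the prediction.

    LV1 orientation is fixed so the response pole is positive: for numeric
    responses, larger response values score positive; for class models, the
    ``positive_class`` (default: first class in sorted order) scores
    positive.  Rotated scores are returned orthonormal — their scale is
    presentational only.
    """
    T = model.scores
    norms = np.linalg.norm(T, axis=0)
    U = T / norms  # orthonormal basis of the score space
    Yhat_s = T @ model.y_loadings.T
    C = U.T @ Yhat_s  # A x r coordinates of the fitted response
    if model.n_lv == 1:
        G = np.ones((1, 1))
    else:
        G, _, _ = np.linalg.svd(C, full_matrices=True)
    T_rot = U @ G
    # orientation of LV1: positive pole = larger response / positive class
    if model.coding.kind == "numeric":
        ref = Yhat_s[:, 0]
    else:
        classes = model.coding.classes
        pc = positive_class if positive_class is not None else classes[0]
        if pc not in classes:
            raise FitError(f"positive_class {pc!r} not among {classes}")
        ref = Yhat_s[:, classes.index(pc)]
    if T_rot[:, 0] @ ref < 0:
        T_rot[:, 0] *= -1
        G[:, 0] *= -1
    # recompute loadings/weights in the rotated basis; predictions (coef)
    # are deliberately untouched
    P_rot = model.x_loadings @ np.diag(norms) @ G  # Xsᵀ T_rot since TᵀT diag
    # note Xsᵀ t̃_a = P D G (columns), valid because P = Xsᵀ T diag(1/tᵀt)
    # with TᵀT = D²:  Xsᵀ T = P D².  Hence Xsᵀ T_rot = P D² D⁻¹ G = P D G.
    W_rot = model.weights @ np.diag(1.0 / norms) @ G
    # Y-loadings against orthonormal rotated scores: q̃ = Ŷᵀ t̃
    Q_rot = Yhat_s.T @ T_rot
    ss_y = (Q_rot * Q_rot).sum(axis=0)  # t̃ᵀt̃ = 1
    return PlsModel(
        n_lv=model.n_lv,
        weights=W_rot,
        x_loadings=P_rot,
        scores=T_rot,
        y_loadings=Q_rot,
        coef=model.coef,
        x_mean=model.x_mean,
        x_sd=model.x_sd,
        coding=model.coding,
        predictors=model.predictors,
        orthogonalized=True,
        ss_y=ss_y,
        nipals_weights=W_rot / np.linalg.norm(W_rot, axis=0),
    )


def vip_scores(model: PlsModel) -> np.ndarray:
    """Variable importance in projection over the model's latent variables.

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja / ‖w_a‖)² / Σ_a SSY_a ), where SSY_a
    is the response sum of squares explained by component a.  By
    construction mean(VIP²) = 1 over predictors.
    """
    W = model.nipals_weights if model.nipals_weights is not None else model.weights
    Wn = W / np.linalg.norm(W, axis=0)
    if model.ss_y is None:
        ss_y = (model.scores ** 2).sum(axis=0) * (model.y_loadings ** 2).sum(axis=0)
    else:
        ss_y = model.ss_y
    p = W.shape[0]
    num = (Wn ** 2) @ ss_y
    return np.sqrt(p * num / ss_y.sum())


def loadings_table(model: PlsModel, vip: Optional[np.ndarray] = None) -> pd.DataFrame:
    """LV1 loadings (and VIP if given) as a tidy table for export/plotting."""
    df = pd.DataFrame(
        {
            "predictor": model.predictors,
            "lv1_loading": model.x_loadings[:, 0],
        }
    )
    if vip is not None:
        df["vip"] = vip
    return df
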