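"""Multiclass PLS discriminant analysis with Monte-Carlo cross-validated
complexity selection.

Class membership is one-hot encoded into an N x B response matrix Y and a
PLS2 regression of Y on the mean-centered spectra is fitted by NIPALS with
deflation.  A new sample is assigned to the class whose predicted response
is nearest to 1.  The number of latent variables is chosen by Monte-Carlo
cross-validation (MCCV): many random splits leave out a substantial
fraction of the training samples, RMSEMCCV(k) pools the hold-out errors at
each complexity k, and an F-test picks the smallest k whose RMSEMCCV is not
significantly higher than the minimum — complexity must be earned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io import SpectraSet


@dataclass
class ClassEncoding:
    classes: list
    Y: np.ndarray            # N x B one-hot

    def __post_init__(self):
        if not np.all(self.Y.sum(axis=1) == 1):
            raise ValueError("every row of Y must contain exactly one 1")


def encode_onehot(labels: Sequence, classes: Sequence) -> ClassEncoding:
    """One-hot encode labels against an ordered class list."""
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for r, lab in enumerate(labels):
        if lab not in index:
            raise ValueError(f"label {lab!r} not among classes {classes!r}")
        Y[r, index[lab]] = 1.0
    return ClassEncoding(classes, Y)


@dataclass
class MCCVResult:
    """RMSEMCCV trace over model complexity, plus the selection outcome."""

    rmse: np.ndarray         # RMSEMCCV(k), k = 1..k_max
    n_pred: int              # pooled hold-out predictions per k
    leave_out_fraction: float
    n_splits: int
    seed: int
    f_alpha: float = 0.25
    selected_k: Optional[int] = None


@dataclass
class PLSDAModel:
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray      # W, p x k
    x_loadings: np.ndarray   # P, p x k
    y_loadings: np.ndarray   # Q, B x k
    rotation: np.ndarray     # R = W (P'W)^-1, p x k; scores of new X = Xc R
    coefficients: np.ndarray  # p x B at the model's k
    k: int
    classes: list = field(default_factory=list)
    mccv: Optional[MCCVResult] = None

    def to_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(), "y_mean": self.y_mean.tolist(),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "rotation": self.rotation.tolist(),
            "coefficients": self.coefficients.tolist(),
            "k": self.k, "classes": list(self.classes),
            "mccv": None if self.mccv is None else {
                "rmse": self.mccv.rmse.tolist(), "n_pred": self.mccv.n_pred,
                "leave_out_fraction": self.mccv.leave_out_fraction,
                "n_splits": self.mccv.n_splits, "seed": self.mccv.seed,
                "f_alpha": self.mccv.f_alpha,
                "selected_k": self.mccv.selected_k,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSDAModel":
        mccv = None
        if d.get("mccv") is not None:
            m = d["mccv"]
            mccv = MCCVResult(np.array(m["rmse"]), m["n_pred"],
                              m["leave_out_fraction"], m["n_splits"],
                              m["seed"], m["f_alpha"], m["selected_k"])
        return cls(np.array(d["x_mean"]), np.array(d["y_mean"]),
                   np.array(d["weights"]), np.array(d["x_loadings"]),
                   np.array(d["y_loadings"]), np.array(d["rotation"]),
                   np.array(d["coefficients"]), d["k"], d["classes"], mccv)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PLSDAModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_pls2(X: np.ndarray, Y: np.ndarray, k: int,
             classes: Optional[Sequence] = None,
             max_iter: int = 1000, tol: float = 1e-12) -> PLSDAModel:
    """NIPALS PLS2 with deflation on mean-centered X and Y.

    Component extraction stops early (with a warning) if the X residual is
    numerically exhausted.  A Y column that is constant (a class absent
    from a resample) is legitimate and simply attracts zero loading.
    """
    X = np.asarray(X, float)
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y row counts differ")
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} outside [1, min(N-1, p)]={min(n - 1, p)}")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    E = X - x_mean
    F = Y - y_mean
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    Q = np.zeros((Y.shape[1], k))
    actual = k
    for a in range(k):
        if np.linalg.norm(E) < 1e-12:
            warnings.warn(f"X residual exhausted after {a} components; "
                          f"truncating k from {k} to {a}")
            actual = a
            break
        u = F[:, int(np.argmax(F.var(axis=0)))]
        if np.linalg.norm(u) < 1e-12:       # Y residual exhausted: take the
            u = E[:, int(np.argmax(E.var(axis=0)))]  # dominant X direction
        w_old = None
        for _ in range(max_iter):
            w = E.T @ u
            w /= np.linalg.norm(w)
            t = E @ w
            tt = t @ t
            q = F.T @ t / tt
            qq = q @ q
            u = F @ q / qq if qq > 0 else t
            if w_old is not None and np.linalg.norm(w - w_old) <= tol:
                break
            w_old = w
        p_vec = E.T @ t / tt
        E = E - np.outer(t, p_vec)
        F = F - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a] = w, p_vec, q
    W, P, Q = W[:, :actual], P[:, :actual], Q[:, :actual]
    R = W @ np.linalg.pinv(P.T @ W)
    coefficients = R @ Q.T
    return PLSDAModel(x_mean=x_mean, y_mean=y_mean, weights=W, x_loadings=P,
                      y_loadings=Q, rotation=R, coefficients=coefficients,
                      k=actual, classes=list(classes) if classes else [])


def predict_response(model: PLSDAModel, X: np.ndarray,
                     k: Optional[int] = None) -> np.ndarray:
    """Predicted responses (X - x_mean) B + y_mean, optionally truncated to
    the first ``k`` latent variables."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != len(model.x_mean):
        raise ValueError(f"X has {X.shape[1]} columns, model expects "
                         f"{len(model.x_mean)}")
    Xc = X - model.x_mean
    if k is None or k == model.k:
        return Xc @ model.coefficients + model.y_mean
    if not 1 <= k <= model.k:
        raise ValueError(f"k={k} outside [1, {model.k}]")
    T = Xc @ model.rotation[:, :k]
    return T @ model.y_loadings[:, :k].T + model.y_mean


def predict_class(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    """Assign each sample to the class whose response is nearest to 1.

    The rule is argmin_j |yhat_j - 1| (not argmax yhat_j; the two differ
    when responses overshoot 1).  Exact ties go to the lowest class index,
    with a warning.
    """
    if not model.classes:
        raise ValueError("model carries no class names")
    resp = predict_response(model, X)
    d = np.abs(resp - 1.0)
    idx = np.argmin(d, axis=1)
    ties = (d == d.min(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        warnings.warn(f"{int(ties.sum())} tie(s) in nearest-to-1 class "
                      f"assignment; lowest class index used")
    return np.array([model.classes[i] for i in idx], dtype=object)


def mccv_rmse(X: np.ndarray, Y: np.ndarray, k_max: int,
              leave_out_fraction: float = 0.3, n_splits: int = 100,
              seed: int = 0, stratify: bool = True) -> MCCVResult:
    """RMSEMCCV(k) for k = 1..k_max by Monte-Carlo cross-validation.

    Each split leaves out ``leave_out_fraction`` of the rows (stratified by
    class by default, so no class vanishes from a kept set), fits PLS2 with
    k_max components on the rest, and predicts the left-out rows at every
    intermediate complexity.  Squared errors are pooled over all response
    entries and splits.
    """
    X = np.asarray(X, float)
    Y = np.atleast_2d(np.asarray(Y, float))
    n, p = X.shape
    B = Y.shape[1]
    if not 0 < leave_out_fraction <= 0.5:
        raise ValueError("leave_out_fraction must lie in (0, 0.5]")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    rng = np.random.default_rng(seed)
    groups = ([np.flatnonzero(Y[:, b] == 1) for b in range(B)]
              if stratify else [np.arange(n)])
    out_sets = []
    for g in groups:
        n_out = int(round(leave_out_fraction * len(g)))
        n_out = max(1, min(n_out, len(g) - 1)) if len(g) > 1 else 0
        out_sets.append((g, n_out))
    n_out_total = sum(n_out for _, n_out in out_sets)
    if n - n_out_total < k_max + 2:
        raise ValueError(f"kept sets of {n - n_out_total} samples are too "
                         f"small for k_max={k_max}; lower k_max or the "
                         f"leave-out fraction")
    sq = np.zeros(k_max)
    for _ in range(n_splits):
        out_idx = np.concatenate([rng.choice(g, size=n_out, replace=False)
                                  for g, n_out in out_sets if n_out > 0])
        kept = np.setdiff1d(np.arange(n), out_idx)
        model = fit_pls2(X[kept], Y[kept], k_max)
        Xc = X[out_idx] - model.x_mean
        T = Xc @ model.rotation
        cum = np.zeros((len(out_idx), B))
        for k in range(model.k):
            cum += np.outer(T[:, k], model.y_loadings[:, k])
            err = Y[out_idx] - (cum + model.y_mean)
            sq[k] += np.sum(err ** 2)
        for k in range(model.k, k_max):     # early-truncated fit: flat tail
            err = Y[out_idx] - (cum + model.y_mean)
            sq[k] += np.sum(err ** 2)
    n_pred = n_splits * n_out_total * B
    rmse = np.sqrt(sq / n_pred)
    return MCCVResult(rmse=rmse, n_pred=n_pred,
                      leave_out_fraction=leave_out_fraction,
                      n_splits=n_splits, seed=seed)


def select_k_ftest(mccv: MCCVResult) -> int:
    """Smallest complexity whose RMSEMCCV is not significantly above the
    minimum, by an F-test on the squared RMSE ratio.

    F(k) = (rmse(k)/rmse(k*))^2 is compared against the (1 - f_alpha)
    quantile of F(n_pred, n_pred); the first k passing wins.  Sets and
    returns ``mccv.selected_k``.
    """
    if not 0 < mccv.f_alpha <= 0.5:
        raise ValueError("f_alpha must lie in (0, 0.5]")
    rmse = np.asarray(mccv.rmse, float)
    k_star = int(np.argmin(rmse))
    if rmse[k_star] == 0.0:
        mccv.selected_k = k_star + 1
        return mccv.selected_k
    crit = stats.f.ppf(1 - mccv.f_alpha, mccv.n_pred, mccv.n_pred)
    F = (rmse / rmse[k_star]) ** 2
    passing = np.flatnonzero(F <= crit)
    mccv.selected_k = int(passing[0]) + 1
    return mccv.selected_k


def train_plsda(train: SpectraSet, k_max: int = 15,
                leave_out_fraction: float = 0.3, n_splits: int = 100,
                f_alpha: float = 0.25, seed: int = 0,
                stratify: bool = True) -> PLSDAModel:
    """Full training path: encode, MCCV complexity selection, final fit.

    The class order is the sorted unique label set; the fitted model keeps
    the whole MCCV trace for reporting.
    """
    classes = sorted(set(train.labels.tolist()))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes, got {classes!r}")
    enc = encode_onehot(train.labels, classes)
    X = train.absorbance
    k_max = min(k_max, X.shape[0] - 1, X.shape[1])
    if k_max == 1:
        mccv = MCCVResult(rmse=np.zeros(1), n_pred=0,
                          leave_out_fraction=leave_out_fraction,
                          n_splits=n_splits, seed=seed, f_alpha=f_alpha,
                          selected_k=1)
        mccv.rmse = np.array([np.nan])
        model = fit_pls2(X, enc.Y, 1, classes=classes)
        model.mccv = mccv
        return model
    mccv = mccv_rmse(X, enc.Y, k_max, leave_out_fraction=leave_out_fraction,
                     n_splits=n_splits, seed=seed, stratify=stratify)
    mccv.f_alpha = f_alpha
    k = select_k_ftest(mccv)
    model = fit_pls2(X, enc.Y, k, classes=classes)
    model.mccv = mccv
    return model
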