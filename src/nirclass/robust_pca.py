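"""Robust principal component analysis with score/orthogonal-distance
outlier diagnosis.

The fitting recipe follows the projection-pursuit + MCD family of robust PCA
estimators for "large p, small n" spectral data:

1. project the data onto its affine span (thin SVD);
2. rank samples by Stahel-Donoho outlyingness over directions through pairs
   of data points and keep the ``h = ceil(alpha * N)`` least outlying;
3. classical PCA of that trimmed subset gives an initial k-dimensional
   subspace;
4. MCD-style concentration (C-steps) of the scores in that subspace,
   consistency correction, and one 0.975 reweighting whose reweighted set
   is re-estimated in full dimension to give the robust center, loadings
   and eigenvalues.

Each sample is then placed in the score-distance / orthogonal-distance plane
and assigned to one of four groups: regular points, good leverage points
(large SD, small OD), orthogonal outliers (small SD, large OD) and bad
leverage points (large SD and OD).  Only the last two groups are excluded;
good leverage points extend the class model and are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .io import SpectraSet

GROUPS = ("regular", "good_leverage", "orthogonal_outlier", "bad_leverage")

_MAD_TO_SD = 1.4826  # consistency factor of the MAD at the normal


class DegenerateDataError(ValueError):
    """The data carry no usable variation for a robust fit."""


@dataclass
class RPCASettings:
    """Knobs of the per-class outlier screen.

    significance is the tail probability of both distance cutoffs (0.05 ->
    0.95 quantiles); alpha_coverage the fraction of points the trimmed
    estimator covers; k fixes the subspace dimension, or is selected by
    cross-validated PRESS when None.
    """

    significance: float = 0.05
    alpha_coverage: float = 0.75
    k: Optional[int] = None
    k_max: int = 15
    press_folds: int = 5
    press_tol: float = 0.05
    n_directions: int = 250
    seed: int = 0


@dataclass
class RobustPCAModel:
    center: np.ndarray        # p-vector, robust location
    loadings: np.ndarray      # p x k, orthonormal columns
    eigenvalues: np.ndarray   # k robust variances, descending
    k: int
    alpha_coverage: float
    significance: float
    support: Optional[np.ndarray] = None   # samples in the reweighted fit

    def __post_init__(self):
        G = self.loadings.T @ self.loadings
        if not np.allclose(G, np.eye(self.k), atol=1e-8):
            raise ValueError("loadings are not orthonormal")
        if np.any(self.eigenvalues <= 0) or np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be positive and non-increasing")


@dataclass
class RobustPCADiagnosis:
    model: RobustPCAModel
    sample_ids: np.ndarray
    sd: np.ndarray
    od: np.ndarray
    sd_cutoff: float
    od_cutoff: float
    group: np.ndarray          # entries from GROUPS
    excluded: np.ndarray       # bool; the two outlier groups

    @property
    def excluded_ids(self) -> np.ndarray:
        return self.sample_ids[self.excluded]


def outlyingness(X: np.ndarray, n_directions: int = 250,
                 seed: int = 0) -> np.ndarray:
    """Stahel-Donoho outlyingness over directions through pairs of points.

    For each sampled direction v the data are projected and robustly
    standardised with median and MAD; a sample's outlyingness is its largest
    standardised deviation over directions.  Deterministic under a fixed
    seed; all point-pair directions are used when there are at most
    ``n_directions`` of them.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if len(pairs) > n_directions:
        idx = rng.choice(len(pairs), size=n_directions, replace=False)
        pairs = [pairs[i] for i in idx]
    dirs = []
    for i, j in pairs:
        v = X[i] - X[j]
        nv = np.linalg.norm(v)
        if nv > 0:
            dirs.append(v / nv)
    if not dirs:
        raise DegenerateDataError("all points identical; outlyingness undefined")
    V = np.array(dirs)                      # d x p
    proj = X @ V.T                          # n x d
    med = np.median(proj, axis=0)
    dev = np.abs(proj - med)
    mad = np.median(dev, axis=0) * _MAD_TO_SD
    out = np.zeros(n)
    ok = mad > 0
    if ok.any():
        out = np.max(dev[:, ok] / mad[ok], axis=1)
    if (~ok).any():
        # a direction where >half the points coincide: any deviating point
        # is infinitely outlying along it
        hit = dev[:, ~ok] > 0
        out = np.where(hit.any(axis=1), np.inf, out)
    return out


def _mcd_consistency(alpha: float, k: int) -> float:
    """Consistency factor for a covariance computed from the most
    concentrated ``alpha`` fraction of Gaussian data."""
    q = stats.chi2.ppf(alpha, k)
    return alpha / stats.chi2.cdf(q, k + 2)


def fit_robpca(X: np.ndarray, k: int, alpha_coverage: float = 0.75,
               significance: float = 0.05, seed: int = 0,
               n_directions: int = 250) -> RobustPCAModel:
    """Fit the robust k-dimensional PCA model described in the module docs."""
    X = np.asarray(X, float)
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} outside [1, min(N-1, p)]={min(n - 1, p)}")
    if not 0.5 <= alpha_coverage <= 1.0:
        raise ValueError("alpha_coverage must lie in [0.5, 1]")
    h = int(np.ceil(alpha_coverage * n))
    if h < k + 1:
        raise ValueError(f"coverage h={h} too small for k={k}")

    # (1) affine-span projection
    mean0 = X.mean(axis=0)
    Xc = X - mean0
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(n, p) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    r = int(np.sum(s > tol))
    if r == 0:
        raise DegenerateDataError("all points identical")
    if r < k:
        raise ValueError(f"data rank {r} < requested k={k}")
    B = Vt[:r]                              # r x p span basis
    Z = Xc @ B.T                            # n x r

    # (2) trim by outlyingness
    w = outlyingness(Z, n_directions=n_directions, seed=seed)
    keep = np.argsort(w, kind="stable")[:h]

    # (3) classical PCA of the trimmed subset
    mu1 = Z[keep].mean(axis=0)
    C1 = np.cov(Z[keep].T, ddof=1).reshape(r, r)
    evals, evecs = np.linalg.eigh(C1)
    order = np.argsort(evals)[::-1]
    V1 = evecs[:, order[:k]]                # r x k

    # (4) MCD-style covariance in the k-subspace: concentrate the h-subset
    # on the Mahalanobis-central ellipsoid (C-steps), correct for the
    # trimming, then one 0.975 reweighting step
    T = (Z - mu1) @ V1                      # n x k scores
    idx = np.sort(keep)
    for _ in range(50):
        muh = T[idx].mean(axis=0)
        Ch = np.cov(T[idx].T, ddof=1).reshape(k, k)
        d2 = _mahalanobis_sq(T - muh, Ch)
        new_idx = np.sort(np.argsort(d2, kind="stable")[:h])
        if np.array_equal(new_idx, idx):
            break
        idx = new_idx
    Ch = Ch * _mcd_consistency(h / n, k)
    d2 = _mahalanobis_sq(T - muh, Ch)
    wts = d2 <= stats.chi2.ppf(0.975, k)
    # points far off the initial subspace (orthogonal outliers) must not
    # enter the reweighted estimate either, or their direction would be
    # absorbed into the model
    resid1 = (Z - mu1) - T @ V1.T
    od1 = np.linalg.norm(resid1, axis=1)
    od1_cut = max(_wilson_hilferty_cutoff(od1, 0.025),
                  2.0 * float(np.median(od1)))
    wts &= od1 <= od1_cut
    if wts.sum() < k + 1:                   # safeguard: keep the h-subset
        wts = np.zeros(n, bool)
        wts[idx] = True

    # re-estimate center and subspace from the reweighted set in full
    # dimension, so the residual (orthogonal-distance) space is fitted to
    # every non-outlying point, not just the trimmed core
    muw = Z[wts].mean(axis=0)
    Cw = np.cov(Z[wts].T, ddof=1).reshape(r, r)
    lam_all, E = np.linalg.eigh(Cw)
    order = np.argsort(lam_all)[::-1][:k]
    lam = lam_all[order] * _mcd_consistency(0.975, k)
    if lam[-1] <= 0:
        raise DegenerateDataError("robust covariance is singular in the "
                                  "requested subspace; reduce k")

    loadings = B.T @ E[:, order]            # p x k, orthonormal
    center = mean0 + muw @ B
    return RobustPCAModel(center=center, loadings=loadings, eigenvalues=lam,
                          k=k, alpha_coverage=alpha_coverage,
                          significance=significance, support=wts)


def _wilson_hilferty_cutoff(od: np.ndarray, tail: float) -> float:
    """Upper-tail cutoff for orthogonal distances: od^(2/3) is treated as
    normal (Wilson-Hilferty) with robust median/MAD location and scale."""
    od23 = np.asarray(od, float) ** (2.0 / 3.0)
    m = float(np.median(od23))
    s = float(np.median(np.abs(od23 - m)) * _MAD_TO_SD)
    if s == 0.0:
        return float(m ** 1.5)
    return float((m + s * stats.norm.ppf(1 - tail)) ** 1.5)


def _mahalanobis_sq(D: np.ndarray, C: np.ndarray) -> np.ndarray:
    sol = np.linalg.solve(C, D.T)
    return np.einsum("ij,ji->i", D, sol)


def score_distance(model: RobustPCAModel, X: np.ndarray) -> np.ndarray:
    """SD_i = sqrt(sum_j t_ij^2 / lambda_j) with t = (x - center) @ loadings."""
    X = _check_p(model, X)
    T = (X - model.center) @ model.loadings
    return np.sqrt(np.sum(T ** 2 / model.eigenvalues, axis=1))


def orthogonal_distance(model: RobustPCAModel, X: np.ndarray) -> np.ndarray:
    """OD_i = || (x_i - center) - proj onto the loading subspace ||_2."""
    X = _check_p(model, X)
    D = X - model.center
    resid = D - (D @ model.loadings) @ model.loadings.T
    return np.linalg.norm(resid, axis=1)


def _check_p(model: RobustPCAModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != len(model.center):
        raise ValueError(f"X has {X.shape[1]} columns, model expects "
                         f"{len(model.center)}")
    return X


def distance_cutoffs(model: RobustPCAModel,
                     od: np.ndarray) -> tuple[float, float]:
    """Cutoffs at the model's significance level.

    The score-distance cutoff is the sqrt of the chi-square(k) quantile.
    The orthogonal-distance cutoff uses the Wilson-Hilferty normal
    approximation of od^(2/3), with median/MAD location and scale so the
    cutoff itself resists outliers.
    """
    sig = model.significance
    sd_cut = float(np.sqrt(stats.chi2.ppf(1 - sig, model.k)))
    od = np.asarray(od, float)
    od23 = od ** (2.0 / 3.0)
    s = float(np.median(np.abs(od23 - np.median(od23))) * _MAD_TO_SD)
    if s == 0.0:
        warnings.warn("orthogonal distances have zero robust scale; "
                      "OD cutoff degenerates to their common value")
    return sd_cut, _wilson_hilferty_cutoff(od, sig)


def classify_samples(sd: np.ndarray, od: np.ndarray, sd_cutoff: float,
                     od_cutoff: float) -> np.ndarray:
    """Four-way diagnosis; 'large' means strictly greater than the cutoff,
    so a distance exactly on its cutoff counts as small."""
    sd = np.asarray(sd, float)
    od = np.asarray(od, float)
    if sd.shape != od.shape:
        raise ValueError(f"sd and od lengths differ: {sd.shape} vs {od.shape}")
    big_sd = sd > sd_cutoff
    big_od = od > od_cutoff
    group = np.where(big_sd & big_od, "bad_leverage",
             np.where(big_sd, "good_leverage",
              np.where(big_od, "orthogonal_outlier", "regular")))
    return group.astype(object)


def select_k_by_press(X: np.ndarray, k_max: int, folds: int = 5,
                      seed: int = 0, tol: float = 0.05, trim: float = 0.9,
                      alpha_coverage: float = 0.75,
                      n_directions: int = 250) -> int:
    """Choose the subspace dimension by cross-validated robust PRESS.

    Each fold is left out in turn; a robust PCA fitted on the remainder
    reconstructs the held-out spectra with 1..k_max components.  PRESS(k)
    sums the smallest ``trim`` fraction of squared reconstruction residuals
    (a robustness trim against held-out outliers).  Returns the smallest k
    whose PRESS is within ``tol`` (relative) of the minimum — extra
    components must earn a significant drop.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    k_max = min(k_max, n - int(np.ceil(n / folds)) - 1, p)
    if k_max < 1:
        raise ValueError("too few samples for cross-validated selection")
    if k_max == 1:
        return 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, int)
    fold_of[perm] = np.arange(n) % folds

    resid2 = np.empty((n, k_max))           # per-sample residuals per k
    for f in range(folds):
        test = fold_of == f
        model = fit_robpca(X[~test], k_max,
                           alpha_coverage=alpha_coverage,
                           seed=seed + 1 + f, n_directions=n_directions)
        D = X[test] - model.center
        T = D @ model.loadings
        total = np.sum(D ** 2, axis=1)
        cum = np.cumsum(T ** 2, axis=1)
        resid2[test] = np.maximum(total[:, None] - cum, 0.0)

    m = int(np.ceil(trim * n))
    press = np.sort(resid2, axis=0)[:m].sum(axis=0)
    # normalise by the residual dimension: even a direction-less subspace
    # removes ~k/p of held-out noise energy, so raw PRESS drifts down
    # linearly with k on pure noise
    press = press / (p - np.arange(1, k_max + 1))
    best = float(press.min())
    ks = np.flatnonzero(press < (1 + tol) * best)
    return int(ks[0] + 1)


def diagnose_class(data: SpectraSet, class_label: str,
                   settings: RPCASettings = RPCASettings()) -> RobustPCADiagnosis:
    """Robust PCA outlier diagnosis of one class.

    Runs on the spectra exactly as given (the pipeline passes raw,
    range-restricted spectra: the diagnosis should see measurement
    artefacts, not preprocessing residue).  Orthogonal outliers and bad
    leverage points are marked for exclusion; good leverage points are
    retained.
    """
    sub = data.class_subset(class_label)
    if sub.n_samples < 10:
        raise ValueError(f"class {class_label!r} has only {sub.n_samples} "
                         f"samples; need >= 10 for a robust diagnosis")
    X = sub.absorbance
    k = settings.k
    if k is None:
        k = select_k_by_press(X, settings.k_max, folds=settings.press_folds,
                              seed=settings.seed, tol=settings.press_tol,
                              alpha_coverage=settings.alpha_coverage,
                              n_directions=settings.n_directions)
    model = fit_robpca(X, k, alpha_coverage=settings.alpha_coverage,
                       significance=settings.significance,
                       seed=settings.seed,
                       n_directions=settings.n_directions)
    sd = score_distance(model, X)
    od = orthogonal_distance(model, X)
    # degrees-of-freedom correction: residuals of the samples that entered
    # the reweighted fit are shrunk by the k-dimensional fit relative to
    # held-out samples, which would otherwise inflate the apparent tail
    if model.support is not None and model.support.any():
        n_sup = int(model.support.sum())
        if n_sup > k:
            od = od.copy()
            od[model.support] /= np.sqrt(1.0 - k / n_sup)
    sd_cut, od_cut = distance_cutoffs(model, od)
    group = classify_samples(sd, od, sd_cut, od_cut)
    excluded = np.isin(group, ("orthogonal_outlier", "bad_leverage"))
    return RobustPCADiagnosis(model=model, sample_ids=sub.sample_ids,
                              sd=sd, od=od, sd_cutoff=sd_cut,
                              od_cutoff=od_cut, group=group,
                              excluded=excluded)
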