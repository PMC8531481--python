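"""Latent-variable engine and evaluation machinery.

NIPALS partial least squares (PLS2 with Y-deflation), Kennard-Stone sample
partitioning, deterministic 7-fold cross-validation with RMSECV-based
latent-variable selection, PLS-DA classification metrics (sensitivity,
specificity, accuracy), regression metrics (R^2, RMSEP), a label-permutation
test, and relative model comparison.

Everything here is deterministic for fixed inputs: NIPALS is initialized
from the response column of maximal variance, folds are venetian blinds
(sample i -> fold i mod n_folds), and Kennard-Stone breaks ties by lowest
index. Randomness enters only through the permutation test's explicit seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthdata import SpectrumSet

logger = logging.getLogger(__name__)

__all__ = [
    "PlsModel",
    "CvResult",
    "ClassReport",
    "RegReport",
    "kennard_stone",
    "fit_pls",
    "cross_validate",
    "one_hot",
    "plsda_predict",
    "class_metrics",
    "reg_metrics",
    "permutation_test",
    "compare_models",
    "cv_class_accuracy",
    "cv_q2",
]

# relative tolerance (on the response RMS scale) below which RMSECV values
# are considered tied; ties resolve to the smallest LV count
_RMSECV_TIE_RTOL = 1e-8

# convergence threshold on the change of the normalized NIPALS weight vector
_NIPALS_W_TOL = 1e-9


# ---------------------------------------------------------------------------
# Kennard-Stone partitioning
# ---------------------------------------------------------------------------

def kennard_stone(data, n_train: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic maximin-distance calibration/test split.

    The seed pair is the two samples at maximal Euclidean distance; each
    subsequent pick maximizes its minimal distance to the already selected
    set. Ties resolve to the lowest index. Returns (train, test) index
    arrays, each sorted ascending.
    """
    X = data.intensities if isinstance(data, SpectrumSet) else np.asarray(data, float)
    n = X.shape[0]
    if not 2 <= n_train <= n:
        raise ValueError(f"n_train must be in [2, {n}]")
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, -np.inf)
    # argmax of the flattened matrix -> lowest (i, j) in row-major order
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    selected = [min(i, j), max(i, j)]
    np.fill_diagonal(d2, np.inf)
    min_d2 = np.minimum(d2[selected[0]], d2[selected[1]])
    min_d2[selected] = -np.inf
    while len(selected) < n_train:
        k = int(np.argmax(min_d2))
        selected.append(k)
        min_d2 = np.minimum(min_d2, d2[k])
        min_d2[k] = -np.inf
    train = np.array(sorted(selected))
    test = np.setdiff1d(np.arange(n), train)
    return train, test


# ---------------------------------------------------------------------------
# NIPALS PLS
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    """A fitted NIPALS PLS model.

    ``n_lv`` is the number of components actually extracted (it may be
    smaller than requested when the residual matrix runs out of rank).
    Scores of new data are computed by sequential deflation with the stored
    weights and X-loadings, so predictions with the first k components are
    available for every k <= n_lv.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray      # (p, n_lv)
    x_loadings: np.ndarray   # (p, n_lv)
    y_loadings: np.ndarray   # (q, n_lv)
    scores: np.ndarray       # (n_train, n_lv)

    @property
    def coefficients(self) -> np.ndarray:
        """Regression matrix mapping centered X to centered Y (all LVs)."""
        return self.coefficients_k(self.n_lv)

    def coefficients_k(self, k: int) -> np.ndarray:
        W, P, Q = self.weights[:, :k], self.x_loadings[:, :k], self.y_loadings[:, :k]
        if k == 0:
            return np.zeros((W.shape[0], Q.shape[0]))
        R = W @ np.linalg.inv(P.T @ W)
        return R @ Q.T

    def transform(self, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        """Scores of new rows, by sequential weight projection/deflation."""
        k = self.n_lv if n_lv is None else min(n_lv, self.n_lv)
        Xc = np.asarray(X, float) - self.x_mean
        T = np.empty((Xc.shape[0], k))
        for a in range(k):
            t = Xc @ self.weights[:, a]
            T[:, a] = t
            Xc = Xc - np.outer(t, self.x_loadings[:, a])
        return T

    def predict(self, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        T = self.transform(X, n_lv)
        return self.y_mean + T @ self.y_loadings[:, : T.shape[1]].T

    def predict_per_lv(self, X: np.ndarray) -> np.ndarray:
        """Cumulative predictions for k = 1..n_lv; shape (n_lv, n, q)."""
        T = self.transform(X)
        contrib = T[:, :, None] * self.y_loadings.T[None, :, :]
        return self.y_mean + np.cumsum(contrib, axis=1).transpose(1, 0, 2)


def _nipals_component(Xc: np.ndarray, Yc: np.ndarray, x_tol: float,
                      tol: float, max_iter: int):
    """One NIPALS factor (w, t, q) from residual matrices, or None if null.

    Initialized from the residual-Y column of maximal variance; for a
    single-column response the inner loop converges in one pass.
    """
    u = Yc[:, int(np.argmax(Yc.var(axis=0)))].copy()
    w = t = q = None
    w_old = None
    for _ in range(max_iter):
        w = Xc.T @ u
        nw = np.linalg.norm(w)
        if nw < x_tol:
            return None
        w = w / nw
        t = Xc @ w
        tt = t @ t
        if tt < x_tol**2:
            return None
        q = Yc.T @ t / tt
        if Yc.shape[1] == 1:
            return w, t, q
        qq = q @ q
        if qq == 0:
            return None
        u = Yc @ q / qq
        if w_old is not None and np.linalg.norm(w - w_old) <= _NIPALS_W_TOL:
            return w, t, q
        w_old = w
    warnings.warn("NIPALS did not converge within max_iter", RuntimeWarning)
    return w, t, q


def fit_pls(X: np.ndarray, Y: np.ndarray, n_lv: int, tol: float = 1e-10,
            max_iter: int = 1000) -> PlsModel:
    """Fit a PLS model by NIPALS with Y-deflation.

    X and Y are centered internally. The score direction for each component
    is initialized from the residual-Y column of maximal variance, making
    the fit deterministic. Requesting more components than the residual rank
    supports truncates with a logged warning.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if n_lv > min(n - 1, p):
        raise ValueError(f"n_lv must be <= min(n_samples-1, n_variables) = {min(n - 1, p)}")
    if np.allclose(Y.std(axis=0), 0):
        raise ValueError("response has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    x_scale = np.linalg.norm(Xc)
    y_scale = np.linalg.norm(Yc)

    x_tol = tol * max(x_scale, 1.0)
    y_tol = tol * max(y_scale, 1.0)
    W, P, Q, T = [], [], [], []
    for a in range(n_lv):
        if np.linalg.norm(Xc) < x_tol or np.linalg.norm(Yc) < y_tol:
            logger.warning("NIPALS stopped at %d of %d components (rank exhausted)", a, n_lv)
            break
        comp = _nipals_component(Xc, Yc, x_tol, tol, max_iter)
        if comp is None:
            logger.warning("NIPALS stopped at %d of %d components (null direction)", a, n_lv)
            break
        w, t, q = comp
        tt = t @ t
        p_load = Xc.T @ t / tt
        Xc = Xc - np.outer(t, p_load)
        Yc = Yc - np.outer(t, q)
        W.append(w)
        P.append(p_load)
        Q.append(q)
        T.append(t)

    k = len(W)
    if k == 0:
        # degenerate: no extractable structure; model predicts the mean
        return PlsModel(
            n_lv=0, x_mean=x_mean, y_mean=y_mean,
            weights=np.zeros((p, 0)), x_loadings=np.zeros((p, 0)),
            y_loadings=np.zeros((Y.shape[1], 0)), scores=np.zeros((n, 0)),
        )
    return PlsModel(
        n_lv=k,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=np.column_stack(W),
        x_loadings=np.column_stack(P),
        y_loadings=np.column_stack(Q),
        scores=np.column_stack(T),
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """RMSECV curve over LV counts plus the selected count.

    ``rmsecv[k-1]`` is the 7-fold cross-validated root mean squared error
    with k latent variables; ``chosen_n_lv`` minimizes it (numerical ties
    resolve to the smallest count). ``cv_predictions[k-1]`` holds the
    out-of-fold predictions used to compute the curve.
    """

    rmsecv: np.ndarray
    chosen_n_lv: int
    fold_assignment: np.ndarray
    cv_predictions: np.ndarray | None = None  # (max_lv, n, q)

    @property
    def chosen_rmsecv(self) -> float:
        return float(self.rmsecv[self.chosen_n_lv - 1])


def venetian_folds(n: int, n_folds: int) -> np.ndarray:
    """Deterministic venetian-blind fold ids: sample i -> fold i mod n_folds."""
    return np.arange(n) % n_folds


def cross_validate(X: np.ndarray, Y: np.ndarray, max_lv: int,
                   n_folds: int = 7) -> CvResult:
    """RMSECV curve for k = 1..max_lv under venetian-blind folds.

    One NIPALS fit with max_lv components per fold provides nested
    predictions for every smaller count, so the curve costs one model per
    fold, not one per (fold, k).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if n_folds > n:
        raise ValueError("n_folds must be <= n_samples")
    folds = venetian_folds(n, n_folds)
    preds = np.full((max_lv, n, Y.shape[1]), np.nan)
    for f in range(n_folds):
        test = folds == f
        train = ~test
        cap = min(max_lv, int(train.sum()) - 1, X.shape[1])
        model = fit_pls(X[train], Y[train], n_lv=cap)
        per_lv = model.predict_per_lv(X[test])  # (n_extracted, n_test, q)
        k_eff = per_lv.shape[0]
        if k_eff > 0:
            preds[:k_eff, test, :] = per_lv
            # components beyond the extracted rank add nothing
            preds[k_eff:, test, :] = per_lv[-1]
        else:
            preds[:, test, :] = model.y_mean
    rmsecv = np.sqrt(np.mean((preds - Y[None]) ** 2, axis=(1, 2)))
    y_rms = max(float(np.sqrt(np.mean(Y**2))), 1.0)
    tie_tol = _RMSECV_TIE_RTOL * y_rms
    best = float(np.min(rmsecv))
    chosen = int(np.flatnonzero(rmsecv <= best + tie_tol)[0]) + 1
    return CvResult(rmsecv=rmsecv, chosen_n_lv=chosen,
                    fold_assignment=folds, cv_predictions=preds)


# ---------------------------------------------------------------------------
# Classification: one-hot encoding, PLS-DA decision rule, metrics
# ---------------------------------------------------------------------------

def one_hot(labels: np.ndarray, classes: np.ndarray | None = None):
    """One-hot indicator matrix and the class order used for its columns."""
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    classes = np.asarray(classes)
    unknown = set(labels.tolist()) - set(classes.tolist())
    if unknown:
        raise ValueError(f"labels not present in the class set: {sorted(unknown)}")
    Y = (labels[:, None] == classes[None, :]).astype(float)
    return Y, classes


def plsda_predict(model: PlsModel, X: np.ndarray, classes: np.ndarray,
                  n_lv: int | None = None) -> np.ndarray:
    """Predicted class = argmax over the predicted indicator columns."""
    scores = model.predict(X, n_lv=n_lv)
    if scores.shape[1] != len(classes):
        raise ValueError("model response width does not match the class set")
    return classes[np.argmax(scores, axis=1)]


@dataclass
class ClassReport:
    """Per-class sensitivity/specificity plus overall accuracy.

    The confusion matrix is stored with true classes on rows and predicted
    classes on columns; SEN_c = TP/(TP+FN), SPE_c = TN/(TN+FP),
    ACC = trace/total.
    """

    classes: np.ndarray
    confusion: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: float
    set_label: str = ""

    def to_rows(self) -> list[dict]:
        return [
            {
                "class": str(c),
                "SEN": float(self.sensitivity[i]),
                "SPE": float(self.specificity[i]),
                "ACC": float(self.accuracy),
            }
            for i, c in enumerate(self.classes)
        ]


def class_metrics(truth: np.ndarray, predicted: np.ndarray,
                  classes: np.ndarray | None = None,
                  set_label: str = "") -> ClassReport:
    """Confusion matrix and SEN/SPE/ACC from true and predicted labels."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted lengths differ")
    if classes is None:
        classes = np.unique(np.concatenate([truth, predicted]))
    classes = np.asarray(classes)
    unknown = set(truth.tolist()) - set(classes.tolist())
    if unknown:
        raise ValueError(f"classes present in data but absent from class set: {sorted(unknown)}")
    k = len(classes)
    index = {c: i for i, c in enumerate(classes.tolist())}
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(truth.tolist(), predicted.tolist()):
        confusion[index[t], index[p]] += 1
    total = confusion.sum()
    tp = np.diag(confusion).astype(float)
    fn = confusion.sum(axis=1) - tp
    fp = confusion.sum(axis=0) - tp
    tn = total - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        sen = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        spe = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
    acc = float(tp.sum() / total)
    return ClassReport(classes=classes, confusion=confusion, sensitivity=sen,
                       specificity=spe, accuracy=acc, set_label=set_label)


# ---------------------------------------------------------------------------
# Regression metrics
# ---------------------------------------------------------------------------

@dataclass
class RegReport:
    """Calibration and prediction metrics of one regression model."""

    r2c: float
    rmsecv: float
    r2p: float
    rmsep: float
    n_train: int = 0
    n_test: int = 0
    set_label: str = ""


def reg_metrics(truth: np.ndarray, predicted: np.ndarray) -> dict[str, float]:
    """RMSE and coefficient of determination R^2 = 1 - SSE/SST."""
    truth = np.asarray(truth, float).ravel()
    predicted = np.asarray(predicted, float).ravel()
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted lengths differ")
    sse = float(np.sum((truth - predicted) ** 2))
    sst = float(np.sum((truth - truth.mean()) ** 2))
    if sst == 0:
        raise ValueError("truth has zero variance; R^2 undefined")
    return {"rmse": float(np.sqrt(sse / truth.size)), "r2": 1.0 - sse / sst}


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_failed: int = 0


def permutation_test(pipeline, X: np.ndarray, Y: np.ndarray, n_iter: int = 200,
                     seed: int = 0) -> PermutationResult:
    """Label-permutation test of a fitting pipeline.

    ``pipeline(X, Y) -> float`` must run the full procedure including
    latent-variable selection and return its cross-validated figure of merit
    (accuracy for classification, Q^2 for regression). Labels/responses are
    permuted ``n_iter`` times; p = (1 + #{null >= observed}) / (n_valid + 1).
    A pipeline failure inside a permutation is recorded and excluded with a
    warning, never silently.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y)
    observed = float(pipeline(X, Y))
    null = []
    n_failed = 0
    for i in range(n_iter):
        perm = rng.permutation(len(Y))
        try:
            null.append(float(pipeline(X, Y[perm])))
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
            n_failed += 1
            warnings.warn(f"permutation {i} failed and was excluded: {exc}",
                          RuntimeWarning)
    null_arr = np.array(null)
    p = (1.0 + np.sum(null_arr >= observed)) / (null_arr.size + 1.0)
    return PermutationResult(observed=observed, null=null_arr, p_value=float(p),
                             n_failed=n_failed)


def cv_class_accuracy(X: np.ndarray, labels: np.ndarray, max_lv: int = 5,
                      n_folds: int = 7) -> float:
    """Cross-validated PLS-DA accuracy with RMSECV-selected LV count.

    The statistic the permutation test uses for classification: out-of-fold
    argmax predictions at the LV count that minimizes the indicator RMSECV.
    """
    Y, classes = one_hot(labels)
    cv = cross_validate(X, Y, max_lv=max_lv, n_folds=n_folds)
    preds = cv.cv_predictions[cv.chosen_n_lv - 1]
    predicted = classes[np.argmax(preds, axis=1)]
    return float(np.mean(predicted == np.asarray(labels)))


def cv_q2(X: np.ndarray, y: np.ndarray, max_lv: int = 5, n_folds: int = 7) -> float:
    """Cross-validated Q^2 (1 - PRESS/SST) at the RMSECV-selected LV count."""
    y = np.asarray(y, float).ravel()
    cv = cross_validate(X, y, max_lv=max_lv, n_folds=n_folds)
    press = float(np.sum((cv.cv_predictions[cv.chosen_n_lv - 1].ravel() - y) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / sst


# ---------------------------------------------------------------------------
# Relative model comparison
# ---------------------------------------------------------------------------

def compare_models(a, b) -> dict[str, float]:
    """Percent change of each shared metric from model a (baseline) to b.

    percent = 100 * (metric_b - metric_a) / metric_a, rounded to one decimal
    for display (negative = decrease). Both arguments must be the same kind
    of report (two RegReports or two ClassReports).
    """
    if isinstance(a, RegReport) and isinstance(b, RegReport):
        metrics = ["r2c", "rmsecv", "r2p", "rmsep"]
        get = lambda r, m: getattr(r, m)  # noqa: E731
    elif isinstance(a, ClassReport) and isinstance(b, ClassReport):
        metrics = ["accuracy"]
        get = lambda r, m: getattr(r, m)  # noqa: E731
    else:
        raise TypeError("compare_models requires two reports of the same kind")
    out = {}
    for m in metrics:
        base = float(get(a, m))
        new = float(get(b, m))
        if base == 0:
            raise ZeroDivisionError(f"baseline metric {m} is zero; percent change undefined")
        out[m] = round(100.0 * (new - base) / base, 1)
    return out
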