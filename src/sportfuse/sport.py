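"""SPORT: sequential preprocessing fusion through orthogonalized PLS.

SPORT is SO-PLS (sequential and orthogonalized partial least squares)
applied to a multi-block dataset whose blocks are differently preprocessed
copies of the same spectra. Blocks are visited in a fixed order; each block
is first orthogonalized against the accumulated scores of the earlier
blocks, then a PLS model on the orthogonalized block fits the current
response residuals and contributes its own scores. The per-block
latent-variable counts (k_1, ..., k_B), each possibly 0, are selected by
exhaustive search over the grid {0..max_lv}^B, scored by deterministic
venetian-blind cross-validated RMSECV (on the one-hot indicator matrix for
classification). A greedy per-block search is available to bound cost for
many blocks.

The final model regresses the centered response on the fused score matrix
[T_1 | ... | T_B]; because the block scores are mutually orthogonal this
equals the sum of the sequential per-block fits, but the explicit
least-squares fit also absorbs any residual non-orthogonality.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .plscore import (
    ClassReport,
    CvResult,
    PlsModel,
    RegReport,
    _RMSECV_TIE_RTOL,
    class_metrics,
    compare_models,
    cross_validate,
    fit_pls,
    kennard_stone,
    one_hot,
    plsda_predict,
    reg_metrics,
    venetian_folds,
)
from .preprocess import PreprocessingBank
from .synthdata import SpectrumSet

logger = logging.getLogger(__name__)

__all__ = [
    "BlockCollection",
    "SportModel",
    "sport_fit",
    "sport_predict",
    "run_sport_workflow",
    "WorkflowResult",
]


@dataclass
class BlockCollection:
    """An ordered list of (name, matrix) blocks sharing row order.

    For SPORT the order is the preprocessing sequence (default
    MSC -> SNV -> VSN -> SD). Row metadata (class labels or content) rides
    along so workflows can carry one object.
    """

    names: list[str]
    matrices: list[np.ndarray]
    class_labels: np.ndarray | None = None
    content: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.names) != len(self.matrices):
            raise ValueError("names and matrices must align")
        if len(set(self.names)) != len(self.names):
            raise ValueError("block names must be unique")
        self.matrices = [np.asarray(m, float) for m in self.matrices]
        n_rows = {m.shape[0] for m in self.matrices}
        if len(n_rows) > 1:
            raise ValueError(f"blocks disagree on sample count: {sorted(n_rows)}")

    @property
    def n_samples(self) -> int:
        return self.matrices[0].shape[0]

    @property
    def n_blocks(self) -> int:
        return len(self.matrices)

    def subset(self, indices: np.ndarray) -> "BlockCollection":
        idx = np.asarray(indices, dtype=int)
        return BlockCollection(
            names=list(self.names),
            matrices=[m[idx] for m in self.matrices],
            class_labels=None if self.class_labels is None else self.class_labels[idx],
            content=None if self.content is None else self.content[idx],
        )


@dataclass
class _BlockFit:
    """Per-block pieces of a fitted SPORT model."""

    name: str
    n_lv: int
    orth_loadings: np.ndarray | None  # (n_acc_scores, p_block); None for block 1
    pls: PlsModel | None              # None when n_lv == 0


@dataclass
class SportModel:
    """A fitted SPORT (sequential orthogonalized PLS) model."""

    block_fits: list[_BlockFit]
    lv_combination: tuple[int, ...]
    y_mean: np.ndarray
    beta: np.ndarray                 # fused-score regression coefficients
    fused_scores: np.ndarray         # (n_train, sum of LV counts)
    fitted: np.ndarray               # training predictions (response scale)
    rmsecv: float
    rmsecv_grid: dict[tuple[int, ...], float]
    classes: np.ndarray | None = None
    task: str = "regress"

    def predict(self, blocks: BlockCollection) -> np.ndarray:
        return sport_predict(self, blocks)


def _orthogonalize(X: np.ndarray, T_acc: np.ndarray | None):
    """Project block columns onto the orthogonal complement of earlier scores.

    Returns (X_orth, loadings); loadings are reused at prediction time.
    """
    if T_acc is None or T_acc.shape[1] == 0:
        return X, None
    loadings, *_ = np.linalg.lstsq(T_acc, X, rcond=None)
    return X - T_acc @ loadings, loadings


def _transform_scores(pls: PlsModel, X: np.ndarray, k: int) -> np.ndarray:
    T = pls.transform(X, n_lv=k)
    if T.shape[1] < k:  # rank-limited extraction: pad with null scores
        T = np.hstack([T, np.zeros((X.shape[0], k - T.shape[1]))])
    return T


def _search_press(
    mats_tr: list[np.ndarray],
    mats_te: list[np.ndarray],
    R_tr: np.ndarray,
    Y_te_c: np.ndarray,
    choices: list[list[int]],
    press: dict[tuple[int, ...], float],
    T_acc_tr: np.ndarray | None = None,
    T_acc_te: np.ndarray | None = None,
    pred_te: np.ndarray | None = None,
    prefix: tuple[int, ...] = (),
) -> None:
    """Accumulate per-combination PRESS for one CV fold, recursively.

    One NIPALS fit per tree node serves every LV count at that node because
    NIPALS components are nested.
    """
    depth = len(prefix)
    if depth == len(mats_tr):
        key = prefix
        resid = (pred_te if pred_te is not None else 0.0) - Y_te_c
        press[key] = press.get(key, 0.0) + float(np.sum(resid**2))
        return
    if pred_te is None:
        pred_te = np.zeros_like(Y_te_c)
    ks = choices[depth]
    X_tr, X_te = mats_tr[depth], mats_te[depth]
    X_tr_o, loadings = _orthogonalize(X_tr, T_acc_tr)
    X_te_o = X_te if loadings is None else X_te - T_acc_te @ loadings
    max_k = max(ks)
    cap = min(max_k, X_tr.shape[0] - 1, X_tr.shape[1])
    model = None
    if cap >= 1 and np.linalg.norm(R_tr) > 1e-12:
        try:
            model = fit_pls(X_tr_o, R_tr, n_lv=cap)
        except ValueError:
            model = None
    for k in ks:
        if k == 0:
            _search_press(mats_tr, mats_te, R_tr, Y_te_c, choices, press,
                          T_acc_tr, T_acc_te, pred_te, prefix + (0,))
            continue
        if model is None:
            # block contributes nothing; identical to k = 0
            _search_press(mats_tr, mats_te, R_tr, Y_te_c, choices, press,
                          T_acc_tr, T_acc_te, pred_te, prefix + (k,))
            continue
        k_eff = min(k, model.n_lv)
        T_tr_k = model.scores[:, :k_eff]
        T_te_k = _transform_scores(model, X_te_o, k_eff)
        Q_k = model.y_loadings[:, :k_eff]
        contrib_tr = model.y_mean + T_tr_k @ Q_k.T
        contrib_te = model.y_mean + T_te_k @ Q_k.T
        T_acc_tr_new = T_tr_k if T_acc_tr is None else np.hstack([T_acc_tr, T_tr_k])
        T_acc_te_new = T_te_k if T_acc_te is None else np.hstack([T_acc_te, T_te_k])
        _search_press(mats_tr, mats_te, R_tr - contrib_tr, Y_te_c, choices, press,
                      T_acc_tr_new, T_acc_te_new, pred_te + contrib_te,
                      prefix + (k,))


def _evaluate_combinations(
    blocks: BlockCollection,
    Y: np.ndarray,
    choices: list[list[int]],
    n_folds: int,
) -> dict[tuple[int, ...], float]:
    """Cross-validated RMSECV for every LV combination in the choice grid."""
    n = blocks.n_samples
    folds = venetian_folds(n, n_folds)
    press: dict[tuple[int, ...], float] = {}
    for f in range(n_folds):
        te = folds == f
        tr = ~te
        y_mean = Y[tr].mean(axis=0)
        _search_press(
            [m[tr] for m in blocks.matrices],
            [m[te] for m in blocks.matrices],
            Y[tr] - y_mean,
            Y[te] - y_mean,
            choices,
            press,
        )
    total = n * Y.shape[1]
    return {combo: float(np.sqrt(p / total)) for combo, p in press.items()}


def _select_combination(
    rmsecv: dict[tuple[int, ...], float], y_rms: float
) -> tuple[int, ...]:
    """Lowest RMSECV; numerical ties -> smallest total LV count, then the
    combination that loads the earliest blocks (so an exact duplicate of an
    earlier block ends up with 0 LVs). The all-zero combination is
    excluded."""
    items = {c: v for c, v in rmsecv.items() if any(c)}
    if not items:
        raise ValueError("no admissible LV combination (all-zero excluded)")
    best = min(items.values())
    tol = _RMSECV_TIE_RTOL * max(y_rms, 1.0)
    tied = [c for c, v in items.items() if v <= best + tol]
    return min(tied, key=lambda c: (sum(c), tuple(-k for k in c)))


def fit_sequential(blocks: BlockCollection, Y: np.ndarray,
                   combo: tuple[int, ...]) -> tuple[list[_BlockFit], np.ndarray, np.ndarray]:
    """Sequential orthogonalized fit of one LV combination on all rows.

    Returns (block fits, fused training scores, global response mean).
    """
    y_mean = Y.mean(axis=0)
    R = Y - y_mean
    T_acc: np.ndarray | None = None
    fits: list[_BlockFit] = []
    for name, X, k in zip(blocks.names, blocks.matrices, combo):
        X_orth, loadings = _orthogonalize(X, T_acc)
        if k == 0:
            fits.append(_BlockFit(name=name, n_lv=0, orth_loadings=loadings, pls=None))
            continue
        cap = min(k, X.shape[0] - 1, X.shape[1])
        try:
            pls = fit_pls(X_orth, R, n_lv=cap)
        except ValueError:
            fits.append(_BlockFit(name=name, n_lv=0, orth_loadings=loadings, pls=None))
            continue
        k_eff = pls.n_lv
        if k_eff < k:
            logger.warning("block %s: only %d of %d LVs extractable", name, k_eff, k)
        T_k = pls.scores[:, :k_eff]
        R = R - (pls.y_mean + T_k @ pls.y_loadings[:, :k_eff].T)
        T_acc = T_k if T_acc is None else np.hstack([T_acc, T_k])
        fits.append(_BlockFit(name=name, n_lv=k_eff, orth_loadings=loadings, pls=pls))
    if T_acc is None:
        raise ValueError("selected combination extracted no latent variables")
    return fits, T_acc, y_mean


def sport_fit(
    blocks: BlockCollection,
    response: np.ndarray,
    max_lv_per_block: int = 10,
    n_folds: int = 7,
    task: str = "regress",
    search: str = "grid",
) -> SportModel:
    """Fit a SPORT model with RMSECV-selected per-block LV counts.

    ``response`` is a content vector (task='regress') or a label vector
    (task='classify', internally one-hot encoded; RMSECV is computed on the
    indicator matrix so one scalar loss serves both tasks). ``search`` is
    'grid' for the exhaustive {0..max_lv}^B search or 'greedy' for the
    per-block sequential search.
    """
    if blocks.n_blocks < 1:
        raise ValueError("need at least one block")
    if max_lv_per_block < 1:
        raise ValueError("max_lv_per_block must be >= 1")
    classes = None
    if task == "classify":
        Y, classes = one_hot(np.asarray(response))
    elif task == "regress":
        Y = np.asarray(response, float)
        Y = Y[:, None] if Y.ndim == 1 else Y
    else:
        raise ValueError("task must be 'classify' or 'regress'")
    if Y.shape[0] != blocks.n_samples:
        raise ValueError("response length does not match block row count")

    full = list(range(max_lv_per_block + 1))
    if search == "grid":
        choices = [full for _ in range(blocks.n_blocks)]
        rmsecv_grid = _evaluate_combinations(blocks, Y, choices, n_folds)
    elif search == "greedy":
        rmsecv_grid = {}
        chosen: list[int] = []
        for i in range(blocks.n_blocks):
            choices = [[c] for c in chosen] + [full] + [[0]] * (blocks.n_blocks - i - 1)
            stage = _evaluate_combinations(blocks, Y, choices, n_folds)
            rmsecv_grid.update(stage)
            stage_ok = {c: v for c, v in stage.items() if any(c)} or stage
            best = min(stage_ok.values())
            tol = _RMSECV_TIE_RTOL * max(float(np.sqrt(np.mean(Y**2))), 1.0)
            tied = [c for c, v in stage_ok.items() if v <= best + tol]
            chosen.append(min(tied, key=lambda c: (sum(c), tuple(-k for k in c)))[i])
        if not any(chosen):
            raise ValueError("greedy search selected the all-zero combination")
    else:
        raise ValueError("search must be 'grid' or 'greedy'")

    y_rms = float(np.sqrt(np.mean(Y**2)))
    combo = _select_combination(rmsecv_grid, y_rms)
    fits, T_acc, y_mean = fit_sequential(blocks, Y, combo)
    beta, *_ = np.linalg.lstsq(T_acc, Y - y_mean, rcond=None)
    fitted = y_mean + T_acc @ beta
    return SportModel(
        block_fits=fits,
        lv_combination=tuple(f.n_lv for f in fits),
        y_mean=y_mean,
        beta=beta,
        fused_scores=T_acc,
        fitted=fitted,
        rmsecv=rmsecv_grid[combo],
        rmsecv_grid=rmsecv_grid,
        classes=classes,
        task=task,
    )


def sport_predict(model: SportModel, blocks: BlockCollection) -> np.ndarray:
    """Predict new rows: sequential orthogonalized scores, fused regression.

    Returns predicted class labels for a classification model, predicted
    response values otherwise. Blocks must arrive preprocessed with
    training-frozen parameters, in the training block order.
    """
    names = [f.name for f in model.block_fits]
    if blocks.names != names:
        missing = [n for n in names if n not in blocks.names]
        if missing:
            raise ValueError(f"blocks missing at prediction time: {missing}")
        raise ValueError(f"block order must match training order {names}")
    T_acc: np.ndarray | None = None
    for f, X in zip(model.block_fits, blocks.matrices):
        X_orth = X if f.orth_loadings is None else X - T_acc @ f.orth_loadings
        if f.n_lv == 0:
            continue
        T_k = _transform_scores(f.pls, X_orth, f.n_lv)
        T_acc = T_k if T_acc is None else np.hstack([T_acc, T_k])
    scores_pred = model.y_mean + T_acc @ model.beta
    if model.task == "classify":
        return model.classes[np.argmax(scores_pred, axis=1)]
    return scores_pred.ravel() if scores_pred.shape[1] == 1 else scores_pred


# ---------------------------------------------------------------------------
# End-to-end workflow: split -> preprocess bank -> baselines + SPORT
# ---------------------------------------------------------------------------

@dataclass
class WorkflowResult:
    """Reports of one qualitative or quantitative study run."""

    task: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    baseline_reports: dict        # method -> report or (train, test) reports
    sport_report: object
    sport_model: SportModel
    deltas: dict                  # comparisons vs baselines
    predictions: dict = field(default_factory=dict)

    @property
    def reports(self) -> dict:
        out = dict(self.baseline_reports)
        out["SPORT"] = self.sport_report
        return out


def run_sport_workflow(
    data: SpectrumSet,
    task: str,
    preproc: list[str] | None = None,
    train_frac: float = 182.0 / 273.0,
    max_lv: int = 10,
    n_folds: int = 7,
    search: str = "grid",
    bank: PreprocessingBank | None = None,
) -> WorkflowResult:
    """The full single-dataset study: KS split, preprocessing bank fit on
    training rows, per-preprocessing PLS baselines (RAW, MSC, SNV, VSN, SD)
    and the SPORT fusion, with relative comparisons.

    Classification reports SEN/SPE/ACC per class for training and test sets;
    regression reports R2c, RMSECV, R2p, RMSEP per model.
    """
    preproc = list(preproc) if preproc is not None else ["MSC", "SNV", "VSN", "SD"]
    if task == "classify":
        if data.class_labels is None:
            raise ValueError("classification requires class labels [stage: split]")
        response = np.asarray(data.class_labels)
    elif task == "regress":
        if data.content is None:
            raise ValueError("regression requires content values [stage: split]")
        response = np.asarray(data.content, float)
    else:
        raise ValueError("task must be 'classify' or 'regress'")

    n = data.n_samples
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 2), n - 1)
    train_idx, test_idx = kennard_stone(data, n_train)
    d_train = data.subset(train_idx)
    d_test = data.subset(test_idx)
    y_train, y_test = response[train_idx], response[test_idx]

    bank = bank or PreprocessingBank(methods=preproc)
    bank.fit(d_train)
    baseline_methods = ["RAW"] + preproc
    cap = min(max_lv, n_train - 1, data.n_wavenumbers)

    baseline_reports: dict = {}
    predictions: dict = {}
    for method in baseline_methods:
        Xtr = bank.transform_one(d_train, method).intensities
        Xte = bank.transform_one(d_test, method).intensities
        report, pred = _fit_baseline(Xtr, y_train, Xte, y_test, task, cap, n_folds)
        baseline_reports[method] = report
        predictions[method] = pred

    blocks_tr = BlockCollection(
        names=preproc,
        matrices=[bank.transform_one(d_train, m).intensities for m in preproc],
        class_labels=y_train if task == "classify" else None,
        content=y_train if task == "regress" else None,
    )
    blocks_te = BlockCollection(
        names=preproc,
        matrices=[bank.transform_one(d_test, m).intensities for m in preproc],
    )
    model = sport_fit(blocks_tr, y_train, max_lv_per_block=cap, n_folds=n_folds,
                      task=task, search=search)
    pred_tr = sport_predict(model, blocks_tr)
    pred_te = sport_predict(model, blocks_te)
    if task == "classify":
        sport_report = {
            "train": class_metrics(y_train, pred_tr, set_label="train"),
            "test": class_metrics(y_test, pred_te, set_label="test"),
        }
    else:
        m_tr = reg_metrics(y_train, pred_tr)
        m_te = reg_metrics(y_test, pred_te)
        sport_report = RegReport(
            r2c=m_tr["r2"], rmsecv=model.rmsecv, r2p=m_te["r2"], rmsep=m_te["rmse"],
            n_train=len(train_idx), n_test=len(test_idx), set_label="SPORT",
        )
    predictions["SPORT"] = {"train": pred_tr, "test": pred_te,
                            "lv_combination": model.lv_combination}

    deltas = {}
    for method, rep in baseline_reports.items():
        a = rep["test"] if task == "classify" else rep
        b = sport_report["test"] if task == "classify" else sport_report
        try:
            deltas[f"{method}->SPORT"] = compare_models(a, b)
        except (ZeroDivisionError, TypeError) as exc:
            deltas[f"{method}->SPORT"] = {"error": str(exc)}

    return WorkflowResult(
        task=task,
        train_idx=train_idx,
        test_idx=test_idx,
        baseline_reports=baseline_reports,
        sport_report=sport_report,
        sport_model=model,
        deltas=deltas,
        predictions=predictions,
    )


def _fit_baseline(Xtr, y_train, Xte, y_test, task, cap, n_folds):
    """One single-preprocessing PLS baseline with RMSECV-chosen LV count."""
    if task == "classify":
        Ytr, classes = one_hot(y_train)
        cv = cross_validate(Xtr, Ytr, max_lv=cap, n_folds=n_folds)
        model = fit_pls(Xtr, Ytr, n_lv=cv.chosen_n_lv)
        pred_tr = plsda_predict(model, Xtr, classes)
        pred_te = plsda_predict(model, Xte, classes)
        report = {
            "train": class_metrics(y_train, pred_tr, classes=classes, set_label="train"),
            "test": class_metrics(y_test, pred_te, classes=classes, set_label="test"),
        }
        pred = {"train": pred_tr, "test": pred_te, "n_lv": cv.chosen_n_lv}
        return report, pred
    cv = cross_validate(Xtr, y_train, max_lv=cap, n_folds=n_folds)
    model = fit_pls(Xtr, y_train, n_lv=cv.chosen_n_lv)
    pred_tr = model.predict(Xtr).ravel()
    pred_te = model.predict(Xte).ravel()
    m_tr = reg_metrics(y_train, pred_tr)
    m_te = reg_metrics(y_test, pred_te)
    report = RegReport(
        r2c=m_tr["r2"], rmsecv=cv.chosen_rmsecv, r2p=m_te["r2"], rmsep=m_te["rmse"],
        n_train=len(y_train), n_test=len(y_test),
    )
    pred = {"train": pred_tr, "test": pred_te, "n_lv": cv.chosen_n_lv}
    return report, pred
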