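"""Evaluation protocol: metrics, stratified splits, CV component
selection, and the five-window comparison.

The protocol mirrors the study design the pipeline emulates: the 56
difference-spectrum rows (8 exposed concentrations × 7 replicates) are
sorted into 20 random splits of 40 training / 16 testing rows; on each
training set the number of latent variables is chosen by k-fold
cross-validation (minimum pooled squared prediction error); the model is
refit and scored with RMSE and R² on both halves. The comparison is run
over five wavenumber windows: the full 1000–3000 cm⁻¹ range and the four
quarters 2500–3000, 2000–2500, 1500–2000, 1000–1500 cm⁻¹.

Splits are stratified 5 train / 2 test per exposed dose by default —
that is the only allocation consistent with 40/16 over eight balanced
dose groups — with a fully random alternative available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bis import BISMatrix, compute_bis
from .errors import DataError, DegeneracyError, DesignError
from .pls import fit_pls, predict, predict_components
from .spectra import SpectrumCollection

DEFAULT_WINDOWS = (
    (1000.0, 3000.0),
    (2500.0, 3000.0),
    (2000.0, 2500.0),
    (1500.0, 2000.0),
    (1000.0, 1500.0),
)


def rmse(observed, predicted) -> float:
    """Root mean squared error, sqrt(mean((obs - pred)^2))."""
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size == 0 or o.size != p.size:
        raise DataError("observed and predicted must be equal-length, non-empty")
    return float(np.sqrt(np.mean((o - p) ** 2)))


def r_squared(observed, predicted, kind: str = "ss") -> float:
    """Coefficient of determination.

    ``kind='ss'`` (default) is 1 − SS_res/SS_tot about the observed mean
    and may be negative for predictors worse than the mean;
    ``kind='pearson'`` is the squared Pearson correlation, an alternative
    reading of R² sometimes used interchangeably.
    """
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size == 0 or o.size != p.size:
        raise DataError("observed and predicted must be equal-length, non-empty")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise DegeneracyError("observed values are constant; R^2 undefined")
    if kind == "ss":
        return 1.0 - float(np.sum((o - p) ** 2)) / ss_tot
    if kind == "pearson":
        if np.std(p) == 0:
            return 0.0
        return float(np.corrcoef(o, p)[0, 1] ** 2)
    raise DataError(f"unknown R^2 kind {kind!r}")


@dataclass(frozen=True)
class SplitSpec:
    """One train/test partition of BIS rows (disjoint, exhaustive)."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    model_id: int
    seed: int


def stratified_split(bis: BISMatrix, train_per_dose: int = 5, test_per_dose: int = 2,
                     seed: int = 0, model_id: int = 1, stratify: bool = True) -> SplitSpec:
    """Seeded random split, 5 train / 2 test within each exposed dose.

    With ``stratify=False`` the same overall sizes are drawn fully at
    random without regard to dose. Every row lands in exactly one half.
    """
    rng = np.random.default_rng(seed)
    group_size = train_per_dose + test_per_dose
    if stratify:
        train, test = [], []
        for dose in np.unique(bis.y):
            idx = np.flatnonzero(bis.y == dose)
            if idx.size != group_size:
                raise DesignError(
                    f"dose {dose:g} has {idx.size} rows; stratified split needs exactly "
                    f"{group_size} per dose"
                )
            perm = rng.permutation(idx)
            train.extend(perm[:train_per_dose])
            test.extend(perm[train_per_dose:])
        train = np.sort(np.array(train))
        test = np.sort(np.array(test))
    else:
        n_train = train_per_dose * np.unique(bis.y).size
        if bis.n_rows <= n_train:
            raise DesignError("not enough rows for an unstratified split")
        perm = rng.permutation(bis.n_rows)
        train = np.sort(perm[:n_train])
        test = np.sort(perm[n_train:])
    return SplitSpec(train_indices=train, test_indices=test, model_id=model_id, seed=seed)


@dataclass(frozen=True)
class CVResult:
    """CV error per candidate component count; selected = argmin."""

    mse_by_lv: np.ndarray  # index j-1 -> pooled MSE with j components
    selected_lv: int


def _stratified_folds(n: int, k_folds: int, rng, labels=None) -> np.ndarray:
    """Fold id per row; rows of each label dealt round-robin across folds."""
    fold = np.empty(n, dtype=int)
    if labels is None:
        perm = rng.permutation(n)
        for pos, row in enumerate(perm):
            fold[row] = pos % k_folds
        return fold
    labels = np.asarray(labels)
    offset = 0
    for lab in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == lab))
        for pos, row in enumerate(idx):
            fold[row] = (offset + pos) % k_folds
        offset += idx.size
    return fold


def cv_lv_curve(X: np.ndarray, y: np.ndarray, max_lv: int, k_folds: int = 7,
                seed: int = 0, stratify_labels=None) -> CVResult:
    """K-fold CV curve of pooled squared prediction error vs component count.

    Folds are seeded and, when ``stratify_labels`` (e.g. doses) are
    given, balanced across label groups. Each fold is fit once at
    ``max_lv`` and truncated models provide the predictions for every
    smaller component count. Ties in the minimum go to the smaller
    count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if k_folds < 2 or k_folds > n:
        raise DesignError(f"k_folds must lie in [2, {n}]")
    biggest_fold = math.ceil(n / k_folds)
    cap = min(n - biggest_fold - 1, X.shape[1])
    if max_lv > cap:
        raise DesignError(f"max_lv {max_lv} exceeds CV capacity {cap}")
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(n, k_folds, rng, stratify_labels)
    sq_err = np.zeros(max_lv)
    for f in range(k_folds):
        test = fold == f
        if not test.any():
            raise DesignError(f"fold {f} is empty; reduce k_folds")
        model = fit_pls(X[~test], y[~test], max_lv)
        preds = predict_components(model, X[test])
        sq_err += np.sum((preds - y[test, None]) ** 2, axis=0)
    mse = sq_err / n
    return CVResult(mse_by_lv=mse, selected_lv=int(np.argmin(mse)) + 1)


@dataclass(frozen=True)
class EvaluationRecord:
    """Per-window, per-split scorecard of the fitted model."""

    window: tuple
    model_id: int
    selected_lv: int
    r2_train: float
    rmse_train: float
    r2_test: float
    rmse_test: float


def evaluate_bis(bis: BISMatrix, n_models: int = 20, max_lv: int = 15,
                 k_folds: int = 7, seed: int = 0, stratify: bool = True,
                 permute_labels: bool = False,
                 window: tuple = (np.nan, np.nan)) -> list[EvaluationRecord]:
    """Run the split/CV/fit/score protocol on one BIS matrix."""
    records = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_models)
    y_all = bis.y.copy()
    for m, child in enumerate(children, start=1):
        state = child.generate_state(3)
        split_seed = int(state[0] % (2 ** 31))
        cv_seed = int(state[1] % (2 ** 31))
        y = y_all
        if permute_labels:
            y = np.random.default_rng(int(state[2] % (2 ** 31))).permutation(y_all)
        split = stratified_split(bis, seed=split_seed, model_id=m, stratify=stratify)
        X_tr, y_tr = bis.X[split.train_indices], y[split.train_indices]
        X_te, y_te = bis.X[split.test_indices], y[split.test_indices]
        n_tr = y_tr.size
        cap = min(max_lv, n_tr - math.ceil(n_tr / k_folds) - 1, bis.X.shape[1])
        cv = cv_lv_curve(X_tr, y_tr, cap, k_folds=k_folds, seed=cv_seed,
                         stratify_labels=bis.y[split.train_indices])
        model = fit_pls(X_tr, y_tr, cv.selected_lv)
        pred_tr = predict(model, X_tr)
        pred_te = predict(model, X_te)
        records.append(EvaluationRecord(
            window=tuple(window),
            model_id=m,
            selected_lv=cv.selected_lv,
            r2_train=r_squared(y_tr, pred_tr),
            rmse_train=rmse(y_tr, pred_tr),
            r2_test=r_squared(y_te, pred_te),
            rmse_test=rmse(y_te, pred_te),
        ))
    return records


def evaluate_windows(collection: SpectrumCollection, windows=DEFAULT_WINDOWS,
                     n_models: int = 20, max_lv: int = 15, k_folds: int = 7,
                     seed: int = 0, stratify: bool = True, control_dose: float = 0.0,
                     permute_labels: bool = False) -> list[EvaluationRecord]:
    """The full windowed comparison on a preprocessed collection.

    For each window the BIS matrix is restricted to that range, then the
    20-split protocol runs with a window-specific derived seed. Returns
    n_models × len(windows) records.
    """
    bis_full = compute_bis(collection, control_dose=control_dose)
    records = []
    ss = np.random.SeedSequence(seed)
    window_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(len(windows))]
    for (lo, hi), wseed in zip(windows, window_seeds):
        sub = bis_full.restrict(lo, hi)
        records.extend(evaluate_bis(
            sub, n_models=n_models, max_lv=max_lv, k_folds=k_folds, seed=wseed,
            stratify=stratify, permute_labels=permute_labels, window=(lo, hi)))
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([{
        "window_lo": r.window[0],
        "window_hi": r.window[1],
        "model_id": r.model_id,
        "selected_lv": r.selected_lv,
        "r2_train": r.r2_train,
        "rmse_train": r.rmse_train,
        "r2_test": r.r2_test,
        "rmse_test": r.rmse_test,
    } for r in records])


def summarize_windows(records) -> pd.DataFrame:
    """Mean ± sd of the scorecard per window."""
    frame = records_to_frame(records)
    grouped = frame.groupby(["window_lo", "window_hi"], sort=False)
    summary = grouped.agg(
        n_models=("model_id", "count"),
        r2_train_mean=("r2_train", "mean"),
        r2_train_sd=("r2_train", "std"),
        rmse_train_mean=("rmse_train", "mean"),
        r2_test_mean=("r2_test", "mean"),
        r2_test_sd=("r2_test", "std"),
        rmse_test_mean=("rmse_test", "mean"),
        selected_lv_median=("selected_lv", "median"),
    ).reset_index()
    return summary
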