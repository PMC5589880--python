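"""Externally cross-validated evaluation and fold-stability signature selection.

The outer loop mirrors the published evaluation: stratified k-fold (default
5) splits; on each training fold the blocks are residualized on age/sex/
smoking and standardized, the per-block sparsity dials are tuned by an inner
cross-validation, a sparse generalized CCA is fit, and a two-class LDA on the
concatenated RNA and imaging component scores predicts diagnosis on the held
out fold.  Fold weight vectors are then aggregated per variable into an
occurrence count (folds with nonzero loading) and the mean absolute loading
across folds ("meanf"); a variable is flagged robust when its occurrence
reaches ``robust_min`` (default 3 of 5).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .dataset import MultiblockDataset
from .lda import BinaryLDA
from .preprocess import ConfoundResidualizer
from .sgcca import SGCCA, DesignSpec, FitResult, build_design

NONZERO_TOL = 1e-12  # |loading| above this counts as selected


@dataclass
class FoldRecord:
    train_idx: np.ndarray
    test_idx: np.ndarray
    sparsity: Tuple[float, ...]
    fit: FitResult
    error: float


@dataclass
class CVReport:
    """Per-fold fits and errors plus signature-table per-variable aggregates."""

    k: int
    design: DesignSpec
    folds: List[FoldRecord]
    block_variables: Dict[str, List[str]]
    robust_min: int = 3
    meta: dict = field(default_factory=dict)

    @property
    def error_rates(self) -> np.ndarray:
        return np.array([f.error for f in self.folds])

    @property
    def mean_error(self) -> float:
        return float(self.error_rates.mean())

    def fold_loadings(self, block: str) -> np.ndarray:
        """k x p matrix of fold weight vectors for one block."""
        b = list(self.design.block_order).index(block)
        return np.vstack([f.fit.weights[b] for f in self.folds])

    def signature(self, block: str, robust_min: Optional[int] = None) -> pd.DataFrame:
        rmin = self.robust_min if robust_min is None else robust_min
        return summarize_fold_loadings(
            self.fold_loadings(block), self.block_variables[block], robust_min=rmin
        )


def summarize_fold_loadings(fold_loadings, variables: Sequence[str],
                            robust_min: int = 3) -> pd.DataFrame:
    """Aggregate a k x p matrix of fold loadings into a signature table.

    Per variable: ``occurrence`` = number of folds with |loading| > 0,
    ``meanf`` = arithmetic mean of the k absolute loadings (zeros included),
    ``robust`` = occurrence >= robust_min.  Sorted descending by meanf.
    """
    L = np.abs(np.asarray(fold_loadings, dtype=float))
    if L.ndim != 2 or L.shape[1] != len(variables):
        raise ValueError("fold_loadings must be k x p with one column per variable")
    k = L.shape[0]
    occurrence = (L > NONZERO_TOL).sum(axis=0)
    meanf = L.mean(axis=0)
    out = pd.DataFrame({
        "variable": list(variables),
        "meanf": meanf,
        "occurrence": occurrence,
        "robust": occurrence >= robust_min,
    })
    for i in range(k):
        out[f"fold{i + 1}"] = L[i]
    return out.sort_values("meanf", ascending=False, kind="mergesort").reset_index(drop=True)


def stability_summary(report: CVReport, robust_min: int = 3) -> Dict[str, pd.DataFrame]:
    """Signature table per penalized block of a cross-validation report."""
    return {
        block: report.signature(block, robust_min=robust_min)
        for block in report.block_variables
    }


def default_sparsity_grid(p: int, n_points: int = 5) -> np.ndarray:
    """Log-spaced sparsity dials from 1/sqrt(p) (one variable) to 1 (dense)."""
    return np.geomspace(1.0 / np.sqrt(p), 1.0, n_points)


def _preprocess_fold(dataset: MultiblockDataset, block_names: Sequence[str],
                     train: np.ndarray, test: np.ndarray, in_fold: bool):
    """Residualize+standardize data blocks and standardize the dx column.

    All parameters come from the training rows only.
    Returns (train_blocks, test_blocks) lists ordered (block..., dx).
    """
    cov = dataset.covariates.to_numpy(dtype=float)
    y = dataset.y().astype(float)
    train_blocks, test_blocks = [], []
    for name in block_names:
        X = dataset.block_matrix(name)
        model = ConfoundResidualizer()
        if in_fold:
            model.fit(X[train], cov[train])
        else:
            model.fit(X, cov)
        train_blocks.append(model.transform(X[train], cov[train]))
        test_blocks.append(model.transform(X[test], cov[test]))
    mu, sd = y[train].mean(), y[train].std(ddof=1)
    if sd == 0:
        raise ValueError("training fold contains a single class; use stratified folds")
    train_blocks.append(((y[train] - mu) / sd)[:, None])
    test_blocks.append(((y[test] - mu) / sd)[:, None])
    return train_blocks, test_blocks


def _fit_and_score(train_blocks, test_blocks, y_train, y_test, design,
                   scheme, sparsity, tol, max_iter, seed):
    est = SGCCA(design=design, scheme=scheme, sparsity=sparsity,
                tol=tol, max_iter=max_iter, random_state=seed)
    est.fit(train_blocks)
    # classifier sees the RNA and imaging components only, never the dx block
    train_scores = est.transform(train_blocks)[:, :-1]
    test_scores = est.transform(test_blocks)[:, :-1]
    clf = BinaryLDA().fit(train_scores, y_train)
    error = float(np.mean(clf.predict(test_scores) != y_test))
    return est, error


def cross_validate(dataset: MultiblockDataset,
                   design: str | DesignSpec = "sequential",
                   scheme: str = "centroid",
                   sparsity_grid: Optional[Dict[str, Sequence[float]]] = None,
                   k: int = 5, seed: int = 0,
                   residualize_in_fold: bool = True,
                   inner_k: int = 3, robust_min: int = 3,
                   tol: float = 1e-8, max_iter: int = 1000) -> CVReport:
    """External stratified k-fold CV with inner sparsity tuning per fold.

    ``sparsity_grid`` maps block name -> candidate dials; defaults to 5
    log-spaced values per data block.  Inner tuning minimizes inner-CV error
    over the joint grid, ties broken toward the sparser combination.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    block_names = dataset.block_names
    if isinstance(design, str):
        design = build_design(design, block_order=(*block_names, "dx"))
    y = dataset.y()
    if min(np.bincount(y)) < k:
        raise ValueError(
            f"smallest class ({min(np.bincount(y))}) cannot stratify {k} folds; "
            "use a smaller k")
    if sparsity_grid is None:
        sparsity_grid = {
            name: default_sparsity_grid(dataset.blocks[name].shape[1])
            for name in block_names
        }
    grids = [np.sort(np.asarray(sparsity_grid[name], dtype=float))
             for name in block_names]
    combos = sorted(itertools.product(*grids),
                    key=lambda c: (sum(c), c))  # sparser combinations first

    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: List[FoldRecord] = []
    for fold_i, (train, test) in enumerate(outer.split(np.zeros(len(y)), y)):
        best = None
        if len(combos) > 1:
            inner = StratifiedKFold(n_splits=inner_k, shuffle=True,
                                    random_state=seed + 1)
            inner_sets = []
            for itr, iva in inner.split(np.zeros(len(train)), y[train]):
                tr, va = train[itr], train[iva]
                tb, vb = _preprocess_fold(dataset, block_names, tr, va,
                                          residualize_in_fold)
                inner_sets.append((tb, vb, y[tr], y[va]))
            for combo in combos:
                sparsity = (*combo, None)
                errs = [
                    _fit_and_score(tb, vb, ytr, yva, design, scheme, sparsity,
                                   tol, max_iter, seed)[1]
                    for tb, vb, ytr, yva in inner_sets
                ]
                mean_err = float(np.mean(errs))
                if best is None or mean_err < best[0]:
                    best = (mean_err, combo)
            chosen = best[1]
        else:
            chosen = combos[0]

        train_blocks, test_blocks = _preprocess_fold(
            dataset, block_names, train, test, residualize_in_fold)
        est, error = _fit_and_score(train_blocks, test_blocks, y[train], y[test],
                                    design, scheme, (*chosen, None),
                                    tol, max_iter, seed)
        folds.append(FoldRecord(train_idx=train, test_idx=test,
                                sparsity=tuple(chosen), fit=est.result(),
                                error=error))

    return CVReport(
        k=k, design=design, folds=folds,
        block_variables={name: list(dataset.blocks[name].columns)
                         for name in block_names},
        robust_min=robust_min,
        meta={"scheme": scheme, "seed": seed,
              "residualize_in_fold": residualize_in_fold},
    )


def compare_designs(dataset: MultiblockDataset, designs: Sequence[str],
                    scheme: str = "centroid",
                    sparsity_grid: Optional[Dict[str, Sequence[float]]] = None,
                    k: int = 5, seeds: Sequence[int] = (0,),
                    **cv_kwargs) -> pd.DataFrame:
    """Fold-level error rates per candidate design, for boxplot-style comparison.

    Returns a tidy frame (design, seed, fold, error); the minimum-mean-error
    design is recoverable with :func:`preferred_design`.
    """
    if len(designs) < 1:
        raise ValueError("at least one design required")
    rows = []
    for name in designs:
        for seed in seeds:
            report = cross_validate(dataset, design=name, scheme=scheme,
                                    sparsity_grid=sparsity_grid, k=k,
                                    seed=seed, **cv_kwargs)
            for i, rec in enumerate(report.folds):
                rows.append((name, seed, i, rec.error))
    return pd.DataFrame(rows, columns=["design", "seed", "fold", "error"])


def preferred_design(error_table: pd.DataFrame) -> str:
    """Design with the lowest mean fold error (first listed wins ties)."""
    means = error_table.groupby("design", sort=False)["error"].mean()
    return str(means.idxmin())
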