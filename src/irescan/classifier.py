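"""Degree-2 polynomial-kernel SVM with Platt posteriors and CV metrics.

The classifier is a soft-margin kernel SVM with a second-order polynomial
kernel and asymmetric misclassification costs of 2:1 (positive : negative),
which trades specificity for sensitivity on the rare positive class.
Decision values are mapped to class posteriors P(IRES | x) with Platt's
sigmoid 1 / (1 + exp(A f(x) + B)), fitted by regularized maximum likelihood
with Platt's target smoothing.  Model selection uses repeated stratified
k-fold cross-validation over a 32-point (gamma, C) grid, scored by mean
accuracy with Cohen's kappa as tie-break.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score, confusion_matrix
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

#: 8 kernel scales x 4 costs = the 32 tuning combinations.
DEFAULT_GAMMA_GRID = [2.0 ** e for e in range(-9, -1)]
DEFAULT_C_GRID = [0.25, 1.0, 4.0, 16.0]

DEFAULT_DEGREE = 2
DEFAULT_COST_RATIO = 2.0  # positive : negative misclassification cost


@dataclass(frozen=True)
class SvmParams:
    gamma: float = 0.01
    C: float = 1.0
    degree: int = DEFAULT_DEGREE
    coef0: float = 1.0
    cost_ratio: float = DEFAULT_COST_RATIO

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma, "C": self.C, "degree": self.degree,
            "coef0": self.coef0, "cost_ratio": self.cost_ratio,
        }


def default_grid() -> list[SvmParams]:
    return [
        SvmParams(gamma=g, C=c)
        for g in DEFAULT_GAMMA_GRID
        for c in DEFAULT_C_GRID
    ]


def train_svm(X: np.ndarray, y: np.ndarray, params: SvmParams) -> SVC:
    """Fit the weighted polynomial-kernel SVM; deterministic given inputs."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    svc = SVC(
        kernel="poly",
        degree=params.degree,
        gamma=params.gamma,
        coef0=params.coef0,
        C=params.C,
        class_weight={1: params.cost_ratio, 0: 1.0},
    )
    svc.fit(np.asarray(X, dtype=float), y)
    return svc


# ---------------------------------------------------------------------------
# Platt calibration

def platt_calibrate(
    decision_values: np.ndarray,
    labels: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[float, float]:
    """Fit sigmoid parameters (A, B) so P(y=1|f) = 1/(1 + exp(A f + B)).

    Regularized maximum likelihood with Platt's smoothed targets
    t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2), optimized by Newton's method
    with backtracking line search to gradient norm < *tol*.
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("Platt calibration needs both classes")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll_grad_hess(a: float, b: float):
        z = a * f + b
        # stable log(1+exp(z)) and sigmoid pieces
        p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
        lse = np.where(z >= 0, z + np.log1p(np.exp(-z)), np.log1p(np.exp(z)))
        nll = float(np.sum(t * z + lse - z))  # -sum t log p + (1-t) log(1-p)
        d = t - p
        g = np.array([np.sum(d * f), np.sum(d)])
        w = p * (1 - p)
        h = np.array(
            [[np.sum(w * f * f), np.sum(w * f)], [np.sum(w * f), np.sum(w)]]
        )
        return nll, g, h

    a, b = 0.0, float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    nll, g, h = nll_grad_hess(a, b)
    for _ in range(max_iter):
        if np.linalg.norm(g) < tol:
            return a, b
        step = np.linalg.solve(h + 1e-12 * np.eye(2), g)
        stepsize = 1.0
        while stepsize > 1e-10:
            na, nb = a - stepsize * step[0], b - stepsize * step[1]
            n_nll, n_g, n_h = nll_grad_hess(na, nb)
            if n_nll < nll + 1e-12:
                a, b, nll, g, h = na, nb, n_nll, n_g, n_h
                break
            stepsize /= 2.0
        else:
            break
    if np.linalg.norm(g) >= tol:
        raise RuntimeError(
            f"Platt calibration did not converge in {max_iter} iterations "
            f"(|grad| = {np.linalg.norm(g):.2e})"
        )
    return a, b


def platt_posterior(decision_values: np.ndarray, a: float, b: float) -> np.ndarray:
    """P(positive | f) under the fitted sigmoid, strictly inside (0, 1)."""
    z = a * np.asarray(decision_values, dtype=float) + b
    p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
    return np.clip(p, 1e-15, 1 - 1e-15)


# ---------------------------------------------------------------------------
# metrics

def confusion_metrics(y_true, y_pred) -> dict[str, float]:
    """Accuracy, Cohen's kappa, sensitivity (TPR) and specificity (TNR)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    return {
        "accuracy": (tp + tn) / y_true.size,
        "kappa": float(cohen_kappa_score(y_true, y_pred, labels=[0, 1])),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def estimate_empirical_fdr(
    n_pos_calls_on_negative_control: int, n_pos_calls_on_utrs: int
) -> float:
    """Empirical FDR (%) = 100 x positive calls on the (assumed IRES-free)
    negative-control windows / positive calls on the UTR windows."""
    if n_pos_calls_on_utrs <= 0:
        raise ValueError("no positive calls on the UTR set: FDR undefined")
    if n_pos_calls_on_negative_control < 0:
        raise ValueError("negative count")
    return 100.0 * n_pos_calls_on_negative_control / n_pos_calls_on_utrs


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CVReport:
    """Per-combination CV means and the chosen parameter set."""

    table: pd.DataFrame  # columns: gamma, C, degree, coef0, accuracy, kappa
    chosen: SvmParams
    folds: int
    repeats: int
    seed: int | None = None

    @property
    def best_accuracy(self) -> float:
        return float(self.table["accuracy"].max())


def grid_search_cv(
    X: np.ndarray,
    y: np.ndarray,
    grid: list[SvmParams] | None = None,
    folds: int = 10,
    repeats: int = 30,
    seed: int | None = None,
) -> CVReport:
    """Repeated stratified k-fold CV over *grid*; best = max mean accuracy,
    kappa then grid order as tie-breaks."""
    grid = grid if grid is not None else default_grid()
    if not grid:
        raise ValueError("empty parameter grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    class_min = int(np.bincount(y).min())
    if folds > class_min:
        raise ValueError(f"{folds} folds infeasible with a class of {class_min}")
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    splits = list(cv.split(X, y))
    rows = []
    for params in grid:
        accs, kappas = [], []
        for train_idx, test_idx in splits:
            svc = train_svm(X[train_idx], y[train_idx], params)
            m = confusion_metrics(y[test_idx], svc.predict(X[test_idx]))
            accs.append(m["accuracy"])
            kappas.append(m["kappa"])
        rows.append(
            {**params.to_dict(), "accuracy": float(np.mean(accs)),
             "kappa": float(np.mean(kappas))}
        )
    table = pd.DataFrame(rows)
    order = np.lexsort((-table.index.to_numpy(), table["kappa"], table["accuracy"]))
    best = grid[int(order[-1])]
    return CVReport(table=table, chosen=best, folds=folds, repeats=repeats, seed=seed)


@dataclass
class PredictionSet:
    """Per-gene predicted labels and IRES-class posteriors."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: gene_id, organism_id, label (0/1), posterior

    @property
    def n_positive(self) -> int:
        return int((self.frame["label"] == 1).sum())

    def positives(self) -> pd.DataFrame:
        return self.frame[self.frame["label"] == 1]
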