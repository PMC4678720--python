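"""Model/Results facade over the full IRES-classification fit.

``IresModel`` is built from a feature table (one row per gene, the 29
canonical features plus ``gene_id``/``organism_id``/``og_id``) and a
boolean training label per row.  ``fit()`` runs the whole estimation chain —
per-organism standardization, correlation pruning, SMOTE/undersampling
balancing, optional (gamma, C) grid search by repeated stratified CV, final
SVM fit and Platt calibration — and returns an ``IresResults`` carrying the
fitted state, CV diagnostics and a ``summary()`` table.  ``predict()`` on
the results applies the persisted standardization and retained-feature list
to new feature tables.

Cross-validation is run on the balanced (post-oversampling) set by default,
mirroring the original protocol; this leaks synthetic-neighbor information
across folds and therefore flatters the CV estimates.  Set
``rebalance_within_folds=True`` to balance inside each training fold
instead and score on untouched held-out originals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import balance as _balance
from . import classifier as _clf
from . import preprocess as _pre
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)


@dataclass
class IresConfig:
    """Tunable parameters of the estimation chain (reference defaults)."""

    correlation_threshold: float = _pre.CORRELATION_THRESHOLD
    n_pos_out: int = _balance.DEFAULT_N_POSITIVE
    n_neg_out: int = _balance.DEFAULT_N_NEGATIVE
    smote_k: int = _balance.DEFAULT_K
    degree: int = _clf.DEFAULT_DEGREE
    coef0: float = 1.0
    cost_ratio: float = _clf.DEFAULT_COST_RATIO
    gamma: float = 0.01
    C: float = 1.0
    folds: int = 10
    repeats: int = 30
    rebalance_within_folds: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class IresModel:
    """IRES classification model over a 29-feature gene table."""

    def __init__(
        self,
        features: pd.DataFrame,
        labels: np.ndarray | pd.Series,
        config: IresConfig | None = None,
        seed: int | None = None,
    ):
        missing = set(FEATURE_NAMES) - set(features.columns)
        if missing:
            raise ValueError(f"feature table missing columns {sorted(missing)}")
        self.features = features.reset_index(drop=True)
        self.labels = np.asarray(labels).astype(int)
        if self.labels.shape[0] != len(self.features):
            raise ValueError("labels and feature table differ in length")
        self.config = config or IresConfig()
        self.seed = seed

    @classmethod
    def from_feature_table(
        cls,
        features: pd.DataFrame,
        positive_genes: set[str],
        config: IresConfig | None = None,
        seed: int | None = None,
    ) -> "IresModel":
        """Labels derived from a set of known-positive gene ids; all other
        rows are treated as (sampled) negatives."""
        labels = features["gene_id"].isin(positive_genes).to_numpy().astype(int)
        if labels.sum() == 0:
            raise ValueError("no positive gene id found in the feature table")
        return cls(features, labels, config=config, seed=seed)

    def fit(self, grid_search: bool = False, cv: bool = True) -> "IresResults":
        cfg = self.config
        rng = np.random.default_rng(self.seed)

        std_df, std_params = _pre.standardize_per_organism(self.features)
        retained = _pre.prune_correlated(
            std_df, threshold=cfg.correlation_threshold
        )
        X = std_df[retained.kept].to_numpy(dtype=float)
        y = self.labels

        training = _balance.build_training_set(
            X, y, n_pos_out=cfg.n_pos_out, n_neg_out=cfg.n_neg_out,
            k=cfg.smote_k, rng=rng, seed=self.seed,
        )

        params = _clf.SvmParams(
            gamma=cfg.gamma, C=cfg.C, degree=cfg.degree,
            coef0=cfg.coef0, cost_ratio=cfg.cost_ratio,
        )
        cv_seed = int(rng.integers(2 ** 31 - 1))
        cv_report = None
        if grid_search:
            cv_report = _clf.grid_search_cv(
                training.X, training.y, folds=cfg.folds,
                repeats=cfg.repeats, seed=cv_seed,
            )
            params = _clf.SvmParams(
                gamma=cv_report.chosen.gamma, C=cv_report.chosen.C,
                degree=cfg.degree, coef0=cfg.coef0, cost_ratio=cfg.cost_ratio,
            )
        elif cv:
            if cfg.rebalance_within_folds:
                cv_report = _rebalanced_cv(X, y, cfg, params, cv_seed)
            else:
                cv_report = _clf.grid_search_cv(
                    training.X, training.y, grid=[params], folds=cfg.folds,
                    repeats=cfg.repeats, seed=cv_seed,
                )

        svc = _clf.train_svm(training.X, training.y, params)
        decisions = svc.decision_function(training.X)
        platt_a, platt_b = _clf.platt_calibrate(decisions, training.y)

        return IresResults(
            model=self,
            svc=svc,
            params=params,
            platt_a=platt_a,
            platt_b=platt_b,
            standardization=std_params,
            retained=retained,
            training=training,
            cv_report=cv_report,
            seed=self.seed,
        )


def _rebalanced_cv(
    X: np.ndarray, y: np.ndarray, cfg: IresConfig,
    params: _clf.SvmParams, seed: int,
) -> _clf.CVReport:
    """Leakage-free CV: balance inside each training fold, score on the
    untouched held-out originals."""
    from sklearn.model_selection import RepeatedStratifiedKFold

    n_pos = int((y == 1).sum())
    folds = min(cfg.folds, n_pos)
    if folds < 2:
        raise ValueError("rebalanced CV needs at least 2 positives")
    cv = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=cfg.repeats, random_state=seed
    )
    rng = np.random.default_rng(seed)
    accs, kappas = [], []
    for train_idx, test_idx in cv.split(X, y):
        y_tr = y[train_idx]
        frac = len(train_idx) / len(y)
        training = _balance.build_training_set(
            X[train_idx], y_tr,
            n_pos_out=max(int(cfg.n_pos_out * frac), int(y_tr.sum()) + 1),
            n_neg_out=min(int(cfg.n_neg_out * frac), int((y_tr == 0).sum())),
            k=cfg.smote_k, rng=rng,
        )
        svc = _clf.train_svm(training.X, training.y, params)
        m = _clf.confusion_metrics(y[test_idx], svc.predict(X[test_idx]))
        accs.append(m["accuracy"])
        kappas.append(m["kappa"])
    table = pd.DataFrame(
        [{**params.to_dict(), "accuracy": float(np.mean(accs)),
          "kappa": float(np.mean(kappas))}]
    )
    return _clf.CVReport(
        table=table, chosen=params, folds=folds, repeats=cfg.repeats, seed=seed
    )


@dataclass
class IresResults:
    """Fitted state + diagnostics of an :class:`IresModel`."""

    model: IresModel
    svc: object
    params: _clf.SvmParams
    platt_a: float
    platt_b: float
    standardization: _pre.StandardizationParams
    retained: _pre.RetainedFeatureSet
    training: _balance.BalancedTrainingSet
    cv_report: _clf.CVReport | None
    seed: int | None

    # -- prediction ---------------------------------------------------------
    def _design(self, features: pd.DataFrame) -> np.ndarray:
        std = _pre.apply_standardization(features, self.standardization)
        return std[self.retained.kept].to_numpy(dtype=float)

    def decision_function(self, features: pd.DataFrame) -> np.ndarray:
        return self.svc.decision_function(self._design(features))

    def predict(self, features: pd.DataFrame) -> _clf.PredictionSet:
        """Labels and IRES-class posteriors for a new feature table."""
        f = self.decision_function(features)
        posterior = _clf.platt_posterior(f, self.platt_a, self.platt_b)
        frame = pd.DataFrame(
            {
                "gene_id": features["gene_id"].to_numpy(),
                "organism_id": features["organism_id"].to_numpy(),
                "label": (posterior >= 0.5).astype(int),
                "posterior": posterior,
            }
        )
        return _clf.PredictionSet(frame=frame)

    # -- reporting ----------------------------------------------------------
    @property
    def cv_metrics(self) -> dict[str, float] | None:
        if self.cv_report is None:
            return None
        best = self.cv_report.table.sort_values(
            ["accuracy", "kappa"], ascending=False
        ).iloc[0]
        return {"accuracy": float(best["accuracy"]), "kappa": float(best["kappa"])}

    def training_metrics(self) -> dict[str, float]:
        return _clf.confusion_metrics(
            self.training.y, self.svc.predict(self.training.X)
        )

    def feature_mean_gaps(self) -> pd.Series:
        """Per-feature standardized mean(positive) - mean(negative) on the
        balanced training set — a descriptive contribution report."""
        Xp = self.training.X[self.training.y == 1]
        Xn = self.training.X[self.training.y == 0]
        return pd.Series(Xp.mean(axis=0) - Xn.mean(axis=0), index=self.retained.kept)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "IRES classification model (polynomial-kernel SVM)",
            "=" * 52,
            f"observations        : {len(self.model.features)}",
            f"original positives  : {int(self.model.labels.sum())}",
            f"balanced set        : {len(self.training)} rows "
            f"({cfg.n_pos_out} pos : {cfg.n_neg_out} neg, "
            f"ratio {self.training.ratio:.2f}:1)",
            f"SMOTE k             : requested {self.training.k_requested}, "
            f"effective {self.training.k_effective}",
            f"features retained   : {len(self.retained.kept)} of "
            f"{len(FEATURE_NAMES)} (|r| > {cfg.correlation_threshold})",
            f"kernel              : poly degree {self.params.degree}, "
            f"gamma {self.params.gamma:g}, coef0 {self.params.coef0:g}, "
            f"C {self.params.C:g}, cost {self.params.cost_ratio:g}:1",
            f"Platt (A, B)        : ({self.platt_a:.4f}, {self.platt_b:.4f})",
        ]
        if self.cv_report is not None:
            m = self.cv_metrics
            lines.append(
                f"CV ({self.cv_report.folds}-fold x {self.cv_report.repeats}) : "
                f"accuracy {m['accuracy']:.3f}, kappa {m['kappa']:.3f}"
            )
        tm = self.training_metrics()
        lines.append(
            f"training fit        : accuracy {tm['accuracy']:.3f}, "
            f"sensitivity {tm['sensitivity']:.3f}, "
            f"specificity {tm['specificity']:.3f}"
        )
        lines.append(f"seed                : {self.seed}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------
    def manifest(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "platt": {"A": self.platt_a, "B": self.platt_b},
            "retained_features": self.retained.to_dict(),
            "standardization": self.standardization.to_dict(),
            "config": self.model.config.to_dict(),
            "seed": self.seed,
            "smote_k_effective": self.training.k_effective,
        }

    def save(self, path) -> None:
        """Persist the fitted model (joblib) plus a JSON manifest."""
        import joblib

        joblib.dump(self, path)
        with open(str(path) + ".manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=1, default=str)

    @staticmethod
    def load(path) -> "IresResults":
        import joblib

        return joblib.load(path)
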