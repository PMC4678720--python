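"""Per-organism feature standardization and correlation-based pruning.

Standardization is fitted per organism (inter-species comparability: each
feature gets mean 0 / sd 1 within every organism) and the fitted parameters
are persisted with the model so prediction-time data is rescaled with the
training-population statistics.  Correlated features are then dropped with a
single greedy pass over the pooled standardized matrix at |r| > 0.55,
keeping the earlier feature in canonical order — deterministic and
auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

CORRELATION_THRESHOLD = 0.55


@dataclass
class StandardizationParams:
    """Fitted (mean, sd) per (organism, feature); sample sd (n-1)."""

    means: pd.DataFrame  # index organism, columns features
    sds: pd.DataFrame

    def to_dict(self) -> dict:
        return {"means": self.means.to_dict(), "sds": self.sds.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        means = pd.DataFrame(d["means"]).rename_axis("organism_id")
        sds = pd.DataFrame(d["sds"]).rename_axis("organism_id")
        return cls(means=means, sds=sds)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "StandardizationParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def standardize_per_organism(
    df: pd.DataFrame,
    feature_cols: list[str] | None = None,
    organism_col: str = "organism_id",
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Fit and apply per-organism standardization.

    Features that are constant within an organism (sd = 0) map to 0 and are
    logged.  An organism contributing a single gene is an error: its variance
    is undefined.
    """
    feature_cols = feature_cols or [c for c in FEATURE_NAMES if c in df.columns]
    sizes = df.groupby(organism_col).size()
    singletons = sizes[sizes < 2]
    if len(singletons):
        raise ValueError(
            f"organism(s) {list(singletons.index)} have a single gene; "
            "per-organism variance is undefined"
        )
    grouped = df.groupby(organism_col)[feature_cols]
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    n_degenerate = int((sds == 0).to_numpy().sum())
    if n_degenerate:
        logger.warning(
            "%d (organism, feature) pairs are constant; standardized to 0",
            n_degenerate,
        )
    params = StandardizationParams(means=means, sds=sds)
    return apply_standardization(df, params, feature_cols, organism_col), params


def apply_standardization(
    df: pd.DataFrame,
    params: StandardizationParams,
    feature_cols: list[str] | None = None,
    organism_col: str = "organism_id",
) -> pd.DataFrame:
    """Rescale *df* with previously fitted per-organism parameters."""
    feature_cols = feature_cols or [c for c in params.means.columns if c in df.columns]
    unknown = set(df[organism_col]) - set(params.means.index)
    if unknown:
        raise ValueError(f"no standardization parameters for organism(s) {sorted(unknown)}")
    out = df.copy()
    mu = params.means.loc[df[organism_col], feature_cols].to_numpy()
    sd = params.sds.loc[df[organism_col], feature_cols].to_numpy()
    vals = df[feature_cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mu) / sd
    z[~np.isfinite(z)] = 0.0  # sd == 0 -> degenerate feature maps to 0
    out[feature_cols] = z
    return out


@dataclass
class RetainedFeatureSet:
    """Kept features after correlation pruning, plus the audit trail."""

    kept: list[str]
    dropped: list[str] = field(default_factory=list)
    audit: list[tuple[str, str, float]] = field(default_factory=list)  # (dropped, kept-because-of, r)

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "dropped": self.dropped,
            "audit": [list(a) for a in self.audit],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RetainedFeatureSet":
        return cls(
            kept=list(d["kept"]), dropped=list(d["dropped"]),
            audit=[tuple(a) for a in d["audit"]],
        )


def prune_correlated(
    df: pd.DataFrame,
    feature_cols: list[str] | None = None,
    threshold: float = CORRELATION_THRESHOLD,
) -> RetainedFeatureSet:
    """Greedy correlation pruning on the pooled (standardized) matrix.

    For each ordered pair (i < j) in canonical order with |Pearson r| >
    *threshold*, feature j is dropped if both are still retained.  Constant
    columns have undefined correlations, treated as uncorrelated.
    """
    feature_cols = feature_cols or [c for c in FEATURE_NAMES if c in df.columns]
    corr = df[feature_cols].corr().to_numpy()
    corr = np.nan_to_num(corr, nan=0.0)
    retained = list(feature_cols)
    dropped: list[str] = []
    audit: list[tuple[str, str, float]] = []
    alive = dict.fromkeys(feature_cols, True)
    for i, fi in enumerate(feature_cols):
        if not alive[fi]:
            continue
        for j in range(i + 1, len(feature_cols)):
            fj = feature_cols[j]
            if alive[fj] and abs(corr[i, j]) > threshold:
                alive[fj] = False
                dropped.append(fj)
                audit.append((fj, fi, float(corr[i, j])))
    retained = [f for f in feature_cols if alive[f]]
    logger.info(
        "correlation pruning at |r| > %.2f: %d of %d features retained",
        threshold, len(retained), len(feature_cols),
    )
    return RetainedFeatureSet(kept=retained, dropped=dropped, audit=audit)
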