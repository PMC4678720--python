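"""Orthologous-group and term enrichment, and the prediction-ranking score.

Over-representation of positive predictions in an orthologous group is
scored with the one-sided (upper-tail) Fisher exact test: with K positive
predictions among N analyzable genes, a group of n members containing k
positives has p = sum_{i >= k} Hypergeom(i; N, K, n).  Group p-values are
corrected with the Benjamini-Hochberg step-up procedure over the tested
groups.

Ranked predictions combine classifier confidence and group conservation:
score = (1 - posterior) x group p, lower is better, with a default
threshold of 0.05 defining the top set.  Only SVM-positive genes are ranked.
The complement (1 - posterior) is used so that confident predictions in
enriched groups score lowest; a literal variant multiplying the posterior
itself is available via ``use_complement=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genome_io import OrthologTable

logger = logging.getLogger(__name__)

DEFAULT_OG_FDR = 0.05
DEFAULT_RANK_THRESHOLD = 0.05


def fisher_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): over-representation p-value.

    k = positives in the group, n = group size, K = total positives,
    N = universe size.  Computed from the survival function (log-space
    internally), never exactly 0.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent 2x2 table (k={k}, n={n}, K={K}, N={N})")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 5e-324), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    group: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_adj: float
    significant: bool


def og_enrichment(
    positive_genes: set[str],
    orthologs: OrthologTable,
    universe: set[str],
    fdr: float = DEFAULT_OG_FDR,
    family: str = "tested",
) -> pd.DataFrame:
    """Fisher enrichment of positive predictions per orthologous group.

    One row per group containing at least one positive prediction; the BH
    family size is the number of tested groups (``family='tested'``) or all
    groups with members in the universe (``family='all'``).
    """
    if not positive_genes <= universe:
        raise ValueError("positive predictions outside the universe")
    N = len(universe)
    K = len(positive_genes)
    rows = []
    tested_all = 0
    for og in orthologs.groups:
        members = [g for g in orthologs.members(og) if g in universe]
        if not members:
            continue
        tested_all += 1
        k = sum(g in positive_genes for g in members)
        if k == 0:
            continue
        n = len(members)
        rows.append(
            {"group": og, "k": k, "n": n, "K": K, "N": N,
             "p_raw": fisher_upper_tail(k, n, K, N)}
        )
    df = pd.DataFrame(rows, columns=["group", "k", "n", "K", "N", "p_raw"])
    if df.empty:
        df["p_adj"] = df["significant"] = []
        return df
    if family == "tested":
        df["p_adj"] = bh_adjust(df["p_raw"])
    elif family == "all":
        # groups with zero positives carry p = 1 and only enlarge the family
        padded = np.concatenate(
            [df["p_raw"].to_numpy(), np.ones(tested_all - len(df))]
        )
        df["p_adj"] = bh_adjust(padded)[: len(df)]
    else:
        raise ValueError(f"unknown BH family {family!r}")
    df["significant"] = df["p_adj"] < fdr
    return df.sort_values("p_raw", ignore_index=True)


@dataclass
class RankedPrediction:
    gene_id: str
    posterior: float
    group_p: float
    score: float
    is_top: bool


def rank_predictions(
    predictions: pd.DataFrame,
    enrichment: pd.DataFrame,
    orthologs: OrthologTable,
    threshold: float = DEFAULT_RANK_THRESHOLD,
    use_adjusted: bool = True,
    use_complement: bool = True,
) -> pd.DataFrame:
    """Rank SVM-positive genes by (1 - posterior) x group enrichment p.

    *predictions* needs columns gene_id, label, posterior.  Genes whose
    group has no enrichment record (or that have no group) use group p = 1.
    Returns a frame sorted ascending by score with an ``is_top`` flag at
    ``score <= threshold``.
    """
    pcol = "p_adj" if use_adjusted else "p_raw"
    group_p = dict(zip(enrichment["group"], enrichment[pcol]))
    pos = predictions[predictions["label"] == 1]
    rows = []
    for row in pos.itertuples(index=False):
        og = orthologs.og_of(row.gene_id)
        gp = float(group_p.get(og, 1.0)) if og is not None else 1.0
        conf = (1.0 - row.posterior) if use_complement else row.posterior
        score = conf * gp
        rows.append(
            {"gene_id": row.gene_id, "posterior": row.posterior,
             "group_p": gp, "score": score, "is_top": score <= threshold}
        )
    out = pd.DataFrame(
        rows, columns=["gene_id", "posterior", "group_p", "score", "is_top"]
    )
    return out.sort_values("score", ignore_index=True)


def set_overlap_test(
    set_a: set[str], set_b: set[str], universe_size: int
) -> float:
    """One-sided Fisher p for the overlap of two gene sets."""
    if universe_size < len(set_a | set_b):
        raise ValueError("universe smaller than the union of the sets")
    k = len(set_a & set_b)
    return fisher_upper_tail(k=k, n=len(set_b), K=len(set_a), N=universe_size)


def term_enrichment(
    foreground: set[str],
    gene_terms: dict[str, set[str]],
    universe: set[str],
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Flat-map term enrichment (no ontology DAG semantics).

    *gene_terms* maps gene id -> set of term ids.  Per-term one-sided Fisher
    tests against the universe, BH-corrected over all terms annotated in the
    universe.
    """
    if not foreground <= universe:
        raise ValueError("foreground genes outside the universe")
    term_members: dict[str, set[str]] = {}
    for gene in universe:
        for term in gene_terms.get(gene, ()):
            term_members.setdefault(term, set()).add(gene)
    N, K = len(universe), len(foreground)
    rows = []
    for term, members in sorted(term_members.items()):
        k = len(members & foreground)
        rows.append(
            {"term": term, "k": k, "n": len(members), "K": K, "N": N,
             "p_raw": fisher_upper_tail(k, len(members), K, N)}
        )
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p_raw"])
    if df.empty:
        df["p_adj"] = df["significant"] = []
        return df
    df["p_adj"] = bh_adjust(df["p_raw"])
    df["significant"] = df["p_adj"] < fdr_threshold
    return df.sort_values("p_raw", ignore_index=True)
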