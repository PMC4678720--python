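"""PPI network density statistics, null simulation and module detection.

The question asked of the interaction network is whether the gene products
of the top predictions are more functionally cohesive than chance: the
observed density (2E / n(n-1)) of the induced subgraph is compared with the
density distribution of equally sized uniform random gene samples drawn
from the full protein-coding gene list.  Sampled genes absent from the
interaction data count as isolated nodes (they dilute density), so the null
is over genes, not over network nodes.  Replicate densities are Box-Cox
transformed toward normality and the upper-tail normal probability of the
transformed observation is the p-value.

Modules come from Louvain multi-level modularity optimization; per-module
density is tested against the same null at the module's size.  Size-1
modules have undefined density and are flagged excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, special
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 400
DEFAULT_NULL_REPS = 10_000


def load_interactions(path, min_score: int = DEFAULT_MIN_SCORE) -> nx.Graph:
    """Read a STRING-style TSV (node1, node2, combined_score) into an
    undirected simple graph.

    Edges below *min_score* are dropped, self-loops removed, duplicate
    edges merged keeping the maximum score.
    """
    df = pd.read_csv(path, sep="\t", dtype={"combined_score": int})
    required = {"node1", "node2", "combined_score"}
    if missing := required - set(df.columns):
        raise ValueError(f"interaction file {path}: missing columns {sorted(missing)}")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        a, b, s = str(row.node1), str(row.node2), int(row.combined_score)
        if a == b or s < min_score:
            continue
        if g.has_edge(a, b):
            g[a][b]["combined_score"] = max(g[a][b]["combined_score"], s)
        else:
            g.add_edge(a, b, combined_score=s)
    return g


def density(graph: nx.Graph) -> float:
    """2E / (n(n-1)) of an undirected simple graph; needs >= 2 nodes."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return nx.density(graph)


@dataclass
class NullDensityModel:
    """Simulated density null for gene samples of size m, Box-Cox fitted."""

    m: int
    densities: np.ndarray
    shift: float
    lmbda: float
    transformed_mean: float
    transformed_sd: float

    @property
    def mean_density(self) -> float:
        return float(self.densities.mean())


def _subgraph_density_sampler(
    graph: nx.Graph, universe: list[str]
) -> tuple[sparse.csr_matrix, dict[str, int]]:
    index = {g: i for i, g in enumerate(universe)}
    rows, cols = [], []
    for a, b in graph.edges():
        if a in index and b in index:
            rows.append(index[a])
            cols.append(index[b])
    n = len(universe)
    adj = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    return adj + adj.T, index


def boxcox_transform(samples) -> tuple[float, float, np.ndarray]:
    """(shift, lambda, transformed samples) with lambda by profile MLE.

    Box-Cox needs strictly positive data; zero densities are certain in
    sparse nulls, so a shift c is added first: c = 0 if min > 0, otherwise
    -min plus half the smallest positive sample (1e-6 if all samples are
    equal to the minimum <= 0).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples for Box-Cox fitting")
    if x.min() == x.max():
        raise ValueError("constant samples: Box-Cox transform undefined")
    if x.min() > 0:
        shift = 0.0
    else:
        positive = x[x > x.min()] - x.min()
        shift = -x.min() + (positive.min() / 2.0 if positive.size else 1e-6)
    transformed, lmbda = sps.boxcox(x + shift)
    return float(shift), float(lmbda), transformed


def simulate_null_density(
    graph: nx.Graph,
    universe: list[str],
    m: int,
    reps: int = DEFAULT_NULL_REPS,
    rng: np.random.Generator | None = None,
    fit_boxcox: bool = True,
) -> NullDensityModel:
    """Null density distribution of uniform m-gene samples from *universe*.

    Genes missing from the interaction data enter as isolated nodes.
    """
    if m < 2:
        raise ValueError("subgraph size must be at least 2")
    if m > len(universe):
        raise ValueError("sample size exceeds the universe")
    rng = rng or np.random.default_rng()
    adj, _ = _subgraph_density_sampler(graph, list(universe))
    n_pairs = m * (m - 1) / 2.0
    densities = np.empty(reps)
    n_universe = adj.shape[0]
    for r in range(reps):
        idx = rng.choice(n_universe, size=m, replace=False)
        e = adj[idx][:, idx].nnz / 2.0
        densities[r] = e / n_pairs
    if fit_boxcox and densities.min() != densities.max():
        shift, lmbda, transformed = boxcox_transform(densities)
        t_mean, t_sd = float(transformed.mean()), float(transformed.std(ddof=1))
    else:
        shift, lmbda, t_mean, t_sd = 0.0, 1.0, float(densities.mean()), float(
            densities.std(ddof=1)
        )
    return NullDensityModel(
        m=m, densities=densities, shift=shift, lmbda=lmbda,
        transformed_mean=t_mean, transformed_sd=t_sd,
    )


def density_pvalue(observed: float, null: NullDensityModel) -> float:
    """Upper-tail normal p of the Box-Cox-transformed observed density."""
    if null.transformed_sd <= 0:
        raise ValueError("degenerate null (zero variance)")
    x = observed + null.shift
    if x <= 0:
        raise ValueError("observed density below the transform domain")
    t = float(special.boxcox(x, null.lmbda))
    return float(sps.norm.sf(t, loc=null.transformed_mean, scale=null.transformed_sd))


@dataclass
class ModulePartition:
    """Louvain partition: node -> 1-based contiguous module id."""

    assignment: dict[str, int]
    modularity: float
    seed: int | None

    @property
    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for mod in self.assignment.values():
            out[mod] = out.get(mod, 0) + 1
        return out

    def members(self, module_id: int) -> list[str]:
        return [n for n, m in self.assignment.items() if m == module_id]

    @property
    def n_modules(self) -> int:
        return len(self.sizes)


def louvain_modules(graph: nx.Graph, seed: int | None = None) -> ModulePartition:
    """Louvain multi-level modularity optimization (resolution 1, unweighted).

    Modules are numbered 1..k by decreasing size; singleton modules are
    permitted (downstream reports flag them as excluded from density tests).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    communities = nx.community.louvain_communities(graph, seed=seed, weight=None)
    communities = sorted(communities, key=lambda c: (-len(c), sorted(c)[0]))
    assignment = {
        node: i + 1 for i, comm in enumerate(communities) for node in comm
    }
    modularity = nx.community.modularity(graph, communities, weight=None)
    return ModulePartition(assignment=assignment, modularity=modularity, seed=seed)


def module_report(
    graph: nx.Graph,
    partition: ModulePartition,
    universe: list[str],
    null_reps: int = DEFAULT_NULL_REPS,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-module size/density/density-p plus per-node degrees.

    Returns (modules, degrees).  Size-1 modules are reported with
    ``excluded=True`` and NaN density.
    """
    rng = rng or np.random.default_rng()
    nulls: dict[int, NullDensityModel] = {}
    rows = []
    for module_id in sorted(partition.sizes):
        members = partition.members(module_id)
        size = len(members)
        if size < 2:
            rows.append(
                {"module": module_id, "size": size, "density": float("nan"),
                 "p_value": float("nan"), "excluded": True}
            )
            continue
        sub = graph.subgraph(members)
        d = density(sub)
        if size not in nulls:
            nulls[size] = simulate_null_density(
                graph, universe, m=size, reps=null_reps, rng=rng
            )
        try:
            p = density_pvalue(d, nulls[size])
        except ValueError:
            p = float("nan")
        rows.append(
            {"module": module_id, "size": size, "density": d,
             "p_value": p, "excluded": False}
        )
    modules = pd.DataFrame(rows)
    degrees = pd.DataFrame(
        [
            {"gene_id": node, "module": partition.assignment[node],
             "degree": deg}
            for node, deg in graph.degree()
        ]
    ).sort_values(["module", "degree"], ascending=[True, False], ignore_index=True)
    return modules, degrees
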