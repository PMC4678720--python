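"""Synthetic multi-organism genomes and fixtures with planted IRES signal.

The generator emulates the statistical structure the prediction method
assumes, so every pipeline stage is testable without external downloads:

* background DNA with composition A=T=0.30, G=C=0.20 (fungal-like AT-rich
  genomes);
* "positive" genes whose 60-nt upstream window is rewritten from an A-rich,
  GC-depleted composition (A=0.45, T=0.25, G=C=0.15) — A-enrichment gives
  the compositional signal, G/C depletion suppresses base pairing so the
  folding-energy feature also separates the classes (unstructured A-rich
  elements);
* orthologous groups spanning organisms, with the positive genes
  concentrated in a small set of planted groups (conservation signal for
  the enrichment stage);
* an extreme imbalance: only a handful of positives are exposed as
  training labels, the rest stay hidden truth.

Everything is reproducible from the master seed; byte-identical files on
re-generation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .genome_io import GeneModel, OrganismAssembly, OrthologTable

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Study-condition defaults for the synthetic genomes."""

    n_organisms: int = 3
    n_chromosomes: int = 2
    genes_per_chromosome: int = 1000
    background_composition: tuple[float, float, float, float] = (0.30, 0.20, 0.20, 0.30)  # A C G T
    positive_composition: tuple[float, float, float, float] = (0.45, 0.15, 0.15, 0.25)
    n_ortholog_groups: int = 400
    n_planted_groups: int = 5
    planted_positive_fraction: float = 0.8
    n_training_positives: int = 9
    window: int = 60
    min_gene_length: int = 300
    max_gene_length: int = 1500
    min_gap: int = 150
    max_gap: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for comp in (self.background_composition, self.positive_composition):
            if abs(sum(comp) - 1.0) > 1e-9:
                raise ValueError(f"composition {comp} does not sum to 1")
        if self.n_planted_groups > self.n_ortholog_groups:
            raise ValueError("planted groups exceed total groups")


@dataclass
class TruthManifest:
    """Ground truth accompanying a synthetic genome set."""

    labels: dict[str, int]  # gene_id -> 1 (IRES) / 0 (background)
    planted_groups: list[str]
    training_positives: list[str]
    module_truth: dict[str, int] = field(default_factory=dict)

    @property
    def positives(self) -> set[str]:
        return {g for g, v in self.labels.items() if v == 1}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "labels": self.labels,
                    "planted_groups": self.planted_groups,
                    "training_positives": self.training_positives,
                    "module_truth": self.module_truth,
                },
                fh, indent=1, sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            labels={k: int(v) for k, v in d["labels"].items()},
            planted_groups=list(d["planted_groups"]),
            training_positives=list(d["training_positives"]),
            module_truth={k: int(v) for k, v in d.get("module_truth", {}).items()},
        )


@dataclass
class SyntheticGenomes:
    assemblies: dict[str, OrganismAssembly]
    genes: list[GeneModel]
    orthologs: OrthologTable
    truth: TruthManifest
    config: SyntheticConfig


def _random_bases(rng: np.random.Generator, n: int, composition) -> np.ndarray:
    return rng.choice(BASES, size=n, p=list(composition))


def generate_genomes(
    config: SyntheticConfig | None = None, outdir: str | Path | None = None
) -> SyntheticGenomes:
    """Generate assemblies, annotations, ortholog table and truth manifest.

    With *outdir* set, writes ``{org}.fasta``, ``{org}.genes.tsv``,
    ``ortholog_groups.tsv`` and ``truth.json`` in the pipeline's input
    formats.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    og_names = [f"OG{i:05d}" for i in range(cfg.n_ortholog_groups)]
    planted = og_names[: cfg.n_planted_groups]
    planted_set = set(planted)

    assemblies: dict[str, OrganismAssembly] = {}
    genes: list[GeneModel] = []
    labels: dict[str, int] = {}
    gene_to_og: dict[str, str] = {}

    for o in range(cfg.n_organisms):
        org = f"org{o + 1}"
        chromosomes: dict[str, str] = {}
        for c in range(cfg.n_chromosomes):
            chrom_name = f"chr{c + 1}"
            parts: list[np.ndarray] = []
            pos = 0
            for g in range(cfg.genes_per_chromosome):
                gene_id = f"{org}_g{c * cfg.genes_per_chromosome + g + 1:05d}"
                og = og_names[int(rng.integers(cfg.n_ortholog_groups))]
                positive = (
                    og in planted_set
                    and rng.uniform() < cfg.planted_positive_fraction
                )
                gap = int(rng.integers(cfg.min_gap, cfg.max_gap + 1))
                gene_len = 3 * int(
                    rng.integers(cfg.min_gene_length // 3, cfg.max_gene_length // 3 + 1)
                )
                gap_seq = _random_bases(rng, gap, cfg.background_composition)
                if positive:
                    gap_seq[-cfg.window:] = _random_bases(
                        rng, cfg.window, cfg.positive_composition
                    )
                body = _random_bases(rng, gene_len, cfg.background_composition)
                body[:3] = list("ATG")
                body[-3:] = list("TAA")
                strand = "+" if rng.uniform() < 0.5 else "-"
                if strand == "+":
                    parts.extend([gap_seq, body])
                    cds_start = pos + gap + 1
                    cds_end = pos + gap + gene_len
                else:
                    # mirror layout: body then downstream gap holding the
                    # (reverse-complemented) upstream window
                    comp = dict(zip("ACGTN", "TGCAN"))
                    rc = lambda arr: np.array([comp[b] for b in arr[::-1]])
                    parts.extend([rc(body), rc(gap_seq)])
                    cds_start = pos + 1
                    cds_end = pos + gene_len
                pos += gap + gene_len
                genes.append(
                    GeneModel(
                        gene_id=gene_id, organism_id=org, chromosome=chrom_name,
                        strand=strand, cds_start=cds_start, cds_end=cds_end,
                        og_id=og,
                    )
                )
                labels[gene_id] = int(positive)
                gene_to_og[gene_id] = og
            # trailing flank so the last - strand gene keeps its window
            parts.append(_random_bases(rng, cfg.max_gap, cfg.background_composition))
            chromosomes[chrom_name] = "".join("".join(p) for p in parts)
        assemblies[org] = OrganismAssembly(organism_id=org, chromosomes=chromosomes)

    positives = sorted(g for g, v in labels.items() if v == 1)
    n_train = min(cfg.n_training_positives, len(positives))
    training_positives = sorted(
        rng.choice(positives, size=n_train, replace=False).tolist()
    )
    truth = TruthManifest(
        labels=labels, planted_groups=planted,
        training_positives=training_positives,
    )
    result = SyntheticGenomes(
        assemblies=assemblies, genes=genes,
        orthologs=OrthologTable(gene_to_og=gene_to_og),
        truth=truth, config=cfg,
    )
    if outdir is not None:
        write_genomes(result, outdir)
    return result


def write_genomes(data: SyntheticGenomes, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for org, assembly in sorted(data.assemblies.items()):
        with open(outdir / f"{org}.fasta", "w") as fh:
            for name, seq in sorted(assembly.chromosomes.items()):
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        rows = [
            {"gene_id": g.gene_id, "chromosome": g.chromosome, "strand": g.strand,
             "cds_start": g.cds_start, "cds_end": g.cds_end, "og_id": g.og_id}
            for g in data.genes if g.organism_id == org
        ]
        pd.DataFrame(rows).to_csv(outdir / f"{org}.genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(data.orthologs.gene_to_og.items()),
        columns=["gene_id", "og_id"],
    ).to_csv(outdir / "ortholog_groups.tsv", sep="\t", index=False)
    data.truth.to_json(outdir / "truth.json")


def generate_labeled_features(
    n_pos: int,
    n_neg: int,
    separation: float = 4.0,
    dims: int = 25,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-variance Gaussian classes whose means differ by *separation*
    (in sd units) along a random direction; classifier unit-test fixture."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one sample per class")
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=dims)
    direction /= np.linalg.norm(direction)
    X_neg = rng.normal(size=(n_neg, dims))
    X_pos = rng.normal(size=(n_pos, dims)) + separation * direction
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    return X, y


def generate_planted_partition(
    block_sizes: list[int],
    p_in: float,
    p_out: float,
    seed: int | None = None,
) -> tuple[nx.Graph, dict[str, int]]:
    """Stochastic block model graph plus node -> true-block truth map."""
    if not (0 <= p_out <= p_in <= 1):
        raise ValueError("need 0 <= p_out <= p_in <= 1")
    k = len(block_sizes)
    probs = [[p_in if i == j else p_out for j in range(k)] for i in range(k)]
    g = nx.stochastic_block_model(block_sizes, probs, seed=seed)
    mapping = {node: f"n{node:04d}" for node in g.nodes()}
    truth = {mapping[node]: int(g.nodes[node]["block"]) for node in g.nodes()}
    g = nx.relabel_nodes(g, mapping)
    g.graph.pop("partition", None)
    return g, truth


def labeled_feature_frame(
    X: np.ndarray, y: np.ndarray, n_organisms: int = 2
) -> pd.DataFrame:
    """Wrap a Gaussian fixture as a canonical feature table (cycled organism
    ids, no ortholog groups) so model-level code can consume it."""
    from .features import FEATURE_NAMES

    if X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"need {len(FEATURE_NAMES)} feature columns")
    df = pd.DataFrame(X, columns=FEATURE_NAMES)
    df.insert(0, "gene_id", [f"g{i:06d}" for i in range(len(df))])
    df.insert(1, "organism_id", [f"org{i % n_organisms + 1}" for i in range(len(df))])
    df.insert(2, "og_id", None)
    df["label"] = y
    return df
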