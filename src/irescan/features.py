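"""The 29 per-gene features describing a 60-nt upstream window.

Fungal cellular IRES elements are A-rich and weakly structured, so the
feature set combines: a folding-energy proxy (``mfe``); GC content of the
window relative to its intergenic region and to its chromosome
(``relGCintergenic``, ``relGCchr``); the gene's normalized distance to the
nearest chromosome end (``relPosChr``, capturing subtelomeric placement of
stress genes); the 16 overlapping dinucleotide frequencies; eight
orthologous-group dispersion statistics (mean/mode/sd/skewness of
``relGCintergenic`` and ``mfe`` over the group's members, pooled across
organisms); and the intergenic-region length.  4 + 16 + 8 + 1 = 29.

The default folding backend is an internal Nussinov-style dynamic program
maximizing total pair weight (GC=3, AU=2, GU=1) with a minimum hairpin loop
of 3 unpaired nt; it returns minus the maximal weight in arbitrary units.
Since features are standardized per organism downstream, the unit of the
energy proxy cancels.  An external backend shells out to the ViennaRNA
``RNAfold`` binary and returns thermodynamic kcal/mol when that program is
available.
"""

from __future__ import annotations

import itertools
import logging
import shutil
import subprocess
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .genome_io import (
    GeneModel,
    OrganismAssembly,
    OrthologTable,
    RegionSequence,
    compute_intergenic_region,
    extract_negative_control_window,
    extract_upstream_window,
)

logger = logging.getLogger(__name__)

DINUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=2)]

#: Canonical feature order; the contract is exactly these 29 names.
FEATURE_NAMES: list[str] = (
    ["mfe", "relGCintergenic", "relGCchr", "relPosChr"]
    + [f"dinuc_{d}" for d in DINUCLEOTIDES]
    + [
        "og_mean_relGC", "og_mode_relGC", "og_sd_relGC", "og_skew_relGC",
        "og_mean_mfe", "og_mode_mfe", "og_sd_mfe", "og_skew_mfe",
        "intergenic_length",
    ]
)

N_FEATURES = len(FEATURE_NAMES)


# ---------------------------------------------------------------------------
# sequence composition

def dinucleotide_frequencies(seq: str) -> dict[str, float]:
    """Overlapping dinucleotide frequencies over the 16 unambiguous pairs.

    Positions containing ``N`` are excluded from numerator and denominator;
    with zero unambiguous positions all 16 frequencies are 0.
    """
    if len(seq) < 2:
        raise ValueError("sequence shorter than 2 nt has no dinucleotides")
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    total = 0
    for i in range(len(seq) - 1):
        pair = seq[i:i + 2]
        if "N" in pair:
            continue
        counts[pair] += 1
        total += 1
    if total == 0:
        return dict.fromkeys(DINUCLEOTIDES, 0.0)
    return {d: c / total for d, c in counts.items()}


def gc_fraction(seq: str, pseudocount: bool = True) -> float:
    """GC fraction over unambiguous bases.

    With the (default) pseudocount the estimate is (G+C+1)/(unambiguous+2),
    which guards the zero denominators that arise in GC-free or all-N
    references downstream.
    """
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    unamb = sum(seq.count(b) for b in "ACGT")
    if pseudocount:
        return (gc + 1) / (unamb + 2)
    return gc / unamb if unamb else 0.0


def rel_gc(utr_seq: str, reference_seq: str) -> float:
    """GC content of the window relative to a reference, pseudocounted."""
    return gc_fraction(utr_seq) / gc_fraction(reference_seq)


def rel_position_chromosome(cds_start: int, cds_end: int, chromosome_length: int) -> float:
    """Normalized distance of the gene midpoint to the nearest chromosome end.

    min(midpoint - 1, L - midpoint) / L, in [0, 0.5]; near 0 means
    subtelomeric, 0.5 means dead center.
    """
    mid = (cds_start + cds_end) / 2.0
    return min(mid - 1.0, chromosome_length - mid) / chromosome_length


# ---------------------------------------------------------------------------
# folding backend

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# symmetric pair weights: GC=3, AU=2, GU=1; N pairs with nothing
_PAIR_WEIGHT = np.zeros((5, 5), dtype=np.int64)
for _a, _b, _w in [("G", "C", 3), ("A", "T", 2), ("G", "T", 1)]:
    _PAIR_WEIGHT[_BASE_CODE[_a], _BASE_CODE[_b]] = _w
    _PAIR_WEIGHT[_BASE_CODE[_b], _BASE_CODE[_a]] = _w

MIN_HAIRPIN_LOOP = 3


@njit(cache=True)
def _nussinov_best_weight(codes, pair_weight, min_loop):  # pragma: no cover - jit
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            if dp[i, j - 1] > best:
                best = dp[i, j - 1]
            w = pair_weight[codes[i], codes[j]]
            if w > 0:
                cand = dp[i + 1, j - 1] + w
                if cand > best:
                    best = cand
            for k in range(i + 1, j):
                cand = dp[i, k] + dp[k + 1, j]
                if cand > best:
                    best = cand
            dp[i, j] = best
    return dp[0, n - 1]


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE[b] for b in seq], dtype=np.int64)


def fold_mfe_internal(seq: str) -> float:
    """Minus the maximal total pair weight over all nested structures with
    hairpin loops of at least 3 unpaired nt (arbitrary units, <= 0)."""
    if len(seq) < 2:
        return 0.0
    return -float(_nussinov_best_weight(_encode(seq), _PAIR_WEIGHT, MIN_HAIRPIN_LOOP))


def fold_mfe_external(seq: str) -> float:
    """Thermodynamic MFE in kcal/mol via the ViennaRNA ``RNAfold`` binary."""
    if shutil.which("RNAfold") is None:
        raise RuntimeError("RNAfold binary not found on PATH")
    out = subprocess.run(
        ["RNAfold", "--noPS"], input=seq + "\n", capture_output=True,
        text=True, check=True,
    ).stdout
    # last line ends "... ( -3.40)"
    energy = out.strip().splitlines()[-1].rsplit("(", 1)[1].rstrip(")")
    return min(0.0, float(energy))


def fold_mfe(seq: str, backend: str = "internal") -> float:
    """Folding-energy proxy of *seq* (lower = more stable; always <= 0)."""
    if not seq:
        raise ValueError("empty sequence")
    if backend == "internal":
        return fold_mfe_internal(seq)
    if backend == "external":
        return fold_mfe_external(seq)
    raise ValueError(f"unknown folding backend {backend!r}")


# ---------------------------------------------------------------------------
# orthologous-group dispersion statistics

def histogram_mode(values: np.ndarray, bins: int = 10) -> float:
    """Mode of a continuous sample: midpoint of the most populated bin of a
    *bins*-bin histogram over [min, max]; ties go to the lowest bin."""
    values = np.asarray(values, dtype=float)
    if values.min() == values.max():
        return float(values[0])
    counts, edges = np.histogram(values, bins=bins, range=(values.min(), values.max()))
    b = int(np.argmax(counts))  # argmax takes the first (lowest) bin on ties
    return float((edges[b] + edges[b + 1]) / 2.0)


def group_statistics(values) -> tuple[float, float, float, float]:
    """(mean, mode, sd, skewness) of one feature over a group's members.

    sd is the sample standard deviation (n-1), 0 for n < 2; skewness is the
    moment coefficient g1 = m3 / m2^(3/2) (population moments), 0 for n < 3
    or zero variance.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("group_statistics of an empty group")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    m2 = float(((values - mean) ** 2).mean())
    if values.size < 3 or m2 == 0.0:
        skew = 0.0
    else:
        m3 = float(((values - mean) ** 3).mean())
        skew = m3 / m2 ** 1.5
    return mean, histogram_mode(values), sd, skew


# ---------------------------------------------------------------------------
# assembly

@dataclass(frozen=True)
class OgStats:
    """The eight per-group dispersion features shared by all group members."""

    mean_relGC: float
    mode_relGC: float
    sd_relGC: float
    skew_relGC: float
    mean_mfe: float
    mode_mfe: float
    sd_mfe: float
    skew_mfe: float


def assemble_feature_vector(
    gene: GeneModel,
    utr60: RegionSequence,
    intergenic: RegionSequence,
    chromosome_seq: str,
    og_stats: OgStats,
    mfe: float,
    chromosome_gc: float | None = None,
) -> dict[str, float]:
    """The 29 named features for one gene, in canonical order.

    *chromosome_gc* may carry the precomputed (pseudocounted) chromosomal GC
    fraction so that callers iterating over many genes scan each chromosome
    only once.
    """
    if chromosome_gc is None:
        chromosome_gc = gc_fraction(chromosome_seq)
    utr_gc = gc_fraction(utr60.sequence)
    if intergenic.length == 0:
        logger.debug(
            "gene %s: zero-length intergenic region, relGCintergenic falls back "
            "to the chromosomal reference", gene.gene_id,
        )
        rel_gc_intergenic = utr_gc / chromosome_gc
    else:
        rel_gc_intergenic = utr_gc / gc_fraction(intergenic.sequence)
    dinucs = dinucleotide_frequencies(utr60.sequence)
    vec = {
        "mfe": mfe,
        "relGCintergenic": rel_gc_intergenic,
        "relGCchr": utr_gc / chromosome_gc,
        "relPosChr": rel_position_chromosome(
            gene.cds_start, gene.cds_end, len(chromosome_seq)
        ),
        **{f"dinuc_{d}": dinucs[d] for d in DINUCLEOTIDES},
        "og_mean_relGC": og_stats.mean_relGC,
        "og_mode_relGC": og_stats.mode_relGC,
        "og_sd_relGC": og_stats.sd_relGC,
        "og_skew_relGC": og_stats.skew_relGC,
        "og_mean_mfe": og_stats.mean_mfe,
        "og_mode_mfe": og_stats.mode_mfe,
        "og_sd_mfe": og_stats.sd_mfe,
        "og_skew_mfe": og_stats.skew_mfe,
        "intergenic_length": float(intergenic.length),
    }
    assert list(vec) == FEATURE_NAMES and len(vec) == N_FEATURES
    return vec


def compute_feature_table(
    assemblies: dict[str, OrganismAssembly],
    genes: list[GeneModel],
    orthologs: OrthologTable | None = None,
    backend: str = "internal",
    width: int = 60,
    kind: str = "utr60",
) -> pd.DataFrame:
    """Feature matrix for every gene with an extractable window.

    Returns a DataFrame with ``gene_id``, ``organism_id``, ``og_id`` and the
    29 feature columns in canonical order.  Orthologous-group statistics are
    computed over all group members that yielded a window, pooled across
    organisms; ungrouped genes form singleton groups (sd = skew = 0).

    ``kind='negctrl60'`` featurizes the pre-stop-codon negative-control
    window instead of the upstream window, keeping every other per-gene
    quantity (intergenic region, chromosomal context, group structure)
    unchanged — the configuration used to estimate the empirical FDR.
    """
    extractors = {
        "utr60": extract_upstream_window,
        "negctrl60": extract_negative_control_window,
    }
    if kind not in extractors:
        raise ValueError(f"unknown window kind {kind!r}")
    extractor = extractors[kind]
    per_chrom: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        per_chrom.setdefault((g.organism_id, g.chromosome), []).append(g)

    chrom_gc: dict[tuple[str, str], float] = {}
    for org, assembly in assemblies.items():
        for name, seq in assembly.chromosomes.items():
            chrom_gc[(org, name)] = gc_fraction(seq)

    rows: list[dict] = []
    n_skipped = 0
    for gene in genes:
        assembly = assemblies[gene.organism_id]
        utr = extractor(assembly, gene, width=width)
        if utr is None:
            n_skipped += 1
            continue
        intergenic = compute_intergenic_region(
            gene, per_chrom[(gene.organism_id, gene.chromosome)], assembly
        )
        if intergenic.length:
            ref_gc = gc_fraction(intergenic.sequence)
        else:
            ref_gc = chrom_gc[(gene.organism_id, gene.chromosome)]
        og = orthologs.og_of(gene.gene_id) if orthologs else gene.og_id
        rows.append(
            {
                "gene_id": gene.gene_id,
                "organism_id": gene.organism_id,
                "og_id": og,
                "_gene": gene,
                "_utr": utr,
                "_intergenic": intergenic,
                "_mfe": fold_mfe(utr.sequence, backend=backend),
                "_relGC": gc_fraction(utr.sequence) / ref_gc,
            }
        )
    if n_skipped:
        logger.info("%d genes skipped during window extraction", n_skipped)
    if not rows:
        return pd.DataFrame(columns=["gene_id", "organism_id", "og_id"] + FEATURE_NAMES)

    # pool group members (singleton groups for ungrouped genes)
    by_group: dict[str, list[dict]] = {}
    for r in rows:
        key = r["og_id"] if r["og_id"] is not None else f"__singleton__{r['gene_id']}"
        by_group.setdefault(key, []).append(r)
    group_stats: dict[str, OgStats] = {}
    for key, members in by_group.items():
        relgc = np.array([m["_relGC"] for m in members])
        mfes = np.array([m["_mfe"] for m in members])
        group_stats[key] = OgStats(
            *group_statistics(relgc), *group_statistics(mfes)
        )

    out = []
    for r in rows:
        key = r["og_id"] if r["og_id"] is not None else f"__singleton__{r['gene_id']}"
        gene = r["_gene"]
        vec = assemble_feature_vector(
            gene, r["_utr"], r["_intergenic"],
            assemblies[gene.organism_id].chromosomes[gene.chromosome],
            group_stats[key], r["_mfe"],
            chromosome_gc=chrom_gc[(gene.organism_id, gene.chromosome)],
        )
        out.append(
            {"gene_id": r["gene_id"], "organism_id": r["organism_id"],
             "og_id": r["og_id"], **vec}
        )
    return pd.DataFrame(out, columns=["gene_id", "organism_id", "og_id"] + FEATURE_NAMES)


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "organism_id": str, "og_id": str})
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"feature table {path}: missing columns {sorted(missing)}")
    return df
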