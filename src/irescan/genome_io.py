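"""Genome, annotation and ortholog-table input plus window extraction.

Coordinates are 1-based inclusive throughout (GFF convention); the only
conversion to Python's 0-based half-open slices happens inside the private
``_slice`` helper.  Sequences are stored uppercased with RNA ``U`` mapped to
``T`` and IUPAC ambiguity codes collapsed to ``N``.

The two 60-nt windows of interest are:

* ``utr60`` — the fixed-width window immediately upstream of the translation
  initiation codon, on the sense (mRNA-equivalent) strand; and
* ``negctrl60`` — the coding-sequence window immediately upstream of the stop
  codon, assumed IRES-free and used to estimate an empirical false-discovery
  rate.

Genes with insufficient flanking sequence (or all-``N`` windows) are skipped
and logged rather than padded: a padded window has no interpretable folding
energy or composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# IUPAC nucleotide codes beyond ACGT(U)N collapse to N on read.
_AMBIGUITY = str.maketrans("RYSWKMBDHV", "N" * 10)
_VALID = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str, *, context: str = "") -> str:
    """Uppercase, map U->T, collapse IUPAC ambiguity codes to N.

    Raises ``ValueError`` naming *context* on any non-IUPAC character.
    """
    s = seq.upper().replace("U", "T").translate(_AMBIGUITY)
    bad = set(s) - _VALID
    if bad:
        raise ValueError(
            f"non-IUPAC character(s) {sorted(bad)} in record {context!r}"
        )
    return s


@dataclass
class OrganismAssembly:
    """One organism's chromosomes, keyed by chromosome name."""

    organism_id: str
    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")

    def length(self, chromosome: str) -> int:
        return len(self.chromosomes[chromosome])


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene as a single CDS span on one chromosome."""

    gene_id: str
    organism_id: str
    chromosome: str
    strand: str
    cds_start: int
    cds_end: int
    og_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )
        if not (1 <= self.cds_start <= self.cds_end):
            raise ValueError(f"gene {self.gene_id}: bad coordinates")
        if self.cds_end - self.cds_start + 1 < 6:
            raise ValueError(
                f"gene {self.gene_id}: CDS shorter than 6 nt (needs start and stop codon)"
            )

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    def validate_against(self, assembly: OrganismAssembly) -> None:
        if self.chromosome not in assembly.chromosomes:
            raise ValueError(
                f"gene {self.gene_id}: chromosome {self.chromosome!r} not in assembly"
            )
        if self.cds_end > assembly.length(self.chromosome):
            raise ValueError(
                f"gene {self.gene_id}: coordinates exceed chromosome bounds"
            )


@dataclass(frozen=True)
class RegionSequence:
    gene_id: str
    kind: str  # utr60 | negctrl60 | intergenic
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, organism_id: str) -> OrganismAssembly:
    """Read a FASTA file into an :class:`OrganismAssembly`.

    Chromosome name = header token before the first whitespace.  Duplicate
    names and non-IUPAC characters are fatal.
    """
    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in chromosomes:
            raise ValueError(f"duplicate chromosome name {name!r} in {path}")
        chromosomes[name] = normalize_sequence(str(record.seq), context=name)
    if not chromosomes:
        raise ValueError(f"no FASTA records in {path}")
    return OrganismAssembly(organism_id=organism_id, chromosomes=chromosomes)


def _genes_from_tsv(path: str | Path, organism_id: str) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chromosome", "strand", "cds_start", "cds_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation {path}: missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        og = getattr(row, "og_id", None)
        if og is not None and pd.isna(og):
            og = None
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                organism_id=organism_id,
                chromosome=row.chromosome,
                strand=row.strand,
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                og_id=og,
            )
        )
    return genes


def _genes_from_gff3(path: str | Path, organism_id: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    spans: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or cds.attributes.get("ID")
        if not parents:
            raise ValueError(f"GFF3 CDS at {cds.seqid}:{cds.start} lacks Parent/ID")
        gene_id = parents[0]
        rec = spans.setdefault(
            gene_id,
            {"chrom": cds.seqid, "strand": cds.strand,
             "start": cds.start, "end": cds.end},
        )
        # multi-exon genes collapse to the min..max CDS span (introns ignored)
        rec["start"] = min(rec["start"], cds.start)
        rec["end"] = max(rec["end"], cds.end)
    return [
        GeneModel(
            gene_id=gid,
            organism_id=organism_id,
            chromosome=rec["chrom"],
            strand=rec["strand"] if rec["strand"] else ".",
            cds_start=rec["start"],
            cds_end=rec["end"],
        )
        for gid, rec in spans.items()
    ]


def read_annotation(
    path: str | Path, dialect: str, organism_id: str,
    assembly: OrganismAssembly | None = None,
) -> list[GeneModel]:
    """Read gene models from a ``tsv`` or ``gff3`` annotation file."""
    if dialect == "tsv":
        genes = _genes_from_tsv(path, organism_id)
    elif dialect == "gff3":
        genes = _genes_from_gff3(path, organism_id)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if assembly is not None:
        for g in genes:
            g.validate_against(assembly)
    return genes


def _slice(chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice; the single coordinate-convention conversion."""
    return chrom[start - 1:end]


def extract_upstream_window(
    assembly: OrganismAssembly, gene: GeneModel, width: int = 60
) -> RegionSequence | None:
    """The *width* nt immediately upstream of the start codon, sense strand.

    Returns ``None`` (logged) when the flank runs off the contig edge or the
    window is entirely ``N``.
    """
    chrom = assembly.chromosomes[gene.chromosome]
    if gene.strand == "+":
        start, end = gene.cds_start - width, gene.cds_start - 1
        if start < 1:
            logger.info("gene %s skipped: <%d nt upstream flank", gene.gene_id, width)
            return None
        seq = _slice(chrom, start, end)
    else:
        start, end = gene.cds_end + 1, gene.cds_end + width
        if end > len(chrom):
            logger.info("gene %s skipped: <%d nt upstream flank", gene.gene_id, width)
            return None
        seq = reverse_complement(_slice(chrom, start, end))
    if set(seq) == {"N"}:
        logger.info("gene %s skipped: all-N upstream window", gene.gene_id)
        return None
    return RegionSequence(gene_id=gene.gene_id, kind="utr60", sequence=seq)


def extract_negative_control_window(
    assembly: OrganismAssembly, gene: GeneModel, width: int = 60
) -> RegionSequence | None:
    """The *width* coding nt immediately 5' of the stop codon, sense strand.

    Needs a CDS of at least ``width + 3`` nt; shorter genes are skipped.
    """
    if gene.cds_length < width + 3:
        logger.info("gene %s skipped: CDS shorter than %d nt", gene.gene_id, width + 3)
        return None
    chrom = assembly.chromosomes[gene.chromosome]
    if gene.strand == "+":
        seq = _slice(chrom, gene.cds_end - width - 2, gene.cds_end - 3)
    else:
        seq = reverse_complement(
            _slice(chrom, gene.cds_start + 3, gene.cds_start + 2 + width)
        )
    if set(seq) == {"N"}:
        logger.info("gene %s skipped: all-N negative-control window", gene.gene_id)
        return None
    return RegionSequence(gene_id=gene.gene_id, kind="negctrl60", sequence=seq)


def compute_intergenic_region(
    gene: GeneModel,
    chromosome_genes: list[GeneModel],
    assembly: OrganismAssembly,
) -> RegionSequence:
    """Span between the gene's translation start and the nearest upstream
    annotated CDS boundary (either strand counts); runs to the contig edge if
    none.  Zero-length spans are allowed and yield an empty sequence.
    """
    chrom = assembly.chromosomes[gene.chromosome]
    bounds: list[int] = []
    for other in chromosome_genes:
        if other.gene_id == gene.gene_id:
            continue
        bounds.extend((other.cds_start, other.cds_end))
    if gene.strand == "+":
        tss = gene.cds_start
        upstream = [b for b in bounds if b < tss]
        lo = (max(upstream) + 1) if upstream else 1
        hi = tss - 1
        seq = _slice(chrom, lo, hi) if hi >= lo else ""
    else:
        tss = gene.cds_end
        upstream = [b for b in bounds if b > tss]
        hi = (min(upstream) - 1) if upstream else len(chrom)
        lo = tss + 1
        seq = reverse_complement(_slice(chrom, lo, hi)) if hi >= lo else ""
    return RegionSequence(gene_id=gene.gene_id, kind="intergenic", sequence=seq)


@dataclass
class OrthologTable:
    """gene -> orthologous-group forward map plus the reverse member index."""

    gene_to_og: dict[str, str]
    og_members: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.og_members:
            members: dict[str, list[str]] = {}
            for gene, og in self.gene_to_og.items():
                members.setdefault(og, []).append(gene)
            self.og_members = members

    def og_of(self, gene_id: str) -> str | None:
        return self.gene_to_og.get(gene_id)

    def members(self, og_id: str) -> list[str]:
        return self.og_members.get(og_id, [])

    @property
    def groups(self) -> list[str]:
        return sorted(self.og_members)

    def __len__(self) -> int:
        return len(self.gene_to_og)


def read_ortholog_groups(
    path: str | Path, og_col: str = "og_id", gene_col: str = "gene_id"
) -> OrthologTable:
    """Read an OrthoDB-style tab-separated gene <-> group mapping.

    A gene occurring in two different groups is an error; the empty file is a
    warning and yields an empty table.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("ortholog table %s is empty", path)
        return OrthologTable(gene_to_og={})
    for col in (og_col, gene_col):
        if col not in df.columns:
            raise ValueError(f"ortholog table {path}: missing column {col!r}")
    if df[[og_col, gene_col]].isna().any().any():
        bad = int(df[[og_col, gene_col]].isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"ortholog table {path}: malformed line {bad}")
    mapping: dict[str, str] = {}
    for row in df.itertuples(index=False):
        gene, og = getattr(row, gene_col), getattr(row, og_col)
        if gene in mapping and mapping[gene] != og:
            raise ValueError(
                f"gene {gene!r} assigned to two groups ({mapping[gene]!r}, {og!r})"
            )
        mapping[gene] = og
    if not mapping:
        logger.warning("ortholog table %s has no rows", path)
    return OrthologTable(gene_to_og=mapping)


def write_windows_fasta(
    regions: list[RegionSequence], organism_id: str, path: str | Path
) -> None:
    """Write extracted windows as FASTA with header ``gene_id|organism_id|kind``."""
    with open(path, "w") as fh:
        for region in regions:
            fh.write(f">{region.gene_id}|{organism_id}|{region.kind}\n")
            fh.write(region.sequence + "\n")
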