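"""Core data model for annotated prokaryotic genomes.

A genome is represented as contigs of ordered genes (adjacency is defined by
gene order along the contig, not nucleotide coordinates), plus per-protein
domain hits, localization calls, sequences, and an optional taxonomy record.
Readers and writers handle the tabular/FASTA dialects the pipeline touches:
a gene-table TSV, protein FASTA, and a GTDB-style taxonomy TSV.

Conventions
-----------
* ``gene_index`` is 0-based and contiguous (0..n-1) within each contig.
* Residue coordinates (``ali_from``/``ali_to``) are 1-based inclusive,
  following HMMER.
* Identifiers are opaque, case-sensitive strings.
* Strand is carried for reporting but never consulted by neighborhood logic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

__all__ = [
    "FormatError",
    "GeneRecord",
    "DomainHit",
    "LocalizationCall",
    "TaxonRecord",
    "AnnotatedGenome",
    "read_gene_table",
    "write_gene_table",
    "read_protein_fasta",
    "write_protein_fasta",
    "read_taxonomy",
    "write_taxonomy",
]

#: Localization classes recognised throughout the pipeline.  SP and TAT are
#: the two signal-peptide classes (Sec/SPI and Tat/SPI); LIPO is a lipoprotein
#: signal (Sec/SPII); OTHER means no predicted export signal.
LOCALIZATION_CALLS = ("SP", "TAT", "LIPO", "OTHER")

#: Calls that place a protein outside the cytosol.
EXTRACYTOSOLIC_CALLS = frozenset({"SP", "TAT", "LIPO"})

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

GENE_TABLE_COLUMNS = (
    "genome_id",
    "contig_id",
    "gene_index",
    "strand",
    "protein_id",
    "length_aa",
)

_LINEAGE_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene in its genomic context (order-based, strand-agnostic)."""

    genome_id: str
    contig_id: str
    gene_index: int
    strand: str
    protein_id: str
    length_aa: int

    def __post_init__(self) -> None:
        if self.gene_index < 0:
            raise ValueError(f"gene_index must be >= 0, got {self.gene_index}")
        if self.length_aa < 0:
            raise ValueError(f"length_aa must be >= 0, got {self.length_aa}")
        if self.strand not in ("+", "-", "unknown"):
            object.__setattr__(self, "strand", "unknown")


@dataclass(frozen=True)
class DomainHit:
    """A single profile-HMM match against a protein.

    ``evalue`` is the full-sequence E-value and ``bitscore`` the full-sequence
    score from the HMMER tabular output; ``ali_from``/``ali_to`` are 1-based
    inclusive alignment coordinates on the protein when available (domtblout)
    and ``None`` otherwise (tblout).
    """

    protein_id: str
    namespace: str  # "pfam" | "kofam"
    accession: str
    evalue: float
    bitscore: float
    ali_from: int | None = None
    ali_to: int | None = None

    def __post_init__(self) -> None:
        if self.namespace not in ("pfam", "kofam"):
            raise ValueError(f"unknown annotation namespace {self.namespace!r}")
        if not self.evalue > 0:
            # HMMER prints 0.0 on underflow; clamp instead of rejecting.
            object.__setattr__(self, "evalue", 5e-324)
        if (self.ali_from is None) != (self.ali_to is None):
            raise ValueError("ali_from and ali_to must be both present or both absent")
        if self.ali_from is not None and not (1 <= self.ali_from <= self.ali_to):
            raise ValueError(
                f"invalid alignment coordinates {self.ali_from}..{self.ali_to}"
            )


@dataclass(frozen=True)
class LocalizationCall:
    """Predicted cellular localization of one protein.

    ``call`` follows the signal-peptide predictor classes (SP, TAT, LIPO,
    OTHER); ``tm_helix_count`` is the number of predicted transmembrane
    helices and is independent of the call.
    """

    protein_id: str
    call: str
    tm_helix_count: int = 0

    def __post_init__(self) -> None:
        if self.call not in LOCALIZATION_CALLS:
            raise ValueError(f"unknown localization call {self.call!r}")
        if self.tm_helix_count < 0:
            raise ValueError("tm_helix_count must be >= 0")

    @property
    def extracytosolic(self) -> bool:
        """True when the protein carries a signal peptide or lipidation site."""
        return self.call in EXTRACYTOSOLIC_CALLS


@dataclass(frozen=True)
class TaxonRecord:
    """GTDB-style 7-rank lineage for one genome."""

    genome_id: str
    lineage: str

    @property
    def ranks(self) -> tuple[str, ...]:
        return tuple(f.strip() for f in self.lineage.split(";"))

    def _rank(self, prefix: str) -> str:
        for f in self.ranks:
            if f.startswith(prefix):
                return f[len(prefix):]
        raise FormatError(
            f"genome {self.genome_id}: lineage field with prefix {prefix!r} missing"
        )

    @property
    def domain(self) -> str:
        return self._rank("d__")

    @property
    def phylum(self) -> str:
        return self._rank("p__")

    @property
    def genus(self) -> str:
        return self._rank("g__")

    def validate(self) -> None:
        fields = self.ranks
        if len(fields) != 7:
            raise FormatError(
                f"genome {self.genome_id}: lineage has {len(fields)} fields, expected 7"
            )
        for f, prefix in zip(fields, _LINEAGE_PREFIXES):
            if not f.startswith(prefix):
                raise FormatError(
                    f"genome {self.genome_id}: lineage field {f!r} lacks prefix {prefix!r}"
                )


@dataclass
class AnnotatedGenome:
    """One genome: ordered genes per contig plus all per-protein annotation."""

    genome_id: str
    contigs: dict[str, list[GeneRecord]] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)
    domains: list[DomainHit] = field(default_factory=list)
    localization: dict[str, LocalizationCall] = field(default_factory=dict)
    taxon: TaxonRecord | None = None

    def genes(self) -> Iterator[GeneRecord]:
        """All genes, ordered by contig id then gene index."""
        for contig_id in sorted(self.contigs):
            yield from self.contigs[contig_id]

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.contigs.values())

    def gene_by_protein(self, protein_id: str) -> GeneRecord:
        gene = self._protein_index().get(protein_id)
        if gene is None:
            raise KeyError(protein_id)
        return gene

    def _protein_index(self) -> dict[str, GeneRecord]:
        idx = getattr(self, "_pidx", None)
        if idx is None or len(idx) != self.n_genes:
            idx = {g.protein_id: g for contig in self.contigs.values() for g in contig}
            self._pidx = idx
        return idx

    def neighbors(self, contig_id: str, gene_index: int, window: int) -> list[GeneRecord]:
        """Genes with index in [gene_index - window, gene_index + window],
        truncated at contig ends, in ascending index order (anchor included)."""
        contig = self.contigs[contig_id]
        lo = max(0, gene_index - window)
        hi = min(len(contig) - 1, gene_index + window)
        return contig[lo : hi + 1]

    def localization_of(self, protein_id: str) -> LocalizationCall:
        return self.localization.get(
            protein_id, LocalizationCall(protein_id, "OTHER", 0)
        )

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`FormatError` on breach."""
        seen_proteins: set[str] = set()
        for contig_id, contig in self.contigs.items():
            for rank, gene in enumerate(contig):
                if gene.gene_index != rank:
                    raise FormatError(
                        f"{self.genome_id}/{contig_id}: gene indices not contiguous "
                        f"from 0 (found {gene.gene_index} at rank {rank})"
                    )
                if gene.protein_id in seen_proteins:
                    raise FormatError(
                        f"{self.genome_id}: duplicate protein_id {gene.protein_id!r}"
                    )
                seen_proteins.add(gene.protein_id)
        for hit in self.domains:
            if hit.protein_id not in seen_proteins:
                raise FormatError(
                    f"{self.genome_id}: domain hit references unknown protein "
                    f"{hit.protein_id!r}"
                )
        for pid in self.localization:
            if pid not in seen_proteins:
                raise FormatError(
                    f"{self.genome_id}: localization call references unknown protein "
                    f"{pid!r}"
                )
        for pid, seq in self.sequences.items():
            if pid in seen_proteins:
                gene = self.gene_by_protein(pid)
                if gene.length_aa and len(seq) != gene.length_aa:
                    raise FormatError(
                        f"{self.genome_id}: sequence length {len(seq)} != length_aa "
                        f"{gene.length_aa} for {pid!r}"
                    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path) -> list[AnnotatedGenome]:
    """Read a gene-table TSV into genome skeletons (genes only).

    The table must carry a header with the columns
    ``genome_id contig_id gene_index strand protein_id length_aa``.
    Genes are grouped by contig and sorted by ``gene_index``; a duplicate
    (contig, gene_index) pair is an error, as is a non-contiguous index set.
    Returns one :class:`AnnotatedGenome` per distinct genome_id, sorted by id.
    """
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, expected a header")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in GENE_TABLE_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        col = {name: header.index(name) for name in GENE_TABLE_COLUMNS}

        rows: dict[str, dict[str, dict[int, GeneRecord]]] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields")
            try:
                gene_index = int(fields[col["gene_index"]])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer gene_index "
                    f"{fields[col['gene_index']]!r}"
                ) from exc
            try:
                length_aa = int(fields[col["length_aa"]])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer length_aa "
                    f"{fields[col['length_aa']]!r}"
                ) from exc
            gene = GeneRecord(
                genome_id=fields[col["genome_id"]],
                contig_id=fields[col["contig_id"]],
                gene_index=gene_index,
                strand=fields[col["strand"]],
                protein_id=fields[col["protein_id"]],
                length_aa=length_aa,
            )
            contig = rows.setdefault(gene.genome_id, {}).setdefault(gene.contig_id, {})
            if gene.gene_index in contig:
                raise FormatError(
                    f"{path}:{lineno}: duplicate gene_index {gene.gene_index} "
                    f"on contig {gene.contig_id!r}"
                )
            contig[gene.gene_index] = gene

    genomes = []
    for genome_id in sorted(rows):
        contigs = {
            contig_id: [contig[i] for i in sorted(contig)]
            for contig_id, contig in sorted(rows[genome_id].items())
        }
        genome = AnnotatedGenome(genome_id=genome_id, contigs=contigs)
        genome.validate()
        genomes.append(genome)
    return genomes


def write_gene_table(genomes: Iterable[AnnotatedGenome], path: str | Path) -> None:
    """Write genomes back to the canonical gene-table TSV dialect.

    Rows are emitted sorted by genome, contig, gene index, so a read/write
    round trip of canonicalized input is byte-identical.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for genome in sorted(genomes, key=lambda g: g.genome_id):
            for gene in genome.genes():
                fh.write(
                    "\t".join(
                        (
                            gene.genome_id,
                            gene.contig_id,
                            str(gene.gene_index),
                            gene.strand,
                            gene.protein_id,
                            str(gene.length_aa),
                        )
                    )
                    + "\n"
                )


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into ``{protein_id: sequence}``.

    The record id is the first whitespace token of the header.  Sequences are
    uppercased and a single trailing ``*`` stop is stripped.  A duplicate id
    is an error; residues outside the 20 amino acids plus ``X`` trigger a
    warning but are retained.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    allowed = set(AMINO_ACIDS + "X")
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate FASTA id {record.id!r}")
        seq = str(record.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        unexpected = set(seq) - allowed
        if unexpected:
            warnings.warn(
                f"{path}: sequence {record.id!r} contains non-amino-acid "
                f"characters {sorted(unexpected)}; retained as-is",
                stacklevel=2,
            )
        sequences[record.id] = seq
    return sequences


def write_protein_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for pid in sorted(sequences):
            fh.write(f">{pid}\n")
            seq = sequences[pid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_taxonomy(path: str | Path) -> dict[str, TaxonRecord]:
    """Read a two-column (genome_id, lineage) GTDB-style taxonomy TSV.

    Each lineage must have exactly 7 semicolon-delimited, prefix-tagged ranks
    (``d__`` .. ``s__``); anything else is an error naming the genome.
    """
    path = Path(path)
    records: dict[str, TaxonRecord] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            record = TaxonRecord(genome_id=fields[0], lineage=fields[1])
            record.validate()
            records[record.genome_id] = record
    return records


def write_taxonomy(records: Mapping[str, TaxonRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for genome_id in sorted(records):
            fh.write(f"{genome_id}\t{records[genome_id].lineage}\n")
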