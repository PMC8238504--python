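"""Parsing of external annotation outputs and best-hit/threshold logic.

Protein function labels come from profile-HMM searches: a single ortholog
(KO) label per protein from a KOfam search, and a multiset of Pfam domains
per protein from a Pfam search.  Both apply the same full-sequence E-value
cutoff (default 0.001).  Localization comes from a signal-peptide predictor
(SignalP-5 summary dialect) and a transmembrane-helix predictor (TMHMM short
format).  The external predictors themselves are consumed, never
reimplemented; a pre-joined annotation TSV serves as the internal
interchange format.

Best-KO tie-break: minimum E-value, then maximum bitscore, then
lexicographically smallest accession — deterministic regardless of input
order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import isfinite
from pathlib import Path
from typing import Iterable, Mapping

from .genome_model import (
    AnnotatedGenome,
    DomainHit,
    FormatError,
    LocalizationCall,
)

__all__ = [
    "AnnotationConfig",
    "ProteinAnnotation",
    "parse_hmmsearch_tbl",
    "assign_best_ko",
    "collect_pfam_domains",
    "parse_localization",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "annotate_proteins",
]

ANNOTATION_TSV_COLUMNS = (
    "protein_id",
    "namespace",
    "accession",
    "evalue",
    "bitscore",
    "ali_from",
    "ali_to",
)

_SIGNALP_TOKENS = {
    "SP(Sec/SPI)": "SP",
    "LIPO(Sec/SPII)": "LIPO",
    "TAT(Tat/SPI)": "TAT",
    "OTHER": "OTHER",
}

_PFAM_VERSIONED = re.compile(r"^(PF\d{5})\.\d+$")


@dataclass(frozen=True)
class AnnotationConfig:
    """Thresholding policy for HMM-based annotation.

    evalue_cutoff
        Full-sequence E-value below or at which a hit counts (default 0.001).
        Applied identically to the KO best-hit selection and to Pfam domain
        presence.
    """

    evalue_cutoff: float = 0.001

    def __post_init__(self) -> None:
        if not self.evalue_cutoff > 0:
            raise ValueError("evalue_cutoff must be > 0")

    def passes(self, hit: DomainHit) -> bool:
        return hit.evalue <= self.evalue_cutoff


@dataclass
class ProteinAnnotation:
    """Consolidated annotation of one protein after thresholding."""

    protein_id: str
    ko: str | None = None
    pfam_hits: list[DomainHit] = field(default_factory=list)
    localization: LocalizationCall | None = None

    @property
    def pfam_accessions(self) -> set[str]:
        return {h.accession for h in self.pfam_hits}

    def pfam_count(self, accession: str) -> int:
        return sum(1 for h in self.pfam_hits if h.accession == accession)

    @property
    def call(self) -> str:
        return self.localization.call if self.localization else "OTHER"

    @property
    def tm_helix_count(self) -> int:
        return self.localization.tm_helix_count if self.localization else 0

    @property
    def extracytosolic(self) -> bool:
        return self.localization.extracytosolic if self.localization else False


# ---------------------------------------------------------------------------
# HMMER tabular parsing
# ---------------------------------------------------------------------------

def _normalize_accession(qname: str, qacc: str, namespace: str) -> str:
    raw = qacc if qacc not in ("-", "") else qname
    m = _PFAM_VERSIONED.match(raw)
    if namespace == "pfam" and m:
        return m.group(1)
    return raw


def _float_field(token: str, path: Path, lineno: int, what: str) -> float:
    try:
        value = float(token)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: malformed {what} {token!r}") from exc
    if not isfinite(value):
        raise FormatError(f"{path}:{lineno}: non-finite {what} {token!r}")
    return value


def parse_hmmsearch_tbl(
    path: str | Path,
    namespace: str,
    dialect: str = "auto",
) -> list[DomainHit]:
    """Parse an hmmsearch ``--tblout`` or ``--domtblout`` file.

    The target (first column) is the protein; the query is the HMM whose
    accession — version suffix stripped for Pfam — or, failing that, name
    becomes the hit accession.  For tblout one hit per target/query pair is
    produced (no coordinates); for domtblout one hit per domain row, carrying
    the full-sequence E-value/score plus alignment coordinates.

    ``dialect`` may be ``"tblout"``, ``"domtblout"`` or ``"auto"`` (sniffed
    per line from the integer tlen/qlen columns unique to domtblout).
    """
    if namespace not in ("pfam", "kofam"):
        raise ValueError(f"unknown namespace {namespace!r}")
    if dialect not in ("auto", "tblout", "domtblout"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    hits: list[DomainHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            t = line.split()
            line_dialect = dialect
            if line_dialect == "auto":
                line_dialect = (
                    "domtblout"
                    if len(t) >= 22 and t[2].isdigit() and t[5].isdigit()
                    else "tblout"
                )
            if line_dialect == "tblout":
                if len(t) < 6:
                    raise FormatError(f"{path}:{lineno}: truncated tblout line")
                hits.append(
                    DomainHit(
                        protein_id=t[0],
                        namespace=namespace,
                        accession=_normalize_accession(t[2], t[3], namespace),
                        evalue=_float_field(t[4], path, lineno, "E-value"),
                        bitscore=_float_field(t[5], path, lineno, "score"),
                    )
                )
            else:
                if len(t) < 22:
                    raise FormatError(f"{path}:{lineno}: truncated domtblout line")
                try:
                    ali_from, ali_to = int(t[17]), int(t[18])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: malformed alignment coordinates"
                    ) from exc
                hits.append(
                    DomainHit(
                        protein_id=t[0],
                        namespace=namespace,
                        accession=_normalize_accession(t[3], t[4], namespace),
                        evalue=_float_field(t[6], path, lineno, "E-value"),
                        bitscore=_float_field(t[7], path, lineno, "score"),
                        ali_from=ali_from,
                        ali_to=ali_to,
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# Thresholding / best-hit selection
# ---------------------------------------------------------------------------

def assign_best_ko(
    hits: Iterable[DomainHit],
    cfg: AnnotationConfig | None = None,
) -> dict[str, str]:
    """Per protein, the accession of the best passing KO hit.

    "Best" minimizes E-value, breaking ties by larger bitscore and then by
    lexicographically smaller accession.  Proteins without a passing hit are
    absent from the mapping.
    """
    cfg = cfg or AnnotationConfig()
    best: dict[str, DomainHit] = {}
    for hit in hits:
        if hit.namespace != "kofam":
            raise ValueError(
                f"assign_best_ko expects kofam hits, got {hit.namespace!r}"
            )
        if not cfg.passes(hit):
            continue
        incumbent = best.get(hit.protein_id)
        if incumbent is None or _ko_key(hit) < _ko_key(incumbent):
            best[hit.protein_id] = hit
    return {pid: h.accession for pid, h in best.items()}


def _ko_key(hit: DomainHit) -> tuple[float, float, str]:
    return (hit.evalue, -hit.bitscore, hit.accession)


def collect_pfam_domains(
    hits: Iterable[DomainHit],
    cfg: AnnotationConfig | None = None,
) -> dict[str, list[DomainHit]]:
    """Per protein, every passing Pfam hit (multiplicity preserved).

    Hits are ordered by (accession, ali_from, E-value) so downstream output
    is deterministic regardless of input order.
    """
    cfg = cfg or AnnotationConfig()
    by_protein: dict[str, list[DomainHit]] = {}
    for hit in hits:
        if hit.namespace != "pfam":
            raise ValueError(
                f"collect_pfam_domains expects pfam hits, got {hit.namespace!r}"
            )
        if cfg.passes(hit):
            by_protein.setdefault(hit.protein_id, []).append(hit)
    for pid in by_protein:
        by_protein[pid].sort(
            key=lambda h: (h.accession, h.ali_from or 0, h.evalue)
        )
    return by_protein


# ---------------------------------------------------------------------------
# Localization predictor output
# ---------------------------------------------------------------------------

def parse_localization(
    path: str | Path,
    tm_path: str | Path | None = None,
) -> dict[str, LocalizationCall]:
    """Parse a SignalP-5 summary plus an optional TMHMM short-format file.

    SignalP-5 summary lines are ``<ID> <Prediction> ...`` where Prediction is
    one of ``SP(Sec/SPI)``, ``LIPO(Sec/SPII)``, ``TAT(Tat/SPI)``, ``OTHER``;
    an unknown token is an error.  TMHMM short-format lines carry a
    ``PredHel=N`` field; proteins absent from the TM file get 0 helices.
    """
    path = Path(path)
    tm_counts: dict[str, int] = {}
    if tm_path is not None:
        tm_path = Path(tm_path)
        with tm_path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split()
                pred = [f for f in fields[1:] if f.startswith("PredHel=")]
                if not pred:
                    raise FormatError(
                        f"{tm_path}:{lineno}: no PredHel= field"
                    )
                try:
                    tm_counts[fields[0]] = int(pred[0].split("=", 1)[1])
                except ValueError as exc:
                    raise FormatError(
                        f"{tm_path}:{lineno}: malformed {pred[0]!r}"
                    ) from exc

    calls: dict[str, LocalizationCall] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected ID and prediction")
            pid, token = fields[0], fields[1]
            if token not in _SIGNALP_TOKENS:
                raise FormatError(
                    f"{path}:{lineno}: unknown prediction token {token!r}"
                )
            calls[pid] = LocalizationCall(
                protein_id=pid,
                call=_SIGNALP_TOKENS[token],
                tm_helix_count=tm_counts.get(pid, 0),
            )
    # Proteins with TM predictions but no signal-peptide line default to OTHER.
    for pid, n in tm_counts.items():
        if pid not in calls:
            calls[pid] = LocalizationCall(protein_id=pid, call="OTHER", tm_helix_count=n)
    return calls


# ---------------------------------------------------------------------------
# Pre-joined annotation TSV (internal interchange format)
# ---------------------------------------------------------------------------

def read_annotation_tsv(path: str | Path) -> list[DomainHit]:
    """Read the pre-joined annotation TSV
    (protein_id, namespace, accession, evalue, bitscore, ali_from, ali_to)."""
    path = Path(path)
    hits: list[DomainHit] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in ANNOTATION_TSV_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        col = {name: header.index(name) for name in ANNOTATION_TSV_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            ali_from = int(f[col["ali_from"]]) if f[col["ali_from"]] else None
            ali_to = int(f[col["ali_to"]]) if f[col["ali_to"]] else None
            hits.append(
                DomainHit(
                    protein_id=f[col["protein_id"]],
                    namespace=f[col["namespace"]],
                    accession=f[col["accession"]],
                    evalue=_float_field(f[col["evalue"]], path, lineno, "E-value"),
                    bitscore=_float_field(f[col["bitscore"]], path, lineno, "score"),
                    ali_from=ali_from,
                    ali_to=ali_to,
                )
            )
    return hits


def write_annotation_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    path = Path(path)
    ordered = sorted(
        hits,
        key=lambda h: (h.protein_id, h.namespace, h.accession, h.evalue, h.ali_from or 0),
    )
    with path.open("w") as fh:
        fh.write("\t".join(ANNOTATION_TSV_COLUMNS) + "\n")
        for h in ordered:
            fh.write(
                "\t".join(
                    (
                        h.protein_id,
                        h.namespace,
                        h.accession,
                        repr(h.evalue),
                        repr(h.bitscore),
                        "" if h.ali_from is None else str(h.ali_from),
                        "" if h.ali_to is None else str(h.ali_to),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Consolidation
# ---------------------------------------------------------------------------

def annotate_proteins(
    genome: AnnotatedGenome,
    cfg: AnnotationConfig | None = None,
) -> dict[str, ProteinAnnotation]:
    """Apply thresholding and best-hit logic to a genome's raw domain hits.

    Returns one :class:`ProteinAnnotation` per gene (including unannotated
    genes, which get empty annotation), keyed by protein_id.
    """
    cfg = cfg or AnnotationConfig()
    kofam = [h for h in genome.domains if h.namespace == "kofam"]
    pfam = [h for h in genome.domains if h.namespace == "pfam"]
    ko_map = assign_best_ko(kofam, cfg)
    pfam_map = collect_pfam_domains(pfam, cfg)
    annotations: dict[str, ProteinAnnotation] = {}
    for gene in genome.genes():
        pid = gene.protein_id
        annotations[pid] = ProteinAnnotation(
            protein_id=pid,
            ko=ko_map.get(pid),
            pfam_hits=pfam_map.get(pid, []),
            localization=genome.localization.get(pid),
        )
    return annotations
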