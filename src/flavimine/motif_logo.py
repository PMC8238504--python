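"""Flavinylation-motif scanning and sequence-logo matrices.

The flavin transferase modifies a serine/threonine hydroxyl inside a short
conserved sequence context; the scanner reports every occurrence of the
[S/T]GA[S/T] pattern (a configurable hook accepts alternative patterns).
Overlapping occurrences are all reported — two motifs may legitimately share
a serine.

Logo matrices are computed from a gapped alignment: per column, amino-acid
frequencies over non-gap residues and the information content in bits,
``log2(20) - H`` with ``H`` the Shannon entropy of the column frequencies
(no small-sample correction, gaps excluded from the entropy).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .genome_model import AMINO_ACIDS, FormatError

__all__ = [
    "DEFAULT_MOTIF_PATTERN",
    "MAX_INFO_BITS",
    "MotifSite",
    "LogoColumn",
    "LogoMatrix",
    "scan_flavinylation_motifs",
    "count_motifs",
    "build_logo",
    "map_alignment_position_to_reference",
    "read_alignment_fasta",
    "write_motif_sites_tsv",
    "write_logo_tsv",
    "plot_logo",
]

DEFAULT_MOTIF_PATTERN = "[ST]GA[ST]"

#: Maximum per-column information content for a 20-letter alphabet.
MAX_INFO_BITS = math.log2(20)

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class MotifSite:
    """One motif occurrence; ``position`` is the 1-based start index."""

    protein_id: str
    position: int
    matched: str


def scan_flavinylation_motifs(
    seq: str,
    protein_id: str = "",
    pattern: str = DEFAULT_MOTIF_PATTERN,
) -> list[MotifSite]:
    """All (possibly overlapping) motif occurrences, ascending by position.

    ``pattern`` must be a fixed-width regular expression; it is wrapped in a
    lookahead so overlapping matches are enumerated.
    """
    compiled = re.compile(f"(?=({pattern}))")
    return [
        MotifSite(protein_id=protein_id, position=m.start() + 1, matched=m.group(1))
        for m in compiled.finditer(seq)
    ]


def count_motifs(
    proteins: Mapping[str, str],
    pattern: str = DEFAULT_MOTIF_PATTERN,
) -> dict[str, int]:
    """Per-protein motif occurrence counts, consistent with the scanner."""
    return {
        pid: len(scan_flavinylation_motifs(seq, pid, pattern))
        for pid, seq in proteins.items()
    }


@dataclass(frozen=True)
class LogoColumn:
    frequencies: dict[str, float]  # over the 20 amino acids, gaps excluded
    n_effective: int               # non-gap residues in the column
    info_bits: float


@dataclass(frozen=True)
class LogoMatrix:
    columns: tuple[LogoColumn, ...]

    def __len__(self) -> int:
        return len(self.columns)


def build_logo(alignment: Sequence[str]) -> LogoMatrix:
    """Column-wise frequency and information-content matrix of an alignment.

    All rows must have equal length; the alphabet is the 20 amino acids plus
    gap characters (``-`` or ``.``).  All-gap columns get ``n_effective=0``
    and ``info_bits=0``.  Characters outside alphabet+gap (e.g. ``X``) are
    excluded from the counts, like gaps.
    """
    rows = list(alignment)
    if not rows:
        raise ValueError("alignment must contain at least one sequence")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise FormatError("alignment rows have unequal lengths")

    aa_set = set(AMINO_ACIDS)
    columns: list[LogoColumn] = []
    for j in range(width):
        counts: dict[str, int] = {}
        for row in rows:
            c = row[j].upper()
            if c in aa_set:
                counts[c] = counts.get(c, 0) + 1
        n = sum(counts.values())
        if n == 0:
            columns.append(LogoColumn(frequencies={}, n_effective=0, info_bits=0.0))
            continue
        freqs = {aa: k / n for aa, k in sorted(counts.items())}
        entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        columns.append(
            LogoColumn(
                frequencies=freqs,
                n_effective=n,
                info_bits=MAX_INFO_BITS - entropy,
            )
        )
    return LogoMatrix(columns=tuple(columns))


def map_alignment_position_to_reference(
    alignment: Mapping[str, str],
    reference_id: str,
) -> dict[int, int]:
    """Map 1-based alignment columns to 1-based residue numbers of the
    reference row; columns where the reference is gapped are absent."""
    if reference_id not in alignment:
        raise KeyError(f"reference row {reference_id!r} not in alignment")
    ref = alignment[reference_id]
    mapping: dict[int, int] = {}
    residue = 0
    for col, c in enumerate(ref, start=1):
        if c not in GAP_CHARS:
            residue += 1
            mapping[col] = residue
    if not mapping:
        raise FormatError(f"reference row {reference_id!r} is all gaps")
    return mapping


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Read a gapped FASTA alignment; duplicate ids are an error."""
    rows: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in rows:
            raise FormatError(f"{path}: duplicate alignment id {record.id!r}")
        rows[record.id] = str(record.seq).upper()
    return rows


def write_motif_sites_tsv(sites: Iterable[MotifSite], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein_id\tposition\tmatched\n")
        for s in sorted(sites, key=lambda s: (s.protein_id, s.position)):
            fh.write(f"{s.protein_id}\t{s.position}\t{s.matched}\n")


def write_logo_tsv(logo: LogoMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "position\t" + "\t".join(AMINO_ACIDS) + "\tn_effective\tinfo_bits\n"
        )
        for j, col in enumerate(logo.columns, start=1):
            freqs = "\t".join(
                format(col.frequencies.get(aa, 0.0), ".6g") for aa in AMINO_ACIDS
            )
            fh.write(f"{j}\t{freqs}\t{col.n_effective}\t{col.info_bits:.6g}\n")


def plot_logo(logo: LogoMatrix, path: str | Path, title: str = "") -> None:
    """Render a simple sequence logo (letter height = frequency x info bits)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.35 * len(logo)), 2.5))
    for j, col in enumerate(logo.columns, start=1):
        y = 0.0
        for aa, f in sorted(col.frequencies.items(), key=lambda kv: kv[1]):
            h = f * col.info_bits
            if h <= 0:
                continue
            ax.text(
                j,
                y + h / 2,
                aa,
                ha="center",
                va="center",
                fontsize=6 + 14 * min(1.0, h / MAX_INFO_BITS),
                family="monospace",
            )
            y += h
    ax.set_xlim(0.5, len(logo) + 0.5)
    ax.set_ylim(0, MAX_INFO_BITS)
    ax.set_xlabel("alignment position")
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(str(path), dpi=150)
    plt.close(fig)
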