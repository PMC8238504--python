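"""Anchored gene-neighborhood mining of flavinylation-associated clusters.

The four anchor roles are the flavinylation components themselves: the ApbE
flavin transferase (PF02424), its canonical FMN-binding substrate domain
(PF04205), and the two alternative substrate domains DUF3570 (PF12094) and
DUF2271 (PF10029).  Around every anchor gene, the five genes upstream and the
five genes downstream are collected (gene-order window, truncated at contig
ends).  Overlapping windows on a contig are merged into one locus by default,
so adjacent anchors of a single system are counted once.  A cluster is kept
as extracytosolic only when at least one anchor-role gene in it carries a
predicted signal peptide (Sec or Tat) or lipoprotein signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .annotation_ingest import AnnotationConfig, ProteinAnnotation, annotate_proteins
from .genome_model import AnnotatedGenome, GeneRecord

__all__ = [
    "ANCHOR_ACCESSIONS",
    "AnchorRole",
    "MiningConfig",
    "GeneCluster",
    "detect_anchors",
    "build_clusters",
    "filter_extracytosolic",
    "mine_genome",
    "write_clusters_tsv",
]

#: Pfam accession -> anchor role.  The role list is closed; one gene may
#: carry several roles (e.g. an ApbE-DUF2271 fusion).
ANCHOR_ACCESSIONS: dict[str, str] = {
    "PF02424": "APBE",
    "PF04205": "FMN_BINDING",
    "PF12094": "DUF3570",
    "PF10029": "DUF2271",
}

AnchorRole = str  # one of ANCHOR_ACCESSIONS.values()


@dataclass(frozen=True)
class MiningConfig:
    """Window geometry for neighborhood mining.

    window
        Genes collected on each side of an anchor (default 5).
    frd_window
        Smaller window used for fumarate-reductase-like co-occurrence
        analysis (default 2).
    merge_overlapping
        Merge anchor windows sharing at least one gene into a single locus
        (default True).
    """

    window: int = 5
    frd_window: int = 2
    merge_overlapping: bool = True

    def __post_init__(self) -> None:
        if self.window < 0 or self.frd_window < 0:
            raise ValueError("windows must be >= 0")
        if self.window < self.frd_window:
            raise ValueError("window must be >= frd_window")


@dataclass
class GeneCluster:
    """An anchor gene (or merged run of anchors) plus its retained neighbors."""

    cluster_id: str
    genome_id: str
    contig_id: str
    anchor_genes: list[tuple[str, frozenset[AnchorRole]]]
    member_genes: list[GeneRecord]
    extracytosolic: bool | None = None

    @property
    def start_index(self) -> int:
        return self.member_genes[0].gene_index

    @property
    def end_index(self) -> int:
        return self.member_genes[-1].gene_index

    @property
    def member_protein_ids(self) -> list[str]:
        return [g.protein_id for g in self.member_genes]

    @property
    def anchor_protein_ids(self) -> list[str]:
        return [pid for pid, _ in self.anchor_genes]

    @property
    def roles(self) -> frozenset[AnchorRole]:
        out: set[AnchorRole] = set()
        for _, roles in self.anchor_genes:
            out |= roles
        return frozenset(out)


def detect_anchors(
    genome: AnnotatedGenome,
    annotations: dict[str, ProteinAnnotation] | None = None,
    cfg: AnnotationConfig | None = None,
) -> list[tuple[GeneRecord, frozenset[AnchorRole]]]:
    """Find all anchor genes: genes with >=1 passing hit to an anchor Pfam.

    Every applicable role is recorded; ordering follows gene order.
    """
    if annotations is None:
        annotations = annotate_proteins(genome, cfg)
    anchors: list[tuple[GeneRecord, frozenset[AnchorRole]]] = []
    for gene in genome.genes():
        ann = annotations.get(gene.protein_id)
        if ann is None:
            continue
        roles = frozenset(
            role
            for acc, role in ANCHOR_ACCESSIONS.items()
            if acc in ann.pfam_accessions
        )
        if roles:
            anchors.append((gene, roles))
    return anchors


def build_clusters(
    genome: AnnotatedGenome,
    anchors: Sequence[tuple[GeneRecord, frozenset[AnchorRole]]],
    cfg: MiningConfig | None = None,
) -> list[GeneCluster]:
    """Expand each anchor into a ±window gene interval and (optionally) merge
    overlapping intervals on a contig into one locus.

    Cluster ids are ``genome:contig:leftmost_index`` and therefore stable
    across re-runs; output is ordered by contig then leftmost index.
    """
    cfg = cfg or MiningConfig()
    by_contig: dict[str, list[tuple[GeneRecord, frozenset[AnchorRole]]]] = {}
    for gene, roles in anchors:
        by_contig.setdefault(gene.contig_id, []).append((gene, roles))

    clusters: list[GeneCluster] = []
    for contig_id in sorted(by_contig):
        contig = genome.contigs[contig_id]
        n = len(contig)
        contig_anchors = sorted(by_contig[contig_id], key=lambda a: a[0].gene_index)
        # (lo, hi, anchors) intervals, clipped to the contig
        intervals: list[tuple[int, int, list[tuple[GeneRecord, frozenset[AnchorRole]]]]] = [
            (
                max(0, g.gene_index - cfg.window),
                min(n - 1, g.gene_index + cfg.window),
                [(g, roles)],
            )
            for g, roles in contig_anchors
        ]
        if cfg.merge_overlapping:
            merged: list[list] = []
            for lo, hi, anch in intervals:
                if merged and lo <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], hi)
                    merged[-1][2].extend(anch)
                else:
                    merged.append([lo, hi, list(anch)])
            intervals = [(lo, hi, anch) for lo, hi, anch in merged]
        for lo, hi, anch in intervals:
            clusters.append(
                GeneCluster(
                    cluster_id=f"{genome.genome_id}:{contig_id}:{lo}",
                    genome_id=genome.genome_id,
                    contig_id=contig_id,
                    anchor_genes=[(g.protein_id, roles) for g, roles in anch],
                    member_genes=contig[lo : hi + 1],
                )
            )
    return clusters


def filter_extracytosolic(
    clusters: Iterable[GeneCluster],
    genome: AnnotatedGenome,
) -> list[GeneCluster]:
    """Keep clusters where >=1 anchor-role gene has an SP/TAT/LIPO call.

    The test applies to anchor-role (target) genes only; an exported
    non-anchor neighbor does not rescue a cluster.  Every input cluster gets
    its ``extracytosolic`` flag set; only the retained ones are returned.
    """
    retained: list[GeneCluster] = []
    for cluster in clusters:
        flag = any(
            genome.localization_of(pid).extracytosolic
            for pid in cluster.anchor_protein_ids
        )
        cluster.extracytosolic = flag
        if flag:
            retained.append(cluster)
    return retained


def mine_genome(
    genome: AnnotatedGenome,
    acfg: AnnotationConfig | None = None,
    mcfg: MiningConfig | None = None,
    annotations: dict[str, ProteinAnnotation] | None = None,
) -> tuple[list[GeneCluster], list[GeneCluster]]:
    """Full mining pass: detect anchors, build windows, apply the
    extracytosolic filter.  Returns (all clusters, retained clusters)."""
    if annotations is None:
        annotations = annotate_proteins(genome, acfg)
    anchors = detect_anchors(genome, annotations)
    clusters = build_clusters(genome, anchors, mcfg)
    retained = filter_extracytosolic(clusters, genome)
    return clusters, retained


def write_clusters_tsv(clusters: Iterable[GeneCluster], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "cluster_id\tgenome_id\tcontig_id\tmember_protein_ids\t"
            "anchor_protein_ids\tanchor_roles\textracytosolic\n"
        )
        for c in clusters:
            fh.write(
                "\t".join(
                    (
                        c.cluster_id,
                        c.genome_id,
                        c.contig_id,
                        ",".join(c.member_protein_ids),
                        ",".join(c.anchor_protein_ids),
                        ",".join(sorted(c.roles)),
                        str(bool(c.extracytosolic)),
                    )
                )
                + "\n"
            )
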