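"""Rule-based assignment of clusters to electron-transfer systems, plus the
derived genome-level analyses.

Each of the ten named systems is defined by a key gene (or, for the
NQR/RNF-like system, a two-domain architecture on one protein); a cluster is
matched against every rule independently, so multi-label assignments are
possible (PepSY-like and MsrQ-like genes genuinely co-occur in some loci).
Accessory features — iron transporters, oxidoreductases, NAD-binding
domains, and the like — are annotated for every cluster regardless of
system.

Genome-level analyses built on the same annotations:

* orphan-ApbE detection under two substrate definitions (FMN-binding only,
  or extended with DUF2271/DUF3570), the mechanism by which recognising the
  two DUF substrates shrinks the orphan fraction;
* multi-flavinylated proteins (>1 FMN-binding domain on one protein);
* fumarate-reductase-superfamily co-occurrence with FMN-binding domains and
  multi-heme cytochrome domains, fused or within ±2 genes;
* P19/FTR1 iron-assimilation cluster typing;
* DsbD-independent DUF3570 loci (ApbE + DUF3570 + thioredoxin-like +
  DUF4266 without DsbD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .annotation_ingest import AnnotationConfig, ProteinAnnotation, annotate_proteins
from .cluster_mining import ANCHOR_ACCESSIONS, GeneCluster, MiningConfig
from .genome_model import AnnotatedGenome, DomainHit

__all__ = [
    "SYSTEM_LABELS",
    "RuleTerm",
    "SystemRule",
    "RuleTable",
    "AccessoryFeature",
    "SystemAssignment",
    "load_rules",
    "classify_cluster",
    "classify_clusters",
    "check_nqr_rnf_like",
    "find_orphan_apbe",
    "find_multiflavinylated",
    "analyze_frd",
    "detect_p19_clusters",
    "detect_dsbd_independent_duf3570",
    "write_assignments_tsv",
]

SYSTEM_LABELS = (
    "RNF",
    "NOS",
    "PCE",
    "EET",
    "NQR",
    "NAPH_LIKE",
    "MSRQ_LIKE",
    "PEPSY",
    "DSBD",
    "NQR_RNF_LIKE",
)

FMN_BINDING = "PF04205"
APBE = "PF02424"
DUF3570 = "PF12094"
DUF2271 = "PF10029"
NQRB_RNFD = "PF03116"
NAD_BINDING = "PF00175"
FRD_SUPERFAMILY = "PF00890"
CYTC_MULTIHEME = "PF14537"
P19 = "PF10634"
FTR1 = "PF03239"
THIOREDOXIN_LIKE = "PF13899"
DUF4266 = "PF14086"
DSBD_PFAM = "PF02683"

#: Substrate sets for orphan-ApbE accounting.
SUBSTRATES_FMN_ONLY = frozenset({FMN_BINDING})
SUBSTRATES_EXTENDED = frozenset({FMN_BINDING, DUF2271, DUF3570})

_VALID_NAMESPACES = ("pfam", "kofam")


class RuleConfigError(ValueError):
    """Raised when the rule table references unknown namespaces or is malformed."""


@dataclass(frozen=True)
class RuleTerm:
    namespace: str
    accession: str
    tm_required: bool = False

    def matches(self, ann: ProteinAnnotation) -> bool:
        if self.namespace == "kofam":
            hit = ann.ko == self.accession
        else:
            hit = self.accession in ann.pfam_accessions
        if hit and self.tm_required:
            return ann.tm_helix_count >= 1
        return hit


@dataclass(frozen=True)
class SystemRule:
    system: str
    any_of: tuple[RuleTerm, ...] = ()
    architecture: str | None = None  # "nqr_rnf_like" or None

    def matches(
        self,
        members: Sequence[ProteinAnnotation],
        lengths: Mapping[str, int],
    ) -> bool:
        if self.architecture == "nqr_rnf_like":
            return any(
                check_nqr_rnf_like(lengths.get(a.protein_id, 0), a.pfam_hits)
                for a in members
            )
        return any(term.matches(a) for term in self.any_of for a in members)


@dataclass(frozen=True)
class RuleTable:
    systems: tuple[SystemRule, ...]
    accessories: tuple[tuple[str, RuleTerm], ...]

    @property
    def system_labels(self) -> tuple[str, ...]:
        return tuple(r.system for r in self.systems)


@dataclass(frozen=True)
class AccessoryFeature:
    """An accessory gene/domain found in a cluster.

    ``fused`` is True when the carrier protein also carries an anchor-role
    domain or a key gene of one of the cluster's assigned systems (i.e. the
    feature sits on the relevant core protein rather than elsewhere in the
    cluster).
    """

    feature: str
    carrier: str
    fused: bool


@dataclass
class SystemAssignment:
    """Outcome of classifying one cluster against the rule table."""

    cluster_id: str
    systems: frozenset[str]
    accessories: list[AccessoryFeature] = field(default_factory=list)
    #: For NapH-like clusters: "fused" when the NapH-like protein itself
    #: carries an FMN-binding domain, "separate" when another cluster gene
    #: does, "none" otherwise.
    naph_fmn_mode: str | None = None


def load_rules(path: str | Path | None = None) -> RuleTable:
    """Load the system rule table (bundled default when ``path`` is None)."""
    if path is None:
        text = resources.files("flavimine.data").joinpath("system_rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "systems" not in raw:
        raise RuleConfigError("rule table must contain a 'systems' mapping")

    def _term(spec: Mapping) -> RuleTerm:
        ns = spec.get("namespace")
        if ns not in _VALID_NAMESPACES:
            raise RuleConfigError(f"unknown annotation namespace {ns!r} in rule table")
        if not spec.get("accession"):
            raise RuleConfigError("rule term missing accession")
        return RuleTerm(
            namespace=ns,
            accession=str(spec["accession"]),
            tm_required=bool(spec.get("tm_required", False)),
        )

    systems = []
    for label, spec in raw["systems"].items():
        arch = spec.get("architecture")
        if arch is not None and arch != "nqr_rnf_like":
            raise RuleConfigError(f"unknown architecture constraint {arch!r}")
        terms = tuple(_term(t) for t in spec.get("any", []))
        if arch is None and not terms:
            raise RuleConfigError(f"system {label!r} has no terms and no architecture")
        systems.append(SystemRule(system=str(label), any_of=terms, architecture=arch))

    accessories = tuple(
        (str(label), _term(spec)) for label, spec in raw.get("accessories", {}).items()
    )
    return RuleTable(systems=tuple(systems), accessories=accessories)


def check_nqr_rnf_like(length_aa: int, hits: Iterable[DomainHit]) -> bool:
    """Single-protein NQR/RNF-like architecture test.

    True iff the protein has a passing NqrB/RnfD membrane-domain hit
    (PF03116) and an NqrF-like NAD-binding hit (PF00175) such that the
    membrane domain starts before the NAD-binding domain and within the
    N-terminal half of the protein.  Hits without alignment coordinates are
    indeterminate and reported as non-matching with a warning.
    """
    membrane = [h for h in hits if h.accession == NQRB_RNFD]
    nad = [h for h in hits if h.accession == NAD_BINDING]
    if not membrane or not nad:
        return False
    missing = [h for h in membrane + nad if h.ali_from is None]
    if missing:
        warnings.warn(
            f"protein {missing[0].protein_id!r}: PF03116/PF00175 hits lack "
            "alignment coordinates; NQR/RNF-like architecture indeterminate",
            stacklevel=2,
        )
        return False
    half = length_aa / 2 if length_aa else float("inf")
    return any(
        m.ali_from < c.ali_from and m.ali_from <= half
        for m in membrane
        for c in nad
    )


def classify_cluster(
    cluster: GeneCluster,
    annotations: Mapping[str, ProteinAnnotation],
    rules: RuleTable,
) -> SystemAssignment:
    """Match one extracytosolic cluster against every system rule.

    All matching labels are recorded (multi-label); clusters matching no
    rule get an empty system set.  Accessory features are annotated for the
    cluster regardless of its labels.
    """
    members = [annotations[g.protein_id] for g in cluster.member_genes]
    lengths = {g.protein_id: g.length_aa for g in cluster.member_genes}
    systems = frozenset(
        rule.system for rule in rules.systems if rule.matches(members, lengths)
    )

    # Accessions considered "core" for the fused flag: anchors plus the key
    # pfam/ko accessions of the systems actually assigned.
    core_pfams = set(ANCHOR_ACCESSIONS)
    core_kos: set[str] = set()
    for rule in rules.systems:
        if rule.system in systems:
            for term in rule.any_of:
                (core_pfams if term.namespace == "pfam" else core_kos).add(
                    term.accession
                )
            if rule.architecture == "nqr_rnf_like":
                core_pfams.add(NQRB_RNFD)

    accessories: list[AccessoryFeature] = []
    for label, term in rules.accessories:
        for ann in members:
            if term.matches(ann):
                fused = bool(
                    (ann.pfam_accessions & core_pfams - {term.accession if term.namespace == "pfam" else ""})
                    or (ann.ko is not None and ann.ko in core_kos)
                )
                accessories.append(
                    AccessoryFeature(feature=label, carrier=ann.protein_id, fused=fused)
                )

    naph_mode: str | None = None
    if "NAPH_LIKE" in systems:
        naph_rule = next(r for r in rules.systems if r.system == "NAPH_LIKE")
        carriers = [
            a for a in members if any(t.matches(a) for t in naph_rule.any_of)
        ]
        if any(FMN_BINDING in a.pfam_accessions for a in carriers):
            naph_mode = "fused"
        elif any(FMN_BINDING in a.pfam_accessions for a in members):
            naph_mode = "separate"
        else:
            naph_mode = "none"

    return SystemAssignment(
        cluster_id=cluster.cluster_id,
        systems=systems,
        accessories=accessories,
        naph_fmn_mode=naph_mode,
    )


def classify_clusters(
    clusters: Iterable[GeneCluster],
    annotations: Mapping[str, ProteinAnnotation],
    rules: RuleTable | None = None,
) -> list[SystemAssignment]:
    rules = rules or load_rules()
    return [classify_cluster(c, annotations, rules) for c in clusters]


# ---------------------------------------------------------------------------
# Genome-level analyses
# ---------------------------------------------------------------------------

def find_orphan_apbe(
    genome: AnnotatedGenome,
    annotations: Mapping[str, ProteinAnnotation] | None = None,
    substrate_set: frozenset[str] = SUBSTRATES_EXTENDED,
    cfg: AnnotationConfig | None = None,
) -> bool:
    """True iff the genome encodes >=1 extracytosolic ApbE and zero
    extracytosolic proteins carrying any substrate accession.

    ``substrate_set`` is :data:`SUBSTRATES_FMN_ONLY` or
    :data:`SUBSTRATES_EXTENDED`; moving from the former to the latter is what
    resolves most orphans.
    """
    if annotations is None:
        annotations = annotate_proteins(genome, cfg)
    has_apbe = False
    for ann in annotations.values():
        if not ann.extracytosolic:
            continue
        if APBE in ann.pfam_accessions:
            has_apbe = True
        if ann.pfam_accessions & substrate_set:
            return False
    return has_apbe


def find_multiflavinylated(
    genome: AnnotatedGenome,
    annotations: Mapping[str, ProteinAnnotation] | None = None,
    extracytosolic_only: bool = True,
    cfg: AnnotationConfig | None = None,
) -> list[tuple[str, int]]:
    """Proteins with more than one FMN-binding (PF04205) domain, with counts,
    ordered by gene order."""
    if annotations is None:
        annotations = annotate_proteins(genome, cfg)
    out: list[tuple[str, int]] = []
    for gene in genome.genes():
        ann = annotations.get(gene.protein_id)
        if ann is None:
            continue
        if extracytosolic_only and not ann.extracytosolic:
            continue
        n = ann.pfam_count(FMN_BINDING)
        if n > 1:
            out.append((gene.protein_id, n))
    return out


def analyze_frd(
    genome: AnnotatedGenome,
    annotations: Mapping[str, ProteinAnnotation] | None = None,
    mcfg: MiningConfig | None = None,
    cfg: AnnotationConfig | None = None,
) -> list[dict]:
    """Per fumarate-reductase-superfamily (PF00890) protein, report whether an
    FMN-binding domain or a multi-heme cytochrome c domain is fused to it or
    encoded nearby (within ±frd_window genes on the contig)."""
    if annotations is None:
        annotations = annotate_proteins(genome, cfg)
    mcfg = mcfg or MiningConfig()
    w = mcfg.frd_window
    records: list[dict] = []
    for gene in genome.genes():
        ann = annotations.get(gene.protein_id)
        if ann is None or FRD_SUPERFAMILY not in ann.pfam_accessions:
            continue
        neighbors = [
            annotations[g.protein_id]
            for g in genome.neighbors(gene.contig_id, gene.gene_index, w)
            if g.protein_id != gene.protein_id and g.protein_id in annotations
        ]
        records.append(
            {
                "protein_id": gene.protein_id,
                "frd": True,
                "fmn_fused": FMN_BINDING in ann.pfam_accessions,
                "fmn_nearby": any(
                    FMN_BINDING in a.pfam_accessions for a in neighbors
                ),
                "cytochrome_fused": CYTC_MULTIHEME in ann.pfam_accessions,
                "cytochrome_nearby": any(
                    CYTC_MULTIHEME in a.pfam_accessions for a in neighbors
                ),
            }
        )
    return records


def detect_p19_clusters(
    genome: AnnotatedGenome,
    annotations: Mapping[str, ProteinAnnotation] | None = None,
    mcfg: MiningConfig | None = None,
    cfg: AnnotationConfig | None = None,
) -> list[dict]:
    """For each P19 (PF10634) gene, inspect its ±window neighborhood for the
    FTR1 iron permease, an FMN-binding gene, and a thioredoxin-like gene.

    Gram-positive-style loci pair P19/FTR1 with an FMN-binding gene; many
    Gram-negative loci instead carry an additional thioredoxin-like gene.
    """
    if annotations is None:
        annotations = annotate_proteins(genome, cfg)
    mcfg = mcfg or MiningConfig()
    records: list[dict] = []
    for gene in genome.genes():
        ann = annotations.get(gene.protein_id)
        if ann is None or P19 not in ann.pfam_accessions:
            continue
        hood = [
            annotations[g.protein_id]
            for g in genome.neighbors(gene.contig_id, gene.gene_index, mcfg.window)
            if g.protein_id in annotations
        ]
        records.append(
            {
                "protein_id": gene.protein_id,
                "ftr1": any(FTR1 in a.pfam_accessions for a in hood),
                "fmn_binding": any(FMN_BINDING in a.pfam_accessions for a in hood),
                "thioredoxin_like": any(
                    THIOREDOXIN_LIKE in a.pfam_accessions for a in hood
                ),
            }
        )
    return records


def detect_dsbd_independent_duf3570(
    clusters: Iterable[GeneCluster],
    annotations: Mapping[str, ProteinAnnotation],
) -> dict[str, bool]:
    """Per cluster: True when it encodes ApbE, DUF3570, a thioredoxin-like
    protein and DUF4266 but no DsbD (such loci are counted as the DsbD system
    when DsbD is present instead)."""
    required = (APBE, DUF3570, THIOREDOXIN_LIKE, DUF4266)
    out: dict[str, bool] = {}
    for cluster in clusters:
        accs: set[str] = set()
        for g in cluster.member_genes:
            ann = annotations.get(g.protein_id)
            if ann is not None:
                accs |= ann.pfam_accessions
        out[cluster.cluster_id] = all(r in accs for r in required) and (
            DSBD_PFAM not in accs
        )
    return out


def write_assignments_tsv(
    assignments: Iterable[SystemAssignment], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("cluster_id\tsystems\taccessories\tnaph_fmn_mode\n")
        for a in assignments:
            acc = ";".join(
                f"{f.feature}:{f.carrier}:{'fused' if f.fused else 'separate'}"
                for f in sorted(a.accessories, key=lambda f: (f.feature, f.carrier))
            )
            fh.write(
                "\t".join(
                    (
                        a.cluster_id,
                        ",".join(sorted(a.systems)),
                        acc,
                        a.naph_fmn_mode or "",
                    )
                )
                + "\n"
            )
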