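"""Synthetic annotated-genome generator with a ground-truth ledger.

Stands in for a large reference-genome collection: it emits genomes whose
contigs are ordered genes carrying Pfam/KO labels with E-values,
localization flags, and (where needed) protein sequences with planted
flavinylation motifs — together with a ledger of exactly what was planted,
so every pipeline stage can be validated end to end without downloads.

Planted elements, each on its own contig so that truth spans are exact:

* system templates — one per electron-transfer system, constructed to
  satisfy exactly that system's key-gene rule plus the anchor and
  extracytosolic-filter requirements and nothing else;
* decoys — type (a) plants anchor genes whose target genes all lack an
  export signal (the filter must remove them); type (b) plants key genes
  with no anchor in the window (no cluster may form);
* orphan-ApbE genomes (extracytosolic ApbE alone, or with a DUF2271
  substrate but no FMN-binding gene) exercising both substrate definitions;
* multi-flavinylated proteins with 2..13 FMN-binding domains and matching
  planted motifs;
* P19/FTR1 iron-assimilation loci (FMN-binding or thioredoxin-like flavors)
  and fumarate-reductase-like loci (FMN/cytochrome, fused/nearby);
* DsbD-independent DUF3570 loci.

Background genes draw annotations from a pool disjoint from every rule,
anchor and accessory accession; sub-threshold anchor hits (E-value in
[0.01, 1]) exercise the 0.001 cutoff.  Planted hits draw E-values
log-uniformly from [1e-30, 1e-4].
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .cluster_mining import ANCHOR_ACCESSIONS
from .genome_model import (
    AnnotatedGenome,
    DomainHit,
    GeneRecord,
    LocalizationCall,
    TaxonRecord,
    write_gene_table,
    write_protein_fasta,
    write_taxonomy,
)
from .annotation_ingest import write_annotation_tsv
from .system_classification import SYSTEM_LABELS

__all__ = [
    "GeneratorConfig",
    "PlantedCluster",
    "SyntheticTruth",
    "generate",
    "make_motif_sequence",
    "emit_fixture_files",
]

#: Flanking alphabet for motif-bearing sequences: no serine or threonine, so
#: no accidental [S/T]GA[S/T] site can form outside the planted windows.
_FLANK_ALPHABET = "ACDEFGHIKLMNPQRVWY"

#: Annotation pool for background genes — disjoint from every anchor, key
#: and accessory accession used by the rule table.
_BACKGROUND_PFAMS = (
    "PF00001", "PF00072", "PF00106", "PF00486",
    "PF01547", "PF02518", "PF07690", "PF00528",
)
_BACKGROUND_KOS = ("K00001", "K02014", "K06147", "K01990", "K03088")

#: Key-gene decoy pool for type-(b) decoys (key accession, namespace, tm).
_KEY_DECOYS = (
    ("K03616", "kofam", 0),
    ("K00376", "kofam", 0),
    ("PF13486", "pfam", 0),
    ("K03885", "kofam", 1),
    ("K00351", "kofam", 0),
    ("PF12801", "pfam", 4),
    ("PF01794", "pfam", 6),
    ("PF03929", "pfam", 3),
    ("PF02683", "pfam", 8),
)

_PHYLA = (
    ("Firmicutes", ("Bacillus", "Listeria", "Clostridium")),
    ("Proteobacteria", ("Escherichia", "Shewanella", "Pseudomonas")),
    ("Actinobacteriota", ("Streptomyces", "Mycobacterium")),
    ("Bacteroidota", ("Bacteroides", "Flavobacterium")),
)

#: Largest number of genes any template occupies on a contig.
MAX_TEMPLATE_SPAN = 5


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for synthetic genome generation.

    ``system_mix`` maps each system label to the per-genome probability of
    planting one cluster of that system.  Decoy and feature rates are also
    per-genome probabilities.  ``contigs_per_genome`` controls the number of
    additional background-only contigs (each planted element always gets its
    own contig so that truth spans are exact).
    """

    n_genomes: int = 50
    contigs_per_genome: tuple[int, int] = (1, 2)
    genes_per_contig: tuple[int, int] = (15, 40)
    system_mix: dict[str, float] = field(
        default_factory=lambda: {s: 0.3 for s in SYSTEM_LABELS}
    )
    decoy_anchor_without_localization: float = 0.2
    decoy_key_without_anchor: float = 0.2
    background_annotation_rate: float = 0.1
    background_sp_rate: float = 0.1
    subthreshold_anchor_rate: float = 0.05
    motif_sites_duf2271: int = 1
    motif_sites_duf3570: int = 2
    multiflav_rate: float = 0.15
    fmn_domain_count: tuple[int, int] = (2, 13)
    orphan_apbe_rate: float = 0.0
    apbe_with_duf2271_rate: float = 0.0
    duf3570_independent_rate: float = 0.0
    p19_rate: float = 0.0
    frd_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "decoy_anchor_without_localization": self.decoy_anchor_without_localization,
            "decoy_key_without_anchor": self.decoy_key_without_anchor,
            "background_annotation_rate": self.background_annotation_rate,
            "background_sp_rate": self.background_sp_rate,
            "subthreshold_anchor_rate": self.subthreshold_anchor_rate,
            "multiflav_rate": self.multiflav_rate,
            "orphan_apbe_rate": self.orphan_apbe_rate,
            "apbe_with_duf2271_rate": self.apbe_with_duf2271_rate,
            "duf3570_independent_rate": self.duf3570_independent_rate,
            "p19_rate": self.p19_rate,
            "frd_rate": self.frd_rate,
            **{f"system_mix[{k}]": v for k, v in self.system_mix.items()},
        }
        for name, p in rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        unknown = set(self.system_mix) - set(SYSTEM_LABELS)
        if unknown:
            raise ValueError(f"unknown system labels in system_mix: {sorted(unknown)}")
        if self.genes_per_contig[0] > self.genes_per_contig[1] or self.genes_per_contig[0] < 1:
            raise ValueError("genes_per_contig range is empty or invalid")
        if self.contigs_per_genome[0] > self.contigs_per_genome[1] or self.contigs_per_genome[0] < 0:
            raise ValueError("contigs_per_genome range is empty or invalid")
        if self.genes_per_contig[0] < MAX_TEMPLATE_SPAN:
            raise ValueError(
                f"genes_per_contig minimum {self.genes_per_contig[0]} is smaller "
                f"than the largest template span ({MAX_TEMPLATE_SPAN})"
            )
        if not self.fmn_domain_count[0] <= self.fmn_domain_count[1]:
            raise ValueError("fmn_domain_count range is empty")
        if self.fmn_domain_count[0] < 2:
            raise ValueError("multi-flavinylated proteins need >= 2 domains")


@dataclass(frozen=True)
class PlantedCluster:
    """One planted element and what the pipeline is expected to report."""

    genome_id: str
    contig_id: str
    start_index: int          # gene index of the first template gene
    end_index: int            # gene index of the last template gene
    kind: str                 # "system", "decoy_a", "decoy_b", "orphan", ...
    systems: frozenset[str]   # expected system labels (empty = unclassified)
    expect_cluster: bool      # an extracytosolic cluster should cover the span
    expect_unfiltered: bool   # a pre-filter cluster should exist
    extras: dict = field(default_factory=dict)


@dataclass
class SyntheticTruth:
    """Ledger of everything the generator planted."""

    plantings: list[PlantedCluster] = field(default_factory=list)
    motif_sites: list[tuple[str, str, int]] = field(default_factory=list)  # genome, protein, 1-based pos
    multiflav: list[tuple[str, str, int]] = field(default_factory=list)    # genome, protein, n domains
    orphan: dict[str, tuple[bool, bool]] = field(default_factory=dict)     # genome -> (fmn_only, extended)

    def expected_filtered(self, genome_id: str | None = None) -> list[PlantedCluster]:
        return [
            p
            for p in self.plantings
            if p.expect_cluster and (genome_id is None or p.genome_id == genome_id)
        ]

    def expected_genome_systems(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for p in self.plantings:
            out.setdefault(p.genome_id, set())
            if p.expect_cluster:
                out[p.genome_id] |= set(p.systems)
        return out


def make_motif_sequence(
    n_sites: int,
    length: int,
    rng: random.Random | int = 0,
) -> tuple[str, list[int]]:
    """A length-``length`` sequence with exactly ``n_sites`` motif windows.

    Flanking residues are drawn from an alphabet without S/T, so the scanner
    must find exactly the planted sites.  Returns (sequence, 1-based start
    positions).  Raises on infeasible packing (4*n_sites > length).
    """
    if isinstance(rng, int):
        rng = random.Random(rng)
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    if 4 * n_sites > length:
        raise ValueError(f"cannot pack {n_sites} motifs into {length} residues")
    seq = [rng.choice(_FLANK_ALPHABET) for _ in range(length)]
    positions: list[int] = []
    if n_sites:
        slots = sorted(rng.sample(range(length - 3 * n_sites), n_sites))
        for i, s in enumerate(slots):
            start = s + 3 * i  # 0-based; consecutive starts differ by >= 4
            motif = rng.choice("ST") + "GA" + rng.choice("ST")
            seq[start : start + 4] = motif
            positions.append(start + 1)
    return "".join(seq), positions


# ---------------------------------------------------------------------------
# Gene specs and templates
# ---------------------------------------------------------------------------

@dataclass
class _GeneSpec:
    pfams: list = field(default_factory=list)  # acc or (acc, ali_from, ali_to)
    ko: str | None = None
    loc: str = "OTHER"
    tm: int = 0
    length: int | None = None
    n_motifs: int = 0  # plant a sequence with this many motif sites


def _fmn(loc: str = "SP") -> _GeneSpec:
    return _GeneSpec(pfams=["PF04205"], loc=loc, length=180)


def _apbe(loc: str = "LIPO") -> _GeneSpec:
    return _GeneSpec(pfams=["PF02424"], loc=loc, length=350)


def _duf2271(cfg: GeneratorConfig, loc: str = "SP") -> _GeneSpec:
    return _GeneSpec(
        pfams=["PF10029"], loc=loc, length=135, n_motifs=cfg.motif_sites_duf2271
    )


def _duf3570(cfg: GeneratorConfig, loc: str = "SP") -> _GeneSpec:
    return _GeneSpec(
        pfams=["PF12094"], loc=loc, length=420, n_motifs=cfg.motif_sites_duf3570
    )


def _system_template(
    system: str, cfg: GeneratorConfig, rng: random.Random
) -> tuple[list[_GeneSpec], dict]:
    """Gene specs for one planted system cluster, plus truth extras.

    Each template satisfies exactly its own rule (anchor present, one
    anchor-role gene exported, the key gene in the window) and implies no
    other system label.
    """
    extras: dict = {}
    if system == "RNF":
        specs = [_fmn(), _apbe(), _GeneSpec(ko="K03616", length=300)]
    elif system == "NOS":
        specs = [_fmn(), _apbe(), _GeneSpec(ko="K00376", loc="TAT", length=640)]
    elif system == "PCE":
        specs = [_fmn(), _apbe(), _GeneSpec(pfams=["PF13486"], loc="TAT", length=500)]
    elif system == "EET":
        specs = [_fmn(), _apbe(), _GeneSpec(ko="K03885", tm=1, length=450)]
    elif system == "NQR":
        specs = [_fmn(), _apbe(), _GeneSpec(ko="K00351", tm=1, length=410)]
    elif system == "NAPH_LIKE":
        fused = rng.random() < 0.5
        use_ko = rng.random() < 0.5
        extras["naph_fmn_mode"] = "fused" if fused else "separate"
        if fused:
            naph = _GeneSpec(
                pfams=[] if use_ko else ["PF12801"],
                ko="K19339" if use_ko else None,
                loc="SP",
                tm=4,
                length=520,
            )
            naph.pfams.append("PF04205")
            specs = [naph, _apbe()]
        else:
            naph = _GeneSpec(
                pfams=[] if use_ko else ["PF12801"],
                ko="K19339" if use_ko else None,
                tm=4,
                length=470,
            )
            specs = [naph, _fmn(), _apbe()]
    elif system == "MSRQ_LIKE":
        specs = [
            _GeneSpec(pfams=["PF01794", "PF00175"], tm=6, length=560),
            _fmn(),
            _apbe(),
        ]
    elif system == "PEPSY":
        pepsy_acc = rng.choice(["PF03929", "PF16357"])
        specs = [
            _GeneSpec(pfams=[pepsy_acc], tm=3, length=210),
            _duf2271(cfg),
            _apbe(),
            _GeneSpec(pfams=["PF10670"], loc="SP", length=300),
        ]
    elif system == "DSBD":
        specs = [
            _GeneSpec(pfams=["PF02683"], tm=8, length=580),
            _duf3570(cfg),
            _apbe(),
            _GeneSpec(pfams=["PF13899"], loc="SP", length=160),
            _GeneSpec(pfams=["PF14086"], loc="SP", length=90),
        ]
    elif system == "NQR_RNF_LIKE":
        length = 600
        m_from = rng.randint(int(0.05 * length), int(0.20 * length))
        m_to = rng.randint(m_from + 40, int(0.45 * length))
        c_from = rng.randint(int(0.55 * length), int(0.75 * length))
        c_to = rng.randint(c_from + 40, int(0.95 * length))
        specs = [
            _GeneSpec(
                pfams=[("PF03116", m_from, m_to), ("PF00175", c_from, c_to)],
                tm=6,
                length=length,
            ),
            _fmn(),
            _apbe(),
        ]
    else:
        raise ValueError(f"no template for system {system!r}")
    rng.shuffle(specs)
    return specs, extras


def _feature_template(
    kind: str, cfg: GeneratorConfig, rng: random.Random
) -> tuple[list[_GeneSpec], dict, bool, bool]:
    """Templates for non-system plantings.

    Returns (specs, extras, expect_cluster, expect_unfiltered).
    """
    if kind == "decoy_a":
        anchor = rng.choice(sorted(ANCHOR_ACCESSIONS))
        return [_GeneSpec(pfams=[anchor], loc="OTHER", length=240)], {
            "anchor": anchor
        }, False, True
    if kind == "decoy_b":
        acc, ns, tm = rng.choice(_KEY_DECOYS)
        spec = _GeneSpec(
            pfams=[acc] if ns == "pfam" else [],
            ko=acc if ns == "kofam" else None,
            loc=rng.choice(["SP", "OTHER"]),
            tm=tm,
            length=380,
        )
        return [spec], {"key": acc}, False, False
    if kind == "orphan_apbe":
        return [_apbe(loc="SP")], {}, True, True
    if kind == "apbe_duf2271":
        return [_apbe(loc="SP"), _duf2271(cfg)], {}, True, True
    if kind == "duf3570_independent":
        return (
            [
                _apbe(),
                _duf3570(cfg),
                _GeneSpec(pfams=["PF13899"], loc="SP", length=160),
                _GeneSpec(pfams=["PF14086"], loc="SP", length=90),
            ],
            {},
            True,
            True,
        )
    if kind == "multiflav":
        n = rng.randint(*cfg.fmn_domain_count)
        spec = _GeneSpec(pfams=[], loc="SP", length=120 * n + 20, n_motifs=n)
        for i in range(n):
            spec.pfams.append(("PF04205", 120 * i + 10, 120 * i + 110))
        return [spec, _apbe()], {"n_domains": n}, True, True
    if kind == "p19":
        flavor = rng.choice(["fmn", "trx"])
        if flavor == "fmn":
            specs = [
                _GeneSpec(pfams=["PF10634"], loc="SP", length=160),
                _GeneSpec(pfams=["PF03239"], tm=7, length=260),
                _fmn(),
                _apbe(),
            ]
            return specs, {"p19_flavor": "fmn"}, True, True
        specs = [
            _GeneSpec(pfams=["PF10634"], loc="SP", length=160),
            _GeneSpec(pfams=["PF03239"], tm=7, length=260),
            _GeneSpec(pfams=["PF13899"], loc="SP", length=160),
        ]
        return specs, {"p19_flavor": "trx"}, False, False
    if kind == "frd":
        flavor = rng.choice(["fmn_fused", "fmn_nearby", "cyt_fused", "cyt_nearby"])
        frd = _GeneSpec(pfams=["PF00890"], loc="SP", length=520)
        if flavor == "fmn_fused":
            frd.pfams.append("PF04205")
            specs = [frd]
        elif flavor == "fmn_nearby":
            specs = [frd, _GeneSpec(length=200), _fmn()]
        elif flavor == "cyt_fused":
            frd.pfams.append("PF14537")
            specs = [frd]
        else:
            specs = [frd, _GeneSpec(length=200), _GeneSpec(pfams=["PF14537"], loc="SP", length=310)]
        has_anchor = flavor in ("fmn_fused", "fmn_nearby")
        return specs, {"frd_flavor": flavor}, has_anchor, has_anchor
    raise ValueError(f"unknown planting kind {kind!r}")


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

class _GenomeBuilder:
    def __init__(self, genome_id: str, cfg: GeneratorConfig, rng: random.Random):
        self.genome_id = genome_id
        self.cfg = cfg
        self.rng = rng
        self.genome = AnnotatedGenome(genome_id=genome_id)
        self.truth_motifs: list[tuple[str, str, int]] = []
        self.truth_multiflav: list[tuple[str, str, int]] = []
        self._protein_counter = 0
        self._contig_counter = 0
        # orphan bookkeeping over extracytosolic planted content
        self.has_extra_apbe = False
        self.extra_substrates: set[str] = set()

    def _next_protein(self) -> str:
        self._protein_counter += 1
        return f"{self.genome_id}_p{self._protein_counter:05d}"

    def _planted_evalue(self) -> float:
        return 10.0 ** self.rng.uniform(-30.0, -4.0)

    def _emit_gene(self, contig_id: str, index: int, spec: _GeneSpec) -> GeneRecord:
        pid = self._next_protein()
        seq = None
        if spec.n_motifs:
            seq, positions = make_motif_sequence(
                spec.n_motifs, spec.length or 4 * spec.n_motifs + 40, self.rng
            )
            for pos in positions:
                self.truth_motifs.append((self.genome_id, pid, pos))
        length = len(seq) if seq is not None else (spec.length or self.rng.randint(100, 700))
        gene = GeneRecord(
            genome_id=self.genome_id,
            contig_id=contig_id,
            gene_index=index,
            strand=self.rng.choice("+-"),
            protein_id=pid,
            length_aa=length,
        )
        if seq is not None:
            self.genome.sequences[pid] = seq
        for pf in spec.pfams:
            if isinstance(pf, tuple):
                acc, ali_from, ali_to = pf
            else:
                acc = pf
                ali_from = min(5, length)
                ali_to = max(ali_from, length - 5)
            self.genome.domains.append(
                DomainHit(
                    protein_id=pid,
                    namespace="pfam",
                    accession=acc,
                    evalue=self._planted_evalue(),
                    bitscore=round(self.rng.uniform(50, 500), 1),
                    ali_from=ali_from,
                    ali_to=ali_to,
                )
            )
        if spec.ko:
            self.genome.domains.append(
                DomainHit(
                    protein_id=pid,
                    namespace="kofam",
                    accession=spec.ko,
                    evalue=self._planted_evalue(),
                    bitscore=round(self.rng.uniform(50, 500), 1),
                )
            )
        self.genome.localization[pid] = LocalizationCall(
            protein_id=pid, call=spec.loc, tm_helix_count=spec.tm
        )
        if spec.loc in ("SP", "TAT", "LIPO"):
            accs = {pf[0] if isinstance(pf, tuple) else pf for pf in spec.pfams}
            if "PF02424" in accs:
                self.has_extra_apbe = True
            self.extra_substrates |= accs & {"PF04205", "PF10029", "PF12094"}
        return gene

    def _background_spec(self) -> _GeneSpec:
        rng = self.rng
        spec = _GeneSpec(length=rng.randint(100, 700))
        if rng.random() < self.cfg.background_annotation_rate:
            if rng.random() < 0.5:
                spec.pfams.append(rng.choice(_BACKGROUND_PFAMS))
            else:
                spec.ko = rng.choice(_BACKGROUND_KOS)
        if rng.random() < self.cfg.background_sp_rate:
            spec.loc = rng.choice(["SP", "LIPO"])
        if rng.random() < 0.15:
            spec.tm = rng.randint(1, 8)
        return spec

    def _maybe_subthreshold_anchor(self, pid: str) -> None:
        if self.rng.random() < self.cfg.subthreshold_anchor_rate:
            self.genome.domains.append(
                DomainHit(
                    protein_id=pid,
                    namespace="pfam",
                    accession=self.rng.choice(sorted(ANCHOR_ACCESSIONS)),
                    evalue=10.0 ** self.rng.uniform(-2.0, 0.0),  # 0.01 .. 1
                    bitscore=round(self.rng.uniform(5, 20), 1),
                )
            )

    def add_contig(self, specs: Sequence[_GeneSpec] | None) -> tuple[str, int, int]:
        """One contig; ``specs`` (if any) are placed contiguously at a random
        offset, the rest is background.  Returns (contig_id, start, end)."""
        cfg, rng = self.cfg, self.rng
        contig_id = f"{self.genome_id}_c{self._contig_counter:03d}"
        self._contig_counter += 1
        span = len(specs) if specs else 0
        n = rng.randint(max(cfg.genes_per_contig[0], span), cfg.genes_per_contig[1])
        start = rng.randint(0, n - span) if span else 0
        genes: list[GeneRecord] = []
        for i in range(n):
            if specs and start <= i < start + span:
                gene = self._emit_gene(contig_id, i, specs[i - start])
            else:
                gene = self._emit_gene(contig_id, i, self._background_spec())
                self._maybe_subthreshold_anchor(gene.protein_id)
            genes.append(gene)
        self.genome.contigs[contig_id] = genes
        return contig_id, start, start + span - 1 if span else -1


def generate(cfg: GeneratorConfig) -> tuple[list[AnnotatedGenome], SyntheticTruth]:
    """Generate the synthetic genome collection and its truth ledger.

    Deterministic given ``cfg.seed``: the same config always yields the same
    genomes, annotations, sequences and truth.
    """
    cfg.validate()
    master = random.Random(cfg.seed)
    truth = SyntheticTruth()
    genomes: list[AnnotatedGenome] = []

    for g in range(cfg.n_genomes):
        genome_id = f"SYN{g:05d}"
        rng = random.Random(master.randrange(2**31))
        builder = _GenomeBuilder(genome_id, cfg, rng)

        plantings: list[tuple[str, str | None]] = []  # (kind, system)
        for system in SYSTEM_LABELS:
            if rng.random() < cfg.system_mix.get(system, 0.0):
                plantings.append(("system", system))
        for kind, rate in (
            ("decoy_a", cfg.decoy_anchor_without_localization),
            ("decoy_b", cfg.decoy_key_without_anchor),
            ("orphan_apbe", cfg.orphan_apbe_rate),
            ("apbe_duf2271", cfg.apbe_with_duf2271_rate),
            ("duf3570_independent", cfg.duf3570_independent_rate),
            ("multiflav", cfg.multiflav_rate),
            ("p19", cfg.p19_rate),
            ("frd", cfg.frd_rate),
        ):
            if rng.random() < rate:
                plantings.append((kind, None))

        for kind, system in plantings:
            if kind == "system":
                specs, extras = _system_template(system, cfg, rng)
                expect_cluster = expect_unfiltered = True
                systems = frozenset({system})
            else:
                specs, extras, expect_cluster, expect_unfiltered = _feature_template(
                    kind, cfg, rng
                )
                systems = frozenset()
            before_multiflav = len(builder.truth_motifs)
            contig_id, start, end = builder.add_contig(specs)
            truth.plantings.append(
                PlantedCluster(
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start_index=start,
                    end_index=end,
                    kind=kind,
                    systems=systems,
                    expect_cluster=expect_cluster,
                    expect_unfiltered=expect_unfiltered,
                    extras=extras,
                )
            )
            if kind == "multiflav":
                # the multi-domain protein is the one carrying the motifs
                pid = builder.truth_motifs[before_multiflav][1]
                builder.truth_multiflav.append(
                    (genome_id, pid, extras["n_domains"])
                )

        for _ in range(rng.randint(*cfg.contigs_per_genome)):
            builder.add_contig(None)

        phylum, genera = _PHYLA[g % len(_PHYLA)]
        genus = genera[g % len(genera)]
        builder.genome.taxon = TaxonRecord(
            genome_id=genome_id,
            lineage=(
                f"d__Bacteria;p__{phylum};c__{phylum}ia;o__{genus}ales;"
                f"f__{genus}aceae;g__{genus};s__{genus} sp{g:05d}"
            ),
        )
        builder.genome.validate()
        genomes.append(builder.genome)
        truth.motif_sites.extend(builder.truth_motifs)
        truth.multiflav.extend(builder.truth_multiflav)
        fmn_only = builder.has_extra_apbe and "PF04205" not in builder.extra_substrates
        extended = builder.has_extra_apbe and not builder.extra_substrates
        truth.orphan[genome_id] = (fmn_only, extended)

    return genomes, truth


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------

def emit_fixture_files(
    genomes: Sequence[AnnotatedGenome],
    truth: SyntheticTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the fixture bundle: gene table, protein FASTA, annotation TSV,
    localization files (signal-peptide summary + TM short format), taxonomy,
    and the truth ledger TSVs.  All files parse cleanly by the reader
    operations; returns a name -> path mapping."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_table": outdir / "genes.tsv",
        "fasta": outdir / "proteins.faa",
        "annotations": outdir / "annotations.tsv",
        "signalp": outdir / "signalp_summary.tsv",
        "tmhmm": outdir / "tmhmm_short.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "truth_clusters": outdir / "truth_clusters.tsv",
        "truth_motifs": outdir / "truth_motifs.tsv",
        "truth_multiflav": outdir / "truth_multiflav.tsv",
        "truth_orphans": outdir / "truth_orphans.tsv",
    }

    write_gene_table(genomes, paths["gene_table"])

    sequences: dict[str, str] = {}
    for genome in genomes:
        sequences.update(genome.sequences)
    write_protein_fasta(sequences, paths["fasta"])

    hits = [h for genome in genomes for h in genome.domains]
    write_annotation_tsv(hits, paths["annotations"])

    token_of = {"SP": "SP(Sec/SPI)", "LIPO": "LIPO(Sec/SPII)", "TAT": "TAT(Tat/SPI)", "OTHER": "OTHER"}
    with paths["signalp"].open("w") as fh:
        fh.write("# ID\tPrediction\n")
        for genome in genomes:
            for gene in genome.genes():
                call = genome.localization_of(gene.protein_id)
                fh.write(f"{gene.protein_id}\t{token_of[call.call]}\n")
    with paths["tmhmm"].open("w") as fh:
        for genome in genomes:
            for gene in genome.genes():
                call = genome.localization_of(gene.protein_id)
                fh.write(
                    f"{gene.protein_id}\tlen={gene.length_aa}\tExpAA=0.00\t"
                    f"First60=0.00\tPredHel={call.tm_helix_count}\tTopology=o\n"
                )

    taxa = {g.genome_id: g.taxon for g in genomes if g.taxon is not None}
    write_taxonomy(taxa, paths["taxonomy"])

    with paths["truth_clusters"].open("w") as fh:
        fh.write(
            "genome_id\tcontig_id\tstart_index\tend_index\tkind\tsystems\t"
            "expect_cluster\texpect_unfiltered\textras\n"
        )
        for p in truth.plantings:
            fh.write(
                "\t".join(
                    (
                        p.genome_id,
                        p.contig_id,
                        str(p.start_index),
                        str(p.end_index),
                        p.kind,
                        ",".join(sorted(p.systems)),
                        str(p.expect_cluster),
                        str(p.expect_unfiltered),
                        json.dumps(p.extras, sort_keys=True),
                    )
                )
                + "\n"
            )
    with paths["truth_motifs"].open("w") as fh:
        fh.write("genome_id\tprotein_id\tposition\n")
        for genome_id, pid, pos in truth.motif_sites:
            fh.write(f"{genome_id}\t{pid}\t{pos}\n")
    with paths["truth_multiflav"].open("w") as fh:
        fh.write("genome_id\tprotein_id\tn_domains\n")
        for genome_id, pid, n in truth.multiflav:
            fh.write(f"{genome_id}\t{pid}\t{n}\n")
    with paths["truth_orphans"].open("w") as fh:
        fh.write("genome_id\torphan_fmn_only\torphan_extended\n")
        for genome_id in sorted(truth.orphan):
            fmn_only, extended = truth.orphan[genome_id]
            fh.write(f"{genome_id}\t{fmn_only}\t{extended}\n")

    return paths
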