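"""End-to-end pipeline orchestration: ingest -> mine -> classify -> motif ->
logo -> summarize, from a single config, with per-stage TSV outputs and a
machine-readable run manifest.

Stage outputs are pure functions of (inputs, config): re-running with an
identical config and identical input files reproduces byte-identical
outputs, recorded as SHA-256 checksums in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation_ingest import (
    AnnotationConfig,
    annotate_proteins,
    parse_localization,
    read_annotation_tsv,
)
from .cluster_mining import MiningConfig, mine_genome, write_clusters_tsv
from .genome_model import read_gene_table, read_protein_fasta, read_taxonomy
from .motif_logo import (
    build_logo,
    read_alignment_fasta,
    scan_flavinylation_motifs,
    write_logo_tsv,
    write_motif_sites_tsv,
)
from .summary_report import (
    summarize_by_taxon,
    summarize_genomes,
    write_itol_presence,
)
from .system_classification import (
    analyze_frd,
    classify_clusters,
    detect_dsbd_independent_duf3570,
    detect_p19_clusters,
    load_rules,
    write_assignments_tsv,
)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger("flavimine")

ALL_STAGES = ("mine", "classify", "motif", "logo", "summarize")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and stage toggles for one pipeline run."""

    gene_table: str
    annotations: str
    signalp: str
    outdir: str
    fasta: str | None = None
    tmhmm: str | None = None
    taxonomy: str | None = None
    alignment: str | None = None  # gapped FASTA for the logo stage
    rules: str | None = None      # system rule table; bundled default if None
    evalue_cutoff: float = 0.001
    window: int = 5
    frd_window: int = 2
    merge_overlapping: bool = True
    stages: tuple[str, ...] = ALL_STAGES
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def annotation_config(self) -> AnnotationConfig:
        return AnnotationConfig(evalue_cutoff=self.evalue_cutoff)

    def mining_config(self) -> MiningConfig:
        return MiningConfig(
            window=self.window,
            frd_window=self.frd_window,
            merge_overlapping=self.merge_overlapping,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def validate_config(config: PipelineConfig) -> list[str]:
    """Report problems without mutating anything; an empty list means clean."""
    problems: list[str] = []
    required = {"gene_table": config.gene_table, "annotations": config.annotations,
                "signalp": config.signalp}
    optional = {"fasta": config.fasta, "tmhmm": config.tmhmm,
                "taxonomy": config.taxonomy, "alignment": config.alignment,
                "rules": config.rules}
    for name, path in required.items():
        if not path or not Path(path).exists():
            problems.append(f"missing input file for {name}: {path!r}")
    for name, path in optional.items():
        if path is not None and not Path(path).exists():
            problems.append(f"configured {name} does not exist: {path!r}")
    if config.evalue_cutoff <= 0:
        problems.append("evalue_cutoff must be > 0")
    if config.window < config.frd_window:
        problems.append(
            f"window ({config.window}) smaller than frd_window ({config.frd_window})"
        )
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        problems.append(f"unknown stages: {sorted(unknown)}")
    # motif/logo stages are skipped (not errors) when their optional input is
    # absent, so stage toggles can stay at the default.
    if config.rules is not None and Path(config.rules).exists():
        try:
            load_rules(config.rules)
        except Exception as exc:  # configuration errors surface at load time
            problems.append(f"rule table invalid: {exc}")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order and write the manifest.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    A hard validation problem raises ValueError before any stage runs.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid pipeline config: " + "; ".join(problems))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    acfg = config.annotation_config()
    mcfg = config.mining_config()
    rules = load_rules(config.rules)

    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    t0 = time.perf_counter()
    genomes = read_gene_table(config.gene_table)
    hits = read_annotation_tsv(config.annotations)
    localization = parse_localization(config.signalp, config.tmhmm)
    sequences = read_protein_fasta(config.fasta) if config.fasta else {}
    taxonomy = read_taxonomy(config.taxonomy) if config.taxonomy else {}
    for genome in genomes:
        pids = {g.protein_id for g in genome.genes()}
        genome.domains = [h for h in hits if h.protein_id in pids]
        genome.localization = {p: c for p, c in localization.items() if p in pids}
        genome.sequences = {p: s for p, s in sequences.items() if p in pids}
        genome.taxon = taxonomy.get(genome.genome_id)
        genome.validate()
    logger.info("ingest: %d genomes in %.2fs", len(genomes), time.perf_counter() - t0)

    annotations_by_genome = {
        g.genome_id: annotate_proteins(g, acfg) for g in genomes
    }

    def _record(stage: str, outputs: dict[str, Path], t_start: float) -> None:
        manifest["stages"][stage] = {
            "outputs": {
                name: {"path": str(p), "sha256": _sha256(p)}
                for name, p in sorted(outputs.items())
            },
            "seconds": round(time.perf_counter() - t_start, 3),
        }
        logger.info("stage %s done (%.2fs)", stage, time.perf_counter() - t_start)

    mined: dict[str, tuple[list, list]] = {}
    try:
        if "mine" in config.stages:
            t = time.perf_counter()
            for genome in genomes:
                mined[genome.genome_id] = mine_genome(
                    genome, acfg, mcfg, annotations_by_genome[genome.genome_id]
                )
            all_clusters = [c for pair in mined.values() for c in pair[0]]
            path = outdir / "clusters.tsv"
            write_clusters_tsv(all_clusters, path)
            _record("mine", {"clusters": path}, t)

        if "classify" in config.stages:
            if "mine" not in config.stages:
                raise ValueError("classify stage requires the mine stage")
            t = time.perf_counter()
            assignments_by_genome = {}
            dsbd_indep: dict[str, bool] = {}
            frd_rows, p19_rows, multiflav_rows, orphan_rows = [], [], [], []
            for genome in genomes:
                anns = annotations_by_genome[genome.genome_id]
                _, retained = mined[genome.genome_id]
                assignments_by_genome[genome.genome_id] = classify_clusters(
                    retained, anns, rules
                )
                dsbd_indep.update(detect_dsbd_independent_duf3570(retained, anns))
                for rec in analyze_frd(genome, anns, mcfg):
                    frd_rows.append({"genome_id": genome.genome_id, **rec})
                for rec in detect_p19_clusters(genome, anns, mcfg):
                    p19_rows.append({"genome_id": genome.genome_id, **rec})
            apath = outdir / "assignments.tsv"
            write_assignments_tsv(
                [a for group in assignments_by_genome.values() for a in group], apath
            )
            dpath = outdir / "dsbd_independent_duf3570.tsv"
            with dpath.open("w") as fh:
                fh.write("cluster_id\tdsbd_independent_duf3570\n")
                for cid in sorted(dsbd_indep):
                    fh.write(f"{cid}\t{dsbd_indep[cid]}\n")
            fpath = outdir / "frd_cooccurrence.tsv"
            _write_dict_rows(
                fpath,
                ["genome_id", "protein_id", "frd", "fmn_fused", "fmn_nearby",
                 "cytochrome_fused", "cytochrome_nearby"],
                frd_rows,
            )
            ppath = outdir / "p19_clusters.tsv"
            _write_dict_rows(
                ppath,
                ["genome_id", "protein_id", "ftr1", "fmn_binding", "thioredoxin_like"],
                p19_rows,
            )
            _record(
                "classify",
                {"assignments": apath, "dsbd_independent": dpath,
                 "frd": fpath, "p19": ppath},
                t,
            )

        if "motif" in config.stages and config.fasta:
            t = time.perf_counter()
            sites = []
            for pid in sorted(sequences):
                sites.extend(scan_flavinylation_motifs(sequences[pid], pid))
            path = outdir / "motif_sites.tsv"
            write_motif_sites_tsv(sites, path)
            _record("motif", {"motif_sites": path}, t)

        if "logo" in config.stages and config.alignment:
            t = time.perf_counter()
            alignment = read_alignment_fasta(config.alignment)
            logo = build_logo(list(alignment.values()))
            path = outdir / "logo_matrix.tsv"
            write_logo_tsv(logo, path)
            _record("logo", {"logo_matrix": path}, t)

        if "summarize" in config.stages:
            if "classify" not in config.stages:
                raise ValueError("summarize stage requires the classify stage")
            t = time.perf_counter()
            summary = summarize_genomes(
                genomes, assignments_by_genome, annotations_by_genome
            )
            gpath = outdir / "genome_summary.tsv"
            summary.to_csv(gpath, sep="\t", index=False)
            outputs = {"genome_summary": gpath}
            if taxonomy:
                for rank in ("genus", "phylum"):
                    tpath = outdir / f"{rank}_summary.tsv"
                    summarize_by_taxon(summary, taxonomy, rank).to_csv(
                        tpath, sep="\t", index=False
                    )
                    outputs[f"{rank}_summary"] = tpath
            ipath = outdir / "itol_presence.txt"
            write_itol_presence(summary, ipath)
            outputs["itol"] = ipath
            _record("summarize", outputs, t)
    except Exception as exc:
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        raise

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _write_dict_rows(path: Path, columns: list[str], rows: list[dict]) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")
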