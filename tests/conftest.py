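"""Shared fixtures: hand-built micro-genomes and a session-scoped synthetic
fixture bundle on disk."""

from __future__ import annotations

import random

import pytest

from flavimine.genome_model import (
    AnnotatedGenome,
    DomainHit,
    GeneRecord,
    LocalizationCall,
)


def make_genome(
    gene_specs,
    genome_id: str = "G1",
    contig_id: str = "c1",
) -> AnnotatedGenome:
    """Build a one-contig genome from compact per-gene specs.

    Each spec is a dict with optional keys: ``pfams`` (list of accession or
    (accession, ali_from, ali_to, evalue) tuples), ``ko``,
    ``ko_evalue``, ``loc``, ``tm``, ``length``, ``seq``.
    """
    genome = AnnotatedGenome(genome_id=genome_id)
    genes = []
    for i, spec in enumerate(gene_specs):
        pid = spec.get("protein_id", f"{genome_id}_{contig_id}_g{i}")
        length = spec.get("length", 300)
        if "seq" in spec:
            length = len(spec["seq"])
            genome.sequences[pid] = spec["seq"]
        genes.append(
            GeneRecord(
                genome_id=genome_id,
                contig_id=contig_id,
                gene_index=i,
                strand=spec.get("strand", "+"),
                protein_id=pid,
                length_aa=length,
            )
        )
        for pf in spec.get("pfams", []):
            if isinstance(pf, tuple):
                acc, ali_from, ali_to = pf[0], pf[1], pf[2]
                evalue = pf[3] if len(pf) > 3 else 1e-10
            else:
                acc, ali_from, ali_to, evalue = pf, 1, length, 1e-10
            genome.domains.append(
                DomainHit(
                    protein_id=pid,
                    namespace="pfam",
                    accession=acc,
                    evalue=evalue,
                    bitscore=100.0,
                    ali_from=ali_from,
                    ali_to=ali_to,
                )
            )
        if "ko" in spec:
            genome.domains.append(
                DomainHit(
                    protein_id=pid,
                    namespace="kofam",
                    accession=spec["ko"],
                    evalue=spec.get("ko_evalue", 1e-10),
                    bitscore=100.0,
                )
            )
        genome.localization[pid] = LocalizationCall(
            protein_id=pid,
            call=spec.get("loc", "OTHER"),
            tm_helix_count=spec.get("tm", 0),
        )
    genome.contigs[contig_id] = genes
    genome.validate()
    return genome


@pytest.fixture
def micro_genome_factory():
    return make_genome


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """A small synthetic genome collection emitted to disk once per session."""
    from flavimine.synthetic_data import GeneratorConfig, emit_fixture_files, generate

    cfg = GeneratorConfig(
        n_genomes=12,
        seed=42,
        orphan_apbe_rate=0.2,
        apbe_with_duf2271_rate=0.2,
        duf3570_independent_rate=0.2,
        p19_rate=0.3,
        frd_rate=0.3,
    )
    genomes, truth = generate(cfg)
    outdir = tmp_path_factory.mktemp("bundle")
    paths = emit_fixture_files(genomes, truth, outdir)
    return {"config": cfg, "genomes": genomes, "truth": truth, "paths": paths}


@pytest.fixture
def rng():
    return random.Random(1234)


# deterministic property-based testing
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
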