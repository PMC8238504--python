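"""Aggregation of per-cluster assignments into reporting units.

Three granularities are used:

* per genome — presence of any extracytosolic flavinylation component
  (exported FMN-binding or ApbE protein), the set of systems present
  (deduplicated: several clusters of one system count once), orphan-ApbE
  flags under both substrate definitions, and multi-flavinylated protein
  counts;
* per genus — boolean presence (any genome of the genus);
* per phylum — genome counts per system.

Cluster-level counts remain available from the assignment table itself; the
genome/taxon tables always state which unit they use.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_ingest import AnnotationConfig, ProteinAnnotation, annotate_proteins
from .genome_model import AnnotatedGenome, TaxonRecord
from .system_classification import (
    APBE,
    FMN_BINDING,
    SUBSTRATES_EXTENDED,
    SUBSTRATES_FMN_ONLY,
    SYSTEM_LABELS,
    SystemAssignment,
    find_multiflavinylated,
    find_orphan_apbe,
)

__all__ = [
    "summarize_genomes",
    "summarize_by_taxon",
    "crosstab",
    "write_itol_presence",
]


def summarize_genomes(
    genomes: Sequence[AnnotatedGenome],
    assignments_by_genome: Mapping[str, Sequence[SystemAssignment]],
    annotations_by_genome: Mapping[str, Mapping[str, ProteinAnnotation]] | None = None,
    cfg: AnnotationConfig | None = None,
) -> pd.DataFrame:
    """One row per genome with flavinylation-component presence, the set of
    systems present, gene counts, orphan flags and multi-flavinylation counts.

    ``has_flavinylation_component`` is True iff the genome encodes at least
    one extracytosolic (SP/TAT/LIPO) protein with an FMN-binding domain or
    an ApbE domain.  ``n_apbe_genes`` counts all ApbE genes regardless of
    localization; ``n_extracytosolic_fmn_genes`` applies the localization
    filter.
    """
    rows = []
    for genome in genomes:
        if annotations_by_genome is not None:
            annotations = annotations_by_genome[genome.genome_id]
        else:
            annotations = annotate_proteins(genome, cfg)
        anns = list(annotations.values())
        n_fmn_extra = sum(
            1 for a in anns if a.extracytosolic and FMN_BINDING in a.pfam_accessions
        )
        n_apbe = sum(1 for a in anns if APBE in a.pfam_accessions)
        has_component = n_fmn_extra > 0 or any(
            a.extracytosolic and APBE in a.pfam_accessions for a in anns
        )
        systems: set[str] = set()
        for assignment in assignments_by_genome.get(genome.genome_id, ()):
            systems |= assignment.systems
        rows.append(
            {
                "genome_id": genome.genome_id,
                "has_flavinylation_component": has_component,
                "systems_present": ";".join(sorted(systems)),
                "n_extracytosolic_fmn_genes": n_fmn_extra,
                "n_apbe_genes": n_apbe,
                "orphan_apbe_fmn_only": find_orphan_apbe(
                    genome, annotations, SUBSTRATES_FMN_ONLY
                ),
                "orphan_apbe_extended": find_orphan_apbe(
                    genome, annotations, SUBSTRATES_EXTENDED
                ),
                "multiflavinylated_proteins": len(
                    find_multiflavinylated(genome, annotations)
                ),
            }
        )
    columns = [
        "genome_id",
        "has_flavinylation_component",
        "systems_present",
        "n_extracytosolic_fmn_genes",
        "n_apbe_genes",
        "orphan_apbe_fmn_only",
        "orphan_apbe_extended",
        "multiflavinylated_proteins",
    ]
    return pd.DataFrame(rows, columns=columns)


def _features_of(row: pd.Series) -> set[str]:
    feats = set(row["systems_present"].split(";")) - {""}
    if row["has_flavinylation_component"]:
        feats.add("FLAVINYLATION")
    return feats


def summarize_by_taxon(
    genome_summaries: pd.DataFrame,
    taxonomy: Mapping[str, TaxonRecord],
    rank: str,
) -> pd.DataFrame:
    """Aggregate genome summaries at genus or phylum rank.

    At ``rank="genus"`` the per-feature columns are boolean presence (at
    least one genome of the genus has the feature); at ``rank="phylum"`` they
    are genome counts.  Genomes absent from the taxonomy are grouped under
    "unclassified".
    """
    if rank not in ("genus", "phylum"):
        raise ValueError(f"unknown rank {rank!r}; expected 'genus' or 'phylum'")

    features = ["FLAVINYLATION", *SYSTEM_LABELS]
    buckets: dict[str, dict] = {}
    for _, row in genome_summaries.iterrows():
        taxon = taxonomy.get(row["genome_id"])
        name = getattr(taxon, rank) if taxon is not None else "unclassified"
        bucket = buckets.setdefault(
            name, {"n_genomes": 0, **{f: 0 for f in features}}
        )
        bucket["n_genomes"] += 1
        present = _features_of(row)
        for f in present & set(features):
            bucket[f] += 1

    rows = []
    for name in sorted(buckets):
        bucket = buckets[name]
        row = {rank: name, "n_genomes": bucket["n_genomes"]}
        for f in features:
            row[f] = bool(bucket[f]) if rank == "genus" else bucket[f]
        rows.append(row)
    return pd.DataFrame(rows, columns=[rank, "n_genomes", *features])


def crosstab(
    labels: Mapping[str, Iterable[str]],
    row_feature: str,
    col_feature: str,
) -> pd.DataFrame:
    """2x2 contingency table of label co-occurrence over units.

    ``labels`` maps a unit id (cluster or genome) to the labels it carries;
    the result counts units by presence/absence of the two features, indexed
    [True, False] x [True, False].
    """
    table = pd.DataFrame(
        0, index=pd.Index([True, False], name=row_feature),
        columns=pd.Index([True, False], name=col_feature),
    )
    for unit_labels in labels.values():
        s = set(unit_labels)
        table.loc[row_feature in s, col_feature in s] += 1
    return table


def write_itol_presence(
    genome_summaries: pd.DataFrame,
    path: str | Path,
    dataset_label: str = "flavinylation systems",
) -> None:
    """Write an iTOL binary-dataset annotation file keyed by genome_id, one
    field per system plus overall flavinylation presence, for decorating an
    externally built species tree."""
    features = ["FLAVINYLATION", *SYSTEM_LABELS]
    path = Path(path)
    with path.open("w") as fh:
        fh.write("DATASET_BINARY\n")
        fh.write("SEPARATOR TAB\n")
        fh.write(f"DATASET_LABEL\t{dataset_label}\n")
        fh.write("COLOR\t#b58900\n")
        fh.write("FIELD_SHAPES\t" + "\t".join(["2"] * len(features)) + "\n")
        fh.write("FIELD_LABELS\t" + "\t".join(features) + "\n")
        fh.write("DATA\n")
        for _, row in genome_summaries.iterrows():
            present = _features_of(row)
            values = "\t".join("1" if f in present else "0" for f in features)
            fh.write(f"{row['genome_id']}\t{values}\n")
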