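# flavimine

Comparative-genomics mining of **extracytosolic protein flavinylation
systems** in prokaryotic genomes.

The ApbE enzyme post-translationally transfers the FMN moiety of FAD onto a
serine/threonine hydroxyl inside a conserved **[S/T]GA[S/T]** sequence
motif. Flavinylated proteins — canonically the FMN-binding domain (Pfam
PF04205), plus the alternative substrates DUF2271 (PF10029) and DUF3570
(PF12094) — mediate electron transfer outside the cytosol in respiratory
and iron-assimilation systems such as NQR, RNF, nitrous-oxide and
organohalide reduction. `flavimine` implements the genomic
guilt-by-association workflow that discovers and classifies these systems:

1. **Anchor mining** — collect the 5 genes upstream and downstream of every
   gene encoding ApbE (PF02424), an FMN-binding domain (PF04205), DUF3570
   (PF12094) or DUF2271 (PF10029), merging overlapping windows into loci.
2. **Extracytosolic filter** — keep clusters in which at least one
   anchor-role gene carries a predicted signal peptide (Sec/Tat) or
   lipoprotein signal.
3. **System classification** — match each retained cluster against key-gene
   rules for ten electron-transfer systems (RNF via RnfB/K03616, Nos via
   NosZ/K00376, Pce via PF13486, EET via K03885 + a transmembrane helix,
   NQR via NqrF/K00351, NapH-like via PF12801/K19339, MsrQ-like via
   PF01794, PepSY via PF03929/PF16357, DsbD via PF02683, and NQR/RNF-like
   via an N-terminal NqrB/RnfD domain (PF03116) fused to a C-terminal
   NqrF-like NAD-binding domain (PF00175) on one protein), annotating
   accessory genes (VIT1, TonB, NuoF-like, thioredoxin-like, P19/FTR1,
   multi-heme cytochromes, ...).
4. **Derived analyses** — orphan-ApbE genomes under two substrate
   definitions, multi-flavinylated proteins (>1 FMN-binding domain),
   fumarate-reductase-superfamily/FMN/cytochrome co-occurrence (±2 genes),
   P19 iron-assimilation cluster typing, DsbD-independent DUF3570 loci.
5. **Motif & logo analysis** — scan sequences for (possibly overlapping)
   [S/T]GA[S/T] motifs; compute per-column frequency/information matrices
   (`info_bits = log2(20) − H`) from alignments.
6. **Summaries** — per-genome system presence, genus-level presence/absence,
   per-phylum genome counts, cross-tabulations, and iTOL annotation export.

Annotation inputs are HMMER tblout/domtblout searches against Pfam and
KOfam (best hit, full-sequence E-value ≤ 0.001), SignalP-5 summaries and
TMHMM short-format output; the external predictors are consumed, never
reimplemented. A seeded synthetic-genome generator plants every system
template, decoys and motif-bearing sequences with a ground-truth ledger, so
the entire pipeline is testable offline.

## Worked example

```sh
flavimine simulate --n-genomes 8 --seed 4 --outdir demo/bundle
flavimine run-all --config demo/config.yaml
```

with `demo/config.yaml` pointing at the emitted bundle:

```yaml
gene_table: demo/bundle/genes.tsv
annotations: demo/bundle/annotations.tsv
signalp: demo/bundle/signalp_summary.tsv
tmhmm: demo/bundle/tmhmm_short.tsv
fasta: demo/bundle/proteins.faa
taxonomy: demo/bundle/taxonomy.tsv
outdir: demo/run
```

`demo/run/assignments.tsv` then starts:

```
cluster_id	systems	accessories	naph_fmn_mode
SYN00000:SYN00000_c000:10	RNF
SYN00000:SYN00000_c001:7	NAPH_LIKE		fused
SYN00000:SYN00000_c002:0	MSRQ_LIKE	NAD_BINDING:SYN00000_p00063:fused
SYN00000:SYN00000_c003:6	PEPSY	DUF4198:SYN00000_p00093:separate
```

Each row is one flavinylation-associated locus: the RNF cluster was
assigned because an RnfB (K03616) gene sits within a retained anchor
window; the NapH-like protein carries its FMN-binding domain fused on the
same polypeptide (`fused`), and the MsrQ-like protein carries a C-terminal
NAD-binding domain. `demo/run/genome_summary.tsv` aggregates per genome:

```
genome_id	has_flavinylation_component	systems_present	n_extracytosolic_fmn_genes	n_apbe_genes	orphan_apbe_fmn_only	orphan_apbe_extended	multiflavinylated_proteins
SYN00000	True	MSRQ_LIKE;NAPH_LIKE;NQR_RNF_LIKE;PEPSY;RNF	4	5	False	False	0
```

and `demo/run/motif_sites.tsv` lists every [S/T]GA[S/T] occurrence with its
1-based position:

```
protein_id	position	matched
SYN00000_p00094	52	SGAS
SYN00002_p00088	49	SGAS
SYN00002_p00088	247	SGAT
```

The same steps are available as library calls (`flavimine.generate`,
`flavimine.mine_genome`, `flavimine.classify_clusters`,
`flavimine.scan_flavinylation_motifs`, `flavimine.summarize_genomes`, ...)
and as per-stage subcommands (`mine`, `motif`, `logo`).

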