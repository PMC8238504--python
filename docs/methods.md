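# Methods

## The model

Extracytosolic flavinylation systems are identified purely from genome
organisation and per-protein annotation; no sequence search is performed by
this package. The working assumptions are:

* **Adjacency is gene order, not nucleotide distance.** Neighborhoods are
  defined as the five genes upstream and five downstream of an anchor gene
  along its contig, indexed by annotation order. Strand is recorded but
  never conditions the window, and every gene-table row counts toward the
  window (including genes without translations, if present in the table).
  This removes any dependence on coordinate conventions and handles draft
  assemblies naturally: contig edges truncate windows silently.
* **Anchors are the flavinylation components themselves**: ApbE (PF02424),
  the FMN-binding substrate domain (PF04205), and the alternative
  substrates DUF3570 (PF12094) and DUF2271 (PF10029). One gene may carry
  several roles (ApbE–substrate fusions occur).
* **Overlapping anchor windows merge into one locus** by default. Adjacent
  anchors of a single system (e.g. an ApbE next to its substrate) would
  otherwise be double-counted; `merge_overlapping=False` is available for
  sensitivity analysis, since whether published locus counts are per anchor
  or per merged locus is ambiguous — reports state which unit they use.
* **"Extracytosolic" means an SP, TAT or LIPO call** on at least one
  anchor-role gene of the locus. The three secreted classes of a
  SignalP-5-style predictor partition exactly into "signal peptide"
  (SP/TAT) and "lipidation site" (LIPO). The filter deliberately tests
  anchor-role genes only — an exported non-anchor neighbor does not rescue
  a cluster.

## Annotation thresholding

All HMM evidence is filtered by the full-sequence E-value at a single
cutoff, 0.001, applied identically to KO assignment and Pfam domain
presence. Per protein, the KO label is the best passing hit, where "best"
minimizes E-value, then maximizes bitscore, then takes the
lexicographically smallest accession — the two tie-breaks exist only to
make results deterministic under input reordering. Pfam hits keep their
multiplicity (a protein may carry several PF04205 domains) and, from
domtblout input, their alignment coordinates. KOfam's per-family adaptive
score thresholds are *not* used; the E-value cutoff is the only criterion.
HMMER prints `0.0` for underflowed E-values; the parser clamps these to the
smallest positive float rather than rejecting real search output.

## System rules

Each of the ten systems is declared in an editable YAML rule table
(`src/flavimine/data/system_rules.yaml`) as key-gene terms with
any-of semantics; a cluster is matched against every rule independently, so
multi-label assignments are possible and real (PepSY-like and MsrQ-like
genes co-occur in some loci). Two operationalisations were genuinely open:

* **EET's "NADH dehydrogenase with a transmembrane helix"** uses
  `tm_helix_count >= 1` on the K03885-carrying protein.
* **The NQR/RNF-like two-domain architecture** requires, on one protein, a
  PF03116 hit starting before a PF00175 hit and within the N-terminal half
  of the protein (no published numeric threshold exists; "N-terminal
  membrane domain" is read as start ≤ length/2). Hits without coordinates
  are indeterminate and reported as non-matching with a warning.

Accessory features (VIT1, TonB, NAD-binding, NuoF-like, thioredoxin-like,
DUF4198, DUF4266, P19, FTR1, multi-heme cytochrome, fumarate-reductase
superfamily, NirS, ExaA) are annotated for every cluster regardless of its
labels; `fused` marks carriers that also bear an anchor-role domain or an
assigned system's key gene. For NapH-like loci the classifier records
whether the FMN-binding domain is fused to the NapH-like protein or encoded
by a separate cluster gene, the two configurations observed in nature.

## Derived analyses

* **Orphan ApbE**: a genome with ≥1 extracytosolic ApbE and zero
  extracytosolic substrate proteins. Two substrate sets are evaluated —
  {PF04205} and {PF04205, PF10029, PF12094} — because recognising the DUF
  substrates is precisely what converts most orphans into explained
  genomes.
* **Multi-flavinylated proteins** count PF04205 *domain hits* per protein
  (>1 qualifies); predicted flavinylation *sites* count [S/T]GA[S/T] motif
  occurrences. These are deliberately distinct counters.
* **Fumarate-reductase-like co-occurrence** uses a tighter ±2-gene window
  (`frd_window`), testing fusion and proximity to FMN-binding and
  multi-heme cytochrome c domains.
* **Motif scanning** uses the strict pattern `[ST]GA[ST]`; reported
  positions are 1-based and overlapping occurrences are all reported (two
  motifs may share a serine). A pattern hook accepts relaxed variants, but
  no mismatch tolerance is applied by default since none is defined.
* **Logo matrices**: per column, frequencies over non-gap residues of the
  20-letter alphabet and `info_bits = log2(20) − H` with Shannon entropy in
  bits, `0·log 0 ≡ 0`, no small-sample correction (matching the default
  bits method of standard logo tools). All-gap columns get zero effective
  count and zero information. Characters outside alphabet+gap (e.g. `X`)
  are excluded from counts like gaps.

## Synthetic data: what it emulates and what it does not

The generator emulates *annotated* genomes — ordered genes with domain/KO
labels, E-values, localization calls and, where needed, sequences — not
genome evolution. Its defaults define the study conditions:

* each genome plants each system with probability 0.3 (templates for all
  ten systems encode exactly their own key-gene rule, an exported anchor,
  and no other system's key gene);
* decoy types: (a) anchor genes whose target genes all lack export signals
  (must be filtered), (b) key genes with no anchor in the window (must
  produce no cluster), each at rate 0.2 in the acceptance conditions;
* background annotation rate 0.1 from an accession pool disjoint from every
  rule accession; 10% of background genes get export signals;
  sub-threshold anchor hits (E-value in [0.01, 1]) at rate 0.05 exercise
  the 0.001 cutoff; planted hits draw E-values log-uniformly from
  [1e-30, 1e-4];
* substrate sequences carry planted motifs (1 per DUF2271 at ~135 aa, 2
  per DUF3570 at ~420 aa, matching the observed domain sizes and motif
  counts); flanking residues exclude S/T so no accidental motif can form;
* multi-flavinylated proteins carry 2–13 PF04205 domains, the observed
  ceiling being 13;
* contigs hold 15–40 genes; each planted element gets its own contig, with
  1–2 extra background-only contigs per genome. One planting per contig
  guarantees that planted loci never merge with each other, making the
  truth ledger exact; real genomes of course interleave systems on one
  replicon, and the merge logic is instead exercised by multi-anchor
  templates and dedicated unit tests.
* taxonomy is assigned round-robin over four phyla / ten genera so taxon
  summaries are exercised.

Because annotations are planted noise-free (decoys aside), perfect
recall/precision on synthetic data demonstrates the *logic* of mining and
classification, not robustness to annotation error, incomplete HMM
coverage, or predictor mistakes on real genomes. Sequences are generated
only where a stage consumes them (motif substrates, multi-flavinylated
proteins); other genes carry lengths only, keeping fixtures small.

## Numerical and design choices

* Determinism everywhere: `random.Random(seed)` with per-genome subseeds;
  cluster ids are `genome:contig:leftmost_index`, stable across runs;
  best-hit ties are fully ordered; output rows are sorted.
* The acceptance script derives all sub-seeds from one `--seed` and uses
  problem sizes (200 genomes for recovery, 120 for the orphan and motif
  cohorts, 10k scanner comparisons in the test suite) chosen to exercise
  every template and decoy while completing in seconds.
* Degenerate inputs: empty files yield empty collections; header-only
  tables are valid; a contig shorter than the window truncates; an empty
  cluster label set is a first-class "unclassified" outcome.

## Known limitations

* Assignments depend entirely on upstream annotation quality; no rescue is
  attempted for proteins missed by the HMM searches or predictors.
* The ten-system rule table encodes key genes only, not full complex
  subunit composition; electron-flow direction is never inferred.
* Genus/phylum summaries take taxonomy strings verbatim; no nomenclature
  normalization is performed.
* The logo renderer is a minimal matplotlib letter stack intended for
  quick inspection, not publication-grade typography.
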