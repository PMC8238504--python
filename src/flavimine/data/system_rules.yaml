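# Key-gene rules assigning flavinylation-associated gene clusters to the ten
# named extracytosolic electron-transfer systems, plus the accessory features
# annotated alongside them.  Edit or extend this file to refine system
# definitions without code changes.
#
# A system matches when any listed term matches some cluster member:
#   namespace: pfam  -> the protein carries a passing hit to `accession`
#   namespace: kofam -> the protein's best passing KO is `accession`
#   tm_required: true -> that same protein must have >=1 predicted TM helix
# A rule may instead declare `architecture: nqr_rnf_like`, the two-domain
# single-protein constraint (N-terminal NqrB/RnfD membrane domain PF03116
# preceding a C-terminal NqrF-like NAD-binding domain PF00175).
systems:
  RNF:                      # Rhodobacter nitrogen fixation complex (RnfB)
    any:
      - {namespace: kofam, accession: K03616}
  NOS:                      # nitrous oxide reduction (NosZ)
    any:
      - {namespace: kofam, accession: K00376}
  PCE:                      # organohalide respiration (PceA)
    any:
      - {namespace: pfam, accession: PF13486}
  EET:                      # Gram-positive extracellular electron transfer
    any:
      - {namespace: kofam, accession: K03885, tm_required: true}
  NQR:                      # Na+-pumping NADH:quinone oxidoreductase (NqrF)
    any:
      - {namespace: kofam, accession: K00351}
  NAPH_LIKE:                # NapH-like iron-sulfur membrane protein
    any:
      - {namespace: pfam, accession: PF12801}
      - {namespace: kofam, accession: K19339}
  MSRQ_LIKE:                # MsrQ-like heme membrane protein
    any:
      - {namespace: pfam, accession: PF01794}
  PEPSY:                    # PepSY-like membrane protein (either family model)
    any:
      - {namespace: pfam, accession: PF03929}
      - {namespace: pfam, accession: PF16357}
  DSBD:                     # DsbD thiol-disulfide membrane transporter
    any:
      - {namespace: pfam, accession: PF02683}
  NQR_RNF_LIKE:             # partial NQR/RNF: NqrB/RnfD + NqrF domains fused
    architecture: nqr_rnf_like

accessories:
  NIRS:             {namespace: kofam, accession: K15864}   # nitrite reductase
  EXAA:             {namespace: kofam, accession: K00114}   # alcohol oxidase
  VIT1:             {namespace: pfam, accession: PF01988}   # ferrous iron transporter
  NAD_BINDING:      {namespace: pfam, accession: PF00175}   # NqrF-like NAD-binding
  TONB:             {namespace: pfam, accession: PF03544}   # TonB siderophore receptor
  DUF4198:          {namespace: pfam, accession: PF10670}
  DUF4266:          {namespace: pfam, accession: PF14086}
  THIOREDOXIN_LIKE: {namespace: pfam, accession: PF13899}
  P19:              {namespace: pfam, accession: PF10634}   # ferrous iron-binding
  FTR1:             {namespace: pfam, accession: PF03239}   # iron permease
  NUOF_LIKE:        {namespace: pfam, accession: PF10589}   # complex I NAD-binding
  CYTC_MULTIHEME:   {namespace: pfam, accession: PF14537}   # multi-heme cytochrome c
  FRD_SUPERFAMILY:  {namespace: pfam, accession: PF00890}   # fumarate-reductase-like
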