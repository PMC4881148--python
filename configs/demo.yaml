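# Small demonstration run: five repeat families in a ~50 kb genome, with a
# CenH3-like enrichment planted on the satellite satA and the chromovirus-like
# element gypsy1, and an input-identical profile everywhere else.
seed: 11
simulate:
  background_length: 24000
  coverage: 2.0
  read_length: 100
  insert_size: 300
  families:
    - {name: satA,    kind: satellite,           length: 327, copies: 30, divergence: 0.02}
    - {name: satB,    kind: satellite,           length: 170, copies: 30, divergence: 0.02}
    - {name: gypsy1,  kind: ltr_retrotransposon, length: 4000, copies: 2, divergence: 0.01}
    - {name: mite1,   kind: dna_transposon,      length: 250, copies: 8,  divergence: 0.02}
    - {name: cp1,     kind: plastid_like,        length: 1500, copies: 1, divergence: 0.0}
chip:
  profile: {satA: 8.0, gypsy1: 3.0}
  n_reads: 2500
  read_length: 138
  trim_length: 50
  n_sample: 2000
cluster:
  min_identity: 90.0
  min_coverage: 0.55
  proportion_threshold: 0.5
annotate:
  db: truth
enrich:
  threshold: 1.5
  min_input: 20
sizes:
  estimated_genome_mb: 758.0
  assembly_mb: 567.0
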