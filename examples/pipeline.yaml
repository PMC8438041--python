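# Demo configuration for `viromehost run`.
seed: 7
synth:
  n_viruses: 15
  n_hosts: 10
  n_samples: 4
  subs_per_spacer: 0        # unmutated spacers: planted links fully recoverable
screen:
  criteria_mode: any        # any-of the three composition criteria
cluster:
  id_threshold: 0.9         # protein clustering global identity
  score_threshold: 3.0      # -log10 P floor for genus edges
hosts:
  min_identity: 0.97        # spacer-protospacer identity over the alignment
  min_coverage: 0.90        # alignment length / spacer length
  max_mismatches: 1
hic:
  min_count: 5              # contact floor for a Hi-C assignment
  dominance_ratio: 2.0      # co-assign bins within this factor of the top
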