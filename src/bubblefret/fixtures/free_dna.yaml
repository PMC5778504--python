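# Free (RNAP-less) duplex promoter DNA: a single static species at E*~0.17.
name: free_dna
alternation_rate_hz: 100
n_molecules: 100
max_duration_s: 10.0
seed: 0
subpopulations:
  - label: static_closed
    proportion: 1.0
    scheme:
      states:
        - {label: free, fret: 0.17, category: closed}
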