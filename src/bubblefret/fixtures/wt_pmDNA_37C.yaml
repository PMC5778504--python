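# Pre-melted promoter DNA at 37 C: a single population centred at E*~0.45
# (+0.05 temperature shift applied, as for duplex DNA) with no residual
# low-FRET state.
name: wt_pmDNA_37C
alternation_rate_hz: 100
n_molecules: 100
max_duration_s: 10.0
seed: 0
subpopulations:
  - label: static_open
    proportion: 1.0
    scheme:
      states:
        - {label: open, fret: 0.50, category: open}
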