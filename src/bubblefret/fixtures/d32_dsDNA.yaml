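# Sigma70 Delta3.2 (residues 513-519 deleted) on duplex DNA: same state
# levels and composition as wild type, with opening and closing rates
# multiplied by 3 (midpoint of the observed 2- to 4-fold speed-up).
name: d32_dsDNA
alternation_rate_hz: 100
n_molecules: 100
max_duration_s: 10.0
seed: 0
subpopulations:
  - label: static_open
    proportion: 0.50
    scheme:
      states:
        - {label: open, fret: 0.45, category: open}
  - label: static_closed
    proportion: 0.20
    scheme:
      states:
        - {label: closed, fret: 0.20, category: closed}
  - label: static_intermediate
    proportion: 0.05
    scheme:
      states:
        - {label: intermediate, fret: 0.35, category: intermediate}
  - label: dynamic
    proportion: 0.25
    scheme:
      states:
        - {label: closed, fret: 0.20, category: closed}
        - {label: open_fast, fret: 0.45, category: open}
        - {label: open_slow, fret: 0.45, category: open}
      rates:
        closed->open_fast: 9.6
        closed->open_slow: 9.6
        open_fast->closed: 13.6363636364
        open_slow->closed: 3.0
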