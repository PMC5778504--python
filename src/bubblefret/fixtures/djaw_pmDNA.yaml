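# Beta' jaw deletion on pre-melted DNA: pmDNA composition with rates x1.3.
name: djaw_pmDNA
alternation_rate_hz: 100
n_molecules: 100
max_duration_s: 10.0
seed: 0
subpopulations:
  - label: static_closed
    proportion: 0.21
    scheme:
      states:
        - {label: closed, fret: 0.26, category: closed}
  - label: static_open
    proportion: 0.16
    scheme:
      states:
        - {label: open, fret: 0.45, category: open}
  - label: static_intermediate
    proportion: 0.13
    scheme:
      states:
        - {label: intermediate, fret: 0.35, category: intermediate}
  - label: dynamic
    proportion: 0.56
    scheme:
      states:
        - {label: closed, fret: 0.26, category: closed}
        - {label: open_fast, fret: 0.45, category: open}
        - {label: open_slow, fret: 0.45, category: open}
      rates:
        closed->open_fast: 2.7083333333
        closed->open_slow: 2.7083333333
        open_fast->closed: 5.9090909091
        open_slow->closed: 1.3
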