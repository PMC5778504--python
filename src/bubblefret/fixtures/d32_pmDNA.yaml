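# Sigma70 Delta3.2 on pre-melted DNA: pmDNA composition and E* levels with
# opening and closing rates multiplied by 3.
name: d32_pmDNA
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
        closed->open_fast: 6.25
        closed->open_slow: 6.25
        open_fast->closed: 13.6363636364
        open_slow->closed: 3.0
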