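# Wild-type RNAP on fully duplex lacCONS promoter DNA, 22 C.
# Four behavioural subpopulations; the dynamic scheme interconverts a
# closed-bubble state (E*~0.2, exit 6.4 s^-1) with two open substates of
# identical E* (0.45) realizing bi-exponential open dwells (0.22 s / 1.0 s,
# entered with equal branching).
name: wt_dsDNA_22C
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
        closed->open_fast: 3.2
        closed->open_slow: 3.2
        open_fast->closed: 4.5454545455
        open_slow->closed: 1.0
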