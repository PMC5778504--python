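# Wild-type RNAP on duplex DNA at 37 C: both E* peaks shift up by ~0.05,
# the intermediate population grows to 20% and dynamics stay at 23%.
# The printed abundances leave the open:closed split of the remaining 57%
# unspecified; the 22 C open:closed ratio (5:2) is kept.
name: wt_dsDNA_37C
alternation_rate_hz: 100
n_molecules: 100
max_duration_s: 10.0
seed: 0
subpopulations:
  - label: static_open
    proportion: 0.41
    scheme:
      states:
        - {label: open, fret: 0.50, category: open}
  - label: static_closed
    proportion: 0.16
    scheme:
      states:
        - {label: closed, fret: 0.25, category: closed}
  - label: static_intermediate
    proportion: 0.20
    scheme:
      states:
        - {label: intermediate, fret: 0.40, category: intermediate}
  - label: dynamic
    proportion: 0.23
    scheme:
      states:
        - {label: closed, fret: 0.25, category: closed}
        - {label: open_fast, fret: 0.50, category: open}
        - {label: open_slow, fret: 0.50, category: open}
      rates:
        closed->open_fast: 3.2
        closed->open_slow: 3.2
        open_fast->closed: 4.5454545455
        open_slow->closed: 1.0
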