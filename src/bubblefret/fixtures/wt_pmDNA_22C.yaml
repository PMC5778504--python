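# Wild-type RNAP on pre-melted (-10/-4 mismatch) promoter DNA, 22 C.
# Printed abundances (~21/16/13/56 %) sum to 106% and are normalized on
# load.  The low-FRET state sits at E*~0.26 for this DNA; the closed-state
# mean dwell lengthens to ~240 ms (exit rate 1/0.24 s^-1) while open-state
# kinetics match duplex DNA.
name: wt_pmDNA_22C
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
        closed->open_fast: 2.0833333333
        closed->open_slow: 2.0833333333
        open_fast->closed: 4.5454545455
        open_slow->closed: 1.0
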