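# Intra-bubble (-5/-3) labelling: the dyes sit inside the transcription
# bubble, so the FRET polarity inverts -- the open bubble reads E*~0.6 and
# the closed bubble very high FRET (E*~0.85).  Contact-mediated quenching of
# the closed state can be enabled via photophysics.quench_states (factor
# 0.1); it is off by default, emulating the non-quenched (>0.8 FRET)
# species.  Note the closed/open *categories* here deliberately do not track
# the usual low/high E* convention.
name: bubble_labels_22C
alternation_rate_hz: 100
n_molecules: 100
max_duration_s: 10.0
seed: 0
photophysics:
  quench_factor: 0.1
subpopulations:
  - label: dynamic
    proportion: 1.0
    scheme:
      states:
        - {label: closed, fret: 0.85, category: closed}
        - {label: open_fast, fret: 0.60, category: open}
        - {label: open_slow, fret: 0.60, category: open}
      rates:
        closed->open_fast: 3.2
        closed->open_slow: 3.2
        open_fast->closed: 4.5454545455
        open_slow->closed: 1.0
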