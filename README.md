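# bubblefret

Single-molecule FRET analysis of transcription-bubble conformational
dynamics in bacterial RNA polymerase (RNAP)–promoter complexes, with a
ground-truthed ALEX trace simulator so every stage is verifiable by
parameter recovery.

## The problem

During transcription initiation, RNAP melts 12–14 bp of promoter DNA to form
the open complex. Surface-immobilized complexes carrying a donor/acceptor
FRET pair flanking the transcription bubble report on its conformation: a
closed bubble reads a low apparent FRET efficiency (E* ≈ 0.2), an open
bubble a high one (E* ≈ 0.45), and some complexes interconvert on the
~0.1-s timescale. Quantifying the state populations and the opening/closing
rate constants from camera-based alternating-laser-excitation (ALEX) time
traces is the job of this package. It is aimed at single-molecule
biophysicists who want a tested, scriptable re-implementation of that
workflow — and at anyone who needs a realistic smFRET trace simulator with
known ground truth.

## What it computes

For each molecule the camera yields three per-frame intensities: DD
(donor-excitation donor-emission), DA (donor-excitation acceptor-emission)
and AA (acceptor-excitation acceptor-emission). The pipeline computes the
apparent (uncorrected) FRET efficiency and stoichiometry

    E* = DA / (DD + DA)          S = (DD + DA) / (DD + DA + AA)

and then:

- **Trace QC** — change-point detection of single-step photobleaching
  (two-sample step statistic, threshold 4.0), blink filtering, brightness
  band; mirrors manual trace curation.
- **Segmentation** — variational-Bayes Gaussian-emission HMMs fitted to each
  E* trajectory for K = 1..3 states; the number of states is selected by
  maximum evidence (the variational lower bound on the marginal likelihood).
- **Classification** — each accepted molecule becomes static closed /
  static intermediate / static open (mean-E* boundaries 0.275 / 0.40) or
  dynamic, the latter requiring decoded transitions between states separated
  by ≥ 0.1 E* with anti-correlated DD/DA changes.
- **Kinetics** — dwell times per state category, maximum-likelihood
  exponential fits left-truncated at one frame, EM fits of bi-exponential
  open-dwell mixtures, BIC model comparison, and molecule-level bootstrap
  confidence intervals. Opening/closing rates are reciprocal mean dwells:
  k_open = 1/τ_closed, k_close = 1/τ_open.

The bundled simulator generates the study conditions as named fixtures
(duplex and pre-melted promoter DNA at 22/37 °C, σ3.2 and β' jaw deletion
mutants, intra-bubble labelling, free DNA): continuous-time Markov state
paths, occupancy-weighted discretization onto camera frames, Poisson shot
noise with EMCCD gain 4.55 counts/photon and excess-noise factor 2,
single-step photobleaching, optional blinking and contact quenching.

## Worked example

```bash
bubblefret run --scenario wt_dsDNA_22C --out out_wt --seed 1
```

prints (abridged):

```
== wt_dsDNA_22C ==
  accepted 96/100 molecules
  dynamic                 25.0%
  static_closed           18.8%
  static_intermediate      4.2%
  static_open             52.1%
```

The four behavioural classes recover the scenario's ground-truth composition
(50/20/5/25 static-open/static-closed/static-intermediate/dynamic): about a
quarter of the complexes interconvert between open and closed bubble
conformations while half sit stably open. The Gaussian-mixture summary of
the pooled E* histogram (100 molecules × 250 frames) gives weights
0.744/0.256 at means 0.45/0.20 — the familiar ~75/25 split between open- and
closed-bubble populations. A kinetics-focused run on dynamic molecules
(`bubblefret run --scenario ... ` on a dynamic-only scenario, or the Python
API) yields k_open ≈ 6.5 s⁻¹ with a 95% bootstrap CI covering the simulated
6.4 s⁻¹, and a bi-exponential open-dwell fit with components near 0.2 s and
0.8–1 s.

The same stages are available individually (`simulate`, `qc`, `fret`,
`hmm`, `classify`, `kinetics`), each reading only the on-disk outputs of the
previous one, and as Python functions (`bubblefret.run_pipeline`,
`bubblefret.select_model`, `bubblefret.fit_biexponential`, ...).

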