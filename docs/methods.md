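# Methods

## Scope and data model

One "frame" is one full laser-alternation period carrying a green-excitation
readout (DD, DA) and a red-excitation readout (AA); at the default 100-Hz
alternation the effective time resolution is 10 ms and one E* value is
plotted per period. All FRET quantities are *apparent*: E* = DA/(DD+DA)
with the detection-correction factor γ fixed at 1 and no leakage or
direct-excitation corrections, matching how camera-based bubble-dynamics
measurements are usually reported. The stoichiometry S = (DD+DA)/(DD+DA+AA)
is carried along to separate donor-only/acceptor-only species but plays no
role in the default pipeline.

## Simulator

**State kinetics.** Each molecule follows a continuous-time Markov chain
over labelled conformational states with E* levels and first-order rates
given by a `KineticScheme`; sampling is exact (Gillespie). Frames are
filled with the occupancy-weighted mean of the state E* values, so a
transition mid-frame produces the blended value a camera would record; the
dominant state per frame (ties to the state entered earlier) is kept as
ground truth.

**Counts.** Mean detected photons per frame are DA = E·N_dex,
DD = (1−E)·N_dex, AA = N_aex. Counts are gain × photons with the photon
variance inflated by an excess-noise factor (default 2.0, the standard
approximation to the EMCCD gain-register cascade; the exact cascade is out
of scope), plus Gaussian read noise, clipped at zero. Defaults: gain 4.55
counts/photon (EM gain 300), N_dex = 100 and N_aex = 50 photons/frame,
background 20 counts/frame/channel, read noise sd 10 counts. N_dex = 100
with excess noise 2 puts the per-frame E* width near 0.07 at E* = 0.45,
matching the histogram widths the fixtures are meant to emulate.

**Photophysics.** Donor and acceptor photobleach as independent exponential
waiting times (defaults 0.02 and 0.03 s⁻¹), independent of conformational
state. After an acceptor bleach, DA and AA fall to background and DD rises
to the full N_dex; after a donor bleach, DD and DA fall to background.
Acceptor blinking is an optional on/off telegraph process (off by default).
Contact quenching (for intra-bubble labelling, where the closed bubble puts
the dyes in contact) multiplies N_dex by a factor q (default 0.1) in the
named quenched states.

**Fixtures.** The bundled scenarios encode the study conditions:
compositions 50/20/5/25 (static-open/closed/intermediate/dynamic) for
duplex DNA at 22 °C and 21/16/13/56 (normalized; the printed values total
106%) for pre-melted DNA; E* levels 0.17 (free DNA), 0.20 closed, 0.35
intermediate, 0.45 open, +0.05 for the 37 °C variants, 0.26 for the
pre-melted-DNA closed state; closed-state exit rate 6.4 s⁻¹ (duplex) or
1/0.24 s⁻¹ (pre-melted). Bi-exponential open dwells are realized as two
open substates with identical E* (0.45) and exit rates 1/0.22 and
1/1.0 s⁻¹, entered from the closed state with equal branching — the
amplitude split of the two components is not constrained by the reported
lifetimes, so 0.5/0.5 was chosen. The Δ3.2 fixtures multiply all dynamic
rates by 3 (midpoint of the reported 2–4-fold speed-up), the ΔJaw fixtures
by 1.3. Subpopulation allocation is exactly proportional (remainders by
seeded multinomial) and all randomness derives from `SeedSequence`
substreams of the scenario seed, so identical seeds give bit-identical
datasets.

**What the simulator does not emulate** (hence what passing recovery tests
do and do not show): no image formation (PSFs, defocus, neighbours), no
spectral crosstalk or γ ≠ 1, no dye spectral-state heterogeneity, no
baseline drift, no diffusing-molecule (confocal) mode. Recovery on these
fixtures demonstrates the estimator chain is correct and unbiased at
realistic noise, not that it is robust to every artefact of real movies.

## Trace QC

Change points are found by recursive binary segmentation maximizing the
two-sample t statistic (mean difference over pooled sd, threshold 4.0,
minimum segment 5 frames). A bleach step is a downward change point whose
following segment sits at the trace-final background within 2 sd *and*
below 25% of the pre-step level; the second condition prevents spurious
change points on unbleached traces (whose final-segment "background" is
really signal) from being read as bleaches. Acceptance requires: no more
than one large downward step per channel (donor presence is judged on the
FRET-invariant sum DD+DA, acceptor presence on AA), first bleach at frame
≥ 105, no dark interval of ≥ 3 frames followed by recovery (shorter
fluctuations are permitted), and mean pre-bleach total intensity within
[0.3×, 3×] the dataset median. The image-plane criteria of manual curation
(circular PSF, defocus, nearest neighbour) have no trace-level counterpart
and auto-pass. Molecules that never bleach within the record are accepted
by default (`QcConfig.require_bleach=True` restores the strict rule): the
simulator truncates records at a fixed duration, whereas an experiment
observes until bleaching, and rejecting long-lived molecules would bias the
populations toward fast bleachers.

Background for E* computation is the per-channel post-bleach median when a
bleach was detected, else the scenario's configured background. Frames
after the first bleach are excluded from histograms, segmentation and
kinetics; frames whose background-subtracted DD+DA is non-positive are
masked.

## Segmentation and model selection

Per-molecule E* trajectories are fitted with Gaussian-emission HMMs by
coordinate-ascent variational Bayes with conjugate priors: Dirichlet(1) on
the initial distribution and each transition row, Normal–Gamma on each
state's emission (mean prior centred on the series mean with precision 0.1;
Gamma(shape 1, rate 0.01) on the precision, i.e. a prior emission sd near
0.1). These hyperparameters are reported in the per-molecule output and are
deliberately weak; they were fixed a priori, not fitted. Iteration stops
when the evidence changes by < 1e-6 or at 500 iterations; 10 restarts
(first deterministic at quantile-placed means, the rest jittered) guard
against local optima and the best-evidence fit is kept. K = 1..3 are
fitted and the maximum-evidence model selected (ties to smaller K). The
K = 1 evidence equals the closed-form conjugate marginal likelihood to
numerical precision, and the evidence is non-decreasing across iterations —
both asserted in the test suite. Decoding uses Viterbi under the posterior
point estimates (checked against brute-force path enumeration on short
series); posterior marginals come from forward–backward. Masked frames
split a trajectory into segments fitted jointly with shared parameters
(gaps < 3 frames are simply dropped). Emissions are modelled on E* rather
than jointly on (DD, DA), since the trajectories analysed are E* traces.

One caveat found while validating selection: at noise well below the
experimental level, frames that straddle a transition carry
occupancy-blended E* values and can legitimately support an extra state; at
the realistic per-frame width (~0.07) selection recovers the true state
count ≥ 90% of the time, which is the regime that matters here.

## Classification

A molecule is *dynamic* when its selected model has ≥ 2 states separated by
≥ 0.1 E*, its decoded path contains at least one transition between such
states, and the DD/DA changes at those transitions are anti-correlated
(Pearson r < −0.5). The intensity changes entering r are differences of
dwell-averaged DD and DA levels flanking each transition (windows of up to
20 frames, truncated at neighbouring state changes): averaging over dwells
is what visual inspection effectively does, and it keeps the statistic
discriminating when the E* step is small (single-frame differences at a
0.19-step have count SNR near 1 and would reject genuine dynamics).
Everything else is static, classed by pre-bleach mean E* with boundaries at
0.275 and 0.40 — midpoints between the canonical 0.2/0.35/0.45 peaks; both
boundaries are configurable. Note that for intra-bubble labelling fixtures
the E*-to-category convention inverts (the closed bubble is the high-FRET
species), so the default boundaries do not apply there.

## Dwell-time kinetics

Decoded paths are mapped to state categories (closed/intermediate/open) and
maximal constant-category runs become dwells; the first dwell of each trace
is left-censored, the last right-censored. Censored dwells are excluded
from fitting by default (a survival-term MLE is available and agrees within
the bootstrap CI on fixture data). The single-exponential MLE is the
shifted mean, τ̂ = mean(d) − t_min, with t_min one frame period — the MLE
of an exponential left-truncated at the shortest resolvable dwell.
Bi-exponential open dwells are fitted as a two-component truncated
exponential mixture by EM (20 seeded restarts, components sorted, collapse
to one component when a weight falls below 0.01 or the means become
indistinguishable) and compared with the single exponential by BIC.
Intermediate-category dwells are tabulated but excluded from the two-state
opening/closing rates. Confidence intervals are percentile bootstrap over
molecules (1000 replicates by default).

Known biases, deliberately uncorrected: (i) missed events — sojourns much
shorter than a frame are decoded over, merging neighbouring dwells and
inflating mean lifetimes by roughly the fraction of sub-frame events (a few
percent at the fixture rates; full missed-event corrections are out of
scope); (ii) finite-window censoring — excluding right-censored dwells
preferentially discards long dwells, biasing the slow open-dwell component
low when its lifetime approaches the record length. Both effects partially
cancel in rate *ratios* between conditions, which is how the mutant
comparisons are reported.

## Pipeline

Stages communicate only through files (TSV traces + JSON manifests/reports,
CSV tables), so each stage can be re-run in isolation; one global seed is
expanded into per-stage, per-molecule `SeedSequence` substreams and
re-running an identical configuration reproduces byte-identical reports.
Numbers are rounded only in the human-readable summary. Problem sizes used
throughout the recovery tests and the acceptance script — 100 molecules,
10-s records at 100 Hz — mirror the study design (100 selected molecules,
250 histogram frames each) and keep a full scenario under a minute on one
CPU; the forward–backward and Viterbi kernels are numba-jitted with a pure
Python fallback.
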