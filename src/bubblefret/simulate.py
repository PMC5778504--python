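"""Ground-truthed ALEX smFRET trace simulation.

Stands in for the microscope + spot-extraction stage: continuous-time Markov
sampling of the conformational state, occupancy-weighted discretization onto
camera frames, and a shot-noise/EMCCD count model with single-step
photobleaching, optional acceptor blinking, and optional contact quenching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    AlexTrace,
    GroundTruth,
    KineticScheme,
    PhotophysicsParams,
    ScenarioConfig,
)

__all__ = [
    "simulate_state_path",
    "discretize_path",
    "simulate_alex_trace",
    "simulate_dataset",
    "Dataset",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_state_path(
    scheme: KineticScheme, duration: float, seed
) -> list[tuple[int, float, float]]:
    """Exact (Gillespie) CTMC sample path over ``[0, duration]``.

    Returns a list of sojourns ``(state, entry_time, exit_time)``.  The
    sojourn in state i is exponential with rate ``-q_ii``; the jump goes to j
    with probability ``k_ij / sum_j k_ij``.  A state with zero exit rate is
    absorbing and yields a single sojourn to ``duration``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = _as_rng(seed)
    q = scheme.rate_matrix
    k = scheme.n_states
    state = int(rng.choice(k, p=scheme.initial_distribution))
    t = 0.0
    events: list[tuple[int, float, float]] = []
    while t < duration:
        exit_rate = -q[state, state]
        if exit_rate <= 0:
            events.append((state, t, duration))
            break
        dt = rng.exponential(1.0 / exit_rate)
        t_end = min(t + dt, duration)
        events.append((state, t, t_end))
        if t + dt >= duration:
            break
        probs = q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(k, p=probs))
        t = t_end
    return events


def discretize_path(
    events: list[tuple[int, float, float]],
    frame_period: float,
    scheme: KineticScheme,
    n_frames: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project a continuous path onto camera frames.

    Returns ``(frame_fret, dominant_state, occupancy)`` where ``frame_fret``
    is the occupancy-weighted mean of the state E* values within each frame,
    ``dominant_state`` the state with the largest occupancy (ties broken by
    the state entered earlier within the frame), and ``occupancy`` the
    (n_frames, K) time-fraction matrix.
    """
    if frame_period <= 0:
        raise ValueError("frame_period must be > 0")
    if not events:
        raise ValueError("empty event list")
    t_end = events[-1][2]
    if n_frames is None:
        n_frames = int(np.floor(t_end / frame_period + 1e-9))
    k = scheme.n_states
    occ = np.zeros((n_frames, k))
    first_entry = np.full((n_frames, k), np.inf)
    for state, t0, t1 in events:
        f0 = int(np.floor(t0 / frame_period + 1e-12))
        f1 = int(np.ceil(t1 / frame_period - 1e-12))
        for f in range(max(f0, 0), min(f1, n_frames)):
            lo = max(t0, f * frame_period)
            hi = min(t1, (f + 1) * frame_period)
            if hi <= lo:
                continue
            occ[f, state] += hi - lo
            first_entry[f, state] = min(first_entry[f, state], lo)
    occ /= frame_period
    # guard rounding: renormalize frames fully covered by the path
    row = occ.sum(axis=1)
    row[row == 0] = 1.0
    frac = occ / row[:, None]
    frame_fret = frac @ scheme.state_fret
    dominant = np.empty(n_frames, dtype=np.int64)
    for f in range(n_frames):
        best = np.max(occ[f])
        cand = np.flatnonzero(occ[f] >= best - 1e-12)
        if len(cand) == 1:
            dominant[f] = cand[0]
        else:
            dominant[f] = cand[np.argmin(first_entry[f, cand])]
    return frame_fret, dominant, frac


def _blink_on_fraction(
    rng: np.random.Generator,
    n_frames: int,
    frame_period: float,
    on_rate: float,
    off_rate: float,
) -> np.ndarray:
    """Fraction of each frame the acceptor spends emissive under a two-state
    (on/off) telegraph process; ``on_rate``/``off_rate`` are the dark->on and
    on->dark rates in s^-1.  Zero rates disable blinking."""
    if on_rate <= 0 or off_rate <= 0:
        return np.ones(n_frames)
    duration = n_frames * frame_period
    t, on = 0.0, True
    frac = np.zeros(n_frames)
    while t < duration:
        rate = off_rate if on else on_rate
        dt = rng.exponential(1.0 / rate)
        t1 = min(t + dt, duration)
        if on:
            f0, f1 = int(t / frame_period), int(np.ceil(t1 / frame_period))
            for f in range(f0, min(f1, n_frames)):
                lo, hi = max(t, f * frame_period), min(t1, (f + 1) * frame_period)
                if hi > lo:
                    frac[f] += (hi - lo) / frame_period
        on = not on
        t = t1
    return np.clip(frac, 0.0, 1.0)


def simulate_alex_trace(
    frame_fret: np.ndarray,
    params: PhotophysicsParams,
    frame_period: float,
    seed,
    quench_fraction: np.ndarray | None = None,
    molecule_id: str = "",
) -> tuple[AlexTrace, dict]:
    """Render a true per-frame FRET series into noisy DD/DA/AA counts.

    Photon means per frame: ``DA = E N_dex``, ``DD = (1-E) N_dex``,
    ``AA = N_aex`` (gamma factor fixed at 1; apparent E* convention).  After
    an acceptor bleach DA and AA fall to background and DD rises to the full
    N_dex; after a donor bleach DD and DA fall to background.  Counts are
    ``gain * photons`` with the photon variance inflated by the excess-noise
    factor, plus Gaussian read noise, clipped at zero.
    """
    fret = np.asarray(frame_fret, dtype=float)
    if fret.size == 0:
        raise ValueError("empty FRET series")
    rng = _as_rng(seed)
    n = fret.size
    gain = params.camera_gain
    enf = params.excess_noise_factor

    def bleach_time(rate: float) -> float:
        return rng.exponential(1.0 / rate) if rate > 0 else np.inf

    t_d = bleach_time(params.donor_bleach_rate)
    t_a = bleach_time(params.acceptor_bleach_rate)
    edges = np.arange(n + 1) * frame_period
    # fraction of each frame during which the fluorophore is still emissive
    w_d = np.clip((t_d - edges[:-1]) / frame_period, 0.0, 1.0)
    w_a = np.clip((t_a - edges[:-1]) / frame_period, 0.0, 1.0)
    w_a = w_a * _blink_on_fraction(
        rng, n, frame_period, params.blink_on_rate, params.blink_off_rate
    )

    n_dex = np.full(n, params.photons_per_frame_dex)
    if quench_fraction is not None:
        qf = np.asarray(quench_fraction, dtype=float)
        n_dex = n_dex * (1.0 - qf + qf * params.quench_factor)

    mu_da = n_dex * fret * w_a * w_d
    mu_dd = n_dex * w_d * ((1.0 - fret) * w_a + (1.0 - w_a))
    mu_aa = params.photons_per_frame_aex * w_a

    bg_ph = params.background_per_channel / gain
    out = {}
    for name, mu in (("DD", mu_dd), ("DA", mu_da), ("AA", mu_aa)):
        mu_tot = mu + bg_ph
        if params.shot_noise:
            photons = rng.poisson(mu_tot).astype(float)
        else:
            photons = mu_tot
        counts = gain * (mu_tot + np.sqrt(enf) * (photons - mu_tot))
        if params.read_noise_sd > 0:
            counts = counts + rng.normal(0.0, params.read_noise_sd, size=n)
        out[name] = np.clip(counts, 0.0, None)

    def frame_of(t: float) -> int | None:
        return int(t / frame_period) if t < n * frame_period else None

    info = {
        "donor_bleach_frame": frame_of(t_d),
        "acceptor_bleach_frame": frame_of(t_a),
    }
    trace = AlexTrace(
        out["DD"], out["DA"], out["AA"], frame_period, molecule_id,
        metadata={"background_per_channel": params.background_per_channel},
    )
    return trace, info


@dataclass
class Dataset:
    """A simulated scenario: traces with ground truth and a manifest."""

    config: ScenarioConfig
    traces: list[AlexTrace]
    truths: list[GroundTruth]

    def __len__(self) -> int:
        return len(self.traces)

    def manifest(self) -> dict:
        mols = []
        for trace, truth in zip(self.traces, self.truths):
            mols.append({
                "molecule_id": trace.molecule_id,
                "file": f"{trace.molecule_id}.tsv",
                "subpopulation": truth.subpopulation,
                "true_class": truth.true_class,
                "n_frames": len(trace),
                "donor_bleach_frame": truth.donor_bleach_frame,
                "acceptor_bleach_frame": truth.acceptor_bleach_frame,
            })
        return {
            "scenario": self.config.name,
            "seed": self.config.seed,
            "frame_period_s": self.config.frame_period_s,
            "background_per_channel": self.config.photophysics.background_per_channel,
            "n_molecules": len(self.traces),
            "molecules": mols,
        }


def _allocate(proportions: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact proportional allocation; fractional remainders by seeded multinomial."""
    base = np.floor(proportions * n).astype(int)
    remainder = n - base.sum()
    if remainder > 0:
        resid = proportions * n - base
        if resid.sum() <= 0:
            resid = np.ones_like(resid)
        extra = rng.multinomial(remainder, resid / resid.sum())
        base = base + extra
    return base


def simulate_dataset(config: ScenarioConfig) -> Dataset:
    """Simulate a full scenario deterministically for its seed."""
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(1 + config.n_molecules)
    alloc_rng = np.random.default_rng(children[0])
    props = np.array([s.proportion for s in config.subpopulations])
    counts = _allocate(props, config.n_molecules, alloc_rng)
    frame_period = config.frame_period_s
    mol_seeds = children[1:]

    traces: list[AlexTrace] = []
    truths: list[GroundTruth] = []
    m = 0
    for sub, n_sub in zip(config.subpopulations, counts):
        scheme = sub.scheme
        quenched = np.array([
            lab in config.photophysics.quench_states for lab in scheme.state_labels
        ])
        for _ in range(n_sub):
            rng = np.random.default_rng(mol_seeds[m])
            mol_id = f"{config.name}_m{m:03d}"
            events = simulate_state_path(scheme, config.max_duration_s, rng)
            fret, dominant, frac = discretize_path(events, frame_period, scheme)
            q_frac = frac @ quenched.astype(float) if quenched.any() else None
            trace, info = simulate_alex_trace(
                fret, config.photophysics, frame_period, rng,
                quench_fraction=q_frac, molecule_id=mol_id,
            )
            truths.append(GroundTruth(
                subpopulation=sub.label,
                scheme=scheme,
                events=events,
                state_index=dominant,
                frame_fret=fret,
                donor_bleach_frame=info["donor_bleach_frame"],
                acceptor_bleach_frame=info["acceptor_bleach_frame"],
            ))
            traces.append(trace)
            m += 1
    return Dataset(config=config, traces=traces, truths=truths)
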