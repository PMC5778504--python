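"""Algorithmic trace selection and four-way behavioural classification.

Mirrors the manual curation applied to immobilized-complex movies: keep
molecules with single-step photobleaching no earlier than a minimum record
length, no blinking, and unexceptional brightness; then label each accepted
molecule static closed / static intermediate / static open, or dynamic when
its segmentation shows anti-correlated DD/DA transitions between
well-separated E* levels.

Image-plane criteria of the original curation (circular PSF, defocus,
nearest-neighbour distance) have no counterpart for extracted traces and are
recorded as auto-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AlexTrace, FretSeries

__all__ = [
    "QcConfig",
    "QcReport",
    "TraceClass",
    "detect_bleach_steps",
    "apply_selection",
    "classify_trace",
    "population_table",
]


@dataclass(frozen=True)
class QcConfig:
    min_frames: int = 105
    step_threshold: float = 4.0
    min_segment: int = 5
    blink_min_frames: int = 3
    intensity_band: tuple[float, float] = (0.3, 3.0)
    require_bleach: bool = False


def _best_split(y: np.ndarray, min_segment: int) -> tuple[float, int]:
    """Best two-sample mean-shift t statistic over split positions."""
    n = y.size
    if n < 2 * min_segment:
        return 0.0, -1
    cs = np.cumsum(y)
    cs2 = np.cumsum(y * y)
    t = np.arange(min_segment, n - min_segment + 1)
    n1 = t.astype(float)
    n2 = n - n1
    s1 = cs[t - 1]
    s2 = cs[-1] - s1
    m1 = s1 / n1
    m2 = s2 / n2
    ss1 = cs2[t - 1] - n1 * m1**2
    ss2 = (cs2[-1] - cs2[t - 1]) - n2 * m2**2
    pooled = (ss1 + ss2) / np.maximum(n1 + n2 - 2, 1)
    pooled = np.maximum(pooled, 1e-12)
    stat = np.abs(m1 - m2) / np.sqrt(pooled * (1 / n1 + 1 / n2))
    best = int(np.argmax(stat))
    return float(stat[best]), int(t[best])


def detect_bleach_steps(
    intensity: np.ndarray,
    threshold: float = 4.0,
    min_segment: int = 5,
) -> list[tuple[int, float]]:
    """Change points by recursive maximization of the two-sample step
    statistic (mean difference over pooled sd), returned as
    ``(first frame of the new level, post - pre mean difference)``."""
    y = np.asarray(intensity, float)
    if y.size < 20:
        raise ValueError("series too short for step detection")
    change_points: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        stat, t = _best_split(y[lo:hi], min_segment)
        if t < 0 or stat < threshold:
            return
        cp = lo + t
        change_points.append(cp)
        recurse(lo, cp)
        recurse(cp, hi)

    recurse(0, y.size)
    change_points.sort()
    bounds = [0, *change_points, y.size]
    steps = []
    for i, cp in enumerate(change_points):
        pre = y[bounds[i]:cp].mean()
        post = y[cp:bounds[i + 2]].mean()
        steps.append((cp, float(post - pre)))
    return steps


def _bleach_like(
    y: np.ndarray, steps: list[tuple[int, float]]
) -> tuple[list[int], int, float]:
    """Identify photobleach-like steps among detected change points.

    A bleach step is a downward change point whose following segment both
    sits at the trace-final background level (within 2 sd) and collapses to
    under 25% of the pre-step signal level -- the latter guards against
    spurious change points on unbleached traces, whose final "background"
    estimate is really signal.  Returns ``(bleach frames, number of large
    downward steps, background)``.
    """
    bounds = [0, *[f for f, _ in steps], y.size]
    tail = y[bounds[-2]:]
    bg, bg_sd = float(tail.mean()), float(tail.std())
    level = float(np.median(y[:steps[0][0]])) if steps else float(np.median(y))
    level = max(level, 1e-9)
    big_down = 0
    frames = []
    for i, (frame, size) in enumerate(steps):
        if size >= 0:
            continue
        if -size >= 0.25 * level:
            big_down += 1
        seg_mean = y[frame:bounds[i + 2]].mean()
        if seg_mean <= bg + 2 * bg_sd and seg_mean <= 0.25 * level:
            frames.append(frame)
    return frames, big_down, bg


def _blink_runs(
    region: np.ndarray, background: float, min_frames: int
) -> int:
    """Longest dark interval (below a level threshold) that recovers."""
    if region.size == 0:
        return 0
    level = float(np.median(region))
    if level <= background:
        return 0
    thresh = background + 0.4 * (level - background)
    dark = region < thresh
    longest = 0
    run = 0
    for i, d in enumerate(dark):
        if d:
            run += 1
        else:
            if run >= min_frames and run > longest:
                longest = run  # recovered: a frame above threshold follows
            run = 0
    return longest


@dataclass
class QcReport:
    molecule_id: str
    accepted: bool
    rejection_reasons: list[str] = field(default_factory=list)
    donor_bleach_frame: int | None = None
    acceptor_bleach_frame: int | None = None
    mean_total_intensity: float = float("nan")

    def __post_init__(self) -> None:
        if self.accepted and self.rejection_reasons:
            raise ValueError("accepted molecule cannot carry rejection reasons")

    @property
    def first_bleach_frame(self) -> int | None:
        frames = [
            f for f in (self.donor_bleach_frame, self.acceptor_bleach_frame)
            if f is not None
        ]
        return min(frames) if frames else None

    def analysis_end(self, n_frames: int) -> int:
        first = self.first_bleach_frame
        return n_frames if first is None else min(first, n_frames)


def apply_selection(
    trace: AlexTrace,
    median_intensity: float | None = None,
    config: QcConfig = QcConfig(),
) -> QcReport:
    """Accept or reject one molecule against the selection criteria.

    Donor presence is judged on DD+DA (FRET-invariant total green-excitation
    signal), acceptor presence on AA.  ``median_intensity`` is the dataset
    median of the mean pre-bleach total intensity; omit it to skip the
    brightness-band criterion.
    """
    donor = trace.DD + trace.DA
    acceptor = trace.AA
    reasons: list[str] = []

    def channel_bleach(y: np.ndarray) -> tuple[int | None, int, float]:
        steps = detect_bleach_steps(y, config.step_threshold, config.min_segment)
        frames, big_down, bg = _bleach_like(y, steps)
        first = frames[0] if frames else None
        # a bleached channel showing several large drops is a multi-molecule
        # staircase (or blink + bleach); count only when a bleach occurred
        n_steps = big_down if frames else 0
        return first, n_steps, bg if frames else 0.0

    d_frame, d_nsteps, d_bg = channel_bleach(donor)
    a_frame, a_nsteps, a_bg = channel_bleach(acceptor)

    if d_nsteps > 1 or a_nsteps > 1:
        reasons.append("multi_step_bleach")
    bleach_frames = [f for f in (d_frame, a_frame) if f is not None]
    first_bleach = min(bleach_frames) if bleach_frames else None
    if first_bleach is not None and first_bleach < config.min_frames:
        reasons.append("too_short")
    if first_bleach is None and config.require_bleach:
        reasons.append("no_bleach_observed")

    d_end = d_frame if d_frame is not None else len(donor)
    a_end = a_frame if a_frame is not None else len(acceptor)
    if _blink_runs(donor[:d_end], d_bg, config.blink_min_frames):
        reasons.append("donor_blink")
    if _blink_runs(acceptor[:a_end], a_bg, config.blink_min_frames):
        reasons.append("acceptor_blink")

    end = first_bleach if first_bleach is not None else len(trace)
    total = float((trace.DD + trace.DA + trace.AA)[:end].mean()) if end else 0.0
    if median_intensity is not None and median_intensity > 0:
        lo, hi = config.intensity_band
        if not lo * median_intensity <= total <= hi * median_intensity:
            reasons.append("intensity_out_of_range")

    return QcReport(
        molecule_id=trace.molecule_id,
        accepted=not reasons,
        rejection_reasons=reasons,
        donor_bleach_frame=d_frame,
        acceptor_bleach_frame=a_frame,
        mean_total_intensity=total,
    )


@dataclass
class TraceClass:
    label: str  # static_closed | static_intermediate | static_open | dynamic | unclassifiable
    mean_fret: float
    n_transitions: int
    anticorrelation: float
    molecule_id: str = ""


def _transition_anticorrelation(
    trace: AlexTrace, states: np.ndarray, frames: np.ndarray,
    max_window: int = 20,
) -> float:
    """Pearson r of (delta DD, delta DA) across decoded transitions.

    Each delta is taken between the dwell-averaged intensities flanking the
    transition (windows capped at ``max_window`` frames and truncated at the
    neighbouring state changes): averaging over the dwells suppresses shot
    noise that would swamp single-frame differences when the E* step is
    small.  A single transition falls back to the sign of the product.
    """
    d_dd, d_da = [], []
    n = len(states)
    for t in frames:
        s_prev, s_next = states[t - 1], states[t]
        lo = t - 1
        while lo > 0 and states[lo - 1] == s_prev and (t - lo) < max_window:
            lo -= 1
        hi = t
        while hi + 1 < n and states[hi + 1] == s_next and (hi - t) < max_window - 1:
            hi += 1
        d_dd.append(trace.DD[t:hi + 1].mean() - trace.DD[lo:t].mean())
        d_da.append(trace.DA[t:hi + 1].mean() - trace.DA[lo:t].mean())
    d_dd, d_da = np.array(d_dd), np.array(d_da)
    if len(frames) == 1:
        return -1.0 if d_dd[0] * d_da[0] < 0 else 1.0
    if np.std(d_dd) == 0 or np.std(d_da) == 0:
        return 0.0
    return float(np.corrcoef(d_dd, d_da)[0, 1])


def classify_trace(
    fret_series: FretSeries,
    model,
    path,
    trace: AlexTrace | None = None,
    boundaries: tuple[float, float] = (0.275, 0.40),
    end_frame: int | None = None,
) -> TraceClass:
    """Assign one accepted molecule to a behavioural class.

    Dynamic requires all three: the selected HMM has >= 2 states separated by
    at least 0.1 E*, the decoded path actually transits between such states,
    and the DD/DA changes at those transitions are anti-correlated (r < -0.5;
    the gate is skipped when no intensity trace is supplied).  Everything
    else is static, classed by the pre-bleach mean E* against ``boundaries``.
    """
    end = len(fret_series) if end_frame is None else end_frame
    valid = fret_series.valid[:end]
    values = fret_series.efficiency[:end][valid]
    if values.size == 0:
        return TraceClass("unclassifiable", float("nan"), 0, 0.0,
                          fret_series.molecule_id)
    mean_e = float(values.mean())

    n_trans = 0
    anticorr = 0.0
    if model is not None and model.n_states >= 2:
        mu = model.emission_mean
        separated = np.abs(mu[:, None] - mu[None, :]) >= 0.1
        states = path.states[:end]
        prev, cur = states[:-1], states[1:]
        ok = (prev >= 0) & (cur >= 0) & (prev != cur)
        frames = np.flatnonzero(ok & separated[prev.clip(0), cur.clip(0)]) + 1
        n_trans = int(len(frames))
        if n_trans >= 1:
            if trace is None:
                anticorr = -1.0
            else:
                anticorr = _transition_anticorrelation(trace, states, frames)
            if anticorr < -0.5:
                return TraceClass("dynamic", mean_e, n_trans, anticorr,
                                  fret_series.molecule_id)

    lo, hi = boundaries
    if mean_e < lo:
        label = "static_closed"
    elif mean_e < hi:
        label = "static_intermediate"
    else:
        label = "static_open"
    return TraceClass(label, mean_e, n_trans, anticorr, fret_series.molecule_id)


def population_table(classes: list[TraceClass]) -> pd.DataFrame:
    """Counts and fractions per behavioural class among accepted molecules."""
    if not classes:
        raise ValueError("no classified molecules")
    labels = [c.label if isinstance(c, TraceClass) else str(c) for c in classes]
    counts = pd.Series(labels).value_counts().sort_index()
    table = pd.DataFrame({"count": counts})
    table["fraction"] = table["count"] / table["count"].sum()
    return table
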