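"""Apparent FRET efficiency, stoichiometry, population histograms and
Gaussian-mixture summaries.

All quantities are *apparent* (proximity-ratio) values: E* = DA/(DD+DA) and
S = (DD+DA)/(DD+DA+AA), uncorrected for the detection factor gamma, spectral
leakage or direct excitation.  Conformational populations are read off pooled
per-frame E* values with a 1-D Gaussian mixture fitted by deterministic EM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import AlexTrace, FretSeries

__all__ = [
    "compute_fret_series",
    "build_fret_histogram",
    "fit_fret_mixture",
    "distance_to_fret",
    "HistogramResult",
    "MixtureFit",
]


def compute_fret_series(
    trace: AlexTrace, background: dict[str, float] | None = None
) -> FretSeries:
    """Per-frame E* and S, with optional per-channel background subtraction.

    Frames whose (background-subtracted) DD+DA denominator is non-positive
    are masked invalid; S is NaN wherever the total DD+DA+AA is non-positive.
    A fully masked molecule is returned flagged empty rather than raising, so
    callers can skip it.
    """
    bg = {"DD": 0.0, "DA": 0.0, "AA": 0.0}
    if background:
        bg.update(background)
    dd = trace.DD - bg["DD"]
    da = trace.DA - bg["DA"]
    aa = trace.AA - bg["AA"]
    dex = dd + da
    total = dex + aa
    valid = dex > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(valid, da / np.where(valid, dex, 1.0), np.nan)
        stoi = np.where(total > 0, dex / np.where(total > 0, total, 1.0), np.nan)
    return FretSeries(
        efficiency=eff,
        stoichiometry=stoi,
        valid=valid,
        frame_period_s=trace.frame_period_s,
        molecule_id=trace.molecule_id,
    )


@dataclass
class MixtureFit:
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    converged: bool
    n_iterations: int

    def as_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "weights": self.weights.tolist(),
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
        }


@dataclass
class HistogramResult:
    """Pooled E* histogram with an equal per-molecule frame budget."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_molecules: int
    frames_per_molecule: int
    pooled_values: np.ndarray = field(repr=False, default=None)
    mixture: MixtureFit | None = None

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())


def build_fret_histogram(
    series_list: list[FretSeries],
    frames_per_molecule: int = 250,
    bin_edges: np.ndarray | None = None,
) -> HistogramResult:
    """Histogram pooled per-frame E*, each molecule contributing its earliest
    ``min(frames_per_molecule, available)`` valid frames.

    Callers are expected to pass series already truncated to the pre-bleach
    region; the default range [-0.2, 1.2] with 0.02-wide bins is for display,
    mixture fits run on the pooled raw values.
    """
    if not series_list:
        raise ValueError("no FRET series given")
    if bin_edges is None:
        bin_edges = np.arange(-0.2, 1.2 + 1e-9, 0.02)
    pooled = []
    n_used = 0
    for series in series_list:
        values = series.efficiency[series.valid]
        if values.size == 0:
            continue
        pooled.append(values[:frames_per_molecule])
        n_used += 1
    if not pooled:
        raise ValueError("all molecules empty")
    pooled_arr = np.concatenate(pooled)
    counts, _ = np.histogram(pooled_arr, bins=bin_edges)
    return HistogramResult(
        bin_edges=np.asarray(bin_edges, float),
        counts=counts,
        n_molecules=n_used,
        frames_per_molecule=frames_per_molecule,
        pooled_values=pooled_arr,
    )


def fit_fret_mixture(
    values: np.ndarray,
    n_components: int,
    means_init: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureFit:
    """Maximum-likelihood 1-D Gaussian mixture on pooled E* values.

    Deterministic EM: means initialized at ``means_init`` (fixture-informed
    peak positions) or, failing that, at evenly spaced quantiles; components
    are reported sorted by mean.  Non-convergence is flagged, not raised.
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    k = int(n_components)
    if k < 1:
        raise ValueError("n_components must be >= 1")
    if x.size <= 10 * k:
        raise ValueError("too few data points for the requested mixture")
    if means_init is not None:
        mu = np.asarray(means_init, float).copy()
        if mu.shape != (k,):
            raise ValueError("means_init length must equal n_components")
    else:
        mu = np.quantile(x, (np.arange(k) + 0.5) / k)
    sd = np.full(k, max(x.std(), 1e-3))
    w = np.full(k, 1.0 / k)
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_comp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2 * np.pi * sd[None, :] ** 2)
            - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
        )
        m = log_comp.max(axis=1, keepdims=True)
        p = np.exp(log_comp - m)
        norm = p.sum(axis=1, keepdims=True)
        ll = float((np.log(norm) + m).sum())
        resp = p / norm
        nk = resp.sum(axis=0)
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / np.maximum(nk, 1e-12)
        sd = np.sqrt(np.maximum(var, 1e-10))
        if abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_prev = ll
    order = np.argsort(mu)
    return MixtureFit(
        means=mu[order], sds=sd[order], weights=w[order],
        log_likelihood=ll, converged=converged, n_iterations=it,
    )


def distance_to_fret(distance_nm: float, forster_radius_nm: float) -> float:
    """FRET efficiency for a donor-acceptor distance R and Forster radius R0:
    E = 1 / (1 + (R/R0)^6)."""
    if distance_nm <= 0 or forster_radius_nm <= 0:
        raise ValueError("distance and Forster radius must be > 0")
    return 1.0 / (1.0 + (distance_nm / forster_radius_nm) ** 6)
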