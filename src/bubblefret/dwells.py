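"""Dwell-time extraction and exponential / bi-exponential rate fitting.

Decoded state paths become category dwells (closed / intermediate / open);
pooled uncensored dwells of a category are fitted by maximum likelihood to a
left-truncated exponential (truncation at one frame period corrects for
unresolvable short dwells; truncating an exponential only shifts it, so the
MLE of the mean is ``mean(d) - t_min``).  Open dwells may follow
bi-exponential kinetics; a two-component truncated-exponential mixture is
fitted by seeded EM and compared against the single exponential by BIC.
Opening/closing rates are reciprocal mean dwell times.  Confidence intervals
come from a molecule-level bootstrap (resampling molecules, not dwells,
respects within-molecule correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DwellRecord",
    "ExpFit",
    "extract_dwells",
    "fit_exponential",
    "fit_biexponential",
    "compare_exp_models",
    "kinetics_report",
    "rate_fold_changes",
]


@dataclass(frozen=True)
class DwellRecord:
    molecule_id: str
    category: str  # closed | intermediate | open
    duration_s: float
    left_censored: bool = False
    right_censored: bool = False

    @property
    def censored(self) -> bool:
        return self.left_censored or self.right_censored


@dataclass
class ExpFit:
    n_components: int
    taus: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    n_dwells: int
    status: str = "ok"  # ok | insufficient_data | fallback_1component | not_converged
    ci: dict = field(default_factory=dict)  # e.g. {"tau": (lo, hi)}

    @property
    def rates(self) -> np.ndarray:
        return 1.0 / self.taus

    def as_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "taus_s": self.taus.tolist(),
            "weights": self.weights.tolist(),
            "rates_per_s": self.rates.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_dwells": self.n_dwells,
            "status": self.status,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }


def extract_dwells(
    state_path: np.ndarray,
    category_map: list[str],
    frame_period: float,
    molecule_id: str = "",
) -> list[DwellRecord]:
    """Maximal runs of constant state *category* along a decoded path.

    The first dwell of a trace is left-censored (its start precedes the
    record); the last is right-censored (truncated by bleach or record end).
    Single-frame dwells are retained.
    """
    states = np.asarray(state_path)
    states = states[states >= 0]
    if states.size == 0:
        return []
    cats = np.array([category_map[s] for s in states])
    change = np.flatnonzero(cats[1:] != cats[:-1]) + 1
    bounds = np.concatenate(([0], change, [cats.size]))
    dwells = []
    n_runs = len(bounds) - 1
    for i in range(n_runs):
        lo, hi = bounds[i], bounds[i + 1]
        dwells.append(DwellRecord(
            molecule_id=molecule_id,
            category=str(cats[lo]),
            duration_s=float((hi - lo) * frame_period),
            left_censored=i == 0,
            right_censored=i == n_runs - 1,
        ))
    return dwells


def _shifted_mle(durations: np.ndarray, t_min: float) -> float:
    return float(np.maximum(durations - t_min, 0.0).mean())


def _mle_with_censoring(
    uncensored: np.ndarray, censored: np.ndarray, t_min: float
) -> float:
    # censored sojourns contribute exposure but no event
    total = np.maximum(uncensored - t_min, 0.0).sum() + censored.sum()
    return float(total / uncensored.size)


def fit_exponential(
    dwells: list[DwellRecord],
    t_min: float,
    use_censored: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
    min_dwells: int = 10,
) -> ExpFit:
    """Single-exponential MLE of the mean dwell time, left-truncated at
    ``t_min`` (one frame).  Fewer than ``min_dwells`` uncensored dwells give
    a flagged insufficient-data result."""
    unc = np.array([d.duration_s for d in dwells if not d.censored])
    cen = np.array([d.duration_s for d in dwells if d.censored])
    if unc.size < min_dwells:
        return ExpFit(1, np.array([np.nan]), np.array([1.0]), np.nan,
                      int(unc.size), status="insufficient_data")
    if use_censored:
        tau = _mle_with_censoring(unc, cen, t_min)
    else:
        tau = _shifted_mle(unc, t_min)
    tau = max(tau, 1e-12)
    s = np.maximum(unc - t_min, 0.0)
    ll = float((-np.log(tau) - s / tau).sum())
    fit = ExpFit(1, np.array([tau]), np.array([1.0]), ll, int(unc.size))
    fit.ci["tau"] = _bootstrap_tau(dwells, t_min, use_censored, n_boot, seed)
    return fit


def _bootstrap_tau(
    dwells: list[DwellRecord], t_min: float, use_censored: bool,
    n_boot: int, seed: int,
) -> tuple[float, float]:
    by_mol: dict[str, list[DwellRecord]] = {}
    for d in dwells:
        by_mol.setdefault(d.molecule_id, []).append(d)
    mols = sorted(by_mol)
    if len(mols) < 2 or n_boot <= 0:
        return (float("nan"), float("nan"))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    taus = []
    for _ in range(n_boot):
        sample = rng.choice(len(mols), size=len(mols), replace=True)
        unc, cen = [], []
        for i in sample:
            for d in by_mol[mols[i]]:
                (cen if d.censored else unc).append(d.duration_s)
        if len(unc) < 2:
            continue
        unc_arr = np.asarray(unc)
        if use_censored:
            taus.append(_mle_with_censoring(unc_arr, np.asarray(cen), t_min))
        else:
            taus.append(_shifted_mle(unc_arr, t_min))
    if len(taus) < 10:
        return (float("nan"), float("nan"))
    lo, hi = np.percentile(taus, [2.5, 97.5])
    return (float(lo), float(hi))


def _em_exp_mixture(
    s: np.ndarray, taus0: np.ndarray, w0: np.ndarray,
    max_iter: int = 500, tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    taus, w = taus0.copy(), w0.copy()
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        log_r = np.log(w)[None, :] - np.log(taus)[None, :] - s[:, None] / taus[None, :]
        m = log_r.max(axis=1, keepdims=True)
        p = np.exp(log_r - m)
        norm = p.sum(axis=1, keepdims=True)
        ll = float((np.log(norm) + m).sum())
        resp = p / norm
        nk = resp.sum(axis=0)
        w = nk / s.size
        taus = (resp * s[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
        taus = np.maximum(taus, 1e-9)
        if abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_prev = ll
    return taus, w, ll, converged


def fit_biexponential(
    dwells: list[DwellRecord],
    t_min: float,
    seed: int = 0,
    n_restarts: int = 20,
    min_dwells: int = 100,
) -> ExpFit:
    """Two-component truncated-exponential mixture by EM with seeded
    restarts; components sorted tau_1 < tau_2.  Collapse (a vanishing weight
    or indistinguishable means) falls back to the single-exponential fit."""
    unc = np.array([d.duration_s for d in dwells if not d.censored])
    if unc.size < min_dwells:
        return ExpFit(2, np.full(2, np.nan), np.full(2, 0.5), np.nan,
                      int(unc.size), status="insufficient_data")
    s = np.maximum(unc - t_min, 0.0)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 29)))
    base = np.array([
        max(np.quantile(s, 0.25) / np.log(2), 1e-6),
        max(np.quantile(s, 0.85) / np.log(2), 2e-6),
    ])
    best = None
    for restart in range(max(1, n_restarts)):
        taus0 = base if restart == 0 else base * rng.lognormal(0.0, 0.5, size=2)
        taus, w, ll, conv = _em_exp_mixture(s, taus0, np.array([0.5, 0.5]))
        if best is None or ll > best[2]:
            best = (taus, w, ll, conv)
    taus, w, ll, conv = best
    order = np.argsort(taus)
    taus, w = taus[order], w[order]
    if w.min() < 0.01 or (taus[1] - taus[0]) / taus[1] < 0.05:
        single = fit_exponential(dwells, t_min, n_boot=0, seed=seed)
        single.status = "fallback_1component"
        return single
    fit = ExpFit(2, taus, w, ll, int(unc.size),
                 status="ok" if conv else "not_converged")
    return fit


def compare_exp_models(
    dwells: list[DwellRecord], t_min: float, seed: int = 0,
    min_biexp: int = 100,
) -> tuple[ExpFit, dict[int, float]]:
    """Choose 1 vs 2 exponential components by BIC (ties and insufficient
    data default to 1 component)."""
    single = fit_exponential(dwells, t_min, n_boot=0, seed=seed)
    if single.status == "insufficient_data":
        return single, {}
    n = single.n_dwells
    bic = {1: 1 * np.log(n) - 2 * single.log_likelihood}
    double = fit_biexponential(dwells, t_min, seed=seed, min_dwells=min_biexp)
    if double.status in ("insufficient_data", "fallback_1component"):
        return single, {1: float(bic[1])}
    bic[2] = 3 * np.log(n) - 2 * double.log_likelihood
    chosen = double if bic[2] < bic[1] - 1e-9 else single
    return chosen, {k: float(v) for k, v in bic.items()}


def kinetics_report(
    dwells: list[DwellRecord],
    condition: str,
    t_min: float,
    seed: int = 0,
    n_boot: int = 1000,
) -> dict:
    """Pooled per-condition kinetics table.

    Closed dwells give k_open = 1/tau_closed; open dwells are summarized
    both by the single-exponential mean (effective k_close) and by the
    BIC-chosen 1- or 2-component fit.  Intermediate dwells, which sit outside
    the two-category opening/closing analysis, are tabulated separately.
    """
    def of(cat):
        return [d for d in dwells if d.category == cat]

    closed_fit = fit_exponential(of("closed"), t_min, n_boot=n_boot, seed=seed)
    open_single = fit_exponential(of("open"), t_min, n_boot=n_boot, seed=seed + 1)
    open_choice, open_bic = compare_exp_models(of("open"), t_min, seed=seed + 2)
    inter_fit = fit_exponential(of("intermediate"), t_min, n_boot=0, seed=seed + 3)
    report = {
        "condition": condition,
        "t_min_s": t_min,
        "closed": closed_fit.as_dict(),
        "open_single": open_single.as_dict(),
        "open_model": open_choice.as_dict(),
        "open_bic": open_bic,
        "intermediate": inter_fit.as_dict(),
    }
    if closed_fit.status == "ok":
        report["k_open_per_s"] = float(closed_fit.rates[0])
        lo, hi = closed_fit.ci.get("tau", (np.nan, np.nan))
        report["k_open_ci"] = [1.0 / hi if hi else np.nan,
                               1.0 / lo if lo else np.nan]
    if open_single.status == "ok":
        report["k_close_per_s"] = float(open_single.rates[0])
        lo, hi = open_single.ci.get("tau", (np.nan, np.nan))
        report["k_close_ci"] = [1.0 / hi if hi else np.nan,
                                1.0 / lo if lo else np.nan]
    return report


def rate_fold_changes(report: dict, reference: dict) -> dict:
    """Opening/closing rate ratios of one condition over a reference."""
    out = {"condition": report["condition"], "reference": reference["condition"]}
    for key in ("k_open_per_s", "k_close_per_s"):
        if key in report and key in reference and reference[key] > 0:
            out[key.replace("_per_s", "_ratio")] = report[key] / reference[key]
    return out
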