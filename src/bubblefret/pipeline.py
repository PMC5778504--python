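"""End-to-end orchestration: simulate -> E*/QC -> HMM -> classify -> kinetics.

Each stage reads only the on-disk outputs of earlier stages, so a run is
re-entrant and any stage can be re-executed in isolation.  A single global
seed is expanded into per-stage, per-molecule substreams
(``SeedSequence((seed, stage, molecule))``), making stage re-runs
reproducible independently.  Re-running an identical config reproduces
byte-identical machine-readable outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dwells import extract_dwells, kinetics_report, rate_fold_changes
from .fret import build_fret_histogram, compute_fret_series, fit_fret_mixture
from .hmm import HmmModel, HmmPriors, decode_path, categorize_states, select_model
from .io import read_dataset, read_json, write_dataset, write_json
from .qc import QcConfig, QcReport, apply_selection, classify_trace, population_table
from .scenarios import load_scenario
from .simulate import simulate_dataset
from .types import FretSeries, ScenarioConfig

log = logging.getLogger("bubblefret")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "compare_conditions"]


@dataclass(frozen=True)
class RunConfig:
    scenarios: tuple[str, ...]
    seed: int
    out_dir: str
    n_molecules: int | None = None
    frames_per_molecule: int = 250
    boundaries: tuple[float, float] = (0.275, 0.40)
    mixture_components: int = 2
    mixture_means_init: tuple[float, float] = (0.2, 0.45)
    k_max: int = 3
    n_restarts: int = 10
    n_boot: int = 1000
    priors: HmmPriors = HmmPriors()
    qc: QcConfig = QcConfig()

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("no scenarios given")
        object.__setattr__(self, "scenarios", tuple(self.scenarios))

    def digest(self) -> str:
        names = [s if isinstance(s, str) else s.name for s in self.scenarios]
        payload = json.dumps({
            "scenarios": names, "seed": self.seed,
            "n_molecules": self.n_molecules,
            "frames_per_molecule": self.frames_per_molecule,
            "boundaries": list(self.boundaries),
            "mixture_components": self.mixture_components,
            "mixture_means_init": list(self.mixture_means_init),
            "k_max": self.k_max, "n_restarts": self.n_restarts,
            "n_boot": self.n_boot,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    conditions: dict[str, dict]
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"conditions": self.conditions, "provenance": self.provenance}


def _mol_seed(seed: int, stage: int, index: int) -> int:
    ss = np.random.SeedSequence((seed, stage, index))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------- stages


def stage_simulate(scenario: ScenarioConfig, sim_dir: Path) -> None:
    dataset = simulate_dataset(scenario)
    write_dataset(dataset, sim_dir)


def stage_qc(sim_dir: Path, qc_dir: Path, qc_config: QcConfig) -> None:
    traces, _ = read_dataset(sim_dir)
    reports = [apply_selection(t, None, qc_config) for t in traces]
    totals = np.array([r.mean_total_intensity for r in reports])
    med = float(np.median(totals))
    lo, hi = qc_config.intensity_band
    rows = []
    for trace, rep in zip(traces, reports):
        reasons = list(rep.rejection_reasons)
        if med > 0 and not lo * med <= rep.mean_total_intensity <= hi * med:
            reasons.append("intensity_out_of_range")
        rows.append({
            "molecule_id": rep.molecule_id,
            "accepted": not reasons,
            "rejection_reasons": ";".join(reasons),
            "donor_bleach_frame": rep.donor_bleach_frame,
            "acceptor_bleach_frame": rep.acceptor_bleach_frame,
            "analysis_end": rep.analysis_end(len(trace)),
            "mean_total_intensity": rep.mean_total_intensity,
        })
    qc_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(qc_dir / "qc_report.csv", index=False)


def _load_qc(qc_dir: Path) -> pd.DataFrame:
    df = pd.read_csv(qc_dir / "qc_report.csv")
    return df.set_index("molecule_id")


def _background_for(trace, qc_row, fallback: float) -> dict[str, float]:
    """Per-channel constant background: post-bleach median where a bleach is
    detected, else the configured scenario background."""
    bg = {}
    d = qc_row["donor_bleach_frame"]
    a = qc_row["acceptor_bleach_frame"]
    d = None if pd.isna(d) else int(d)
    a = None if pd.isna(a) else int(a)
    for name, series, bleach in (
        ("DD", trace.DD, d), ("DA", trace.DA, d), ("AA", trace.AA, a),
    ):
        if bleach is not None and len(series) - bleach >= 5:
            bg[name] = float(np.median(series[bleach + 1:]))
        else:
            bg[name] = fallback
    # DA goes dark at whichever fluorophore bleaches first
    if a is not None and (d is None or a < d) and len(trace.DA) - a >= 5:
        bg["DA"] = float(np.median(trace.DA[a + 1:]))
    return bg


def stage_fret(
    sim_dir: Path, qc_dir: Path, fret_dir: Path, config: RunConfig
) -> None:
    traces, manifest = read_dataset(sim_dir)
    qc = _load_qc(qc_dir)
    fallback = float(manifest.get("background_per_channel", 0.0))
    fret_dir.mkdir(parents=True, exist_ok=True)
    truncated = []
    for trace in traces:
        row = qc.loc[trace.molecule_id]
        bg = _background_for(trace, row, fallback)
        series = compute_fret_series(trace, background=bg)
        end = int(row["analysis_end"])
        pd.DataFrame({
            "frame_index": np.arange(len(series)),
            "efficiency": series.efficiency,
            "stoichiometry": series.stoichiometry,
            "valid": series.valid.astype(int),
        }).to_csv(fret_dir / f"{trace.molecule_id}_fret.tsv", sep="\t", index=False)
        if row["accepted"]:
            truncated.append(FretSeries(
                series.efficiency[:end], series.stoichiometry[:end],
                series.valid[:end], series.frame_period_s, series.molecule_id,
            ))
    if truncated:
        hist = build_fret_histogram(truncated, config.frames_per_molecule)
        pd.DataFrame({
            "bin_left": hist.bin_edges[:-1],
            "bin_right": hist.bin_edges[1:],
            "count": hist.counts,
        }).to_csv(fret_dir / "histogram.csv", index=False)
        mixture = fit_fret_mixture(
            hist.pooled_values, config.mixture_components,
            means_init=np.asarray(config.mixture_means_init),
        )
        write_json(mixture.as_dict(), fret_dir / "mixture.json")


def _read_fret(fret_dir: Path, molecule_id: str, frame_period: float) -> FretSeries:
    df = pd.read_csv(fret_dir / f"{molecule_id}_fret.tsv", sep="\t")
    return FretSeries(
        df["efficiency"].to_numpy(), df["stoichiometry"].to_numpy(),
        df["valid"].to_numpy().astype(bool), frame_period, molecule_id,
    )


def _slice_series(series: FretSeries, end: int) -> FretSeries:
    return FretSeries(
        series.efficiency[:end], series.stoichiometry[:end],
        series.valid[:end], series.frame_period_s, series.molecule_id,
    )


def stage_hmm(
    sim_dir: Path, qc_dir: Path, fret_dir: Path, hmm_dir: Path, config: RunConfig
) -> None:
    manifest = read_json(sim_dir / "manifest.json")
    qc = _load_qc(qc_dir)
    hmm_dir.mkdir(parents=True, exist_ok=True)
    frame_period = float(manifest["frame_period_s"])
    for idx, entry in enumerate(manifest["molecules"]):
        mol = entry["molecule_id"]
        row = qc.loc[mol]
        if not row["accepted"]:
            continue
        series = _slice_series(
            _read_fret(fret_dir, mol, frame_period), int(row["analysis_end"])
        )
        if series.n_valid < 50:
            log.warning("%s: too few valid frames for HMM", mol)
            continue
        model = select_model(
            series, k_max=config.k_max, priors=config.priors,
            seed=_mol_seed(config.seed, 3, idx), n_restarts=config.n_restarts,
        )
        path = decode_path(model, series)
        write_json(model.as_dict(), hmm_dir / f"{mol}_hmm.json")
        post_max = np.max(np.nan_to_num(path.posterior, nan=-1.0), axis=1)
        pd.DataFrame({
            "frame_index": np.arange(len(path.states)),
            "state": path.states,
            "posterior_max": np.where(path.states >= 0, post_max, np.nan),
        }).to_csv(hmm_dir / f"{mol}_path.tsv", sep="\t", index=False)


def _model_from_json(doc: dict) -> HmmModel:
    return HmmModel(
        n_states=int(doc["n_states"]),
        initial_probs=np.array(doc["initial_probs"]),
        transition_matrix=np.array(doc["transition_matrix"]),
        emission_mean=np.array(doc["emission_mean"]),
        emission_sd=np.array(doc["emission_sd"]),
        evidence=float(doc["evidence"]),
        converged=bool(doc["converged"]),
        n_iterations=int(doc["n_iterations"]),
    )


def stage_classify(
    sim_dir: Path, qc_dir: Path, fret_dir: Path, hmm_dir: Path,
    classify_dir: Path, config: RunConfig,
) -> None:
    from .io import read_trace
    from .hmm import StatePath

    manifest = read_json(sim_dir / "manifest.json")
    qc = _load_qc(qc_dir)
    classify_dir.mkdir(parents=True, exist_ok=True)
    frame_period = float(manifest["frame_period_s"])
    rows = []
    for entry in manifest["molecules"]:
        mol = entry["molecule_id"]
        row = qc.loc[mol]
        if not row["accepted"]:
            continue
        end = int(row["analysis_end"])
        series = _read_fret(fret_dir, mol, frame_period)
        model = path = None
        hmm_file = hmm_dir / f"{mol}_hmm.json"
        if hmm_file.exists():
            model = _model_from_json(read_json(hmm_file))
            pdf = pd.read_csv(hmm_dir / f"{mol}_path.tsv", sep="\t")
            states = pdf["state"].to_numpy()
            path = StatePath(states=states, posterior=np.zeros((len(states), 1)))
        trace = read_trace(sim_dir / entry["file"])
        cls = classify_trace(
            series, model, path, trace=trace,
            boundaries=config.boundaries, end_frame=end,
        )
        rows.append({
            "molecule_id": mol,
            "class": cls.label,
            "mean_fret": cls.mean_fret,
            "n_transitions": cls.n_transitions,
            "anticorrelation": cls.anticorrelation,
        })
    df = pd.DataFrame(rows)
    df.to_csv(classify_dir / "classes.csv", index=False)
    if len(df):
        table = population_table([
            r for r in df["class"].tolist() if r != "unclassifiable"
        ])
        write_json({
            "fractions": table["fraction"].to_dict(),
            "counts": {k: int(v) for k, v in table["count"].to_dict().items()},
            "n_accepted": int(len(df)),
        }, classify_dir / "populations.json")


def stage_kinetics(
    sim_dir: Path, qc_dir: Path, fret_dir: Path, hmm_dir: Path,
    classify_dir: Path, kinetics_dir: Path, config: RunConfig, condition: str,
) -> None:
    manifest = read_json(sim_dir / "manifest.json")
    qc = _load_qc(qc_dir)
    classes = pd.read_csv(classify_dir / "classes.csv").set_index("molecule_id")
    kinetics_dir.mkdir(parents=True, exist_ok=True)
    frame_period = float(manifest["frame_period_s"])
    all_dwells = []
    for entry in manifest["molecules"]:
        mol = entry["molecule_id"]
        if mol not in classes.index or classes.loc[mol, "class"] != "dynamic":
            continue
        model = _model_from_json(read_json(hmm_dir / f"{mol}_hmm.json"))
        cats = categorize_states(model, config.boundaries)
        pdf = pd.read_csv(hmm_dir / f"{mol}_path.tsv", sep="\t")
        states = pdf["state"].to_numpy()[: int(qc.loc[mol, "analysis_end"])]
        all_dwells.extend(extract_dwells(states, cats, frame_period, mol))
    pd.DataFrame([{
        "molecule_id": d.molecule_id, "category": d.category,
        "duration_s": d.duration_s,
        "left_censored": d.left_censored, "right_censored": d.right_censored,
    } for d in all_dwells]).to_csv(kinetics_dir / "dwells.csv", index=False)
    report = kinetics_report(
        all_dwells, condition, t_min=frame_period,
        seed=_mol_seed(config.seed, 5, 0), n_boot=config.n_boot,
    )
    write_json(report, kinetics_dir / "kinetics.json")


# ---------------------------------------------------------------- driver


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage for every scenario; returns and writes the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conditions: dict[str, dict] = {}
    for i, name in enumerate(config.scenarios):
        if isinstance(name, ScenarioConfig):
            scenario = replace(
                name, seed=_mol_seed(config.seed, 0, i),
                **({"n_molecules": config.n_molecules}
                   if config.n_molecules else {}),
            )
        else:
            scenario = load_scenario(
                name, n_molecules=config.n_molecules,
                seed=_mol_seed(config.seed, 0, i),
            )
        base = out / scenario.name
        log.info("scenario %s: simulate", scenario.name)
        stage_simulate(scenario, base / "sim")
        stage_qc(base / "sim", base / "qc", config.qc)
        stage_fret(base / "sim", base / "qc", base / "fret", config)
        stage_hmm(base / "sim", base / "qc", base / "fret", base / "hmm", config)
        stage_classify(base / "sim", base / "qc", base / "fret",
                       base / "hmm", base / "classify", config)
        stage_kinetics(base / "sim", base / "qc", base / "fret", base / "hmm",
                       base / "classify", base / "kinetics", config,
                       scenario.name)
        conditions[scenario.name] = _collect_condition(base)
    report = RunReport(
        conditions=conditions,
        provenance={
            "seed": config.seed,
            "config_digest": config.digest(),
            "version": __version__,
        },
    )
    write_json(report.as_dict(), out / "report.json")
    _write_summary(report, out / "summary.txt")
    return report


def _collect_condition(base: Path) -> dict:
    out: dict = {}
    pop = base / "classify" / "populations.json"
    if pop.exists():
        out["populations"] = read_json(pop)
    mix = base / "fret" / "mixture.json"
    if mix.exists():
        out["mixture"] = read_json(mix)
    kin = base / "kinetics" / "kinetics.json"
    if kin.exists():
        out["kinetics"] = read_json(kin)
    qc = pd.read_csv(base / "qc" / "qc_report.csv")
    out["qc"] = {
        "n_molecules": int(len(qc)),
        "n_accepted": int(qc["accepted"].sum()),
    }
    return out


def _write_summary(report: RunReport, path: Path) -> None:
    lines = []
    for name, cond in sorted(report.conditions.items()):
        lines.append(f"== {name} ==")
        qc = cond.get("qc", {})
        lines.append(
            f"  accepted {qc.get('n_accepted', 0)}/{qc.get('n_molecules', 0)} molecules"
        )
        pops = cond.get("populations", {}).get("fractions", {})
        for label, frac in sorted(pops.items()):
            lines.append(f"  {label:22s} {100 * frac:5.1f}%")
        kin = cond.get("kinetics", {})
        if "k_open_per_s" in kin:
            lines.append(f"  k_open  = {kin['k_open_per_s']:.2f} /s")
        if "k_close_per_s" in kin:
            lines.append(f"  k_close = {kin['k_close_per_s']:.2f} /s")
        om = kin.get("open_model", {})
        if om.get("n_components") == 2:
            t1, t2 = om["taus_s"]
            w1, w2 = om["weights"]
            lines.append(
                f"  open dwells bi-exponential: "
                f"tau1={t1 * 1e3:.0f} ms ({100 * w1:.0f}%), "
                f"tau2={t2 * 1e3:.0f} ms ({100 * w2:.0f}%)"
            )
    path.write_text("\n".join(lines) + "\n")


def compare_conditions(report: RunReport, reference: str) -> dict:
    """Per-condition deltas of population fractions and rate ratios versus a
    reference condition."""
    if reference not in report.conditions:
        raise ValueError(f"reference {reference!r} not in report")
    ref = report.conditions[reference]
    out: dict[str, dict] = {}
    ref_pops = ref.get("populations", {}).get("fractions", {})
    for name, cond in report.conditions.items():
        entry: dict = {}
        pops = cond.get("populations", {}).get("fractions", {})
        entry["population_delta"] = {
            label: pops.get(label, 0.0) - ref_pops.get(label, 0.0)
            for label in sorted(set(pops) | set(ref_pops))
        }
        if "kinetics" in cond and "kinetics" in ref:
            entry["rates"] = rate_fold_changes(cond["kinetics"], ref["kinetics"])
        out[name] = entry
    return out
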