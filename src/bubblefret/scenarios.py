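"""Scenario (experimental-condition) configuration: YAML schema and bundled
fixtures.

Schema (all photophysics keys optional, defaulting to
:class:`~bubblefret.types.PhotophysicsParams`)::

    name: wt_dsDNA_22C
    alternation_rate_hz: 100      # frames per second (one frame = one period)
    n_molecules: 100
    max_duration_s: 10.0
    seed: 0
    photophysics:
      photons_per_frame_dex: 100.0
      quench_states: [closed]     # optional contact-quenched states
    subpopulations:
      - label: dynamic
        proportion: 0.25
        scheme:
          states:
            - {label: closed, fret: 0.20, category: closed}
            - {label: open, fret: 0.45, category: open}
          rates:                  # off-diagonal CTMC rates, s^-1
            closed->open: 6.4
            open->closed: 1.64
          initial_distribution: stationary   # default

Proportions are normalized to sum to 1 on load.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .types import KineticScheme, PhotophysicsParams, ScenarioConfig, Subpopulation

__all__ = [
    "list_scenarios",
    "load_scenario",
    "scenario_from_dict",
    "dynamic_only",
]


def list_scenarios() -> list[str]:
    """Names of the bundled scenario fixtures."""
    pkg = resources.files("bubblefret") / "fixtures"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def _parse_scheme(spec: dict) -> KineticScheme:
    states = spec["states"]
    labels = [s["label"] for s in states]
    fret = [float(s["fret"]) for s in states]
    cats = [s["category"] for s in states]
    rates = {}
    for key, value in (spec.get("rates") or {}).items():
        src, dst = (part.strip() for part in key.split("->"))
        rates[(src, dst)] = float(value)
    init = spec.get("initial_distribution", "stationary")
    return KineticScheme.from_rates(labels, fret, cats, rates, init)


def scenario_from_dict(doc: dict, **overrides) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a parsed YAML document.

    ``overrides`` may replace any top-level field (``n_molecules``, ``seed``,
    ``max_duration_s``, ...).
    """
    doc = {**doc, **{k: v for k, v in overrides.items() if v is not None}}
    phot = dict(doc.get("photophysics") or {})
    if "quench_states" in phot:
        phot["quench_states"] = frozenset(phot["quench_states"])
    subs = tuple(
        Subpopulation(
            label=s.get("label", f"sub{i}"),
            proportion=float(s["proportion"]),
            scheme=_parse_scheme(s["scheme"]),
        )
        for i, s in enumerate(doc["subpopulations"])
    )
    return ScenarioConfig(
        name=doc["name"],
        subpopulations=subs,
        photophysics=PhotophysicsParams(**phot),
        alternation_rate_hz=float(doc.get("alternation_rate_hz", 100.0)),
        n_molecules=int(doc.get("n_molecules", 100)),
        max_duration_s=float(doc.get("max_duration_s", 10.0)),
        seed=int(doc.get("seed", 0)),
    )


def load_scenario(name_or_path: str | Path, **overrides) -> ScenarioConfig:
    """Load a bundled fixture by name or any scenario YAML by path."""
    path = Path(name_or_path)
    if path.suffix in {".yaml", ".yml"} and path.exists():
        text = path.read_text()
    else:
        res = resources.files("bubblefret") / "fixtures" / f"{name_or_path}.yaml"
        if not res.is_file():
            raise FileNotFoundError(
                f"unknown scenario {name_or_path!r}; bundled: {list_scenarios()}"
            )
        text = res.read_text()
    return scenario_from_dict(yaml.safe_load(text), **overrides)


def dynamic_only(config: ScenarioConfig, **overrides) -> ScenarioConfig:
    """Restrict a scenario to its dynamic subpopulation(s) (proportion 1).

    Used for kinetics-focused runs where only interconverting molecules carry
    dwell-time information.
    """
    subs = tuple(s for s in config.subpopulations if s.label == "dynamic")
    if not subs:
        raise ValueError(f"scenario {config.name!r} has no dynamic subpopulation")
    doc = {
        "name": config.name + "_dynamic",
        "n_molecules": config.n_molecules,
        "max_duration_s": config.max_duration_s,
        "alternation_rate_hz": config.alternation_rate_hz,
        "seed": config.seed,
    }
    doc.update({k: v for k, v in overrides.items() if v is not None})
    return ScenarioConfig(
        name=doc["name"],
        subpopulations=subs,
        photophysics=config.photophysics,
        alternation_rate_hz=doc["alternation_rate_hz"],
        n_molecules=doc["n_molecules"],
        max_duration_s=doc["max_duration_s"],
        seed=doc["seed"],
    )
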