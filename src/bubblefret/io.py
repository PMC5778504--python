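"""On-disk dataset layout: one TSV per molecule plus ``manifest.json``.

TSV columns are ``frame_index  time_s  DD  DA  AA`` (tab-delimited, UTF-8)
with ``#``-prefixed header lines carrying metadata (molecule_id,
frame_period_s).  The manifest records the scenario, seed and per-molecule
ground-truth summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Dataset
from .types import AlexTrace

__all__ = ["write_dataset", "read_trace", "read_dataset", "write_json", "read_json"]


def write_trace(trace: AlexTrace, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# molecule_id: {trace.molecule_id}\n")
        fh.write(f"# frame_period_s: {trace.frame_period_s!r}\n")
        for key, value in trace.metadata.items():
            fh.write(f"# {key}: {value!r}\n")
        fh.write("frame_index\ttime_s\tDD\tDA\tAA\n")
        for i in range(len(trace)):
            fh.write(
                f"{i}\t{i * trace.frame_period_s:.6f}\t"
                f"{trace.DD[i]:.3f}\t{trace.DA[i]:.3f}\t{trace.AA[i]:.3f}\n"
            )


def read_trace(path: Path) -> AlexTrace:
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            pos = fh.tell()
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip().strip("'\"")
        df = pd.read_csv(fh, sep="\t")
    return AlexTrace(
        DD=df["DD"].to_numpy(),
        DA=df["DA"].to_numpy(),
        AA=df["AA"].to_numpy(),
        frame_period_s=float(meta.pop("frame_period_s")),
        molecule_id=meta.pop("molecule_id", path.stem),
        metadata={
            k: _maybe_float(v) for k, v in meta.items()
        },
    )


def _maybe_float(value: str):
    try:
        return float(value)
    except (TypeError, ValueError):
        return value


def write_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write every trace plus the manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest()
    for trace, entry in zip(dataset.traces, manifest["molecules"]):
        write_trace(trace, out / entry["file"])
    path = out / "manifest.json"
    write_json(manifest, path)
    return path


def read_dataset(in_dir: str | Path) -> tuple[list[AlexTrace], dict]:
    """Load all traces listed in a dataset directory's manifest."""
    in_dir = Path(in_dir)
    manifest = read_json(in_dir / "manifest.json")
    traces = [read_trace(in_dir / m["file"]) for m in manifest["molecules"]]
    return traces, manifest


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        return super().default(obj)


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
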