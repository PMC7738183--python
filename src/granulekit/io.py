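"""File I/O: TIFF stacks, CSV tables, JSON sidecars, YAML scenario configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import fcs as _fcs
from . import synthetic as _syn

__all__ = [
    "save_stack",
    "load_stack",
    "save_ground_truth",
    "scenario_to_yaml",
    "scenario_from_yaml",
    "write_fcs_curves",
    "read_fcs_curves",
    "write_events",
]


def save_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write an unsigned 16-bit ImageJ-compatible TIFF stack."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16), imagej=True)


def load_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def save_ground_truth(path: str | Path, truth: pd.DataFrame) -> None:
    """JSON sidecar: ground-truth records plus any table-level attrs."""
    payload = {"attrs": dict(truth.attrs), "records": json.loads(truth.to_json(orient="records"))}
    Path(path).write_text(json.dumps(payload, indent=1))


def scenario_to_yaml(config: _syn.ScenarioConfig, path: str | Path | None = None) -> str:
    doc = {
        "name": config.name,
        "seed": config.seed,
        "populations": [dataclasses.asdict(p) for p in config.populations],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def scenario_from_yaml(source: str | Path) -> _syn.ScenarioConfig:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    doc = yaml.safe_load(text)
    pops = tuple(_syn.PopulationParams(**p) for p in doc["populations"])
    return _syn.ScenarioConfig(name=doc["name"], populations=pops, seed=doc.get("seed", 0))


def write_fcs_curves(path: str | Path, curves: list[_fcs.FcsCurve]) -> None:
    """Long-format CSV with columns run_id, tau_s, g, temperature_K."""
    frames = [
        pd.DataFrame(
            {"run_id": i, "tau_s": c.tau, "g": c.g, "temperature_K": c.temperature}
        )
        for i, c in enumerate(curves)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_fcs_curves(path: str | Path) -> list[_fcs.FcsCurve]:
    df = pd.read_csv(path)
    curves = []
    for _, sub in df.groupby("run_id", sort=True):
        curves.append(
            _fcs.FcsCurve(
                tau=sub["tau_s"].to_numpy(),
                g=sub["g"].to_numpy(),
                temperature=float(sub["temperature_K"].iloc[0]),
            )
        )
    return curves


def write_events(path: str | Path, events, frame_interval: float) -> None:
    """Event-table CSV: granule_id, onset_s, duration_s, delta_ic, mode, rss."""
    rows = [
        {
            "granule_id": i,
            "onset_s": e.onset_frame * frame_interval,
            "duration_s": e.duration,
            "delta_ic": e.delta_ic,
            "mode": e.mode,
            "rss": e.fit_rss,
        }
        for i, e in enumerate(events)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
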