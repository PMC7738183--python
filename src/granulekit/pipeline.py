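"""End-to-end scenario runs: configuration, orchestration, reporting.

A :class:`RunConfig` names the scenarios to simulate, toggles stages, and
carries the seed; :func:`run` executes simulate -> detect/fit ->
dose-response -> sizing -> biochemistry for each scenario and writes a JSON
report plus a human-readable summary.  Reports are deterministic for a fixed
config and seed, and every output records the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import biochem, dose_response, fcs, synthetic, tirf
from . import io as gio

__all__ = ["RunConfig", "run", "validate_config"]

log = logging.getLogger("granulekit")

_VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Configuration of an end-to-end run (all defaults documented inline)."""

    scenarios: list[str] = field(
        default_factory=lambda: ["untreated", "ffa", "cytokine"]
    )
    seed: int = 0
    outdir: str = "granulekit_out"
    # stage toggles
    do_dose_response: bool = True
    do_sizing: bool = True
    do_fcs: bool = True
    do_tirf: bool = True
    do_lipids: bool = True
    do_secretion: bool = True
    # dose-response stage
    calcium_levels_um: list[float] = field(
        default_factory=lambda: [2, 5, 10, 20, 35, 60, 120, 300]
    )
    granules_per_level: int = 300
    # sizing stage
    n_diameters: int = 2000
    # FCS stage: hydrodynamic radius (m) per scenario from the size mixture
    fcs_runs: int = 20
    fcs_noise: float = 0.01
    # TIRF stage
    stack_granules: int = 30
    stack_shape: tuple[int, int] = (128, 128)
    # lipidomics stage
    lipid_reps: int = 4
    lipid_cv: float = 0.15

    def hash(self) -> str:
        # paths excluded: the same scientific configuration hashes the same
        # wherever its outputs land
        doc = dataclasses.asdict(self)
        doc.pop("outdir")
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config, reporting all problems together."""
    try:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    except OSError as exc:
        raise ValueError(f"unreadable config file: {exc}") from exc
    known = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    errors = [f"unknown key: {k}" for k in doc if k not in known]
    cfg = RunConfig(**{k: v for k, v in doc.items() if k in known})
    if cfg.seed < 0:
        errors.append("seed must be non-negative")
    if any(c <= 0 for c in cfg.calcium_levels_um):
        errors.append("calcium levels must be positive")
    if cfg.granules_per_level < 1:
        errors.append("granules_per_level must be >= 1")
    for name in cfg.scenarios:
        if name not in synthetic.SCENARIO_NAMES:
            errors.append(f"unknown scenario: {name}")
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return cfg


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("dose_response")
def _run_dose_response(cfg: RunConfig, scenario, seed):
    outcomes = synthetic.simulate_fusion_outcomes(
        scenario, cfg.calcium_levels_um, cfg.granules_per_level, seed=seed
    )
    curve = dose_response.assemble(outcomes)
    fit1 = dose_response.fit_dose_response(curve, 1)
    fit2 = dose_response.fit_dose_response(curve, 2)
    chosen, evidence = dose_response.select_model(fit1, fit2)
    return {
        "n_components": chosen.n_components,
        "k_half_um": [round(float(k), 3) for k in chosen.k_half],
        "weights": [round(float(w), 4) for w in chosen.weights],
        "f_max": round(chosen.f_max, 4),
        "evidence": {k: (round(v, 3) if isinstance(v, float) else v)
                     for k, v in evidence.items()},
    }, chosen


@_stage("sizing")
def _run_sizing(cfg: RunConfig, scenario, seed):
    d = synthetic.sample_diameters(scenario, cfg.n_diameters, seed=seed)
    mean, sd = fcs.summarize_diameters(d)
    out = {"mean_nm": round(mean, 2), "sd_nm": round(sd, 2)}
    if len(scenario.populations) > 1:
        mix = fcs.fit_diameter_mixture(d, k=2, seed=seed)
        out["mixture_means_nm"] = [round(float(m), 2) for m in mix.means]
        out["mixture_weights"] = [round(float(w), 3) for w in mix.weights]
        out["separable"] = mix.separable
    return out


@_stage("fcs")
def _run_fcs(cfg: RunConfig, scenario, seed):
    # effective particle radius: half the mixture mean diameter
    mean_d = sum(p.weight * p.diam_mean for p in scenario.populations)
    rh = mean_d / 2 * 1e-9
    rng = np.random.default_rng(seed)
    cal_curves = synthetic.simulate_fcs(
        d=4.5e-10, temperature=298.15, t_b=0.0, noise=cfg.fcs_noise,
        n_runs=5, temperature_jitter=0.0, seed=int(rng.integers(2**31)),
    )
    cal_avg = fcs.FcsCurve(
        tau=cal_curves[0].tau,
        g=np.mean([c.g for c in cal_curves], axis=0),
        temperature=298.15,
    )
    calib = fcs.calibrate(cal_avg, d_ref=4.5e-10, temperature=298.15)
    curves = synthetic.simulate_fcs(
        rh=rh, temperature=295.15, noise=cfg.fcs_noise,
        n_runs=cfg.fcs_runs, seed=int(rng.integers(2**31)),
    )
    fits = [fcs.fit_curve(c, "blink", calib) for c in curves]
    agg = fcs.aggregate_rh(fits)
    return {
        "true_diameter_nm": round(mean_d, 1),
        "fitted_diameter_nm": round(agg.diameter_nm, 2),
        "rh_sd_nm": round(agg.sd * 1e9, 3),
        "omega_r_um": round(calib.omega_r * 1e6, 4),
    }


@_stage("tirf")
def _run_tirf(cfg: RunConfig, scenario, seed, outdir: Path):
    stack, truth = synthetic.simulate_stack(
        scenario, calcium_um=100.0, shape=cfg.stack_shape,
        n_granules=cfg.stack_granules, seed=seed,
    )
    dt = truth.attrs["frame_interval"]
    filtered = tirf.preprocess(stack, 3)
    det = tirf.detect(filtered)
    traces = tirf.extract_traces(filtered, det.centers, frame_interval=dt)
    events = []
    n_moving = 0
    for tr in traces:
        seg = tirf.segment_event(tr)
        if seg is None:
            continue
        # moving granules are excluded from release-mode analysis
        drift = tirf.centroid_drift(
            filtered, tr.roi_center, slice(0, 10), slice(max(seg[0] - 10, 0), seg[0] + 1)
        )
        if drift > 2.0:
            n_moving += 1
            continue
        events.append(tirf.fit_release(tr, seg))
    gio.write_events(outdir / f"events_{scenario.name}.csv", events, dt)
    out = {
        "n_detected": int(len(det.centers)),
        "n_true": int(len(truth)),
        "n_events": len(events),
        "n_moving_excluded": n_moving,
        "fraction_fused": round(len(events) / max(len(det.centers), 1), 3),
    }
    if len(events) >= 20:
        _, report = tirf.classify_modes(events)
        out["mode_report"] = {
            k: (round(v, 2) if isinstance(v, float) else v) for k, v in report.items()
            if k in ("degenerate", "boundary", "single_label")
        }
        out["n_fast"] = sum(e.mode == "fast" for e in events)
        out["n_slow"] = sum(e.mode == "slow" for e in events)
    return out


@_stage("lipids")
def _run_lipids(cfg: RunConfig, seed):
    table = synthetic.simulate_lipid_table(n_reps=cfg.lipid_reps, cv=cfg.lipid_cv, seed=seed)
    vol = biochem.volcano(biochem.normalize_lipids(table))
    hits = vol[vol["significant"]]
    sm = vol.set_index("species").loc["SM 42:1"]
    return {
        "n_species": int(len(vol)),
        "n_significant": int(len(hits)),
        "significant_species": hits["species"].tolist(),
        "sm_42_1_fold_syt7_over_syt9": round(1.0 / float(sm["ratio"]), 3),
    }


@_stage("secretion")
def _run_secretion(cfg: RunConfig, scenario, seed):
    out = {}
    rows = []
    for stim in (25.0, 90.0):
        ms = synthetic.simulate_secretion(scenario, stim, seed=seed + int(stim))
        rows += ms
        out[f"fractional_secretion_{int(stim)}mM_pct"] = round(
            float(np.mean([biochem.fractional_secretion(m.secreted, m.lysate) for m in ms])), 2
        )
    return out


def run(config: RunConfig) -> dict:
    """Execute the configured stages for every scenario and write the report.

    Outputs ``report.json`` and ``summary.txt`` in ``config.outdir``.  A
    stage failure aborts the run with a stage-tagged error; outputs of
    completed stages are preserved on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {
        "version": _VERSION,
        "config_hash": config.hash(),
        "seed": config.seed,
        "scenarios": {},
    }
    for name in config.scenarios:
        scen_seed = int(rng.integers(2**31))
        scenario = synthetic.make_scenario(name, seed=scen_seed)
        gio.scenario_to_yaml(scenario, outdir / f"scenario_{name}.yaml")
        entry: dict = {}
        if config.do_dose_response:
            entry["dose_response"], _ = _run_dose_response(config, scenario, scen_seed)
        if config.do_sizing:
            entry["sizing"] = _run_sizing(config, scenario, scen_seed + 1)
        if config.do_fcs:
            entry["fcs"] = _run_fcs(config, scenario, scen_seed + 2)
        if config.do_tirf:
            entry["tirf"] = _run_tirf(config, scenario, scen_seed + 3, outdir)
        if config.do_secretion:
            entry["secretion"] = _run_secretion(config, scenario, scen_seed + 4)
        report["scenarios"][name] = entry
    if config.do_lipids:
        report["lipidomics"] = _run_lipids(config, config.seed + 7)

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    lines = [f"granulekit {_VERSION}  config {report['config_hash']}  seed {config.seed}"]
    for name, entry in report["scenarios"].items():
        lines.append(f"\n[{name}]")
        for stage, vals in entry.items():
            lines.append(f"  {stage}: {vals}")
    if "lipidomics" in report:
        lines.append(f"\nlipidomics: {report['lipidomics']}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return report
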