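"""End-to-end orchestration of the analysis stages.

``run_full`` executes the complete study: simulate a labeled dataset of
averaged metapixel spectra -> stratified 70/30 split -> train the 6-layer
CNN -> integrated-gradients metapixel importance -> select the top metapixel
-> train the pruned 4-layer CNN on that metapixel alone -> evaluate both
models -> classify a simulated LED switching trajectory frame by frame.
``run_simulate`` writes time-resolved hyperspectral cubes plus the
ground-truth sidecar for the extraction stages.

Every stage is logged as one JSON line with its duration and seed, and every
artifact embeds a hash of the generating configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .barcode import build_target_barcode, double_and_randomize, save_layout
from .cube import NoiseModel, drift_path, save_cube, simulate_cube
from .datasets import (ContrastConfig, default_contrast,
                       generate_labeled_dataset, trajectory_spectra)
from .extraction import exclusion_flags
from .grid import model_grid
from .kinetics import (KineticsParams, MembraneState, SwitchProtocol,
                       default_protocol, switching_trajectory)
from .nn import (ModelSpec, TrainConfig, build_model, classify_timeseries,
                 evaluate, importance_from_model, select_top_metapixels,
                 split_dataset, train)

__all__ = ["PipelineConfig", "run_simulate", "run_full", "config_hash"]


@dataclass
class PipelineConfig:
    """Fully serializable configuration of one pipeline run."""

    experiment: str = "default"
    seed: int = 0
    n_per_class: int = 247
    n_metapixels: int = 49
    split: float = 0.7
    epochs: int = 160
    dropout: float = 0.2
    arrangement: str = "channels"
    block_px: int = 16
    lead_in_s: float = 4200.0
    n_cycles: int = 3
    additive_sigma: float = 5e-3
    drift_amplitude: float = 0.02
    drift_timescale_s: float = 600.0
    ig_steps: int = 64
    ig_items: int = 64
    out_dir: str | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def noise(self) -> NoiseModel:
        return NoiseModel(self.additive_sigma, self.drift_amplitude,
                          self.drift_timescale_s, self.seed)

    @property
    def protocol(self) -> SwitchProtocol:
        return default_protocol(lead_in_s=self.lead_in_s,
                                n_cycles=self.n_cycles)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class _StageLogger:
    def __init__(self, path: Path | None):
        self.path = path
        self.records: list[dict] = []

    def stage(self, name: str, seed: int | None = None):
        return _Stage(self, name, seed)


class _Stage:
    def __init__(self, logger: _StageLogger, name: str, seed: int | None):
        self.logger, self.name, self.seed = logger, name, seed

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        rec = {"stage": self.name, "seed": self.seed,
               "duration_s": round(time.perf_counter() - self.t0, 3),
               "ok": exc_type is None}
        if exc_type is not None:
            rec["error"] = f"{exc_type.__name__}: {exc}"
        self.logger.records.append(rec)
        if self.logger.path is not None:
            with open(self.logger.path, "a") as f:
                f.write(json.dumps(rec) + "\n")
        if exc_type is not None:
            raise RuntimeError(f"pipeline stage {self.name!r} failed") from exc
        return False


def run_simulate(config: PipelineConfig, out_dir: str | Path | None = None
                 ) -> dict:
    """Simulate a time series of hyperspectral cubes with ground truth.

    Writes one HDF5 cube per frame period (64 s of simulated time), the
    layout JSON, and a sidecar with the generating membrane-state trajectory
    and LED event log.  Idempotent for a fixed config/seed.
    """
    out = Path(out_dir or config.out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    grid = model_grid()
    barcode = build_target_barcode(config.n_metapixels)
    layout = double_and_randomize(barcode, seed=config.seed)
    protocol = config.protocol
    kinetics = KineticsParams()
    t_end = protocol.events[-1].end_s + 900.0
    times, states = switching_trajectory(protocol, kinetics,
                                         MembraneState(0.1), t_end)
    # lead-in: pure D2O for the first 11 min, then a supported bilayer forms
    # by vesicle fusion (exponential coverage ramp, complete before the
    # 14-min pre-illumination exclusion window)
    t_d2o = min(660.0, 0.15 * config.lead_in_s)
    tau = max((config.lead_in_s - t_d2o) / 6.0, 1.0)
    coverage = np.where(times < t_d2o, 0.0,
                        0.9 * (1.0 - np.exp(-(times - t_d2o) / tau)))
    states = [MembraneState(s.cis_fraction, float(c))
              for s, c in zip(states, coverage)]
    rng = np.random.default_rng(config.seed)
    drifts = drift_path(len(times), protocol.frame_period_s, config.noise, rng)
    chash = config_hash(config)
    contrast = default_contrast()
    cube_files = []
    for i, (t, state) in enumerate(zip(times, states)):
        cube = simulate_cube(layout, state, contrast.molecular, config.noise,
                             grid, rng, block_px=config.block_px,
                             drift_value=float(drifts[i]), timestamp_s=float(t))
        path = out / f"cube_{i:04d}.h5"
        save_cube(cube, path, attrs={"seed": config.seed, "config_hash": chash})
        cube_files.append(str(path))
    save_layout(layout, out / "layout.json")
    sidecar = {
        "config": config.to_dict(), "config_hash": chash,
        "times_s": [float(t) for t in times],
        "cis_fraction": [s.cis_fraction for s in states],
        "coverage": [s.coverage for s in states],
        "events": [{"led": e.led, "start_s": e.start_s,
                    "duration_s": e.duration_s} for e in protocol.events],
        "cubes": cube_files,
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
    return sidecar


def run_full(config: PipelineConfig, out_dir: str | Path | None = None
             ) -> dict:
    """Execute the full classification study; returns the result record."""
    target = out_dir or config.out_dir
    out = Path(target) if target else None
    log = _StageLogger(out / "stages.jsonl" if out else None)
    if out:
        out.mkdir(parents=True, exist_ok=True)
        if log.path is not None and log.path.exists():
            log.path.unlink()
    chash = config_hash(config)
    grid = model_grid()
    noise = config.noise
    contrast = config.extra.get("contrast") or default_contrast()
    assert isinstance(contrast, ContrastConfig)

    with log.stage("simulate", config.seed):
        ds = generate_labeled_dataset(config.n_per_class, contrast, noise,
                                      seed=config.seed, grid=grid,
                                      n_metapixels=config.n_metapixels,
                                      block_px=config.block_px)
    with log.stage("split", config.seed):
        train_set, val_set = split_dataset(ds, config.split, seed=config.seed)
    tcfg = TrainConfig(split=config.split, epochs=config.epochs,
                       dropout=config.dropout, seed=config.seed)
    with log.stage("train_original", config.seed):
        spec_o = ModelSpec("original", n_metapixels=config.n_metapixels,
                           n_wavenumbers=len(grid),
                           arrangement=config.arrangement,
                           dropout=config.dropout)
        model_o = build_model(spec_o, seed=config.seed)
        train(model_o, train_set, tcfg)
    with log.stage("evaluate_original"):
        report_o = evaluate(model_o, val_set)
    with log.stage("integrated_gradients", config.seed):
        importances = importance_from_model(model_o, val_set.X,
                                            n_steps=config.ig_steps,
                                            max_items=config.ig_items)
    with log.stage("select"):
        top = select_top_metapixels(importances, ds.nu0s, k=1)
        selected = int(top[0])
    with log.stage("train_pruned", config.seed):
        spec_p = ModelSpec("pruned", n_wavenumbers=len(grid),
                           dropout=config.dropout)
        model_p = build_model(spec_p, seed=config.seed)
        train(model_p, (train_set.X[:, [selected], :], train_set.y), tcfg)
    with log.stage("evaluate_pruned"):
        report_p = evaluate(model_p, (val_set.X[:, [selected], :], val_set.y))
    with log.stage("classify_trajectory", config.seed):
        protocol = config.protocol
        kinetics = KineticsParams()
        times, states, frames = trajectory_spectra(
            protocol, kinetics, MembraneState(0.1), contrast, noise,
            seed=config.seed, grid=grid, n_metapixels=config.n_metapixels,
            block_px=config.block_px)
        excluded = exclusion_flags(times, protocol)
        ts = classify_timeseries(model_p, frames[:, selected, :], times,
                                 excluded)
        ts["true_label"] = ["cis" if s.cis_fraction >= 0.5 else "trans"
                            for s in states]

    result = {
        "experiment": config.experiment, "seed": config.seed,
        "config_hash": chash,
        "original": report_o.to_dict(), "pruned": report_p.to_dict(),
        "selected_metapixel": selected,
        "selected_nu0": float(ds.nu0s[selected]),
        "agreement": None,
        "stages": log.records,
    }
    # prediction agreement between the two models on the validation set
    from .nn.train import _to_input
    pred_o = model_o.predict(_to_input(val_set.X, model_o))
    pred_p = model_p.predict(val_set.X[:, [selected], :])
    result["agreement"] = float(np.mean(pred_o == pred_p))

    if out:
        (out / "report.json").write_text(json.dumps(
            {k: v for k, v in result.items() if k != "stages"}, indent=1))
        pd.DataFrame({"metapixel": np.arange(len(importances)),
                      "nu0": ds.nu0s, "importance": importances}) \
            .to_csv(out / "importances.csv", index=False)
        ts.to_csv(out / "timeseries_predictions.csv", index=False)
    result["timeseries"] = ts
    result["importances"] = importances
    result["models"] = {"original": model_o, "pruned": model_p}
    result["dataset"] = ds
    return result
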