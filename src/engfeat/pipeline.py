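"""End-to-end experiment orchestration.

One config drives the whole chain: input (synthetic or a saved
recording) → bandpass → steady-state windows → one of the five feature
frameworks → OFNDA → stratified 10-fold LDA, with CSV outputs and a
machine-readable manifest that reproduces the run exactly.  The single
config seed fans out to per-stage seeds through a SeedSequence spawn so
stages can be rerun independently yet deterministically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features_td import (FeatureMatrix, TDDConfig, run_mav_framework,
                          run_mav_wl_framework, run_tdd_framework,
                          run_tsd_framework)
from .preprocess import WindowSpec, apply_filter, design_bandpass, windows_from_recording
from .reduce_classify import (compare_window_sizes, export_scatter, lda_crossval,
                              ofnda_fit, ofnda_transform, summarize_accuracy,
                              time_framework)
from .signal_io import Recording, load_recording
from .stw import STWConfig, run_stw_framework
from .synthdata import ProtocolConfig, SignalModelConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "FRAMEWORKS", "extract_features",
           "run_experiment", "run_window_sweep", "run_timing_sweep"]

FRAMEWORKS = ("mav", "mav_wl", "tdd", "tsd", "stw")

#: window-length sweep grid (ms)
SWEEP_SIZES_MS = tuple(range(50, 351, 25))


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    framework: str = "stw"
    input_path: str | None = None            # saved recording; None -> synth
    synth_protocol: dict = field(default_factory=dict)
    synth_signal: dict = field(default_factory=dict)
    window_ms: float = 175.0
    overlap_pct: float = 20.0
    trim_s: float = 0.25
    filter_low_hz: float = 800.0
    filter_high_hz: float = 2200.0
    filter_order: int | None = None          # None -> scaled to fs
    ofnda_dim: int = 6
    ofnda_k: int = 5
    cv_folds: int = 10
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        if self.framework not in FRAMEWORKS:
            raise ValueError(
                f"unknown framework {self.framework!r}; valid: {', '.join(FRAMEWORKS)}"
            )

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def stage_seed(self, stage: str) -> int:
        """Derived per-stage seed: stable fan-out from the config seed."""
        order = ("synth", "cv", "shuffle", "timing")
        children = np.random.SeedSequence(self.seed).spawn(len(order))
        return int(children[order.index(stage)].generate_state(1)[0] % (2 ** 31))


def _load_input(cfg: ExperimentConfig) -> Recording:
    if cfg.input_path is not None:
        return load_recording(cfg.input_path)
    pc = ProtocolConfig(**{"seed": cfg.stage_seed("synth"), **cfg.synth_protocol})
    sm = SignalModelConfig(**{"seed": cfg.stage_seed("synth") + 1, **cfg.synth_signal})
    return generate_dataset(pc, sm)


def extract_features(rec: Recording, framework: str,
                     spec: WindowSpec, trim_s: float = 0.25,
                     filter_low_hz: float = 800.0, filter_high_hz: float = 2200.0,
                     filter_order: int | None = None) -> FeatureMatrix:
    """Bandpass, window and featurize a recording with one framework."""
    if filter_order is None:
        filter_order = max(20, int(round(600 * rec.fs / 30000.0)))
    taps = design_bandpass(rec.fs, filter_low_hz, filter_high_hz, filter_order)
    t0 = time.perf_counter()
    filtered = apply_filter(rec, taps)
    logger.info("filter: %d ch x %d samples in %.2fs", rec.n_channels,
                rec.n_samples, time.perf_counter() - t0)
    ws = windows_from_recording(filtered, spec, trim_s=trim_s)
    logger.info("windows: %d of %d samples", len(ws),
                spec.window_samples(rec.fs))
    t0 = time.perf_counter()
    if framework == "mav":
        fm = run_mav_framework(ws)
    elif framework == "mav_wl":
        fm = run_mav_wl_framework(ws)
    elif framework == "tdd":
        fm = run_tdd_framework(ws, TDDConfig())
    elif framework == "tsd":
        fm = run_tsd_framework(ws, TDDConfig())
    elif framework == "stw":
        fm = run_stw_framework(ws, STWConfig())
    else:
        raise ValueError(
            f"unknown framework {framework!r}; valid: {', '.join(FRAMEWORKS)}"
        )
    logger.info("features: %d x %d (%s) in %.2fs", fm.n_instances, fm.n_features,
                framework, time.perf_counter() - t0)
    return fm


def run_experiment(cfg: ExperimentConfig, rec: Recording | None = None) -> dict:
    """Run one full experiment and write its artifacts.

    Writes ``features.csv``, ``fold_accuracies.csv``, ``confusion.csv``,
    ``scatter.csv`` (first two reduced dimensions) and ``manifest.json``
    into ``cfg.out_dir``.  Returns the in-memory results bundle.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if rec is None:
        rec = _load_input(cfg)
    spec = WindowSpec(length_s=cfg.window_ms / 1000.0,
                      overlap_frac=cfg.overlap_pct / 100.0)
    fm = extract_features(rec, cfg.framework, spec, trim_s=cfg.trim_s,
                          filter_low_hz=cfg.filter_low_hz,
                          filter_high_hz=cfg.filter_high_hz,
                          filter_order=cfg.filter_order)
    model = ofnda_fit(fm, target_dim=cfg.ofnda_dim, k_neighbors=cfg.ofnda_k)
    reduced = ofnda_transform(model, fm)
    cv = lda_crossval(reduced, folds=cfg.cv_folds, seed=cfg.stage_seed("cv"))
    logger.info("cv: overall accuracy %.3f", cv.accuracy)

    fm.to_csv(out / "features.csv")
    pd.DataFrame({"fold": np.arange(cfg.cv_folds),
                  "accuracy": cv.fold_accuracies}).to_csv(
        out / "fold_accuracies.csv", index=False)
    pd.DataFrame(cv.confusion,
                 index=[str(c) for c in cv.class_set],
                 columns=[str(c) for c in cv.class_set]).to_csv(out / "confusion.csv")
    if reduced.n_features >= 2:
        export_scatter(reduced, out / "scatter.csv")
    manifest = {"config": asdict(cfg), "package_version": __version__,
                "n_instances": fm.n_instances, "n_features": fm.n_features,
                "overall_accuracy": cv.accuracy}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"features": fm, "reduced": reduced, "cv": cv,
            "summary": summarize_accuracy(cv.fold_accuracies),
            "manifest": manifest}


def run_window_sweep(cfg: ExperimentConfig, sizes_ms=SWEEP_SIZES_MS,
                     rec: Recording | None = None) -> dict:
    """Repeat the experiment across window lengths and compare accuracies.

    Returns per-size fold-accuracy arrays plus the Kruskal–Wallis /
    Bonferroni pairwise table; also written as CSV under ``cfg.out_dir``.
    """
    sizes_ms = list(sizes_ms)
    if len(sizes_ms) < 2:
        raise ValueError("need at least 2 window sizes to compare")
    if rec is None:
        rec = _load_input(cfg)
    groups: dict[float, np.ndarray] = {}
    for size in sizes_ms:
        sub = ExperimentConfig(**{**asdict(cfg), "window_ms": size,
                                  "out_dir": str(Path(cfg.out_dir) / f"w{int(size)}ms")})
        groups[size] = run_experiment(sub, rec=rec)["cv"].fold_accuracies
    table = compare_window_sizes(groups)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "window_comparison.csv", index=False)
    pd.DataFrame(groups).to_csv(out / "window_accuracies.csv", index=False)
    return {"accuracies": groups, "comparison": table}


def run_timing_sweep(frameworks=FRAMEWORKS, sizes_ms=(50, 175, 350),
                     channel_counts=(3, 10, 16), fs: float = 30000.0,
                     repeats: int = 1000, seed: int = 0,
                     out_path=None) -> pd.DataFrame:
    """Mean per-window extraction time over a (framework, size, NC) grid."""
    rows = []
    for fw in frameworks:
        for size in sizes_ms:
            for nc in channel_counts:
                t = time_framework(fw, size, nc, fs, repeats=repeats, seed=seed)
                rows.append({"framework": fw, "window_ms": size,
                             "n_channels": nc, "mean_seconds": t})
                logger.info("timing %s w=%sms nc=%d: %.3g s", fw, size, nc, t)
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df
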