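"""Pipeline orchestration: staged runs, demo fixture, and run manifests.

A run is described by a single YAML-serializable config with one section
per stage (simulate, degrade, train, enhance, evaluate, reliability).  All
randomness derives from the global seed; a manifest recording the resolved
config, seeds and SHA-256 checksums of every output file makes runs
byte-reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core_io import Axis, Spectrum2D, write_spectrum
from .degrade import DegradeConfig, degrade
from .evaluate import form_pairs, pick_peaks, records_to_frame, reliability, score_pairs, summarize
from .model import GeneratorConfig, LossWeights, enhance, save_checkpoint, train
from .simulate import MixtureConfig, build_dataset, default_library, scaled_linewidths

__all__ = ["RunConfig", "run_pipeline", "demo_fixture", "DEMO_F1_POINTS", "DEMO_F2_POINTS"]

DEMO_F1_POINTS = 64
DEMO_F2_POINTS = 1024


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults give the desk-scale demo run."""

    seed: int = 0
    outdir: str = "runs/demo"
    stages: tuple[str, ...] = ("simulate", "degrade", "train", "enhance", "evaluate")
    # simulate
    metabolite_counts: tuple[int, ...] = (6, 8, 15, 34, 40)
    spectra_per_type: int = 4
    n_metabolites: int = 40
    f1_points: int = DEMO_F1_POINTS
    f2_points: int = DEMO_F2_POINTS
    # degrade
    kernel: tuple[int, int] = (5, 7)
    sigma: tuple[float, float] | None = None
    factor: int = 2
    # train
    iterations: int = 200
    learning_rate: float = 4e-3
    batch_size: int = 16
    patch_size: int = 48
    n_blocks: int = 3
    n_features: int = 24
    w_pixel: float = 1.0
    w_perceptual: float = 0.0
    w_gan: float = 0.0
    w_symmetric: float = 0.1
    # evaluate
    test_counts: tuple[int, ...] = (1, 3, 6, 9, 12, 15)
    test_spectra_per_type: int = 3
    peak_threshold: float = 0.01
    k_nearest: int = 3
    max_pair_distance: float = 30.0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            doc = yaml.safe_load(f) or {}
        valid = set(cls.__dataclass_fields__)
        unknown = set(doc) - valid
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("metabolite_counts", "test_counts", "stages", "kernel"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def validate(self) -> None:
        known = {"simulate", "degrade", "train", "enhance", "evaluate", "reliability"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if self.f1_points % 2 or self.f2_points % 2:
            raise ValueError("grid dimensions must be even")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _axes(cfg: RunConfig) -> tuple[Axis, Axis]:
    from .core_io import default_f1_axis, default_f2_axis

    return default_f1_axis(cfg.f1_points), default_f2_axis(cfg.f2_points)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in cfg.__dict__.items()},
        "seed": cfg.seed,
        "files": {},
    }
    f1_axis, f2_axis = _axes(cfg)
    dcfg = DegradeConfig(cfg.kernel[0], cfg.kernel[1],
                         None if cfg.sigma is None else cfg.sigma[0],
                         None if cfg.sigma is None else cfg.sigma[1],
                         cfg.factor)
    lw1, lw2 = scaled_linewidths(cfg.f1_points, cfg.f2_points)
    library = default_library(cfg.n_metabolites, lw_f1=lw1, lw_f2=lw2)
    hr_specs: list[Spectrum2D] = []
    lr_specs: list[Spectrum2D] = []
    state = None

    def record(path: str) -> None:
        manifest["files"][os.path.relpath(path, cfg.outdir)] = _sha256(path)

    for stage in cfg.stages:
        try:
            if stage == "simulate":
                mix = MixtureConfig(cfg.metabolite_counts, cfg.spectra_per_type,
                                    f1_axis, f2_axis, seed=cfg.seed)
                hr_specs = build_dataset(mix, library)
                for i, spec in enumerate(hr_specs):
                    path = os.path.join(cfg.outdir, f"hr_{i:04d}.h5")
                    write_spectrum(spec, path)
                    record(path)
            elif stage == "degrade":
                lr_specs = [degrade(s, dcfg) for s in hr_specs]
                for i, spec in enumerate(lr_specs):
                    path = os.path.join(cfg.outdir, f"lr_{i:04d}.h5")
                    write_spectrum(spec, path)
                    record(path)
            elif stage == "train":
                state = train(
                    hr_specs,
                    GeneratorConfig(2, cfg.n_blocks, cfg.n_features, seed=cfg.seed),
                    LossWeights(cfg.w_pixel, cfg.w_perceptual, cfg.w_gan, cfg.w_symmetric),
                    cfg.iterations,
                    np.random.default_rng(cfg.seed),
                    learning_rate=cfg.learning_rate,
                    batch_size=cfg.batch_size,
                    patch_size=cfg.patch_size,
                    degrade_cfg=dcfg,
                )
                ckpt = os.path.join(cfg.outdir, "checkpoint.npz")
                save_checkpoint(state, ckpt)
                record(ckpt)
                log = os.path.join(cfg.outdir, "train_log.csv")
                import pandas as pd

                pd.DataFrame(state.history).to_csv(log, index=False)
                record(log)
            elif stage in ("enhance", "evaluate", "reliability"):
                if state is None:
                    raise ValueError(f"stage {stage!r} requires a trained model")
                test_rng = np.random.default_rng(cfg.seed + 1)
                mix = MixtureConfig(cfg.test_counts, cfg.test_spectra_per_type,
                                    f1_axis, f2_axis, seed=cfg.seed + 1)
                test_hr = build_dataset(mix, library)
                summaries = []
                for i, hr in enumerate(test_hr):
                    lr = degrade(hr, dcfg)
                    sr = enhance(lr, state)
                    if stage == "enhance":
                        path = os.path.join(cfg.outdir, f"sr_{i:04d}.h5")
                        write_spectrum(sr, path)
                        record(path)
                        continue
                    if stage == "reliability":
                        tbl = reliability(lr, sr, hr)
                        path = os.path.join(cfg.outdir, f"reliability_{i:04d}.csv")
                        tbl.to_csv(path, index=False)
                        record(path)
                        continue
                    pairs = form_pairs(pick_peaks(hr, cfg.peak_threshold),
                                       cfg.k_nearest, cfg.max_pair_distance)
                    if len(pairs) < 2:
                        continue
                    recs = score_pairs(hr, lr, sr, pairs)
                    frame = records_to_frame(recs)
                    path = os.path.join(cfg.outdir, f"scores_{i:04d}.csv")
                    frame.to_csv(path, index=False)
                    record(path)
                    summaries.append(summarize(recs))
                if stage == "evaluate" and summaries:
                    path = os.path.join(cfg.outdir, "summary.json")
                    with open(path, "w") as f:
                        json.dump(summaries, f, indent=2)
                    record(path)
                del test_rng
            else:  # pragma: no cover - validate() rejects unknown stages
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = os.path.join(cfg.outdir, "manifest.json")
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest


def toy_benchmark(seed: int = 0, iterations: int = 200,
                  test_spectra_per_type: int = 3) -> dict:
    """Desk-scale end-to-end benchmark: train on the demo fixture, score a
    held-out plasma-style test set.

    Trains the x2 generator for ``iterations`` Adam steps on the seeded
    20-spectrum demo fixture, then simulates a held-out set
    (``test_spectra_per_type`` spectra for each of the six plasma-style
    mixture sizes 1/3/6/9/12/15), degrades each, super-resolves the LR, and
    pools the per-pair resolvability records across spectra.  Returns the
    pooled summary plus the trained state under ``"state"``.
    """
    hr_specs, _ = demo_fixture(seed)
    state = train(
        hr_specs,
        GeneratorConfig(2, 3, 24, seed=seed),
        LossWeights(w_pixel=1.0, w_perceptual=0.0, w_gan=0.0, w_symmetric=0.1),
        iterations=iterations,
        rng=np.random.default_rng(seed),
        learning_rate=4e-3,
        batch_size=16,
        patch_size=48,
        peak_threshold=0.01,
        patches_per_spectrum=60,
    )
    from .core_io import default_f1_axis, default_f2_axis

    f1_axis = default_f1_axis(DEMO_F1_POINTS)
    f2_axis = default_f2_axis(DEMO_F2_POINTS)
    lw1, lw2 = scaled_linewidths(DEMO_F1_POINTS, DEMO_F2_POINTS)
    library = default_library(40, lw_f1=lw1, lw_f2=lw2)
    mix = MixtureConfig((1, 3, 6, 9, 12, 15), test_spectra_per_type,
                        f1_axis, f2_axis, seed=seed + 1000)
    pooled = []
    for hr in build_dataset(mix, library):
        lr = degrade(hr)
        sr = enhance(lr, state)
        pairs = form_pairs(pick_peaks(hr, 0.01), 3, 30.0)
        if len(pairs) < 2:
            continue
        pooled.extend(score_pairs(hr, lr, sr, pairs))
    summary = summarize(pooled)
    summary["state"] = state
    return summary


def demo_fixture(seed: int = 0, outdir: str | None = None
                 ) -> tuple[list[Spectrum2D], list[Spectrum2D]]:
    """Seeded 20-spectrum paired HR/LR fixture on a 64 x 1024 grid.

    Four spectra for each of the five training mixture sizes; completes in
    well under a minute on one CPU.  Used by the tests and documentation.
    """
    from .core_io import default_f1_axis, default_f2_axis

    f1_axis = default_f1_axis(DEMO_F1_POINTS)
    f2_axis = default_f2_axis(DEMO_F2_POINTS)
    lw1, lw2 = scaled_linewidths(DEMO_F1_POINTS, DEMO_F2_POINTS)
    library = default_library(40, lw_f1=lw1, lw_f2=lw2)
    mix = MixtureConfig((6, 8, 15, 34, 40), 4, f1_axis, f2_axis, seed=seed)
    hr = build_dataset(mix, library)
    lr = [degrade(s) for s in hr]
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        for i, (a, b) in enumerate(zip(hr, lr)):
            write_spectrum(a, os.path.join(outdir, f"hr_{i:04d}.h5"))
            write_spectrum(b, os.path.join(outdir, f"lr_{i:04d}.h5"))
    return hr, lr
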