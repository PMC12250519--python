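"""End-to-end pipeline driver: denoise -> preprocess -> (train | load) ->
segment -> evaluate -> volumetry, with a manifest tying every output to the
configuration hash that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .denoise import Bm3dConfig, denoise_stack
from .io import (ImageStack, MaskStack, preprocess_geometry,
                 read_image_stack, read_mask_stack, write_mask_stack)
from .metrics import pooled_confusion, report_from_confusion
from .phantom import PhantomSpec, benchmark_set, generate
from .train import TrainConfig, UNetSegmenter, load_checkpoint, split_dataset
from .volumetry import VoxelGeometry, damage_volume, healing_table

log = logging.getLogger("octseg.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat composition of every stage's configuration."""

    # I/O; when images_dir is None a seeded phantom benchmark is generated
    images_dir: str | None = None
    masks_dir: str | None = None
    out_dir: str = "octseg_run"
    checkpoint: str | None = None      # load instead of training

    denoise: bool = True
    bm3d: Bm3dConfig = field(default_factory=Bm3dConfig)
    preprocess: bool = False           # 460->512 geometry (native-size inputs
    resize_to: tuple = (460, 460)      # skip it for already-divisible sizes)
    pad_to: tuple = (512, 512)

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_phantoms: int = 12

    variant: str = "parallel"
    base_width: int = 16
    depth: int = 3
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        lr=1e-3, epochs=30))
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    dose: float = 0.0
    timepoint: str = "t0"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_or_simulate(cfg: PipelineConfig):
    if cfg.images_dir is not None:
        images = read_image_stack(cfg.images_dir)
        masks = read_mask_stack(cfg.masks_dir) if cfg.masks_dir else None
        return images, masks
    pairs = benchmark_set(cfg.n_phantoms, cfg.phantom, seed=cfg.seed)
    images = ImageStack([p.images.slices[0] for p in pairs])
    masks = MaskStack([p.truth.slices[0] for p in pairs])
    return images, masks


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns paths and in-memory results."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    stage = "load"
    try:
        images, truth = _load_or_simulate(cfg)

        stage = "denoise"
        if cfg.denoise:
            images = denoise_stack(images, cfg.bm3d)

        stage = "preprocess"
        if cfg.preprocess:
            images = ImageStack([
                preprocess_geometry(s, cfg.resize_to, cfg.pad_to)
                for s in images])

        stage = "train"
        if cfg.checkpoint:
            model, mcfg = load_checkpoint(cfg.checkpoint)
            est = UNetSegmenter(variant=cfg.variant,
                                base_width=mcfg.base_width, depth=mcfg.depth)
            est.model_ = model
            est.model_config_ = mcfg
            est.depth = mcfg.depth
        else:
            if truth is None:
                raise ValueError("training requires ground-truth masks "
                                 "(or pass a checkpoint)")
            items = list(range(len(images)))
            tr, va, _ = split_dataset(items, cfg.train.split_ratios,
                                      cfg.train.seed)
            arr = images.as_array()
            lab = truth.as_array()
            est = UNetSegmenter(
                variant=cfg.variant, base_width=cfg.base_width,
                depth=cfg.depth, lr=cfg.train.lr,
                weight_decay=cfg.train.weight_decay,
                lr_period=cfg.train.lr_period, epochs=cfg.train.epochs,
                batch_size=cfg.train.batch_size,
                class_weights=cfg.train.class_weights,
                grad_clip_max_norm=cfg.train.grad_clip_max_norm,
                seed=cfg.seed)
            est.fit(arr[tr], lab[tr], validation_data=(arr[va], lab[va]))
            hist_path = out / "history.csv"
            est.history_.to_frame().to_csv(hist_path, index=False)
            outputs.append(hist_path.name)

        stage = "segment"
        pred = est.predict_stack(images)
        write_mask_stack(pred, out / "masks")
        outputs.append("masks/")

        stage = "evaluate"
        report = None
        if truth is not None:
            cm = pooled_confusion(pred, truth)
            report = report_from_confusion(cm)
            rep_path = out / "report.csv"
            pd.DataFrame([report.as_dict()]).to_csv(
                rep_path, index=False, float_format="%.4g")
            outputs.append(rep_path.name)
        else:
            log.info("no ground truth supplied; evaluation skipped")

        stage = "volume"
        vol = damage_volume(pred, cfg.geometry,
                            meta={"dose": cfg.dose,
                                  "timepoint": cfg.timepoint})
        table = healing_table([vol])
        vol_path = out / "volumes.csv"
        table.to_csv(vol_path, index=False)
        outputs.append(vol_path.name)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"report": report, "volumes": table, "pred": pred,
            "manifest": manifest, "out_dir": str(out)}
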