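"""End-to-end orchestration: the two-stage pipeline and the ablation grid.

``run_pipeline`` goes simulate -> train Stage 1 -> restore -> train Stage 2
-> evaluate, with every random draw fanned out from one root seed, so a
repeated run reproduces its reports bitwise.  ``run_ablation`` trains the
architectural variants (pressure stream only / + mask stream and
cross-attention / + pyramidal pooling) over a shared seed set and tabulates
restoration and pose errors per variant.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeding import spawn_seed
from .denoiser import DDSEModel, restoration_mse, reverse_denoise, train_stage1
from .io import RunConfig, config_hash, validate_ablation
from .metrics import mpjpe, pose_report, restoration_report
from .posenet import PoseNetConfig, mean_pose, train_stage2
from .synthetic import desk_config, make_dataset

log = logging.getLogger("tacpose")


@dataclass
class ExperimentRecord:
    config_hash: str
    version: str
    reports: dict
    checkpoints: dict = field(default_factory=dict)


def desk_run_config(seed: int = 0) -> RunConfig:
    """The desk-scale preset used by the examples and the test suite:
    a 64 x 40 raster of the two-module mat patch, a 10-step schedule and
    small networks that train in seconds on a laptop CPU."""
    from .cda import CDAConfig
    from .denoiser import Stage1TrainConfig, UNetConfig
    from .io import DataConfig, ScheduleConfig
    from .posenet import Stage2TrainConfig

    from .mask import MaskParams

    return RunConfig(
        scene=desk_config(seed=seed),
        schedule=ScheduleConfig(D=10, alpha_end=0.99),
        mask=MaskParams(threshold=3.0),
        unet=UNetConfig(depth=2, base_channels=8,
                        cda=CDAConfig(channels=8, n_heads=2, pool_size=4)),
        posenet=PoseNetConfig(patch_size=8, d_model=32, n_layers=1, n_heads=4,
                              decoder_blocks=1, frame_h=64, frame_w=40),
        train1=Stage1TrainConfig(epochs=5, batch=8),
        train2=Stage2TrainConfig(epochs=15, batch=32),
        data=dataclasses.replace(DataConfig(), n_frames=160, body_scale=0.45),
        seed=seed,
    )


def _simulate(cfg: RunConfig):
    scene = dataclasses.replace(cfg.scene, seed=spawn_seed(cfg.seed, "data"))
    return make_dataset(
        cfg.data.n_frames, scene, cfg.data.build_body(),
        split=cfg.data.split, activities=cfg.data.activities,
        holdout=cfg.data.holdout,
    )


def run_pipeline(cfg: RunConfig, out_dir=None) -> ExperimentRecord:
    """Full two-stage run; returns a record with restoration and pose reports.

    Stage 2 is trained on the frames restored by the trained Stage 1 and
    evaluated on the activity-disjoint validation split.
    """
    from . import __version__

    sched = cfg.schedule.build()
    scenes, split = _simulate(cfg)
    train_sc = [scenes[i] for i in split["train"]]
    test_sc = [scenes[i] for i in split["test"]]
    val_sc = [scenes[i] for i in split["val"]]
    log.info("pipeline %s: %d train / %d test / %d val frames",
             config_hash(cfg), len(train_sc), len(test_sc), len(val_sc))

    t1 = dataclasses.replace(cfg.train1, seed=spawn_seed(cfg.seed, "stage1"))
    model1, hist1 = train_stage1(
        train_sc, sched, cfg.mask, cfg.unet, t1,
        use_mask_stream=cfg.use_mask_stream, use_pp=cfg.use_pp,
        pressure_scale=cfg.scene.max_pressure,
    )

    def restore_all(scs, tag):
        return [
            reverse_denoise(sc.noisy, sched, cfg.mask, model1,
                            rng_seed=spawn_seed(cfg.seed, "restore", tag, i))
            for i, sc in enumerate(scs)
        ]

    restored_test = restore_all(test_sc, "test")
    rep_restored = restoration_report(restored_test, [s.clean for s in test_sc],
                                      max_i=cfg.scene.max_pressure)
    rep_noisy = restoration_report([s.noisy for s in test_sc],
                                   [s.clean for s in test_sc],
                                   max_i=cfg.scene.max_pressure)

    restored_train = restore_all(train_sc, "train")
    restored_val = restore_all(val_sc, "val")
    t2 = dataclasses.replace(cfg.train2, seed=spawn_seed(cfg.seed, "stage2"))
    model2, hist2 = train_stage2(
        np.stack(restored_train), np.stack([s.pose for s in train_sc]),
        cfg.posenet, t2,
    )
    pred_val = model2.predict_mm(np.stack(restored_val))
    gt_val = np.stack([s.pose for s in val_sc])
    rep_pose = pose_report(pred_val, gt_val)
    base = mean_pose(np.stack([s.pose for s in train_sc]))
    base_mpjpe = mpjpe(np.broadcast_to(base, gt_val.shape), gt_val)

    reports = {
        "restoration": {
            "noisy": rep_noisy.as_dict(),
            "restored": rep_restored.as_dict(),
            "stage1_loss_history": hist1,
        },
        "pose": {
            **rep_pose.as_dict(),
            "mean_pose_baseline_mpjpe_mm": base_mpjpe,
            "stage2_loss_history": hist2,
        },
    }
    record = ExperimentRecord(config_hash=config_hash(cfg), version=__version__,
                              reports=reports)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        model1.save(out_dir / "stage1.npz")
        model2.save(out_dir / "stage2.npz")
        record.checkpoints = {"stage1": str(out_dir / "stage1.npz"),
                              "stage2": str(out_dir / "stage2.npz")}
        import json

        (out_dir / "reports.json").write_text(json.dumps(reports, indent=1))
    return record


PAPER_VARIANTS: tuple[tuple[str, ...], ...] = (
    ("PSFD",),
    ("PSFD", "RMFD", "CA"),
    ("PSFD", "RMFD", "CA", "PP"),
)


def run_ablation(
    cfg: RunConfig,
    variants: Sequence[Sequence[str]] = PAPER_VARIANTS,
    seeds: Sequence[int] = (0, 1, 2),
    with_stage2: bool = False,
    n_val_frames: int | None = 24,
) -> pd.DataFrame:
    """Train each architecture variant per seed and tabulate validation
    errors (restoration MSE always; pose MPJPE when ``with_stage2``).

    Emits one row per (variant, seed); a soft ordering check — the full
    model should not be worse than the pressure-only variant in median —
    is logged, not asserted.
    """
    sched = cfg.schedule.build()
    scenes, split = _simulate(cfg)
    train_sc = [scenes[i] for i in split["train"]]
    val_sc = [scenes[i] for i in split["val"]]
    if n_val_frames is not None:
        val_sc = val_sc[:n_val_frames]
    rows = []
    for flags in variants:
        flags = validate_ablation(flags)
        name = "+".join(flags)
        for seed in seeds:
            t1 = dataclasses.replace(cfg.train1, seed=spawn_seed(cfg.seed, "abl", name, seed))
            try:
                model1, _ = train_stage1(
                    train_sc, sched, cfg.mask, cfg.unet, t1,
                    use_mask_stream="RMFD" in flags, use_pp="PP" in flags,
                    pressure_scale=cfg.scene.max_pressure,
                )
            except RuntimeError as e:  # pragma: no cover - defensive
                log.error("variant %s seed %d failed to train: %s", name, seed, e)
                rows.append({"variant": name, "seed": seed, "val_mse": np.nan,
                             "mpjpe_mm": np.nan})
                continue
            row = {"variant": name, "seed": seed,
                   "val_mse": restoration_mse(model1, val_sc, sched, cfg.mask,
                                              rng_seed=spawn_seed(cfg.seed, "ablval", seed))}
            if with_stage2:
                restored = [
                    reverse_denoise(sc.noisy, sched, cfg.mask, model1,
                                    rng_seed=spawn_seed(cfg.seed, "ablr", name, seed, i))
                    for i, sc in enumerate(train_sc)
                ]
                restored_val = [
                    reverse_denoise(sc.noisy, sched, cfg.mask, model1,
                                    rng_seed=spawn_seed(cfg.seed, "ablrv", name, seed, i))
                    for i, sc in enumerate(val_sc)
                ]
                t2 = dataclasses.replace(cfg.train2, seed=spawn_seed(cfg.seed, "abl2", name, seed))
                model2, _ = train_stage2(
                    np.stack(restored), np.stack([s.pose for s in train_sc]),
                    cfg.posenet, t2,
                )
                pred = model2.predict_mm(np.stack(restored_val))
                row["mpjpe_mm"] = mpjpe(pred, np.stack([s.pose for s in val_sc]))
            rows.append(row)
    df = pd.DataFrame(rows)
    med = df.groupby("variant")["val_mse"].median()
    full = "+".join(PAPER_VARIANTS[-1])
    only = "+".join(PAPER_VARIANTS[0])
    if full in med.index and only in med.index and med[full] > med[only]:
        log.warning("ablation ordering check: full model (%.4g) worse than "
                    "pressure-only (%.4g) in median val MSE", med[full], med[only])
    return df
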