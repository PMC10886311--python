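"""End-to-end workflow orchestration with config files and fixed seeds.

A run is a sequence of stages (``phantom``, ``preprocess``, ``synth``,
``train``, ``upscale``, ``evaluate``) driven by one :class:`RunConfig`.
Each stage derives its own seed deterministically from the master seed and
its name, writes self-describing outputs into the run directory, and the
final report records the fully resolved configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import metrics, phantom, preprocess, semisynth, srnet, vector_eval

logger = logging.getLogger("vascusr")

KNOWN_STAGES = ("phantom", "preprocess", "synth", "train", "upscale", "evaluate")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: sha256(master || stage) mod 2**31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclasses.dataclass
class RunConfig:
    """Stage list plus per-stage option dictionaries."""

    stages: list[str]
    out_dir: str
    master_seed: int = 0
    log_level: str = "INFO"
    options: dict[str, dict[str, Any]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in KNOWN_STAGES:
                raise ValueError(
                    f"unknown stage {s!r}; expected one of {KNOWN_STAGES}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        stages = raw.pop("stages")
        out_dir = raw.pop("out_dir")
        master_seed = raw.pop("master_seed", 0)
        log_level = raw.pop("log_level", "INFO")
        return cls(
            stages=stages,
            out_dir=out_dir,
            master_seed=master_seed,
            log_level=log_level,
            options=raw,
        )

    def stage_options(self, stage: str) -> dict[str, Any]:
        return dict(self.options.get(stage, {}))


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the configured stages in order and write a run report.

    Re-running with an identical config reproduces the metric tables (all
    randomness flows from the master seed through :func:`stage_seed`).
    Stage failures abort with a stage-tagged error after writing a partial
    manifest.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    ctx: dict[str, Any] = {}
    report: dict[str, Any] = {
        "config": _resolved_config(cfg),
        "stages_completed": [],
    }
    logger.info("resolved config: %s", json.dumps(report["config"], default=str))
    for stage in cfg.stages:
        try:
            _STAGE_FNS[stage](cfg, ctx, report, out_dir)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage tag
            report["failed_stage"] = stage
            report["error"] = str(exc)
            (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        report["stages_completed"].append(stage)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _resolved_config(cfg: RunConfig) -> dict[str, Any]:
    return {
        "stages": cfg.stages,
        "out_dir": str(cfg.out_dir),
        "master_seed": cfg.master_seed,
        "log_level": cfg.log_level,
        "stage_seeds": {s: stage_seed(cfg.master_seed, s) for s in cfg.stages},
        "options": cfg.options,
    }


# --- stages ------------------------------------------------------------------


def _stage_phantom(cfg, ctx, report, out_dir):
    opts = cfg.stage_options("phantom")
    n_volumes = int(opts.pop("n_volumes", 1))
    pcfg = phantom.PhantomConfig(
        seed=stage_seed(cfg.master_seed, "phantom"), **_phantom_kwargs(opts)
    )
    volumes = phantom.make_phantom_dataset(pcfg, n_volumes, out_dir / "phantom")
    ctx["volumes"] = volumes
    ctx["hr_frames"] = [
        f for vol in volumes for f in vol.image.astype_float()
    ]
    ctx["hr_stack_ids"] = [
        f"phantom{i}" for i, vol in enumerate(volumes) for _ in range(vol.image.n_frames)
    ]
    report["phantom"] = {
        "n_volumes": n_volumes,
        "frames": len(ctx["hr_frames"]),
        "foreground_fractions": [float(v.truth_mask.mean()) for v in volumes],
    }


def _phantom_kwargs(opts: dict) -> dict:
    out = dict(opts)
    for key in ("volume_shape", "spacing_um", "psf_sigma_um", "radius_range_um"):
        if key in out:
            out[key] = tuple(out[key])
    return out


def _stage_preprocess(cfg, ctx, report, out_dir):
    opts = cfg.stage_options("preprocess")
    paths = opts.get("inputs", [])
    if not paths:
        raise ValueError("preprocess stage needs 'inputs': list of TIFF paths")
    stage_dir = out_dir / "preprocessed"
    stage_dir.mkdir(exist_ok=True)
    frames, stack_ids = [], []
    for p in paths:
        stack = preprocess.read_stack(p, spacing_um=opts.get("spacing_um"))
        proc = preprocess.preprocess_stack(
            stack,
            median_radius=tuple(opts.get("median_radius", (1, 1, 1))),
            saturation_frac=opts.get("saturation_frac", 0.003),
        )
        preprocess.write_stack(proc, stage_dir / Path(p).name)
        frames.extend(proc.astype_float())
        stack_ids.extend([Path(p).stem] * proc.n_frames)
    ctx["hr_frames"] = frames
    ctx["hr_stack_ids"] = stack_ids
    report["preprocess"] = {"inputs": [str(p) for p in paths], "frames": len(frames)}


def _stage_synth(cfg, ctx, report, out_dir):
    opts = cfg.stage_options("synth")
    if "hr_frames" not in ctx:
        raise ValueError("synth stage needs HR frames from phantom/preprocess")
    noise = semisynth.NoiseConfig(
        kind=opts.get("noise", "additive_gaussian"),
        mu=opts.get("mu", 0.0),
        sigma=opts.get("sigma", 5.0),
        local_var_scale=opts.get("local_var_scale", 0.001),
        seed=stage_seed(cfg.master_seed, "synth"),
    )
    factor = int(opts.get("factor", 4))
    samples = []
    frames, ids = ctx["hr_frames"], ctx["hr_stack_ids"]
    for stack_id in dict.fromkeys(ids):  # preserves order
        sub = [f for f, sid in zip(frames, ids) if sid == stack_id]
        samples.extend(
            semisynth.make_single_frame_dataset(
                sub, noise, factor=factor, stack_id=stack_id
            )
        )
    window = opts.get("window")
    if window:
        samples = semisynth.make_multiframe_dataset(samples, window=int(window))
    ctx["samples"] = samples
    ctx["scale"] = factor
    report["synth"] = {"n_samples": len(samples), "noise": noise.kind}


def _stage_train(cfg, ctx, report, out_dir):
    opts = cfg.stage_options("train")
    if "samples" not in ctx:
        raise ValueError("train stage needs samples from synth")
    samples = ctx["samples"]
    in_frames = samples[0].n_input_frames
    est = srnet.ResUNetUpscaler(
        in_frames=in_frames,
        scale=ctx.get("scale", 4),
        encoder_depth=int(opts.get("encoder_depth", 4)),
        base_channels=int(opts.get("base_channels", 32)),
        learning_rate=opts.get("learning_rate"),
        epochs=int(opts.get("epochs", 5)),
        batch_size=int(opts.get("batch_size", 8)),
        seed=stage_seed(cfg.master_seed, "train"),
    )
    X = np.stack([s.lr_input for s in samples])
    y = np.stack([s.hr_target for s in samples])
    est.fit(X, y)
    ckpt = out_dir / "model.npz"
    srnet.save_checkpoint(est, ckpt)
    ctx["model"] = est
    report["train"] = {
        "checkpoint": str(ckpt),
        "epochs": est.epochs,
        "best_val_loss": est.best_val_loss_,
        "loss_history": est.loss_history_,
    }


def _stage_upscale(cfg, ctx, report, out_dir):
    opts = cfg.stage_options("upscale")
    if "model" not in ctx:
        ckpt = opts.get("checkpoint")
        if ckpt is None:
            raise ValueError("upscale stage needs a trained model or checkpoint")
        ctx["model"] = srnet.load_checkpoint(ckpt)
    est = ctx["model"]
    lr_path = opts.get("lr_stack")
    if lr_path is not None:
        lr_stack = preprocess.read_stack(lr_path)
    elif "samples" in ctx:
        lr_frames = [
            s.lr_input if s.n_input_frames == 1 else s.lr_input[2]
            for s in ctx["samples"]
        ]
        lr_stack = preprocess.from_float(np.stack(lr_frames), bit_depth=8)
    else:
        raise ValueError("upscale stage needs 'lr_stack' or samples in context")
    ctx["lr_stack"] = lr_stack
    ctx["model_up"] = srnet.upscale(est, lr_stack)
    ctx["bilinear_up"] = srnet.bilinear_upscale(lr_stack, factor=est.scale)
    preprocess.write_stack(ctx["model_up"], out_dir / "upscaled_model.tif")
    preprocess.write_stack(ctx["bilinear_up"], out_dir / "upscaled_bilinear.tif")
    report["upscale"] = {
        "frames": lr_stack.n_frames,
        "model_output": str(out_dir / "upscaled_model.tif"),
        "bilinear_output": str(out_dir / "upscaled_bilinear.tif"),
    }


def _stage_evaluate(cfg, ctx, report, out_dir):
    opts = cfg.stage_options("evaluate")
    if "hr_stack" in opts and "lr_stack" in opts:
        hr_stack = preprocess.read_stack(opts["hr_stack"])
        hr = hr_stack.astype_float()
        lr_stack = preprocess.read_stack(opts["lr_stack"])
        candidates = {
            "bilinear": srnet.bilinear_upscale(
                lr_stack, factor=hr.shape[1] // lr_stack.frame_shape[0]
            ).astype_float()
        }
        if "model" in ctx or opts.get("checkpoint"):
            est = ctx.get("model") or srnet.load_checkpoint(opts["checkpoint"])
            candidates["model"] = srnet.upscale(est, lr_stack).astype_float()
    elif "samples" in ctx and "model_up" in ctx:
        hr = np.stack([s.hr_target for s in ctx["samples"]])
        candidates = {
            "bilinear": ctx["bilinear_up"].astype_float(),
            "model": ctx["model_up"].astype_float(),
        }
    else:
        raise ValueError(
            "evaluate stage needs either explicit 'hr_stack'/'lr_stack' paths "
            "or upscaled stacks from earlier stages"
        )
    entries = []
    for method, frames in candidates.items():
        for i, (f, h) in enumerate(zip(frames, hr)):
            entries.append(
                {
                    "frame": i,
                    "method": method,
                    "psnr": metrics.psnr(f, h, peak=1.0),
                    "ssim": metrics.ssim(f, h, peak=1.0),
                }
            )
    table, summary = metrics.metric_report(entries)
    table.to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
    summary.to_csv(out_dir / "metrics_summary.tsv", sep="\t", index=False)
    report["evaluate"] = {
        "table": str(out_dir / "metrics.tsv"),
        "summary": summary.to_dict(orient="records"),
    }
    # segmentation fidelity when the phantom ground truth is available
    if ctx.get("volumes") and "model_up" in ctx:
        vol = ctx["volumes"][0]
        seg = {}
        n = vol.image.n_frames
        for method in ("bilinear", "model"):
            up = ctx[f"{method}_up"].astype_float()[:n]
            _, acc, _ = vector_eval.peak_accuracy_sweep(
                np.asarray(up), vol.truth_mask[: len(up)],
                thresholds=np.linspace(0.0, 1.0, 256),
            )
            seg[method] = acc
        report["evaluate"]["peak_weighted_accuracy"] = seg
    return report


_STAGE_FNS = {
    "phantom": _stage_phantom,
    "preprocess": _stage_preprocess,
    "synth": _stage_synth,
    "train": _stage_train,
    "upscale": _stage_upscale,
    "evaluate": _stage_evaluate,
}
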