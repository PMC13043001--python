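"""Desk-scale study harnesses on synthetic scenes.

Two reproducible experiments exercise the full method without external
data:

* ``denoise_benchmark`` — PSNR of every denoising ordering (A1-A5)
  against the clean reference over seeded low-SNR scenes.
* ``end_to_end_benchmark`` — simulate a contaminated train/test split,
  train the compact CNN variant of the segmentation network, run the full
  predict-and-pick path on held-out scenes and score precision / recall /
  F1 / Dice against the planted ground truth, together with the
  confidence-only ablation of the collaborative filter.

Problem sizes here are the package's desk-scale defaults; both harnesses
accept overrides.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .collab import FilterConfig
from .evalmetrics import mask_dice, match_and_score
from .mfunet import ModelConfig
from .pipeline import RunConfig, TrainConfig, pick_confidence_only, \
    predict_and_pick, train
from .preprocess import DenoiseConfig, preprocess, psnr
from .proposals import classical_propose
from .simdata import SynthConfig, simulate_scene


def denoise_benchmark(n_scenes=10, size=96, snr=0.3, zsn2n_steps=300,
                      seed=0, modes=("A1", "A2", "A3", "A4", "A5")):
    """Mean PSNR (dB, affine-fit) per denoising mode over seeded scenes.

    Returns {"psnr": {mode: mean}, "per_scene": {mode: [values]}}.
    """
    scene_cfg = SynthConfig(
        size=size, n_particles=max(3, (size // 40) ** 2), radius_mean=size / 14,
        radius_sd=size / 110, snr=snr, n_contaminants=0, seed=seed,
    )
    per_scene = {m: [] for m in modes}
    for i in range(n_scenes):
        scene = simulate_scene(replace(scene_cfg, seed=seed + i))
        for mode in modes:
            dcfg = DenoiseConfig(mode=mode, zsn2n_steps=zsn2n_steps, seed=seed + i)
            out = preprocess(scene.micrograph, dcfg)
            per_scene[mode].append(psnr(scene.clean.pixels, out.pixels))
    return {
        "psnr": {m: float(np.mean(v)) for m, v in per_scene.items()},
        "per_scene": per_scene,
    }


def desk_run_config(seed=0, denoise_mode="A2", input_size=256,
                    epochs=25, n_particles=25, scene_size=512,
                    n_contaminants=5, snr=0.3) -> RunConfig:
    """The desk-scale study configuration (CPU-friendly sizes)."""
    return RunConfig(
        denoise=DenoiseConfig(mode=denoise_mode, zsn2n_steps=100),
        model=ModelConfig(encoder="tiny_cnn", input_size=input_size),
        filter=FilterConfig(),
        synth=SynthConfig(
            size=scene_size, n_particles=n_particles, snr=snr,
            n_contaminants=n_contaminants,
        ),
        train=TrainConfig(epochs=epochs, batch_size=2, learning_rate=1e-3,
                          patch_size=160),
        seed=seed,
    )


def end_to_end_benchmark(cfg: RunConfig | None = None, n_train=40, n_test=10,
                         seed=0, progress=None):
    """Train on synthetic scenes, pick on held-out scenes, score vs GT.

    Returns a dict with mean precision/recall/F1/Dice of the full
    collaborative pipeline, the confidence-only ablation precision, and
    the per-scene records.
    """
    if cfg is None:
        cfg = desk_run_config(seed=seed)
    synth = cfg.synth

    train_scenes = []
    for i in range(n_train):
        scene = simulate_scene(replace(synth, seed=synth.seed + i))
        pre = preprocess(scene.micrograph, cfg.denoise)
        train_scenes.append((pre.pixels, scene.gt_mask))
        if progress:
            progress(f"prepared train scene {i + 1}/{n_train}")

    model, log = train(cfg, train_scenes)
    if progress:
        progress("training done")

    records = []
    for i in range(n_test):
        scene = simulate_scene(replace(synth, seed=synth.seed + n_train + i))
        picks, sem, _prov = predict_and_pick(cfg, scene.micrograph, model=model)
        res = match_and_score(picks, scene.gt_particles)
        # semantic mask Dice in the original frame
        from skimage.transform import resize

        prob_full = resize(sem.prob.astype(np.float64), scene.gt_mask.shape,
                           order=1, preserve_range=True)
        dice = mask_dice(prob_full >= 0.5, scene.gt_mask)
        # ablation: confidence-only filtering of the same proposals
        proposals = classical_propose(sem.prob, cfg.proposer)
        conf_only = pick_confidence_only(
            cfg, sem.prob, proposals, scene.micrograph.shape,
            micrograph_id=scene.micrograph.id,
        )
        res_conf = match_and_score(conf_only, scene.gt_particles)
        records.append(
            {
                "seed": synth.seed + n_train + i,
                "precision": res.precision,
                "recall": res.recall,
                "f1": res.f1,
                "dice": dice,
                "n_picks": len(picks),
                "precision_conf_only": res_conf.precision,
                "recall_conf_only": res_conf.recall,
                "n_picks_conf_only": len(conf_only),
            }
        )
        if progress:
            progress(
                f"test scene {i + 1}/{n_test}: f1={res.f1:.3f} "
                f"p={res.precision:.3f} r={res.recall:.3f}"
            )

    summary = {
        k: float(np.mean([r[k] for r in records]))
        for k in ("precision", "recall", "f1", "dice", "precision_conf_only",
                  "recall_conf_only")
    }
    summary["precision_gain_vs_conf_only"] = (
        summary["precision"] - summary["precision_conf_only"]
    )
    return {"summary": summary, "per_scene": records, "train_log_tail": log[-3:]}
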