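"""Synthetic low-SNR micrographs with planted ground truth.

Scenes emulate the statistical regime the picker targets: roughly
circular spherical-projection particles of heterogeneous radius, dark
against the background (the cryo-EM contrast sign), a few large irregular
contaminants (random-walk blobs, the false-positive bait that exercises
the size and semantic-consistency filters), and additive Gaussian noise
scaled so that variance(particle layer)/variance(noise) hits the target
SNR — below 0.5, the regime where real micrographs live.

Not emulated: CTF oscillations, ice gradients, beam-induced motion,
particle overlap/adhesion. Passing tests on these scenes therefore
demonstrate the machinery (denoising, segmentation, filtering, export),
not performance on real micrographs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_star import Micrograph, Particle, ParticleSet, write_micrograph, write_star


@dataclass
class SynthConfig:
    """Scene parameters; defaults are the desk-scale benchmark profile."""

    size: int = 512
    n_particles: int = 25
    radius_mean: float = 12.0
    radius_sd: float = 2.0
    min_separation: float = 1.1  # centers >= this multiple of the radius sum apart
    snr: float = 0.3  # signal-variance / noise-variance; inf disables noise
    n_contaminants: int = 5
    contaminant_scale: float = 1.0  # contrast relative to particles
    contrast_sign: str = "dark_particles"
    seed: int = 0

    def __post_init__(self):
        if self.contrast_sign not in ("dark_particles", "bright_particles"):
            raise ValueError(f"unknown contrast_sign {self.contrast_sign!r}")
        if not self.snr > 0:
            raise ValueError("snr must be positive")


@dataclass
class SynthScene:
    """A generated micrograph plus exact ground truth."""

    micrograph: Micrograph
    clean: Micrograph
    gt_particles: ParticleSet
    gt_mask: np.ndarray
    gt_instance_masks: list = field(default_factory=list)

    def validate(self):
        union = np.zeros_like(self.gt_mask)
        for m in self.gt_instance_masks:
            union |= m
        if not np.array_equal(union, self.gt_mask):
            raise AssertionError("gt_mask != union of instance masks")
        if len(self.gt_instance_masks) != len(self.gt_particles):
            raise AssertionError("instance mask / particle count mismatch")
        return self


def _place_particles(cfg: SynthConfig, rng) -> list[Particle]:
    """Rejection-sample non-overlapping centers; bounded retries."""
    particles: list[Particle] = []
    max_tries = 200 * cfg.n_particles
    tries = 0
    while len(particles) < cfg.n_particles:
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {cfg.n_particles} particles of mean radius "
                f"{cfg.radius_mean} in a {cfg.size}^2 frame; use fewer "
                "particles or smaller radii"
            )
        tries += 1
        r = max(3.0, rng.normal(cfg.radius_mean, cfg.radius_sd))
        margin = r + 2.0
        x = rng.uniform(margin, cfg.size - margin)
        y = rng.uniform(margin, cfg.size - margin)
        ok = all(
            math.hypot(x - p.x, y - p.y) >= cfg.min_separation * (r + p.radius)
            for p in particles
        )
        if ok:
            particles.append(Particle(x=x, y=y, radius=r, confidence=1.0))
    return particles


def _render_particle(layer, mask_out, p: Particle):
    """Spherical-projection profile: intensity ~ sqrt(1 - (d/r)^2)."""
    size = layer.shape[0]
    r = p.radius
    x0, x1 = int(max(0, p.x - r - 1)), int(min(size, p.x + r + 2))
    y0, y1 = int(max(0, p.y - r - 1)), int(min(size, p.y + r + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - p.x) ** 2 + (yy - p.y) ** 2
    inside = d2 <= r * r
    prof = np.zeros_like(d2, dtype=np.float64)
    prof[inside] = np.sqrt(1.0 - d2[inside] / (r * r))
    layer[y0:y1, x0:x1] += prof
    mask_out[y0:y1, x0:x1] |= inside


def _render_contaminant(layer, cfg: SynthConfig, rng):
    """Irregular random-walk blob, deliberately a size outlier."""
    size = cfg.size
    stamp_r = rng.uniform(1.6, 2.4) * cfg.radius_mean
    n_steps = rng.integers(6, 12)
    x = rng.uniform(stamp_r, size - stamp_r)
    y = rng.uniform(stamp_r, size - stamp_r)
    step = stamp_r * 0.9
    for _ in range(n_steps):
        rr = stamp_r * rng.uniform(0.6, 1.0)
        x0, x1 = int(max(0, x - rr - 1)), int(min(size, x + rr + 2))
        y0, y1 = int(max(0, y - rr - 1)), int(min(size, y + rr + 2))
        if x1 > x0 and y1 > y0:
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d2 = (xx - x) ** 2 + (yy - y) ** 2
            inside = d2 <= rr * rr
            prof = np.zeros_like(d2, dtype=np.float64)
            prof[inside] = np.sqrt(1.0 - d2[inside] / (rr * rr))
            np.maximum(layer[y0:y1, x0:x1], prof, out=layer[y0:y1, x0:x1])
        theta = rng.uniform(0, 2 * np.pi)
        x = float(np.clip(x + step * np.cos(theta), stamp_r, size - stamp_r))
        y = float(np.clip(y + step * np.sin(theta), stamp_r, size - stamp_r))


def simulate_scene(cfg: SynthConfig) -> SynthScene:
    """Generate one scene; fully deterministic per ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    sign = -1.0 if cfg.contrast_sign == "dark_particles" else 1.0
    particles = _place_particles(cfg, rng)

    particle_layer = np.zeros((cfg.size, cfg.size), dtype=np.float64)
    gt_mask = np.zeros((cfg.size, cfg.size), dtype=bool)
    instance_masks = []
    for p in particles:
        inst = np.zeros_like(gt_mask)
        _render_particle(particle_layer, inst, p)
        instance_masks.append(inst)
        gt_mask |= inst

    contaminant_layer = np.zeros_like(particle_layer)
    for _ in range(cfg.n_contaminants):
        _render_contaminant(contaminant_layer, cfg, rng)

    signal_var = float(particle_layer.var())
    clean = sign * (particle_layer + cfg.contaminant_scale * contaminant_layer)
    if math.isinf(cfg.snr):
        noisy = clean.copy()
    else:
        sigma = math.sqrt(signal_var / cfg.snr)
        noisy = clean + rng.normal(0.0, sigma, clean.shape)

    mid = f"synth_{cfg.seed:06d}"
    pset = ParticleSet(
        micrograph_id=mid, particles=particles, source_shape=(cfg.size, cfg.size)
    ).validate()
    return SynthScene(
        micrograph=Micrograph(noisy.astype(np.float32), id=mid),
        clean=Micrograph(clean.astype(np.float32), id=mid + "_clean"),
        gt_particles=pset,
        gt_mask=gt_mask,
        gt_instance_masks=instance_masks,
    ).validate()


def measured_snr(scene: SynthScene) -> float:
    """Variance ratio of the rendered particle layer to the noise realization.

    The particle-only layer is re-rendered from the ground-truth records
    so contaminant overlap does not bias the measurement.
    """
    clean = scene.clean.pixels.astype(np.float64)
    noise = scene.micrograph.pixels.astype(np.float64) - clean
    particle_layer = np.zeros_like(clean)
    scratch = np.zeros(clean.shape, dtype=bool)
    for p in scene.gt_particles:
        _render_particle(particle_layer, scratch, p)
    if float(noise.var()) == 0.0:
        return math.inf
    return float(particle_layer.var() / noise.var())


def simulate_dataset(cfg: SynthConfig, n_train: int, n_test: int, outdir):
    """Write scenes as MRC + GT STAR + GT-mask PNG; returns the manifest.

    Scene i uses seed ``cfg.seed + i``; re-running reproduces identical
    files.
    """
    import imageio.v3 as iio
    from dataclasses import replace

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {**cfg.__dict__}, "scenes": []}
    for i in range(n_train + n_test):
        scene = simulate_scene(replace(cfg, seed=cfg.seed + i))
        split = "train" if i < n_train else "test"
        stem = f"{split}_{i:04d}"
        mrc = outdir / f"{stem}.mrc"
        star = outdir / f"{stem}_gt.star"
        mask = outdir / f"{stem}_mask.png"
        write_micrograph(scene.micrograph, mrc)
        write_star(scene.gt_particles, star, diameter_column=True)
        iio.imwrite(mask, (scene.gt_mask * 255).astype(np.uint8))
        manifest["scenes"].append(
            {
                "id": stem,
                "split": split,
                "seed": cfg.seed + i,
                "micrograph": mrc.name,
                "gt_star": star.name,
                "gt_mask": mask.name,
            }
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
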