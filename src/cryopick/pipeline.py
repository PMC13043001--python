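"""End-to-end orchestration: train / predict / pick / evaluate.

One seed governs every stochastic stage; provenance (config hash, seed,
package version) is attached to each prediction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
import numpy as np
from skimage.transform import resize

from . import __version__, nn
from .collab import FilterConfig, collaborative_pick, confidence_filter, \
    extract_particles
from .io_star import Micrograph, ParticleSet
from .losses import LossWeights, total_loss_t
from .mfunet import MFUNet, ModelConfig, load_checkpoint, save_checkpoint
from .nn import tensor as T
from .preprocess import DenoiseConfig, preprocess
from .proposals import ProposerConfig, classical_propose
from .simdata import SynthConfig


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 2
    learning_rate: float = 1e-4
    patch_size: int = 256
    val_fraction: float = 0.2
    seed: int = 0


@dataclass
class RunConfig:
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossWeights = field(default_factory=LossWeights)
    filter: FilterConfig = field(default_factory=FilterConfig)
    proposer: ProposerConfig = field(default_factory=ProposerConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def __post_init__(self):
        # one master seed propagates to every stochastic stage
        self.denoise.seed = self.seed
        self.model.seed = self.seed
        self.synth.seed = self.seed
        self.train.seed = self.seed

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        sections = {
            "denoise": DenoiseConfig,
            "model": ModelConfig,
            "loss": LossWeights,
            "filter": FilterConfig,
            "proposer": ProposerConfig,
            "synth": SynthConfig,
            "train": TrainConfig,
        }
        for key, klass in sections.items():
            if key in raw:
                val = raw[key]
                for tup in ("mu", "stage_channels", "decoder_channels",
                            "dilations"):
                    if tup in val:
                        val[tup] = tuple(val[tup])
                kwargs[key] = klass(**val)
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        return cls(**kwargs)


def _resize_pair(image, mask, side):
    img = resize(np.asarray(image, dtype=np.float64), (side, side),
                 order=1, anti_aliasing=True, preserve_range=True)
    msk = resize(np.asarray(mask, dtype=float), (side, side), order=0,
                 anti_aliasing=False, preserve_range=True) > 0.5
    return img.astype(np.float32), msk


def _augment(img, msk, rng):
    k = int(rng.integers(0, 4))
    if k:
        img, msk = np.rot90(img, k), np.rot90(msk, k)
    if rng.random() < 0.5:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < 0.5:
        img, msk = img[::-1, :], msk[::-1, :]
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


def _sample_batch(pool, batch_size, patch, rng):
    xs, ys = [], []
    for _ in range(batch_size):
        img, msk = pool[int(rng.integers(0, len(pool)))]
        side = img.shape[0]
        if patch < side:
            y0 = int(rng.integers(0, side - patch + 1))
            x0 = int(rng.integers(0, side - patch + 1))
            img = img[y0 : y0 + patch, x0 : x0 + patch]
            msk = msk[y0 : y0 + patch, x0 : x0 + patch]
        img, msk = _augment(img, msk, rng)
        xs.append(img)
        ys.append(msk)
    x = np.stack(xs)[:, None].astype(np.float32)
    y = np.stack(ys)[:, None].astype(np.float32)
    return nn.Tensor(x), nn.Tensor(y)


def _val_dice(model: MFUNet, val_pool) -> float:
    from .evalmetrics import mask_dice

    scores = []
    for img, msk in val_pool:
        prob = model.predict(img).prob
        scores.append(mask_dice(prob >= 0.5, msk))
    return float(np.mean(scores)) if scores else 0.0


def train(cfg: RunConfig, scenes, checkpoint_path=None, val_every=None):
    """Fit the segmentation network on (image, mask) training pairs.

    ``scenes`` is a list of (image, gt_mask) at native resolution, with
    image intensities already preprocessed to [0, 1]. Images are resized
    to the network input size; training runs on random augmented crops of
    ``patch_size``. The checkpoint with the best validation Dice is kept.

    Returns (model, log): ``log`` is a list of per-step records with the
    loss breakdown, plus validation entries.
    """
    if not scenes:
        raise ValueError("no training scenes provided")
    tc = cfg.train
    rng = np.random.default_rng(tc.seed)
    side = cfg.model.input_size
    pool = [_resize_pair(img, msk, side) for img, msk in scenes]
    n_val = max(1, int(round(tc.val_fraction * len(pool)))) if len(pool) > 1 else 0
    val_pool, train_pool = pool[:n_val], pool[n_val:]
    if not train_pool:
        train_pool, val_pool = pool, []

    model = MFUNet(cfg.model)
    opt = nn.Adam(model.parameters(), lr=tc.learning_rate)
    steps_per_epoch = max(1, (len(train_pool) + tc.batch_size - 1) // tc.batch_size)
    total_steps = tc.epochs * steps_per_epoch
    if val_every is None:
        val_every = max(1, total_steps // 8)
    patch = min(tc.patch_size, side)
    if patch % 32:
        raise ValueError("patch_size must be divisible by 32")

    log = []
    best = {"dice": -1.0, "state": None, "step": -1}
    for step in range(total_steps):
        opt.zero_grad()
        x, y = _sample_batch(train_pool, tc.batch_size, patch, rng)
        logits, aux = model.forward(x)
        prob = T.sigmoid(logits)
        aux_probs = [T.sigmoid(a) for a in aux]
        loss, breakdown = total_loss_t(prob, aux_probs, y, cfg.loss)
        value = float(loss.data)
        if not np.isfinite(value):
            raise RuntimeError(
                f"non-finite loss at step {step}; breakdown: {breakdown}"
            )
        loss.backward()
        opt.step()
        log.append({"step": step, "loss": value, **breakdown})
        if val_pool and ((step + 1) % val_every == 0 or step + 1 == total_steps):
            dice = _val_dice(model, val_pool)
            log.append({"step": step, "val_dice": dice})
            if dice > best["dice"]:
                best = {"dice": dice, "state": model.named_state(), "step": step}
    if best["state"] is not None:
        model.load_state(best["state"])
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return model, log


def predict_semantic(model: MFUNet, mic: Micrograph, cfg: RunConfig):
    """Preprocess, resize to the network frame and run the forward pass.

    Returns (prob map in the network frame, preprocessed micrograph).
    """
    if min(mic.shape) < 64:
        raise ValueError(
            f"micrograph {mic.shape} too small; the pipeline requires >= 64 px"
        )
    pre = preprocess(mic, cfg.denoise)
    side = cfg.model.input_size
    img = resize(pre.pixels.astype(np.float64), (side, side), order=1,
                 anti_aliasing=True, preserve_range=True).astype(np.float32)
    out = model.predict(img)
    return out, pre


def predict_and_pick(cfg: RunConfig, mic: Micrograph, model: MFUNet | None = None,
                     checkpoint_path=None, proposals=None):
    """Full inference path: denoise -> segment -> propose -> filter -> pick.

    ``proposals`` may inject precomputed instance proposals (e.g. from the
    SAM adapter or a test oracle); by default the classical proposer runs
    on the semantic probability map.

    Returns (ParticleSet in the original frame, SemanticOutput,
    provenance dict).
    """
    if model is None:
        if checkpoint_path is None:
            raise ValueError("provide a model or a checkpoint path")
        model = load_checkpoint(checkpoint_path)
    out, _pre = predict_semantic(model, mic, cfg)
    if proposals is None:
        proposals = classical_propose(out.prob, cfg.proposer)
    picks = collaborative_pick(
        out.prob, proposals, mic.shape, cfg.filter, micrograph_id=mic.id
    )
    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "micrograph": mic.id,
        "n_proposals": len(proposals),
        "n_picks": len(picks),
    }
    return picks, out, provenance


def pick_confidence_only(cfg: RunConfig, prob, proposals, source_shape,
                         micrograph_id="") -> ParticleSet:
    """Ablation baseline: confidence filter only, no size/semantic stages."""
    survivors = confidence_filter(proposals, cfg.filter)
    return extract_particles(
        survivors, source_shape, np.asarray(prob).shape, cfg.filter,
        micrograph_id=micrograph_id,
    )
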