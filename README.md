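# cryopick

Semantic–instance collaborative particle picking for cryo-EM micrographs.

Single-particle cryo-EM reconstruction starts by locating tens of
thousands of individual macromolecule projections in micrographs whose
signal-to-noise ratio is typically below 0.5. At that noise level,
per-pixel (semantic) segmentation finds *where* particles are but blurs
*which pixel belongs to which particle*, while instance proposals
delineate individual objects but happily propose ice, carbon edges and
aggregates. `cryopick` implements a pipeline that plays the two against
each other:

1. **Structure-preserving denoising** — per-image Zero-Shot Noise2Noise
   (a tiny network fitted to two diagonally pair-downsampled siblings of
   the image itself, no training data) followed by a classical chain
   (Gaussian → non-local means → Wiener → CLAHE → guided-filter fusion).
   The five orderings A1 (none) … A5 (unsupervised → classical, default)
   are all available.
2. **Multi-frequency U-Net** — a 4-stage pyramid encoder (transformer-
   style with spatial-reduction attention, or a compact CNN that trains
   on a laptop CPU), a dilated-convolution context-aggregation bottleneck
   (rates 1/3/5 + global pooling), Global–Local ECA gating on the skip
   connections, and a decoder that convolves features per wavelet subband
   between an orthonormal DWT/IDWT pair. Trained with
   `L = λ₁·BCE + λ₂·Dice + λ₃·Focal + Σⱼ μⱼ(BCEʲ + Diceʲ)`,
   λ = (1, 1, 0.5), μ = (0.4, 0.3, 0.2) on three deep-supervision heads.
3. **Collaborative filtering** — instance proposals (watershed-based by
   default; a SAM-style backend is pluggable) pass three filters:
   confidence ≥ 0.80, bounding-box diagonal within k·σ of the median
   (k = 2), and IoU ≥ 0.30 against the semantic foreground components
   they touch. Survivors become `(x, y, r, confidence)` records written
   as RELION-dialect STAR files.

A synthetic-scene generator (spherical-projection particles, irregular
contaminants, calibrated SNR, exact ground truth) makes every stage
testable offline, and the evaluation module scores picks by one-to-one
center matching (precision / recall / F1) and mask Dice.

The network, its training loop and the per-image denoiser run on a small
reverse-mode autodiff engine over numpy (`cryopick.nn`) — the package has
no deep-learning framework dependency.

## Worked example

```bash
python examples/03_train_and_pick.py
```

simulates 12 contaminated training scenes (512², 25 particles, SNR 0.3,
5 contaminants), trains the compact network variant and picks on three
held-out scenes. Output from one run:

```
training: 200 steps, best validation Dice 0.736
scene 0: 21 picks / 25 GT -> precision 0.952, recall 0.800, F1 0.870
scene 1: 21 picks / 25 GT -> precision 0.952, recall 0.800, F1 0.870
scene 2: 27 picks / 25 GT -> precision 0.926, recall 1.000, F1 0.962
```

A pick counts as a true positive when its center lies within the
ground-truth particle's radius; precision is the fraction of picks that
hit a real particle, recall the fraction of planted particles found.
`examples/02_denoise_modes.py` prints the PSNR of each denoising
ordering against the clean reference, and
`examples/04_collaborative_filter.py` walks a crafted proposal set
through the three filter stages.

The same pipeline is scriptable from the shell:

```bash
cryopick simulate --out data/ --n-train 6 --n-test 1
cryopick train    --data data/ --checkpoint model.npz
cryopick pick     --model model.npz --in data/test_0006.mrc --out picks.star
cryopick evaluate --picks picks.star --gt data/test_0006_gt.star --shape 512,512
```

## Scope

Picking only: movie alignment, CTF estimation, particle extraction and
3D reconstruction belong to the surrounding SPA pipeline (RELION,
CryoSPARC). The SAM adapter never downloads weights — without an
injected backend it raises and points to the classical proposer.
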