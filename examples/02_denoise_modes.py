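"""Compare the five denoising orderings (A1-A5) on one noisy scene.

For each mode, prints the PSNR against the clean reference (after an
affine intensity fit, so the per-mode rescaling does not bias the
comparison). Expected ordering: the combined modes beat either family
alone, and everything beats the raw image (A1).
"""

from cryopick.preprocess import DenoiseConfig, preprocess, psnr
from cryopick.simdata import SynthConfig, simulate_scene

scene = simulate_scene(
    SynthConfig(size=128, n_particles=6, radius_mean=9, snr=0.3,
                n_contaminants=0, seed=1)
)
clean = scene.clean.pixels

labels = {
    "A1": "no denoising",
    "A2": "classical chain only",
    "A3": "zero-shot Noise2Noise only",
    "A4": "classical then ZS-N2N",
    "A5": "ZS-N2N then classical (default)",
}
for mode, label in labels.items():
    cfg = DenoiseConfig(mode=mode, zsn2n_steps=300, seed=0)
    out = preprocess(scene.micrograph, cfg)
    print(f"{mode} ({label:35s}): PSNR {psnr(clean, out.pixels):6.2f} dB")
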