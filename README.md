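# srpomb

Real-world structural-MRI super-resolution scaffolding with **Pareto-optimal
Markov blanket (POMB)** hyperparameter selection.

Super-resolving brain MRI slices before feeding them to a downstream
classifier (e.g. for mild-cognitive-impairment detection) involves a large
stack of design choices: a composite GAN training objective, a randomized
"real-world" degradation pipeline that synthesizes low-resolution training
inputs, a discriminator/critic architecture, and a crowded hyperparameter
space.  This package implements that stack end-to-end at desk scale —
trainable and testable on procedurally generated brain phantoms, with no
image downloads — for researchers who want to study the method itself rather
than reproduce a GPU-scale clinical result.

## What is inside

**Losses** (`srpomb.losses`). The generator minimizes the plain sum

```
L = L_Charbonnier + L_FD + L_G + L_LPIPS
```

with `L_Charbonnier = mean sqrt((y_i - x_i)^2 + eps^2)`, a frequency-domain
term `L_FD` comparing FFT amplitudes and phases with L1, the Wasserstein
adversarial term `L_G = -mean(critic(G(z)))` (a verbatim sign-flipped
convention is switchable), and an LPIPS-style perceptual term — the mean
over layers of the MSE between feature maps,
`LPIPS(x,y) = (1/m) * sum_j MSE(phi_j(x), phi_j(y))`.

**Degradations** (`srpomb.degrade`). Blur, resize, Gaussian/Poisson/speckle
noise, JPEG compression, brightness/contrast jitter, sharpening, gamma,
cutout and rotation, shuffled per pass and included at random, all captured
in a seeded JSON-serializable plan whose replay is bit-identical.  A
shape-preserving preset covers classifier-training augmentation.

**Image quality** (`srpomb.iqa`). `PSNR = 10*log10(peak^2/MSE)`, SSIM as the
luminance-contrast-structure product `l*c*s` (global or Gaussian-windowed),
LPIPS with pluggable feature extractors, and
accuracy/sensitivity/specificity from confusion counts.

**POMB** (`srpomb.pomb`). The hyperparameter space is a Bayesian network
over hyperparameters and metrics.  The Markov blanket of the target metric
`T` — parents, children and spouses — is the minimal set with
`P(T | MB(T), X) = P(T | MB(T))` for every outside `X`.  Candidate blankets
are scored on `f_perf` (cross-validated explained variance of predicting
`T`) and `f_red` (mean pairwise normalized mutual information), then ranked
by Pareto dominance, dominance degree and crowding distance; the top entry
is the POMB.  D-separation (Bayes-ball), V-structure detection, blanket
refinement and a relevance taxonomy (strongly relevant / redundant /
irrelevant / conditionally independent) are included.

**SR networks** (`srpomb.srnet`). A small residual CNN generator with the
`nearest+conv` upsampling head (nearest-neighbour enlargement followed by an
overlapping convolution, avoiding checkerboard artifacts), a critic registry
(VGG-, ConvMixer-, U-Net-, ResNet-, ResNeXt-style), and a deterministic
alternating WGAN training loop with a cosine-annealed learning rate — all on
a compact numpy autodiff stack, CPU-only.

**Phantoms** (`srpomb.phantoms`). Deterministic brain-like images and
volumes (skull rim, tissue texture, internal structures), paired HR/LR
samples, and hyperparameter trial tables with analytically known relevance
ground truth.

## Worked example

```python
import numpy as np
from srpomb import phantoms, pomb

trials = phantoms.make_hyperparameter_trials(500, seed=7)
net = pomb.HyperNet(edges=[("h1", "accuracy"), ("h2", "accuracy"),
                           ("h1", "h3")], nodes=["h4"], target="accuracy")
result = pomb.identify_pomb(net, trials, "accuracy")
for e in result.entries:
    print(f"rank {e.rank}: {sorted(e.candidate.variables)}  "
          f"fperf={e.candidate.fperf:.3f}  fred={e.candidate.fred:.3f}  "
          f"front={e.in_front}  D={e.dominance_degree}")
print("POMB:", sorted(result.pomb_variables))
```

prints

```
rank 1: ['h1', 'h2']  fperf=0.963  fred=0.001  front=True  D=2
rank 2: ['h4']  fperf=-0.010  fred=0.000  front=True  D=0
rank 3: ['h1', 'h2', 'h3']  fperf=0.963  fred=0.334  front=False  D=1
rank 4: ['h1', 'h3']  fperf=0.748  fred=1.000  front=False  D=0
POMB: ['h1', 'h2']
```

The trial generator drives `accuracy` from `h1` and `h2` only, with `h3` an
exact copy of `h1` and `h4` pure noise.  `{h1, h2}` predicts 96% of the
metric variance at near-zero redundancy and is selected; adding the copy
`h3` leaves `fperf` unchanged while redundancy jumps to 0.334, so that
variant is Pareto-dominated; the noise variable survives on the front only
because a singleton has zero redundancy, and its dominance degree keeps it
below the true blanket.

The imaging side works the same way from the shell:

```bash
srpomb phantom --seed 1 --size 256 --out hr.png
srpomb degrade --in hr.png --scale 4 --seed 5 --out lr.png --plan-out plan.json
srpomb evaluate-iq --ref hr.png --test hr.png --report iq.json
```

On this phantom the seed-5 degradation plan leaves a 64x64 LR image whose
nearest-neighbour enlargement scores 13.6 dB PSNR and 0.24 SSIM against the
original — the gap the super-resolution model is trained to close
(`srpomb train-sr`, `srpomb super-resolve`).

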