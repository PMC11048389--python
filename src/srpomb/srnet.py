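"""Adversarial super-resolution scaffolding at desk scale.

The generator is a pluggable contract fulfilled here by a small residual CNN
with a nearest+conv upsampling head: features are enlarged by
nearest-neighbour repetition and then passed through an overlapping
convolution, which avoids the periodic "checkerboard" artifacts of strided
or pixel-shuffle upsampling (a pixel-shuffle head remains available for
comparison).  The network learns a residual on top of the nearest-neighbour
enlargement of its input, so an untrained model already reproduces the
plain-upsampling baseline.

The critic ("discriminator") registry mirrors the architecture families used
for the Wasserstein adversarial term — VGG-style, ConvMixer-style
(width/depth/kernel/patch parameterization), U-Net-style, ResNet-style and
ResNeXt-style — structurally, at configurable width; every critic maps an
image batch to one scalar score per image.

Training alternates critic and generator Adam steps under a cosine-annealed
learning rate; the generator objective is the combined Charbonnier +
frequency-domain + Wasserstein + perceptual loss.  Lipschitz control on the
critic defaults to weight clipping (configurable, switchable off).  All
randomness flows from ``TrainConfig.seed``, so runs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _nn as nn
from .losses import LossBreakdown

__all__ = [
    "GeneratorSpec",
    "CriticSpec",
    "TrainConfig",
    "Checkpoint",
    "CRITIC_REGISTRY",
    "nearest_upsample",
    "nearest_conv_upsample",
    "build_generator",
    "build_critic",
    "cosine_lr",
    "toy_train_config",
    "train_adversarial",
    "super_resolve",
    "make_sr_training_set",
    "TrainingDiverged",
]


@dataclass
class GeneratorSpec:
    """Small residual CNN generator contract."""

    upsampler: str = "nearest_conv"       # or "pixel_shuffle"
    scale: int = 2
    width: int = 16
    n_blocks: int = 2

    def __post_init__(self) -> None:
        if self.scale not in (2, 4):
            raise ValueError(f"scale must be 2 or 4, got {self.scale}")
        if self.upsampler not in ("nearest_conv", "pixel_shuffle"):
            raise ValueError(f"unknown upsampler {self.upsampler!r}")


#: critic families and their declared parameter grids
CRITIC_REGISTRY = {
    "vgg_style": {"features": (128, 256)},
    "unet_style": {"features": (128, 256)},
    "convmixer_style": {"presets": ((1536, 20, 9, 7), (1024, 20, 9, 14))},
    "resnet_style": {},
    "resnext_style": {},
}


@dataclass
class CriticSpec:
    family: str = "unet_style"
    features: int = 128                    # vgg/unet width parameter
    width: int = 64                        # convmixer width
    depth: int = 4                         # convmixer depth
    kernel: int = 9                        # convmixer depthwise kernel
    patch: int = 7                         # convmixer patch size

    def __post_init__(self) -> None:
        if self.family not in CRITIC_REGISTRY:
            raise ValueError(f"unknown critic family {self.family!r}")
        if self.family in ("vgg_style", "unet_style") and \
                self.features not in CRITIC_REGISTRY[self.family]["features"]:
            raise ValueError(
                f"{self.family} features must be one of "
                f"{CRITIC_REGISTRY[self.family]['features']}, got {self.features}")


@dataclass
class TrainConfig:
    batch_size: int = 4
    iterations: int = 200
    lr_start: float = 1e-4
    lr_min: float = 1e-7
    schedule: str = "cosine_annealing"     # or "fixed"
    weight_decay: float = 1e-3
    seed: int = 0
    loss_weights: dict = field(default_factory=lambda: {
        "charbonnier": 1.0, "frequency": 1.0, "adversarial": 1.0,
        "perceptual": 1.0})
    flipped_sign: bool = False
    charbonnier_eps: float = 1e-3
    n_critic: int = 1
    lipschitz: str = "clip"                # "clip" or "none"
    clip_value: float = 0.01

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.lr_min > self.lr_start:
            raise ValueError("lr_min must be <= lr_start")
        if self.schedule not in ("cosine_annealing", "fixed"):
            raise ValueError(f"unknown schedule {self.schedule!r}")


def toy_train_config(iterations: int = 200, seed: int = 0, **kwargs) -> TrainConfig:
    """Desk-scale training preset.

    At a few hundred iterations the full-scale learning-rate schedule
    (1e-4 cosine-annealed) barely moves a freshly initialized network, so the
    toy preset scales the rate up to 3e-3 -> 3e-6 while keeping batch size,
    weight decay, schedule shape and losses at their defaults.
    """
    base = dict(iterations=iterations, seed=seed, lr_start=3e-3, lr_min=3e-6)
    base.update(kwargs)
    return TrainConfig(**base)


class TrainingDiverged(RuntimeError):
    """Raised when a loss goes non-finite; carries a batch diagnostic."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


# --------------------------------------------------------------------------
# upsampling
# --------------------------------------------------------------------------

def nearest_upsample(img: np.ndarray, scale: int) -> np.ndarray:
    """Plain nearest-neighbour enlargement of the trailing two axes."""
    return np.asarray(img, dtype=np.float64).repeat(scale, axis=-2).repeat(scale, axis=-1)


def nearest_conv_upsample(features: np.ndarray, scale: int,
                          conv: "nn.Conv2d | None" = None,
                          seed: int = 0) -> np.ndarray:
    """Nearest-neighbour enlargement followed by an overlapping 3x3
    convolution on a (B, C, H, W) (or (C, H, W)) feature grid.

    With ``conv=None`` a deterministic seeded convolution of matching
    channel count is used.
    """
    if scale not in (2, 4):
        raise ValueError(f"scale must be 2 or 4, got {scale}")
    f = np.asarray(features, dtype=np.float64)
    squeeze = f.ndim == 3
    if squeeze:
        f = f[None]
    if conv is None:
        rng = np.random.default_rng(seed)
        conv = nn.Conv2d(f.shape[1], f.shape[1], 3, rng)
    out = conv(nn.nearest_up(nn.Tensor(f), scale)).data
    return out[0] if squeeze else out


# --------------------------------------------------------------------------
# networks
# --------------------------------------------------------------------------

class _ResBlock(nn.Module):
    def __init__(self, width, rng, groups=1):
        self.c1 = nn.Conv2d(width, width, 3, rng, groups=groups)
        self.c2 = nn.Conv2d(width, width, 3, rng, groups=groups)
        self.act = nn.LeakyReLU()

    def forward(self, x):
        return x + self.c2(self.act(self.c1(x)))


class SmallResNetSR(nn.Module):
    """Reference generator: shallow residual trunk + upsampling head +
    global nearest-neighbour skip from the input image."""

    def __init__(self, spec: GeneratorSpec, rng):
        w = spec.width
        self.spec = spec
        self.head = nn.Conv2d(1, w, 3, rng)
        self.blocks = [_ResBlock(w, rng) for _ in range(spec.n_blocks)]
        self.up = []
        for _ in range(spec.scale // 2):
            if spec.upsampler == "nearest_conv":
                self.up.append(nn.NearestUp(2))
                self.up.append(nn.Conv2d(w, w, 3, rng))
                self.up.append(nn.LeakyReLU())
            else:
                self.up.append(nn.Conv2d(w, 4 * w, 3, rng))
                self.up.append(nn.DepthToSpace(2))
                self.up.append(nn.LeakyReLU())
        # zero-init output conv: the untrained net is the nearest baseline
        self.tail = nn.Conv2d(w, 1, 3, rng, zero_init=True)
        self.act = nn.LeakyReLU()

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        skip = nn.Tensor(nearest_upsample(x.data, self.spec.scale))
        f = self.act(self.head(x))
        for blk in self.blocks:
            f = blk(f)
        for m in self.up:
            f = m(f)
        return self.tail(f) + skip


def build_generator(spec: GeneratorSpec, seed: int = 0) -> SmallResNetSR:
    return SmallResNetSR(spec, np.random.default_rng(seed))


class _Critic(nn.Module):
    """Base: trunk producing a feature map, 1x1 head, per-sample mean score."""

    def forward(self, x):
        f = self.trunk(x)
        return nn.per_sample_mean(self.score_head(f))

    def scores(self, batch: np.ndarray) -> np.ndarray:
        return self.forward(nn.Tensor(batch)).data


class _VGGCritic(_Critic):
    def __init__(self, features, rng):
        w = max(4, features // 32)
        self.trunk = nn.Sequential(
            nn.Conv2d(1, w, 3, rng), nn.LeakyReLU(), nn.AvgPool2(),
            nn.Conv2d(w, 2 * w, 3, rng), nn.LeakyReLU(), nn.AvgPool2(),
            nn.Conv2d(2 * w, 4 * w, 3, rng), nn.LeakyReLU(),
        )
        self.score_head = nn.Conv2d(4 * w, 1, 1, rng)


class _UNetCritic(_Critic):
    def __init__(self, features, rng):
        w = max(4, features // 32)
        self.enc1 = nn.Sequential(nn.Conv2d(1, w, 3, rng), nn.LeakyReLU())
        self.enc2 = nn.Sequential(nn.AvgPool2(),
                                  nn.Conv2d(w, 2 * w, 3, rng), nn.LeakyReLU())
        self.mid = nn.Sequential(nn.Conv2d(2 * w, 2 * w, 3, rng), nn.LeakyReLU())
        self.up_conv = nn.Conv2d(2 * w, w, 3, rng)
        self.fuse = nn.Sequential(nn.Conv2d(2 * w, w, 3, rng), nn.LeakyReLU())
        self.score_head = nn.Conv2d(w, 1, 1, rng)
        self.act = nn.LeakyReLU()

    def forward(self, x):
        e1 = self.enc1(x)
        e2 = self.mid(self.enc2(e1))
        u = self.act(self.up_conv(nn.nearest_up(e2, 2)))
        f = self.fuse(nn.concat_channels(u, e1))
        return nn.per_sample_mean(self.score_head(f))


class _ConvMixerCritic(_Critic):
    def __init__(self, width, depth, kernel, patch, rng):
        self.embed = nn.Conv2d(1, width, patch, rng, stride=patch)
        self.blocks = []
        for _ in range(depth):
            self.blocks.append(nn.Conv2d(width, width, kernel, rng, groups=width))
            self.blocks.append(nn.LeakyReLU())
            self.blocks.append(nn.Conv2d(width, width, 1, rng))
            self.blocks.append(nn.LeakyReLU())
        self.score_head = nn.Conv2d(width, 1, 1, rng)
        self.act = nn.LeakyReLU()

    def forward(self, x):
        f = self.act(self.embed(x))
        for m in self.blocks:
            f = m(f)
        return nn.per_sample_mean(self.score_head(f))


class _ResNetCritic(_Critic):
    def __init__(self, rng, groups=1, width=8):
        self.trunk = nn.Sequential(
            nn.Conv2d(1, width, 3, rng), nn.LeakyReLU(),
            _ResBlock(width, rng, groups=groups), nn.AvgPool2(),
            _ResBlock(width, rng, groups=groups),
        )
        self.score_head = nn.Conv2d(width, 1, 1, rng)


def build_critic(spec: CriticSpec, seed: int = 0) -> _Critic:
    """Instantiate a critic from the registry; the returned object maps an
    image batch (B, 1, H, W) to one finite score per image via ``scores``."""
    rng = np.random.default_rng(seed)
    if spec.family == "vgg_style":
        return _VGGCritic(spec.features, rng)
    if spec.family == "unet_style":
        return _UNetCritic(spec.features, rng)
    if spec.family == "convmixer_style":
        return _ConvMixerCritic(spec.width, spec.depth, spec.kernel, spec.patch, rng)
    if spec.family == "resnet_style":
        return _ResNetCritic(rng, groups=1)
    if spec.family == "resnext_style":
        return _ResNetCritic(rng, groups=4, width=8)
    raise ValueError(f"unknown critic family {spec.family!r}")


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def cosine_lr(cfg: TrainConfig, iteration: int) -> float:
    """Learning rate at ``iteration``; equals ``lr_start`` at 0 and exactly
    ``lr_min`` at the final iteration under cosine annealing."""
    if cfg.schedule == "fixed" or cfg.iterations == 1:
        return cfg.lr_start
    frac = iteration / (cfg.iterations - 1)
    return cfg.lr_min + 0.5 * (cfg.lr_start - cfg.lr_min) * (1 + np.cos(np.pi * frac))


@dataclass
class Checkpoint:
    gen_spec: GeneratorSpec
    cfg: TrainConfig
    arrays: list
    seed: int

    def save(self, path) -> None:
        meta = json.dumps({"gen_spec": asdict(self.gen_spec),
                           "cfg": asdict(self.cfg), "seed": self.seed})
        np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **{f"p{i}": a for i, a in enumerate(self.arrays)})

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            arrays = [z[f"p{i}"] for i in range(len(z.files) - 1)]
        return cls(gen_spec=GeneratorSpec(**meta["gen_spec"]),
                   cfg=TrainConfig(**meta["cfg"]), arrays=arrays,
                   seed=meta["seed"])

    def build(self) -> SmallResNetSR:
        gen = build_generator(self.gen_spec, seed=self.seed)
        gen.load_state_arrays(self.arrays)
        return gen


def make_sr_training_set(n: int, hr_size: int, scale: int, seed: int,
                         easy: bool = True) -> list[tuple[np.ndarray, np.ndarray]]:
    """Paired phantom training samples.

    ``easy=True`` pairs each HR phantom with its plain bilinear downscale
    (the clean toy task); otherwise the randomized degradation pipeline
    produces the LR member.
    """
    from skimage.transform import resize as _sk_resize

    from . import phantoms

    pairs = []
    for i in range(n):
        if easy:
            hr = phantoms.make_phantom_2d(seed + i, size=hr_size)
            lr = np.clip(_sk_resize(hr, (hr_size // scale, hr_size // scale),
                                    order=1, mode="reflect", anti_aliasing=True),
                         0.0, 1.0)
        else:
            hr, lr = phantoms.make_paired_sample(seed + i, hr_size=hr_size,
                                                 scale=scale)
        pairs.append((hr, lr))
    return pairs


def _stack(pairs, idx) -> tuple[np.ndarray, np.ndarray]:
    hr = np.stack([pairs[i][0] for i in idx])[:, None]
    lr = np.stack([pairs[i][1] for i in idx])[:, None]
    return hr, lr


def train_adversarial(gen_spec: GeneratorSpec, critic_spec: CriticSpec,
                      cfg: TrainConfig, data) -> tuple[Checkpoint, list[dict]]:
    """Alternating Wasserstein critic / generator training.

    ``data`` is a list of (hr, lr) image pairs.  Returns the final
    checkpoint and a per-iteration history of the loss breakdown (plus
    critic loss and learning rate).  Fully deterministic given
    ``cfg.seed``.
    """
    from .iqa import make_seeded_extractor  # noqa: F401  (numpy-side twin)

    rng = np.random.default_rng(cfg.seed)
    gen = build_generator(gen_spec, seed=int(rng.integers(2 ** 31)))
    critic = build_critic(critic_spec, seed=int(rng.integers(2 ** 31)))

    # frozen seeded conv stack for the perceptual term, inside the graph
    feat_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
    feat_layers = []
    cin = 1
    for _ in range(2):
        feat_layers.append(nn.Conv2d(cin, 4, 3, feat_rng))
        feat_layers.append(nn.LeakyReLU(0.1))
        cin = 4
    feat_net = nn.Sequential(*feat_layers)

    opt_g = nn.Adam(gen.parameters(), lr=cfg.lr_start,
                    weight_decay=cfg.weight_decay)
    opt_c = nn.Adam(critic.parameters(), lr=cfg.lr_start,
                    weight_decay=cfg.weight_decay)

    sign = -1.0 if cfg.flipped_sign else 1.0
    history: list[dict] = []
    for it in range(cfg.iterations):
        lr_t = cosine_lr(cfg, it)
        # deterministic round-robin batches: every window of the loss log
        # sees the same sample mix, so window means are comparable
        idx = np.arange(it * cfg.batch_size,
                        (it + 1) * cfg.batch_size) % len(data)
        hr, lr_in = _stack(data, idx)

        # --- critic step(s): minimize mean(fake) - mean(real) (standard) ---
        critic_loss_val = 0.0
        for _ in range(cfg.n_critic):
            fake = gen(nn.Tensor(lr_in)).detach()
            s_fake = critic(fake)
            s_real = critic(nn.Tensor(hr))
            c_loss = sign * (s_fake.mean() - s_real.mean())
            opt_c.zero_grad()
            c_loss.backward()
            opt_c.step(lr_t)
            if cfg.lipschitz == "clip":
                for p in critic.parameters():
                    np.clip(p.data, -cfg.clip_value, cfg.clip_value, out=p.data)
            critic_loss_val = float(c_loss.data)

        # --- generator step: combined loss ---
        sr = gen(nn.Tensor(lr_in))
        l_charb = nn.charbonnier_loss(sr, hr, eps=cfg.charbonnier_eps)
        l_fd = nn.fd_loss(sr, hr)
        l_adv = (-sign) * critic(sr).mean()
        fx = feat_net(sr)
        fy = feat_net(nn.Tensor(hr))
        l_lpips = (fx - fy).square().mean()

        w = cfg.loss_weights
        total = (w.get("charbonnier", 1.0) * l_charb
                 + w.get("frequency", 1.0) * l_fd
                 + w.get("adversarial", 1.0) * l_adv
                 + w.get("perceptual", 1.0) * l_lpips)

        breakdown = LossBreakdown(
            charbonnier=float(l_charb.data), frequency=float(l_fd.data),
            adversarial=float(l_adv.data), perceptual=float(l_lpips.data),
            weights=dict(w))
        row = {"iteration": it, "lr": lr_t, "critic_loss": critic_loss_val,
               **breakdown.as_dict()}
        if not all(np.isfinite(v) for v in row.values()):
            raise TrainingDiverged(
                f"non-finite loss at iteration {it}",
                diagnostics={"iteration": it, "batch_indices": idx.tolist(),
                             "losses": row})
        history.append(row)

        opt_g.zero_grad()
        total.backward()
        opt_g.step(lr_t)

    # the stored arrays are the trained weights; the seed only sizes the init
    ckpt = Checkpoint(gen_spec=gen_spec, cfg=cfg,
                      arrays=[a.copy() for a in gen.state_arrays()],
                      seed=0)
    return ckpt, history


def super_resolve(checkpoint: Checkpoint, lr_image: np.ndarray) -> np.ndarray:
    """Run a checkpointed generator on a single LR image; output dims are
    input dims times the checkpoint scale, clipped to [0, 1]."""
    gen = checkpoint.build()
    img = np.asarray(lr_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("lr_image must be 2D")
    out = gen(nn.Tensor(img[None, None])).data[0, 0]
    return np.clip(out, 0.0, 1.0)
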