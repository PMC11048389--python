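"""Randomized "real-world" degradation pipeline and classification augmentations.

Low-resolution training inputs are synthesized from high-resolution images by
a seeded, serializable plan: per pass, the corruption operators are shuffled,
each is included with a configured probability, and its parameters are drawn
from configured ranges.  A plan fully captures every sampled value (including
per-operator noise sub-seeds), so replaying it on the same input is
bit-identical and plans round-trip through JSON exactly.

Geometric operators (rotation, cutout) are applied to the high-resolution
image *before* any photometric corruption so that an HR/LR training pair
remains geometrically aligned; :func:`apply_plan_paired` returns both members.

A separate shape-preserving preset (:func:`augment_classification`) covers the
downstream-classifier augmentations: affine warp, brightness/contrast jitter,
sharpening, blur and motion blur, Gaussian noise, gamma, and compression
noise.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import AffineTransform, resize as _sk_resize, rotate as _sk_rotate

__all__ = [
    "OP_NAMES",
    "OpConfig",
    "DegradationConfig",
    "DegradationOp",
    "DegradationPlan",
    "ClassificationPreset",
    "build_plan",
    "apply_plan",
    "apply_plan_paired",
    "augment_classification",
]

#: the closed operator vocabulary of the SR degradation pipeline
OP_NAMES = (
    "blur", "resize", "gaussian_noise", "poisson_noise", "speckle_noise",
    "jpeg_noise", "brightness_contrast_jitter", "sharpen", "gamma",
    "cutout", "rotate",
)

_GEOMETRIC = ("rotate", "cutout")
_STOCHASTIC = ("gaussian_noise", "poisson_noise", "speckle_noise")


@dataclass
class OpConfig:
    """Inclusion probability and parameter ranges for one operator."""

    probability: float = 0.5
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)


def _default_ops() -> dict[str, OpConfig]:
    # Parameter ranges follow common real-world-SR practice; all configurable.
    return {
        "blur": OpConfig(ranges={"sigma": (0.2, 3.0)}),
        "resize": OpConfig(ranges={"factor": (0.5, 1.2)}),
        "gaussian_noise": OpConfig(ranges={"sigma": (1.0 / 255.0, 25.0 / 255.0)}),
        "poisson_noise": OpConfig(ranges={"peak": (64.0, 512.0)}),
        "speckle_noise": OpConfig(ranges={"variance": (0.001, 0.02)}),
        "jpeg_noise": OpConfig(ranges={"quality": (30.0, 95.0)}),
        "brightness_contrast_jitter": OpConfig(
            ranges={"brightness": (-0.1, 0.1), "contrast": (0.8, 1.2)}),
        "sharpen": OpConfig(ranges={"amount": (0.3, 1.0), "sigma": (0.8, 1.2)}),
        "gamma": OpConfig(ranges={"gamma": (0.7, 1.5)}),
        "cutout": OpConfig(ranges={"area": (0.01, 0.10)}),
        "rotate": OpConfig(ranges={"angle": (-15.0, 15.0)}),
    }


@dataclass
class DegradationConfig:
    """Pipeline-level configuration: operator pool and number of passes."""

    ops: dict[str, OpConfig] = field(default_factory=_default_ops)
    passes: int = 2

    def __post_init__(self) -> None:
        if not self.ops:
            raise ValueError("degradation config has an empty operator pool")
        unknown = set(self.ops) - set(OP_NAMES)
        if unknown:
            raise ValueError(f"unknown degradation op(s): {sorted(unknown)}")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")

    def with_probability(self, p: float) -> "DegradationConfig":
        return DegradationConfig(
            ops={k: OpConfig(probability=p, ranges=dict(v.ranges))
                 for k, v in self.ops.items()},
            passes=self.passes,
        )


@dataclass
class DegradationOp:
    name: str
    params: dict[str, float]
    applied: bool = True


@dataclass
class DegradationPlan:
    """Fully sampled, replayable degradation schedule."""

    passes: list[list[DegradationOp]]
    seed: int
    scale: int

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "scale": self.scale,
            "passes": [[asdict(op) for op in p] for p in self.passes],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DegradationPlan":
        d = json.loads(text)
        return cls(
            passes=[[DegradationOp(**op) for op in p] for p in d["passes"]],
            seed=int(d["seed"]),
            scale=int(d["scale"]),
        )


def build_plan(config: DegradationConfig, seed: int, scale: int = 4) -> DegradationPlan:
    """Sample a degradation plan: shuffled operator order per pass, per-op
    inclusion with the configured probability, parameters from the ranges.

    Stochastic noise operators additionally receive a stored sub-seed so that
    replay is bit-identical.
    """
    if scale not in (2, 4):
        raise ValueError(f"scale must be 2 or 4, got {scale}")
    rng = np.random.default_rng(seed)
    names = sorted(config.ops)
    passes: list[list[DegradationOp]] = []
    for _ in range(config.passes):
        order = [names[i] for i in rng.permutation(len(names))]
        ops: list[DegradationOp] = []
        for name in order:
            oc = config.ops[name]
            include = bool(rng.uniform() < oc.probability)
            params = {k: float(rng.uniform(lo, hi))
                      for k, (lo, hi) in sorted(oc.ranges.items())}
            if name == "cutout":
                params["cy"] = float(rng.uniform())
                params["cx"] = float(rng.uniform())
            if name in _STOCHASTIC:
                params["noise_seed"] = int(rng.integers(0, 2 ** 31))
            if include:
                ops.append(DegradationOp(name=name, params=params))
        passes.append(ops)
    return DegradationPlan(passes=passes, seed=seed, scale=scale)


# --------------------------------------------------------------------------
# operator kernels (all take/return float images in [0, 1])
# --------------------------------------------------------------------------

def _op_blur(img, p):
    return ndi.gaussian_filter(img, sigma=p["sigma"], mode="reflect")


def _op_resize(img, p):
    h, w = img.shape
    f = p["factor"]
    nh, nw = max(8, int(round(h * f))), max(8, int(round(w * f)))
    return _sk_resize(img, (nh, nw), order=1, mode="reflect",
                      anti_aliasing=f < 1.0)


def _op_gaussian_noise(img, p):
    rng = np.random.default_rng(int(p["noise_seed"]))
    return img + rng.normal(0.0, p["sigma"], size=img.shape)


def _op_poisson_noise(img, p):
    rng = np.random.default_rng(int(p["noise_seed"]))
    peak = p["peak"]
    return rng.poisson(np.clip(img, 0.0, 1.0) * peak).astype(np.float64) / peak


def _op_speckle_noise(img, p):
    rng = np.random.default_rng(int(p["noise_seed"]))
    return img * (1.0 + rng.normal(0.0, np.sqrt(p["variance"]), size=img.shape))


def _op_jpeg_noise(img, p):
    # Realized as an in-memory baseline-JPEG encode/decode via Pillow at the
    # sampled integer quality; the dialect is fixed for bit-exact replay.
    from PIL import Image

    q = int(round(p["quality"]))
    arr = np.clip(np.round(np.clip(img, 0.0, 1.0) * 255.0), 0, 255).astype(np.uint8)
    buf = io.BytesIO()
    Image.fromarray(arr, mode="L").save(buf, format="JPEG", quality=q)
    buf.seek(0)
    with Image.open(buf) as im:
        out = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
    return out


def _op_bc_jitter(img, p):
    return (img - 0.5) * p["contrast"] + 0.5 + p["brightness"]


def _op_sharpen(img, p):
    blurred = ndi.gaussian_filter(img, sigma=p["sigma"], mode="reflect")
    return img + p["amount"] * (img - blurred)


def _op_gamma(img, p):
    return np.power(np.clip(img, 0.0, 1.0), p["gamma"])


def _op_cutout(img, p):
    out = img.copy()
    h, w = img.shape
    side = np.sqrt(p["area"])
    ch, cw = max(1, int(round(h * side))), max(1, int(round(w * side)))
    y0 = int(round(p["cy"] * (h - ch)))
    x0 = int(round(p["cx"] * (w - cw)))
    out[y0:y0 + ch, x0:x0 + cw] = 0.0
    return out


def _op_rotate(img, p):
    return _sk_rotate(img, p["angle"], order=1, mode="constant", cval=0.0,
                      preserve_range=True)


_KERNELS = {
    "blur": _op_blur,
    "resize": _op_resize,
    "gaussian_noise": _op_gaussian_noise,
    "poisson_noise": _op_poisson_noise,
    "speckle_noise": _op_speckle_noise,
    "jpeg_noise": _op_jpeg_noise,
    "brightness_contrast_jitter": _op_bc_jitter,
    "sharpen": _op_sharpen,
    "gamma": _op_gamma,
    "cutout": _op_cutout,
    "rotate": _op_rotate,
}


def _apply_op(img: np.ndarray, op: DegradationOp) -> np.ndarray:
    out = _KERNELS[op.name](img, op.params)
    return np.clip(out, 0.0, 1.0)


def apply_plan_paired(hr: np.ndarray, plan: DegradationPlan) -> tuple[np.ndarray, np.ndarray]:
    """Replay a plan, returning ``(hr_geometric, lr)``.

    Geometric operators are applied to the HR image first (in plan order);
    the photometric corruptions then run pass by pass, and the result is
    resized to ``hr_dims / scale``.
    """
    hr = np.asarray(hr, dtype=np.float64)
    h, w = hr.shape
    if h % plan.scale or w % plan.scale:
        raise ValueError(f"HR dims {hr.shape} not divisible by scale {plan.scale}")

    hr_geo = hr
    for p in plan.passes:
        for op in p:
            if op.name in _GEOMETRIC:
                hr_geo = _apply_op(hr_geo, op)

    img = hr_geo
    for p in plan.passes:
        for op in p:
            if op.name not in _GEOMETRIC:
                img = _apply_op(img, op)

    lr = _sk_resize(img, (h // plan.scale, w // plan.scale), order=1,
                    mode="reflect", anti_aliasing=True)
    return hr_geo, np.clip(lr, 0.0, 1.0)


def apply_plan(hr: np.ndarray, plan: DegradationPlan) -> np.ndarray:
    """Replay a plan and return the low-resolution output only."""
    return apply_plan_paired(hr, plan)[1]


# --------------------------------------------------------------------------
# classification augmentation preset
# --------------------------------------------------------------------------

@dataclass
class ClassificationPreset:
    """Shape-preserving augmentation preset for classifier training."""

    probability: float = 0.5
    max_rotation: float = 10.0        # degrees
    max_translation: float = 0.05     # fraction of side
    scale_range: tuple[float, float] = (0.95, 1.05)
    brightness: tuple[float, float] = (-0.1, 0.1)
    contrast: tuple[float, float] = (0.8, 1.2)
    sharpen_amount: tuple[float, float] = (0.3, 1.0)
    blur_sigma: tuple[float, float] = (0.2, 1.5)
    motion_length: tuple[int, int] = (3, 9)
    noise_sigma: tuple[float, float] = (1.0 / 255.0, 10.0 / 255.0)
    gamma: tuple[float, float] = (0.7, 1.5)
    jpeg_quality: tuple[float, float] = (40.0, 95.0)


def _motion_blur(img: np.ndarray, length: int, angle: float) -> np.ndarray:
    kernel = np.zeros((length, length))
    kernel[length // 2, :] = 1.0
    kernel = _sk_rotate(kernel, angle, order=1, preserve_range=True)
    s = kernel.sum()
    if s > 0:
        kernel /= s
    return ndi.convolve(img, kernel, mode="reflect")


def augment_classification(img: np.ndarray, seed: int,
                           preset: ClassificationPreset | None = None) -> np.ndarray:
    """Apply the classifier-training augmentation preset.

    Each operator is included independently with ``preset.probability``; the
    output has the same spatial dims as the input and is deterministic for a
    fixed seed.  With ``probability = 0`` the function is the identity.
    """
    preset = preset or ClassificationPreset()
    img = np.asarray(img, dtype=np.float64)
    rng = np.random.default_rng(seed)
    out = img
    u = lambda lohi: float(rng.uniform(*lohi))  # noqa: E731

    take = lambda: bool(rng.uniform() < preset.probability)  # noqa: E731

    # affine: rotation + translation + isotropic scale about the center
    inc = take()
    ang = np.deg2rad(rng.uniform(-preset.max_rotation, preset.max_rotation))
    ty = rng.uniform(-preset.max_translation, preset.max_translation) * img.shape[0]
    tx = rng.uniform(-preset.max_translation, preset.max_translation) * img.shape[1]
    sc = u(preset.scale_range)
    if inc:
        from skimage.transform import warp

        h, w = out.shape
        center = np.array([w, h]) / 2.0
        tf = (AffineTransform(translation=-center)
              + AffineTransform(rotation=ang, scale=(sc, sc), translation=(tx, ty))
              + AffineTransform(translation=center))
        out = warp(out, tf.inverse, order=1, mode="constant", cval=0.0,
                   preserve_range=True)

    inc = take()
    b, c = u(preset.brightness), u(preset.contrast)
    if inc:
        out = (out - 0.5) * c + 0.5 + b

    inc = take()
    amt = u(preset.sharpen_amount)
    if inc:
        out = out + amt * (out - ndi.gaussian_filter(out, 1.0, mode="reflect"))

    inc = take()
    sig = u(preset.blur_sigma)
    if inc:
        out = ndi.gaussian_filter(out, sig, mode="reflect")

    inc = take()
    mlen = int(rng.integers(preset.motion_length[0], preset.motion_length[1] + 1))
    mang = float(rng.uniform(0.0, 180.0))
    if inc:
        out = _motion_blur(out, mlen, mang)

    inc = take()
    nsig = u(preset.noise_sigma)
    noise = rng.normal(0.0, 1.0, size=out.shape)
    if inc:
        out = out + nsig * noise

    inc = take()
    g = u(preset.gamma)
    if inc:
        out = np.power(np.clip(out, 0.0, 1.0), g)

    inc = take()
    q = float(rng.uniform(*preset.jpeg_quality))
    if inc:
        out = _op_jpeg_noise(np.clip(out, 0.0, 1.0), {"quality": q})

    return np.clip(out, 0.0, 1.0) if out is not img else img
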