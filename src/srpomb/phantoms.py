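"""Deterministic synthetic brain phantoms and hyperparameter trial tables.

Everything downstream (degradation, losses, image-quality metrics, the
Markov-blanket machinery, toy adversarial training) is exercised on data
produced here, so no external MRI archive is ever required.

Conventions
-----------
* A 2D image is a float64 :class:`numpy.ndarray` of shape ``(m, n)`` with
  intensities in the canonical range ``[0, 1]``.
* A 3D volume is a float64 array whose axes are, in order,
  ``(sagittal, coronal, axial)``.  The mid slice along a dimension of size
  ``d`` is index ``d // 2`` (floor convention).
* All generators are driven by :class:`numpy.random.Generator` seeded from
  the ``seed`` argument and are bit-reproducible for a fixed seed.

Trial-table landscape
---------------------
:func:`make_hyperparameter_trials` draws discrete hyperparameters and a
target metric from the documented response surface

    ``accuracy = 0.6 * (h1 / 3) + 0.3 * (h2 / 2) + eps``,  eps ~ N(0, 0.05²)

with ``h1 in {0..3}``, ``h2 in {0..2}`` uniform, ``h3 = h1`` (an exact,
hence redundant, copy) and ``h4 in {0..3}`` independent noise (irrelevant).
The relevance ground truth is therefore analytically known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

__all__ = [
    "TrialTable",
    "TRIAL_COEFF_H1",
    "TRIAL_COEFF_H2",
    "TRIAL_NOISE_SD",
    "make_phantom_2d",
    "make_phantom_volume",
    "make_paired_sample",
    "extract_mid_slices",
    "make_hyperparameter_trials",
    "validate_image",
    "write_png",
    "read_png",
    "write_nifti",
]

#: coefficients of the documented trial response surface
TRIAL_COEFF_H1 = 0.6
TRIAL_COEFF_H2 = 0.3
TRIAL_NOISE_SD = 0.05

_H1_LEVELS = 4
_H2_LEVELS = 3
_H4_LEVELS = 4


def validate_image(img: np.ndarray, *, name: str = "image") -> np.ndarray:
    """Check the canonical 2D image contract: finite float grid in [0, 1]."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2D, got shape {arr.shape}")
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise ValueError(f"{name} must be at least 8x8, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite intensities")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(f"{name} intensities outside [0, 1]")
    return arr


@dataclass
class TrialTable:
    """Hyperparameter-assignment -> metric records.

    ``frame`` holds one row per trial; hyperparameter columns are discrete
    integers, metric columns are floats.  ``ground_truth`` optionally maps a
    hyperparameter name to its known relevance role.
    """

    frame: pd.DataFrame
    hyperparameters: list[str]
    metrics: list[str]
    ground_truth: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in self.hyperparameters + self.metrics:
            if col not in self.frame.columns:
                raise ValueError(f"trial table missing column {col!r}")
        vals = self.frame[self.metrics].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("trial table contains non-finite metric values")

    @property
    def schema(self) -> list[str]:
        return list(self.hyperparameters) + list(self.metrics)

    def to_csv(self, path) -> None:
        self.frame[self.schema].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, hyperparameters: list[str], metrics: list[str],
                 ground_truth: dict[str, str] | None = None) -> "TrialTable":
        frame = pd.read_csv(path)
        return cls(frame=frame, hyperparameters=list(hyperparameters),
                   metrics=list(metrics), ground_truth=dict(ground_truth or {}))


# --------------------------------------------------------------------------
# image phantoms
# --------------------------------------------------------------------------

def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float,
                  angle: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    y = yy - cy
    x = xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _bandlimited_noise(rng: np.random.Generator, size: int,
                       cutoff: float = 0.15) -> np.ndarray:
    """Smooth texture: white noise low-pass filtered in the Fourier domain."""
    spec = rng.normal(size=(size, size)) + 1j * rng.normal(size=(size, size))
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    spec *= np.exp(-((fy ** 2 + fx ** 2) / (2 * cutoff ** 2)))
    tex = np.fft.ifft2(spec).real
    tex -= tex.min()
    peak = tex.max()
    if peak > 0:
        tex /= peak
    return tex


def make_phantom_2d(seed: int, size: int = 256, contrast: float = 0.8) -> np.ndarray:
    """Procedural axial-style brain phantom.

    The image contains an elliptical skull rim, interior tissue texture and
    several darker/lighter internal structures (ventricle-like lobes and a
    round lesion-like blob).  Geometry and texture are jittered by ``seed``;
    the output is deterministic for a fixed seed.

    Parameters
    ----------
    seed : int
        Seeds all randomness.
    size : int
        Side length in pixels, at least 32.
    contrast : float
        Intensity span of the tissue, in ``(0, 1]``.
    """
    if size < 32:
        raise ValueError(f"size must be >= 32, got {size}")
    if not (0.0 < contrast <= 1.0):
        raise ValueError(f"contrast must be in (0, 1], got {contrast}")
    rng = np.random.default_rng(seed)

    img = np.zeros((size, size), dtype=np.float64)
    c = size / 2.0
    jit = lambda lo, hi: rng.uniform(lo, hi)  # noqa: E731

    ry = size * jit(0.40, 0.46)
    rx = size * jit(0.33, 0.40)
    tilt = jit(-0.2, 0.2)
    skull = _ellipse_mask(size, c, c, ry, rx, tilt)
    brain = _ellipse_mask(size, c, c, ry * 0.90, rx * 0.90, tilt)

    # skull rim: bright ring between the two ellipses
    img[skull & ~brain] = 0.95

    # interior tissue: mid gray modulated by band-limited texture
    tex = _bandlimited_noise(rng, size, cutoff=jit(0.08, 0.18))
    tissue = 0.45 + (tex - 0.5) * 0.35 * contrast
    img[brain] = tissue[brain]

    # internal structures: two ventricle-like dark lobes + one bright blob
    for sx in (-1.0, 1.0):
        lobe = _ellipse_mask(
            size,
            c + jit(-0.04, 0.04) * size,
            c + sx * jit(0.08, 0.14) * size,
            size * jit(0.10, 0.16),
            size * jit(0.03, 0.06),
            tilt + sx * jit(0.2, 0.5),
        )
        img[lobe & brain] = 0.12 * (1.0 - contrast) + 0.08
    blob = _ellipse_mask(
        size,
        c + jit(-0.22, 0.22) * size * 0.8,
        c + jit(-0.18, 0.18) * size * 0.8,
        size * jit(0.03, 0.06),
        size * jit(0.03, 0.06),
    )
    img[blob & brain] = 0.55 + 0.4 * contrast

    return np.clip(img, 0.0, 1.0)


def make_phantom_volume(seed: int, shape: tuple[int, int, int] = (64, 64, 64),
                        contrast: float = 0.8) -> np.ndarray:
    """Stack of smoothly varying phantom slices as a (sagittal, coronal, axial) volume.

    Each axial slice is a phantom whose geometry drifts with slice index, so
    all three orthogonal mid slices show structure.
    """
    if any(d < 8 for d in shape):
        raise ValueError(f"every volume dim must be >= 8, got {shape}")
    sag, cor, axi = shape
    base = make_phantom_2d(seed, size=max(32, sag, cor), contrast=contrast)
    rng = np.random.default_rng(seed + 1)
    vol = np.empty(shape, dtype=np.float64)
    for k in range(axi):
        # scale the base slice towards the poles to mimic a head outline
        frac = 1.0 - 0.6 * abs(k - axi / 2.0) / (axi / 2.0)
        sl = _sk_resize(base, (sag, cor), order=1, mode="reflect",
                        anti_aliasing=True)
        vol[:, :, k] = np.clip(sl * frac + 0.02 * rng.standard_normal((sag, cor)),
                               0.0, 1.0)
    return vol


def make_paired_sample(seed: int, hr_size: int = 256, scale: int = 4,
                       degradation_config=None) -> tuple[np.ndarray, np.ndarray]:
    """HR phantom plus its degraded LR counterpart.

    The LR member is produced by the :mod:`srpomb.degrade` pipeline (randomly
    sequenced corruptions followed by the final downscale); geometric
    operations are applied to the HR member as well so the pair stays aligned.
    With ``degradation_config=None`` a mild default configuration is used.
    """
    if scale not in (2, 4):
        raise ValueError(f"scale must be 2 or 4, got {scale}")
    if hr_size % scale != 0:
        raise ValueError(f"hr_size {hr_size} not divisible by scale {scale}")
    from . import degrade  # deferred: degrade imports nothing from here

    hr = make_phantom_2d(seed, size=hr_size)
    cfg = degradation_config or degrade.DegradationConfig()
    plan = degrade.build_plan(cfg, seed=seed + 10_007, scale=scale)
    hr_geo, lr = degrade.apply_plan_paired(hr, plan)
    return hr_geo, lr


def extract_mid_slices(vol: np.ndarray, out_size: int = 256) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mid slice per labelled plane, each resized to ``out_size`` square.

    Axis order is (sagittal, coronal, axial); the mid index along a dimension
    of size ``d`` is ``d // 2``.  Resizing uses bilinear interpolation with
    anti-aliasing (the resize interpolation is this package's documented
    choice).
    """
    vol = np.asarray(vol, dtype=np.float64)
    if vol.ndim != 3 or any(d < 8 for d in vol.shape):
        raise ValueError(f"volume must be 3D with every dim >= 8, got {vol.shape}")
    sag = vol[vol.shape[0] // 2, :, :]
    cor = vol[:, vol.shape[1] // 2, :]
    axi = vol[:, :, vol.shape[2] // 2]
    out = []
    for sl in (sag, cor, axi):
        r = _sk_resize(sl, (out_size, out_size), order=1, mode="reflect",
                       anti_aliasing=True)
        out.append(np.clip(r, 0.0, 1.0))
    return out[0], out[1], out[2]


# --------------------------------------------------------------------------
# hyperparameter trials
# --------------------------------------------------------------------------

def make_hyperparameter_trials(n_trials: int, seed: int,
                               metric_name: str = "accuracy") -> TrialTable:
    """Synthetic hyperparameter-search log with known relevance structure.

    See the module docstring for the generating equations.  Ground truth:
    ``h1``/``h2`` strongly relevant, ``h3`` redundant (exact copy of ``h1``),
    ``h4`` irrelevant.
    """
    if n_trials < 50:
        raise ValueError(f"n_trials must be >= 50, got {n_trials}")
    rng = np.random.default_rng(seed)
    h1 = rng.integers(0, _H1_LEVELS, size=n_trials)
    h2 = rng.integers(0, _H2_LEVELS, size=n_trials)
    h4 = rng.integers(0, _H4_LEVELS, size=n_trials)
    eps = rng.normal(0.0, TRIAL_NOISE_SD, size=n_trials)
    metric = (TRIAL_COEFF_H1 * h1 / (_H1_LEVELS - 1)
              + TRIAL_COEFF_H2 * h2 / (_H2_LEVELS - 1) + eps)
    frame = pd.DataFrame({
        "h1": h1, "h2": h2, "h3": h1.copy(), "h4": h4, metric_name: metric,
    })
    return TrialTable(
        frame=frame,
        hyperparameters=["h1", "h2", "h3", "h4"],
        metrics=[metric_name],
        ground_truth={
            "h1": "strongly_relevant",
            "h2": "strongly_relevant",
            "h3": "redundant",
            "h4": "irrelevant",
        },
    )


# --------------------------------------------------------------------------
# fixture I/O
# --------------------------------------------------------------------------

def write_png(img: np.ndarray, path) -> None:
    """8-bit grayscale PNG (round-half-up quantization of the [0,1] grid)."""
    from PIL import Image

    arr = validate_image(img)
    q = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(q, mode="L").save(path)


def read_png(path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
    return arr


def write_nifti(vol: np.ndarray, path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine=np.eye(4))
    nib.save(img, str(path))
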