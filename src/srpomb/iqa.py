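"""Image-quality assessment and classification metrics.

PSNR/MSE/SSIM/LPIPS for the super-resolution evaluation side, and
accuracy/sensitivity/specificity from confusion counts for the downstream
classification task.

Canonical image range is ``[0, 1]``; PSNR and SSIM rescale internally by
``peak`` (default 255) so the conventional 8-bit constants apply.  Note PSNR
is invariant to that rescaling when both images live on the same scale.

LPIPS here is the plain multi-layer feature-MSE distance: the mean over
layers of the MSE between the two images' feature maps.  The feature
extractor is pluggable; :func:`make_seeded_extractor` provides a fixed,
seeded, randomly initialized convolutional stack so the metric is
deterministic and self-contained (a pretrained backbone can be plugged in
through the same interface).  No learned per-channel calibration weights are
applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "SSIMParams",
    "FeatureExtractor",
    "ConfusionCounts",
    "mse",
    "psnr",
    "ssim",
    "lpips",
    "classification_metrics",
    "make_identity_extractor",
    "make_seeded_extractor",
]

_DEFAULT_PEAK = 255.0


@dataclass
class SSIMParams:
    """Stabilizing constants and window of the structural similarity index.

    Defaults follow the metric's original convention: ``C1 = (0.01*peak)^2``,
    ``C2 = (0.03*peak)^2``, ``C3 = C2 / 2``, 11x11 Gaussian window with
    sigma 1.5 averaged over the image.  ``window="global"`` uses one window
    spanning the whole image (plain means/stds, the straight-from-formula
    evaluation).
    """

    peak: float = _DEFAULT_PEAK
    C1: float = (0.01 * _DEFAULT_PEAK) ** 2
    C2: float = (0.03 * _DEFAULT_PEAK) ** 2
    C3: float = (0.03 * _DEFAULT_PEAK) ** 2 / 2.0
    window: str = "gaussian"   # "gaussian" or "global"
    window_size: int = 11
    window_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.C1 <= 0 or self.C2 <= 0 or self.C3 <= 0:
            raise ValueError("SSIM constants must be > 0")
        if self.window not in ("gaussian", "global"):
            raise ValueError(f"unknown window {self.window!r}")


@dataclass
class FeatureExtractor:
    """Ordered feature-map transforms for the perceptual distance.

    Each layer maps the previous stage's feature grid (2D image for the
    first layer) to an ``(h, w, c)`` feature grid.
    """

    layers: list
    names: list[str]
    deterministic: bool = True

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("feature extractor must have at least one layer")

    def features(self, img: np.ndarray) -> list[np.ndarray]:
        maps = []
        cur = np.asarray(img, dtype=np.float64)
        for layer in self.layers:
            cur = layer(cur)
            maps.append(cur)
        return maps


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def N(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _check_pair(I: np.ndarray, K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(I, dtype=np.float64)
    b = np.asarray(K, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(I: np.ndarray, K: np.ndarray) -> float:
    """Mean squared error on the inputs' working scale."""
    a, b = _check_pair(I, K)
    return float(np.mean((a - b) ** 2))


def psnr(I: np.ndarray, K: np.ndarray, peak: float = _DEFAULT_PEAK) -> float:
    """Peak signal-to-noise ratio in dB: ``10*log10(peak^2 / MSE)``.

    Inputs are on the canonical [0, 1] scale and are rescaled by ``peak``;
    identical images give ``+inf``.
    """
    if peak <= 0:
        raise ValueError("peak must be > 0")
    a, b = _check_pair(I, K)
    err = mse(a * peak, b * peak)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak ** 2 / err))


def _ssim_terms(mu_x, mu_y, var_x, var_y, cov, p: SSIMParams):
    sd_x = np.sqrt(np.maximum(var_x, 0.0))
    sd_y = np.sqrt(np.maximum(var_y, 0.0))
    l = (2 * mu_x * mu_y + p.C1) / (mu_x ** 2 + mu_y ** 2 + p.C1)
    c = (2 * sd_x * sd_y + p.C2) / (var_x + var_y + p.C2)
    s = (cov + p.C3) / (sd_x * sd_y + p.C3)
    return l * c * s


def ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams | None = None) -> float:
    """Structural similarity: product of luminance, contrast and structure
    terms, either on global statistics or averaged over Gaussian windows."""
    p = params or SSIMParams()
    a, b = _check_pair(x, y)
    a = a * p.peak
    b = b * p.peak
    if p.window == "global":
        mu_x, mu_y = a.mean(), b.mean()
        var_x, var_y = a.var(), b.var()
        cov = float(np.mean((a - mu_x) * (b - mu_y)))
        return float(_ssim_terms(mu_x, mu_y, var_x, var_y, cov, p))
    # Gaussian-window mode: local weighted statistics; the border (one
    # window radius), where the filter response depends on padding, is
    # cropped before averaging the similarity map.
    trunc = (p.window_size - 1) / 2.0 / p.window_sigma
    filt = lambda z: ndi.gaussian_filter(  # noqa: E731
        z, p.window_sigma, mode="reflect", truncate=trunc)
    mu_x, mu_y = filt(a), filt(b)
    var_x = filt(a * a) - mu_x ** 2
    var_y = filt(b * b) - mu_y ** 2
    cov = filt(a * b) - mu_x * mu_y
    smap = _ssim_terms(mu_x, mu_y, var_x, var_y, cov, p)
    r = (p.window_size - 1) // 2
    if min(smap.shape) > 2 * r:
        smap = smap[r:smap.shape[0] - r, r:smap.shape[1] - r]
    return float(np.mean(smap))


def lpips(x: np.ndarray, y: np.ndarray, extractor: FeatureExtractor) -> float:
    """Perceptual distance: mean over layers of the feature-map MSE."""
    a, b = _check_pair(x, y)
    fx = extractor.features(a)
    fy = extractor.features(b)
    return float(np.mean([mse(fa, fb) for fa, fb in zip(fx, fy)]))


def classification_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from confusion counts.

    Degenerate denominators produce NaN with a warning rather than an error.
    """
    if c.N < 1:
        raise ValueError("need at least one prediction")

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                          RuntimeWarning, stacklevel=3)
            return float("nan")
        return num / den

    accuracy = (c.TP + c.TN) / c.N
    sensitivity = ratio(c.TP, c.TP + c.FN, "sensitivity")
    specificity = ratio(c.TN, c.TN + c.FP, "specificity")
    return float(accuracy), float(sensitivity), float(specificity)


# --------------------------------------------------------------------------
# feature extractors
# --------------------------------------------------------------------------

def make_identity_extractor() -> FeatureExtractor:
    """Single identity layer: LPIPS with this extractor equals plain MSE."""
    return FeatureExtractor(layers=[lambda z: np.asarray(z, dtype=np.float64)],
                            names=["identity"])


def _conv_layer(weights: np.ndarray, leak: float = 0.1):
    """'Same'-padded multi-channel correlation followed by a leaky ReLU.

    ``weights`` has shape (cout, cin, k, k); a 2D input is treated as a
    single-channel (h, w, 1) grid.
    """

    def apply(feat: np.ndarray) -> np.ndarray:
        f = np.asarray(feat, dtype=np.float64)
        if f.ndim == 2:
            f = f[:, :, None]
        cout, cin, k, _ = weights.shape
        if f.shape[2] != cin:
            raise ValueError(f"layer expects {cin} channels, got {f.shape[2]}")
        out = np.zeros((f.shape[0], f.shape[1], cout))
        for o in range(cout):
            acc = np.zeros(f.shape[:2])
            for i in range(cin):
                acc += ndi.correlate(f[:, :, i], weights[o, i], mode="reflect")
            out[:, :, o] = acc
        return np.where(out > 0, out, leak * out)

    return apply


def make_seeded_extractor(seed: int, n_layers: int = 3, channels: int = 4,
                          kernel: int = 3) -> FeatureExtractor:
    """Deterministic randomly initialized convolutional feature stack."""
    rng = np.random.default_rng(seed)
    layers, names = [], []
    cin = 1
    for j in range(n_layers):
        w = rng.normal(0.0, 1.0 / np.sqrt(cin * kernel * kernel),
                       size=(channels, cin, kernel, kernel))
        layers.append(_conv_layer(w))
        names.append(f"conv{j}")
        cin = channels
    return FeatureExtractor(layers=layers, names=names)
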