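"""Generator and critic training losses for adversarial super-resolution.

The generator objective is the plain sum (unit weights by default) of four
terms: a Charbonnier pixel loss, a frequency-domain L1 loss on FFT amplitudes
and phases, the Wasserstein adversarial term, and a perceptual (LPIPS) term.
Weights are exposed because they are natural hyperparameter-search variables.

Sign conventions.  The Wasserstein critic scores real and generated batches;
the standard optimization minimizes ``mean(fake) - mean(real)`` for the
critic and ``-mean(fake)`` for the generator.  A ``flipped_sign``
convention flips both signs (generator ``+mean(fake)``, critic
``mean(real) - mean(fake)``); the two conventions are equal in magnitude and
opposite in sign.

Frequency-domain loss.  Per sample the 2D DFT is taken, amplitude and phase
are compared with L1, *averaged* over frequency bins, and the per-sample
values are averaged over the batch.  Bin-averaging keeps the term on the
same O(1) scale as the other unit-weight terms.  The phase of a
zero-amplitude bin is defined as 0 (atan2 convention); no unwrapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CriticScores",
    "LossBreakdown",
    "charbonnier",
    "frequency_domain_loss",
    "wgan_generator_loss",
    "wgan_critic_loss",
    "combined_generator_loss",
]


@dataclass
class CriticScores:
    """One scalar critic score per mini-batch sample."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size == 0:
            raise ValueError("critic scores must be non-empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("critic scores must be finite")


@dataclass
class LossBreakdown:
    """Per-term generator loss values and their weighted combination."""

    charbonnier: float
    frequency: float
    adversarial: float
    perceptual: float
    weights: dict[str, float] = field(default_factory=lambda: {
        "charbonnier": 1.0, "frequency": 1.0, "adversarial": 1.0,
        "perceptual": 1.0,
    })

    @property
    def total(self) -> float:
        return combined_generator_loss(self)

    def as_dict(self) -> dict[str, float]:
        return {
            "charbonnier": self.charbonnier,
            "frequency": self.frequency,
            "adversarial": self.adversarial,
            "perceptual": self.perceptual,
            "total": self.total,
        }


def _as_batch(x: np.ndarray) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected an image or batch of images, got shape {arr.shape}")
    return arr


def charbonnier(pred: np.ndarray, target: np.ndarray, eps: float = 1e-3) -> float:
    """Smooth-L1 pixel loss: mean over elements of sqrt((y - x)^2 + eps^2).

    Equals the mean absolute error at ``eps = 0`` and is bounded below by
    ``eps`` everywhere.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    p, t = _as_batch(pred), _as_batch(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(np.mean(np.sqrt((p - t) ** 2 + eps ** 2)))


def frequency_domain_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """L1 distance between FFT amplitudes and phases, averaged over bins and
    over the batch.  Zero for identical inputs; symmetric in its arguments."""
    p, t = _as_batch(pred), _as_batch(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    total = 0.0
    for xi, yi in zip(p, t):
        fx, fy = np.fft.fft2(xi), np.fft.fft2(yi)
        ax, ay = np.abs(fx), np.abs(fy)
        # phase of an exactly-zero bin is 0 by the atan2(0, 0) convention
        px, py = np.angle(fx), np.angle(fy)
        total += float(np.mean(np.abs(ax - ay)) + np.mean(np.abs(px - py)))
    return total / p.shape[0]


def wgan_generator_loss(scores_fake: CriticScores | np.ndarray,
                        flipped_sign: bool = False) -> float:
    """Adversarial generator term.

    Standard convention (default): ``-mean(scores_fake)`` (the generator
    raises its critic score by minimizing).  ``flipped_sign=True`` returns
    ``+mean(scores_fake)``.
    """
    s = scores_fake if isinstance(scores_fake, CriticScores) else CriticScores(scores_fake)
    m = float(np.mean(s.values))
    return m if flipped_sign else -m


def wgan_critic_loss(scores_real: CriticScores | np.ndarray,
                     scores_fake: CriticScores | np.ndarray,
                     flipped_sign: bool = False) -> float:
    """Critic term: ``mean(fake) - mean(real)`` by default (minimized, so the
    critic scores real above fake); sign flipped under ``flipped_sign``."""
    r = scores_real if isinstance(scores_real, CriticScores) else CriticScores(scores_real)
    f = scores_fake if isinstance(scores_fake, CriticScores) else CriticScores(scores_fake)
    mr, mf = float(np.mean(r.values)), float(np.mean(f.values))
    return (mr - mf) if flipped_sign else (mf - mr)


def combined_generator_loss(parts: LossBreakdown) -> float:
    """Weighted sum of the four generator terms (plain sum at unit weights)."""
    terms = {
        "charbonnier": parts.charbonnier,
        "frequency": parts.frequency,
        "adversarial": parts.adversarial,
        "perceptual": parts.perceptual,
    }
    for name, v in terms.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite loss term {name!r}: {v}")
    return float(sum(parts.weights.get(k, 1.0) * v for k, v in terms.items()))
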