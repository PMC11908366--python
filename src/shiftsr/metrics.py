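"""Image-quality metrics: PSNR, SSIM, GMSD, perceptual distance.

Directions: higher PSNR/SSIM is better; lower GMSD/perceptual is better.

Conventions
-----------
* ``data_range`` is the width of the normalization interval (fixed per
  dataset, not per-image max), so values are comparable across slices.
* PSNR of two identical images is reported through an ``identical`` flag
  rather than propagating infinity into aggregates.
* PSNR's MSE is symmetric but ``data_range`` conceptually belongs to the
  reference scale; SSIM (this form) and GMSD are symmetric.
* An optional binary mask restricts PSNR to masked pixels and SSIM/GMSD to
  the masked region of their quality maps (perceptual distance is always
  full-frame); default is full-frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.ndimage import convolve
from skimage.metrics import structural_similarity

from .nn.perceptual import RandomFeaturePerceptual

__all__ = ["psnr", "ssim", "gmsd", "evaluate_pairs", "MetricReport"]

# 1/3-normalized Prewitt operators, the gradient stencil of the GMSD method
_PREWITT_X = np.array([[1, 0, -1], [1, 0, -1], [1, 0, -1]], dtype=np.float64) / 3.0
_PREWITT_Y = _PREWITT_X.T

#: GMSD stability constant, defined as 170 on the 8-bit (0-255) scale and
#: rescaled with the square of the working range.
GMSD_C_8BIT = 170.0


def _check_pair(ref: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: ref {ref.shape} vs test {test.shape}")
    return ref, test


def psnr(ref: np.ndarray, test: np.ndarray, data_range: float = 1.0,
         mask: Optional[np.ndarray] = None) -> float:
    """Peak signal-to-noise ratio in dB: ``10*log10(data_range**2 / MSE)``.

    Returns ``inf`` for identical images (callers that aggregate should use
    :func:`evaluate_pairs`, which flags this case instead).
    """
    ref, test = _check_pair(ref, test)
    if data_range <= 0:
        raise ValueError(f"data_range must be positive, got {data_range}")
    d = (ref - test) ** 2
    mse = float(d[np.asarray(mask, bool)].mean()) if mask is not None else float(d.mean())
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(data_range**2 / mse)


def ssim(ref: np.ndarray, test: np.ndarray, data_range: float = 1.0,
         mask: Optional[np.ndarray] = None) -> float:
    """Single-scale SSIM, 11x11 Gaussian window (sigma 1.5), K1/K2 = 0.01/0.03."""
    ref, test = _check_pair(ref, test)
    if min(ref.shape) < 11:
        raise ValueError(f"image {ref.shape} smaller than the 11x11 SSIM window")
    _, smap = structural_similarity(
        ref, test, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03, full=True,
    )
    if mask is not None:
        return float(smap[np.asarray(mask, bool)].mean())
    return float(smap.mean())


def gmsd(ref: np.ndarray, test: np.ndarray, data_range: float = 1.0,
         mask: Optional[np.ndarray] = None) -> float:
    """Gradient magnitude similarity deviation (lower = more similar).

    Prewitt gradient magnitudes ``m_r``, ``m_t``; pointwise similarity
    ``(2 m_r m_t + c) / (m_r^2 + m_t^2 + c)`` with ``c`` rescaled from the
    8-bit definition; the score is the standard deviation of that map.
    """
    ref, test = _check_pair(ref, test)
    if min(ref.shape) < 3:
        raise ValueError(f"image {ref.shape} smaller than the 3x3 gradient stencil")
    c = GMSD_C_8BIT * (data_range / 255.0) ** 2
    m_r = np.hypot(convolve(ref, _PREWITT_X, mode="nearest"),
                   convolve(ref, _PREWITT_Y, mode="nearest"))
    m_t = np.hypot(convolve(test, _PREWITT_X, mode="nearest"),
                   convolve(test, _PREWITT_Y, mode="nearest"))
    gms = (2.0 * m_r * m_t + c) / (m_r**2 + m_t**2 + c)
    if mask is not None:
        gms = gms[np.asarray(mask, bool)]
    return float(gms.std())


_default_perceptual = None


def perceptual_distance(ref: np.ndarray, test: np.ndarray) -> float:
    """Default perceptual distance (fixed random-feature stack, seed 0)."""
    global _default_perceptual
    if _default_perceptual is None:
        _default_perceptual = RandomFeaturePerceptual(seed=0)
    ref, test = _check_pair(ref, test)
    return _default_perceptual(ref, test)


@dataclass
class MetricReport:
    """Per-slice metric records plus mean +/- SD aggregates.

    ``records`` holds one dict per slice (``slice_id``, ``psnr``, ``ssim``,
    ``gmsd``, ``perceptual``, ``identical``); identical pairs carry
    ``psnr=None`` and are excluded from the PSNR aggregate.  SD is the
    sample standard deviation (ddof=1; 0.0 for a single slice).
    """

    records: list[dict] = field(default_factory=list)

    def aggregates(self) -> dict[str, tuple[float, float]]:
        out = {}
        for key in ("psnr", "ssim", "gmsd", "perceptual"):
            vals = np.array([r[key] for r in self.records if r[key] is not None])
            if len(vals) == 0:
                out[key] = (float("nan"), float("nan"))
            else:
                sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
                out[key] = (float(vals.mean()), sd)
        return out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "records": self.records,
            "aggregates": {k: {"mean": m, "sd": s} for k, (m, s) in self.aggregates().items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def evaluate_pairs(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    data_range: float = 1.0,
    mask: Optional[np.ndarray] = None,
    perceptual: Optional[Callable[[np.ndarray, np.ndarray], float]] = None,
) -> MetricReport:
    """Apply all four metrics to ``(ref, test)`` pairs and aggregate."""
    if len(pairs) == 0:
        raise ValueError("evaluate_pairs needs at least one (ref, test) pair")
    if perceptual is None:
        perceptual = perceptual_distance
    records = []
    for i, (ref, test) in enumerate(pairs):
        p = psnr(ref, test, data_range, mask)
        identical = not np.isfinite(p)
        records.append(
            {
                "slice_id": i,
                "psnr": None if identical else p,
                "ssim": ssim(ref, test, data_range, mask),
                "gmsd": gmsd(ref, test, data_range, mask),
                "perceptual": perceptual(ref, test),
                "identical": identical,
            }
        )
    return MetricReport(records=records)
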