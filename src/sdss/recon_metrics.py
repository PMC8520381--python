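"""Reconstruction-quality indices for original-vs-reconstructed rasters.

Three classical tomography-style indices over an image pair (t, r):

* normalized mean square distance
  ``l = sqrt( sum (t - r)^2 / sum (t - tbar)^2 )`` -- 0 iff identical,
  larger means more deviation;
* normalized mean absolute distance
  ``f = sum |t - r| / sum |t|`` -- 0 iff identical;
* ``MSE = (1/(M N)) sum (t - r)^2`` and
  ``PSNR = 10 log10(max_value^2 / MSE)`` in dB (+inf when r = t).

Images are compared in linear intensity; log-compressed display images
should be converted back (or compared deliberately post-compression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ImagePair", "MetricReport", "metric_l", "metric_f", "mse_psnr", "evaluate"]


def _default_max_value(original: np.ndarray) -> float:
    if np.issubdtype(original.dtype, np.integer):
        return float(np.iinfo(original.dtype).max)
    peak = float(np.max(original)) if original.size else 0.0
    return peak if peak > 0 else 1.0


@dataclass
class ImagePair:
    """Original raster t and reconstructed raster r of identical shape.

    ``max_value`` is the dynamic-range ceiling used by PSNR; defaults to
    the integer dtype ceiling (255 for 8-bit) or, for float rasters, the
    peak of the original.
    """

    original: np.ndarray
    reconstructed: np.ndarray
    max_value: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.original)
        r = np.asarray(self.reconstructed)
        if t.shape != r.shape:
            raise ValueError(f"image shapes differ: {t.shape} vs {r.shape}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise ValueError("images must be finite")
        if self.max_value is None:
            self.max_value = _default_max_value(t)
        if self.max_value <= 0:
            raise ValueError("max_value must be positive")
        self.original = np.asarray(t, dtype=float)
        self.reconstructed = np.asarray(r, dtype=float)


@dataclass
class MetricReport:
    metric_l: float
    metric_f: float
    mse: float
    psnr_db: float  # +inf when the images are identical

    def as_dict(self) -> dict[str, float]:
        return {"l": self.metric_l, "f": self.metric_f,
                "mse": self.mse, "psnr_db": self.psnr_db}


def metric_l(pair: ImagePair) -> float:
    """Normalized mean square distance; normalizer is the variance about tbar.

    Raises on a constant original (zero normalizer).
    """
    t, r = pair.original, pair.reconstructed
    denom = float(np.sum((t - t.mean()) ** 2))
    if denom <= 0:
        raise ValueError("original image is constant; NMSD normalizer is zero")
    return math.sqrt(float(np.sum((t - r) ** 2)) / denom)


def metric_f(pair: ImagePair) -> float:
    """Normalized mean absolute distance; normalizer is sum |t|."""
    t, r = pair.original, pair.reconstructed
    denom = float(np.sum(np.abs(t)))
    if denom <= 0:
        raise ValueError("original image is all-zero; NMAD normalizer is zero")
    return float(np.sum(np.abs(t - r))) / denom


def mse_psnr(pair: ImagePair) -> tuple[float, float]:
    """(MSE, PSNR in dB); PSNR is +inf for identical images."""
    t, r = pair.original, pair.reconstructed
    mse = float(np.mean((t - r) ** 2))
    if mse == 0.0:
        return 0.0, math.inf
    return mse, 10.0 * math.log10(pair.max_value**2 / mse)


def evaluate(pair: ImagePair) -> MetricReport:
    """All three indices in one report."""
    mse, psnr = mse_psnr(pair)
    return MetricReport(metric_l=metric_l(pair), metric_f=metric_f(pair),
                        mse=mse, psnr_db=psnr)
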