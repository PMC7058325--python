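"""Image preparation: auto-crop, resize, CLAHE and gamma correction.

The chain mirrors common fundus-photography practice: crop away the black
border around the circular field of view to a square, resize to a working
side length, then raise local contrast with contrast-limited adaptive
histogram equalization and a power-law (gamma) brightness lift
``I_out = p * I ** gamma`` with gamma < 1.

All stages keep intensities inside [0, 1] and are deterministic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from skimage import exposure, transform

from .exceptions import ConfigurationError, DataError
from .synthetic import FundusImage


@dataclass
class PreprocessConfig:
    target_side: int = 565
    gamma: float = 1 / 1.2
    gamma_norm: float = 1.0  # the normalization factor p; 1 keeps I=1 fixed
    clahe_tiles: int = 8
    clahe_clip: float = 0.01  # clip limit as a fraction of the tile pixel count
    border_threshold: float = 0.05
    op_order: str = "clahe_then_gamma"  # or "gamma_then_clahe"

    def validate(self) -> None:
        if self.gamma <= 0 or self.gamma_norm <= 0:
            raise ConfigurationError("gamma and gamma_norm must be > 0")
        if self.clahe_tiles < 1 or self.clahe_clip <= 0:
            raise ConfigurationError("clahe_tiles >= 1 and clahe_clip > 0 required")
        if self.op_order not in ("clahe_then_gamma", "gamma_then_clahe"):
            raise ConfigurationError(f"unknown op_order {self.op_order!r}")
        if self.target_side < 8:
            raise ConfigurationError("target_side too small")


def _as_array(image) -> np.ndarray:
    pixels = image.pixels if isinstance(image, FundusImage) else np.asarray(image)
    if pixels.ndim == 3:  # RGB: operate on luminance
        pixels = pixels @ np.array([0.2126, 0.7152, 0.0722])
    if pixels.min() < -1e-9 or pixels.max() > 1 + 1e-9:
        raise DataError("intensities must lie in [0, 1]")
    return np.clip(pixels.astype(np.float64), 0.0, 1.0)


def autocrop_bounds(image, border_threshold: float = 0.05):
    """Row/column bounds of the smallest square window holding every
    above-threshold pixel (centred on the bounding box, shifted inward at
    canvas edges). Returns (r0, r1, c0, c1), end-exclusive."""
    pixels = _as_array(image)
    fg = pixels > border_threshold
    if not fg.any():
        raise DataError("empty field of view: no pixel above border_threshold")
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    side = max(r1 - r0, c1 - c0)
    h, w = pixels.shape
    side = min(side, h, w)

    def expand(lo, hi, limit):
        grow = side - (hi - lo)
        lo = lo - grow // 2
        hi = hi + (grow - grow // 2)
        if lo < 0:
            hi -= lo
            lo = 0
        if hi > limit:
            lo -= hi - limit
            hi = limit
        return lo, hi

    r0, r1 = expand(r0, r1, h)
    c0, c1 = expand(c0, c1, w)
    return r0, r1, c0, c1


def autocrop_square(image, border_threshold: float = 0.05) -> np.ndarray:
    """Smallest square window containing every above-threshold pixel;
    content is never rescaled here."""
    pixels = _as_array(image)
    r0, r1, c0, c1 = autocrop_bounds(pixels, border_threshold)
    return pixels[r0:r1, c0:c1]


def gamma_correct(image, gamma: float, norm: float = 1.0) -> np.ndarray:
    """Pointwise power-law mapping I -> clip(norm * I**gamma, 0, 1)."""
    if gamma <= 0 or norm <= 0:
        raise ConfigurationError("gamma and norm must be > 0")
    pixels = _as_array(image)
    return np.clip(norm * np.power(pixels, gamma), 0.0, 1.0)


def clahe(image, tiles: int = 8, clip: float = 0.01) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 1] image.

    ``tiles`` is the per-axis tile grid dimension and ``clip`` the histogram
    clip limit as a fraction of the tile pixel count. Degenerate constant
    images pass through unchanged.
    """
    if tiles < 1 or clip <= 0:
        raise ConfigurationError("tiles >= 1 and clip > 0 required")
    pixels = _as_array(image)
    h, w = pixels.shape
    if tiles > min(h, w):
        raise ConfigurationError("tile grid finer than the image")
    if np.ptp(pixels) < 1e-12:
        return pixels.copy()
    kernel = (max(h // tiles, 1), max(w // tiles, 1))
    out = exposure.equalize_adapthist(pixels, kernel_size=kernel, clip_limit=float(clip))
    return np.clip(out, 0.0, 1.0)


def resize_square(pixels: np.ndarray, side: int) -> np.ndarray:
    out = transform.resize(
        pixels, (side, side), order=1, anti_aliasing=True, preserve_range=True
    )
    return np.clip(out, 0.0, 1.0)


def enhance(image, config: PreprocessConfig | None = None) -> FundusImage:
    """Full chain: autocrop -> resize -> CLAHE and gamma (configured order)."""
    config = config or PreprocessConfig()
    config.validate()
    pixels = autocrop_square(image, config.border_threshold)
    pixels = resize_square(pixels, config.target_side)
    if config.op_order == "clahe_then_gamma":
        pixels = clahe(pixels, config.clahe_tiles, config.clahe_clip)
        pixels = gamma_correct(pixels, config.gamma, config.gamma_norm)
    else:
        pixels = gamma_correct(pixels, config.gamma, config.gamma_norm)
        pixels = clahe(pixels, config.clahe_tiles, config.clahe_clip)
    label = getattr(image, "label", None)
    subject = getattr(image, "subject_id", None)
    return FundusImage(pixels=pixels, label=label, subject_id=subject, provenance="enhanced")


def enhance_cohort(cohort, config: PreprocessConfig | None = None):
    """Enhance every record of a cohort in place-preserving copy."""
    out = dataclasses.replace(cohort)
    out.records = [
        dataclasses.replace(rec, image=enhance(rec.image, config)) for rec in cohort.records
    ]
    return out


def rms_local_contrast(pixels: np.ndarray, window: int = 9) -> float:
    """Root-mean-square of the sliding-window standard deviation."""
    from scipy.ndimage import uniform_filter

    mean = uniform_filter(pixels, window)
    sq = uniform_filter(pixels * pixels, window)
    var = np.clip(sq - mean * mean, 0.0, None)
    return float(np.sqrt(var.mean()))
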