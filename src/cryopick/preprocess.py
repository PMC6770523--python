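"""Quality-improvement chain applied before clustering.

Cryo-EM micrographs are recorded at very low electron dose, so the particle
signal sits barely above shot noise.  The chain stacks standard restoration
and contrast operators, in a fixed order, each individually callable and
skippable:

1. ``downscale``  — anti-aliased resolution reduction (noise averaging);
2. ``normalize``  — global min-max normalization to [0, 1];
3. ``hist_eq``    — global histogram equalization;
4. ``wiener``     — adaptive Wiener noise suppression;
5. ``clahe``      — contrast-limited adaptive histogram equalization;
6. ``guided``     — edge-preserving guided filtering;
7. ``morph``      — morphological particle localization (opening then closing),
                    off by default and enabled ahead of base clustering only.

Every step maps [0, 1] images to [0, 1] images and is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import wiener as _scipy_wiener
from skimage import exposure, morphology, transform

from .errors import ParameterError
from .micrograph import Micrograph

__all__ = [
    "PreprocessConfig",
    "DEFAULT_STEPS",
    "preprocess",
    "downscale",
    "normalize01",
    "hist_equalize",
    "wiener_denoise",
    "clahe",
    "guided_filter",
    "morph_localize",
]

DEFAULT_STEPS: tuple[str, ...] = (
    "downscale",
    "normalize",
    "hist_eq",
    "wiener",
    "clahe",
    "guided",
)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the pre-processing chain.

    All length-like values are in pixels of the input image.  ``morph_auto``
    lets the picking pipeline flip the morphological localization step on for
    base clustering and off for super-clustering, where the posterized masks
    are already clean.
    """

    downscale_factor: float = 1.0
    wiener_window: int = 5
    clahe_tile: int = 64
    clahe_clip: float = 0.01
    guided_radius: int = 4
    guided_eps: float = 0.0001  # 0.01 ** 2
    morph_radius: int = 2
    steps_enabled: tuple[str, ...] = DEFAULT_STEPS
    morph_auto: bool = True

    def __post_init__(self) -> None:
        if self.downscale_factor <= 0:
            raise ParameterError("downscale_factor must be positive")
        if self.wiener_window < 1 or self.wiener_window % 2 == 0:
            raise ParameterError(f"wiener_window must be an odd positive integer, got {self.wiener_window}")
        if self.clahe_tile < 1 or self.guided_radius < 1 or self.morph_radius < 1:
            raise ParameterError("clahe_tile, guided_radius and morph_radius must be >= 1")
        if not (0 < self.clahe_clip <= 1):
            raise ParameterError("clahe_clip must lie in (0, 1]")
        if self.guided_eps <= 0:
            raise ParameterError("guided_eps must be positive")
        unknown = set(self.steps_enabled) - set(DEFAULT_STEPS) - {"morph"}
        if unknown:
            raise ParameterError(f"unknown preprocessing steps: {sorted(unknown)}")


def _clip01(img: np.ndarray) -> np.ndarray:
    return np.clip(img, 0.0, 1.0)


def downscale(img: np.ndarray, factor: float) -> np.ndarray:
    """Anti-aliased downsampling by ``factor`` (1 = no-op)."""
    if factor == 1.0:
        return img
    out = transform.rescale(img, 1.0 / factor, anti_aliasing=factor > 1.0, preserve_range=True)
    return _clip01(out)


def normalize01(img: np.ndarray) -> np.ndarray:
    """Min-max normalization; a flat image maps to constant 0.5."""
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.full_like(img, 0.5)
    return (img - lo) / (hi - lo)


def hist_equalize(img: np.ndarray) -> np.ndarray:
    """Global histogram equalization (empirical-CDF intensity mapping)."""
    return _clip01(exposure.equalize_hist(img))


def wiener_denoise(img: np.ndarray, window: int) -> np.ndarray:
    """Adaptive (locally estimated) Wiener filtering with a square window."""
    if window > min(img.shape):
        raise ParameterError(
            f"wiener_window {window} exceeds the smallest image dimension {min(img.shape)}"
        )
    if float(img.std()) == 0.0:
        return img  # zero noise estimate would produce 0/0
    out = _scipy_wiener(img, mysize=window)
    return _clip01(np.nan_to_num(out, nan=float(img.mean())))


def clahe(img: np.ndarray, tile: int, clip: float) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization."""
    tile = min(tile, min(img.shape))
    return _clip01(exposure.equalize_adapthist(img, kernel_size=tile, clip_limit=clip))


def guided_filter(img: np.ndarray, radius: int, eps: float) -> np.ndarray:
    """Self-guided edge-preserving filter (box-filter formulation).

    Smooths within near-homogeneous regions while preserving edges whose local
    variance exceeds ``eps``.
    """
    size = 2 * radius + 1
    mean = uniform_filter(img, size=size, mode="reflect")
    corr = uniform_filter(img * img, size=size, mode="reflect")
    var = np.maximum(corr - mean * mean, 0.0)
    a = var / (var + eps)
    b = (1.0 - a) * mean
    mean_a = uniform_filter(a, size=size, mode="reflect")
    mean_b = uniform_filter(b, size=size, mode="reflect")
    return _clip01(mean_a * img + mean_b)


def morph_localize(img: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening then closing with a disk — suppresses small bright
    and dark specks while keeping particle-scale structure."""
    footprint = morphology.disk(radius)
    out = morphology.opening(img, footprint)
    out = morphology.closing(out, footprint)
    return _clip01(out)


def preprocess(m: Micrograph, cfg: PreprocessConfig | None = None) -> Micrograph:
    """Run the enabled steps, in canonical order, on a [0, 1] micrograph.

    Disabling every step returns the input unchanged.  The chain is fully
    deterministic: identical input and config give bit-identical output.
    """
    cfg = cfg or PreprocessConfig()
    img = m.pixels
    order = [s for s in (*DEFAULT_STEPS, "morph") if s in cfg.steps_enabled]
    for step in order:
        if step == "downscale":
            img = downscale(img, cfg.downscale_factor)
        elif step == "normalize":
            img = normalize01(img)
        elif step == "hist_eq":
            img = hist_equalize(img)
        elif step == "wiener":
            img = wiener_denoise(img, cfg.wiener_window)
        elif step == "clahe":
            img = clahe(img, cfg.clahe_tile, cfg.clahe_clip)
        elif step == "guided":
            img = guided_filter(img, cfg.guided_radius, cfg.guided_eps)
        elif step == "morph":
            img = morph_localize(img, cfg.morph_radius)
    return replace(m, pixels=img)
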