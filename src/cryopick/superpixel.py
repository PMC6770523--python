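"""SLIC superpixel over-segmentation and posterization.

SLIC (simple linear iterative clustering) seeds ~k cluster centers on a
regular grid of spacing ``S = sqrt(N/k)``, nudges each seed to the lowest
gradient position in its 3x3 neighborhood, then iterates a localized k-means:
each center only competes for pixels within a (2S)x(2S) window around itself,
under the combined distance

    D = sqrt(dc^2 + (ds / S)^2 * m^2)

where ``dc`` is the absolute intensity difference, ``ds`` the Euclidean
spatial distance and ``m`` the compactness constant weighting spatial
regularity against intensity homogeneity.  Pixels take the label of their
nearest center (ties to the lowest center id), centers move to the mean
(intensity, x, y) of their members, and iteration stops when the summed
spatial center displacement E drops below ``residual_tol``.

Posterization replaces every pixel by its superpixel's mean intensity,
producing the piecewise-constant "intermediate image" that the
super-clustering variants cluster instead of raw pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .micrograph import Micrograph

__all__ = [
    "SlicParams",
    "SuperPixelMap",
    "SlicSnapshot",
    "slic",
    "slic_history",
    "posterize",
    "gradient_magnitude",
    "default_k",
]


def default_k(shape: tuple[int, int]) -> int:
    """Default superpixel count: one per ~16x16 px block, so superpixels stay
    smaller than particles (which span tens of pixels)."""
    return max(4, (shape[0] * shape[1]) // 256)


@dataclass(frozen=True)
class SlicParams:
    """SLIC parameters.

    ``k_superpixels=None`` resolves to :func:`default_k` of the image.
    ``compactness`` is the constant m on the [0, 1] intensity scale.  The
    default 1.5 keeps superpixels spatially coherent even when per-pixel noise
    is comparable to the particle contrast: with a much smaller m the
    intensity term dominates and each "superpixel" degenerates into scattered
    same-intensity speckle, which defeats both posterization and the
    component-count cluster selection downstream.  ``residual_tol`` bounds the
    total spatial center displacement E (in pixels) at convergence.
    """

    k_superpixels: int | None = None
    compactness: float = 1.5
    max_iters: int = 10
    residual_tol: float = 1.0

    def __post_init__(self) -> None:
        if self.k_superpixels is not None and self.k_superpixels < 1:
            raise ParameterError(f"k_superpixels must be >= 1, got {self.k_superpixels}")
        if self.compactness <= 0:
            raise ParameterError("compactness must be positive")
        if self.max_iters < 1:
            raise ParameterError("max_iters must be >= 1")
        if self.residual_tol < 0:
            raise ParameterError("residual_tol must be non-negative")


@dataclass(frozen=True)
class SuperPixelMap:
    """Per-pixel superpixel labels (1-based) plus per-superpixel centers.

    ``centers`` has one row (intensity, x, y) per superpixel; row ``i``
    corresponds to label ``i + 1``.  ``grid_interval`` is the seeding spacing
    S = sqrt(N/k).
    """

    labels: np.ndarray
    centers: np.ndarray
    grid_interval: float

    @property
    def n_superpixels(self) -> int:
        return self.centers.shape[0]


@dataclass(frozen=True)
class SlicSnapshot:
    """State after one SLIC iteration.

    ``cost`` is the sum of D over pixels and ``cost_sq`` the sum of D^2, both
    w.r.t. the centers the assignment used.  Mean updates minimize the
    *squared* cost, so ``cost_sq`` is the quantity guaranteed to be
    non-increasing; the unsquared sum tracks it closely but may fluctuate.
    ``residual`` is the summed spatial center displacement E."""

    labels: np.ndarray
    centers: np.ndarray
    cost: float
    cost_sq: float
    residual: float


def gradient_magnitude(m: Micrograph | np.ndarray) -> np.ndarray:
    """Central-difference gradient magnitude; one-sided at the borders."""
    img = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=np.float64)
    if img.shape[0] > 1 and img.shape[1] > 1:
        gy, gx = np.gradient(img)
    elif img.shape[0] > 1:
        gy, gx = np.gradient(img, axis=0), np.zeros_like(img)
    elif img.shape[1] > 1:
        gy, gx = np.zeros_like(img), np.gradient(img, axis=1)
    else:
        return np.zeros_like(img)
    return np.hypot(gy, gx)


def _seed_grid(shape: tuple[int, int], k: int) -> tuple[int, int]:
    """Choose a seeding grid of at most k centers roughly matching the image
    aspect ratio."""
    h, w = shape
    n_rows = max(1, int(round(np.sqrt(k * h / w))))
    n_cols = max(1, int(round(k / n_rows)))
    while n_rows * n_cols > k:
        if n_cols >= n_rows and n_cols > 1:
            n_cols -= 1
        elif n_rows > 1:
            n_rows -= 1
        else:
            break
    return n_rows, n_cols


def _init_centers(img: np.ndarray, k: int) -> np.ndarray:
    """Grid seeds perturbed to the lowest-gradient position in a 3x3
    neighborhood (the seed itself wins gradient ties, so a flat image keeps
    the unperturbed grid)."""
    h, w = img.shape
    grad = gradient_magnitude(img)
    n_rows, n_cols = _seed_grid((h, w), k)
    centers = []
    for r in range(n_rows):
        for c in range(n_cols):
            py = min(h - 1, int(round((r + 0.5) * h / n_rows - 0.5)))
            px = min(w - 1, int(round((c + 0.5) * w / n_cols - 0.5)))
            best = (py, px)
            best_g = grad[py, px]
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = py + dy, px + dx
                    if 0 <= ny < h and 0 <= nx < w and grad[ny, nx] < best_g:
                        best_g = grad[ny, nx]
                        best = (ny, nx)
            centers.append((img[best], float(best[1]), float(best[0])))
    return np.asarray(centers, dtype=np.float64)


def _assign(img: np.ndarray, centers: np.ndarray, S: float, m: float):
    """Assign every pixel to its best center within the (2S)x(2S) windows.

    A center's window is all pixels with |y - cy| <= S and |x - cx| <= S.
    Returns 0-based labels (-1 for orphans, fixed up by the caller), the
    per-pixel best squared distance, and nothing else.
    """
    h, w = img.shape
    best_d2 = np.full((h, w), np.inf)
    labels = np.full((h, w), -1, dtype=np.int64)
    w2 = (m * m) / (S * S)
    for ci in range(centers.shape[0]):
        l, cx, cy = centers[ci]
        y0 = max(0, int(np.ceil(cy - S)))
        y1 = min(h - 1, int(np.floor(cy + S)))
        x0 = max(0, int(np.ceil(cx - S)))
        x1 = min(w - 1, int(np.floor(cx + S)))
        if y0 > y1 or x0 > x1:
            continue
        win = img[y0 : y1 + 1, x0 : x1 + 1]
        yy = np.arange(y0, y1 + 1, dtype=np.float64)[:, None] - cy
        xx = np.arange(x0, x1 + 1, dtype=np.float64)[None, :] - cx
        d2 = (win - l) ** 2 + (yy * yy + xx * xx) * w2
        sub = best_d2[y0 : y1 + 1, x0 : x1 + 1]
        upd = d2 < sub  # strict: earlier (lower-id) centers keep ties
        sub[upd] = d2[upd]
        labels[y0 : y1 + 1, x0 : x1 + 1][upd] = ci
    return labels, best_d2


def _fix_orphans(labels: np.ndarray, best_d2: np.ndarray, img: np.ndarray, centers: np.ndarray) -> None:
    """Assign pixels never covered by any window to the spatially nearest
    center (ties to the lowest id); their cost contribution is spatial-only."""
    orphan = labels < 0
    if not orphan.any():
        return
    ys, xs = np.nonzero(orphan)
    d2 = (ys[:, None] - centers[None, :, 2]) ** 2 + (xs[:, None] - centers[None, :, 1]) ** 2
    nearest = np.argmin(d2, axis=1)
    labels[ys, xs] = nearest
    best_d2[ys, xs] = d2[np.arange(len(ys)), nearest]


def _update_centers(img: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, float]:
    """Move each center to the mean (intensity, x, y) of its members; an empty
    cluster keeps its previous center.  Returns the new centers and the summed
    spatial displacement E."""
    n = centers.shape[0]
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=n).astype(np.float64)
    h, w = img.shape
    ys, xs = np.mgrid[0:h, 0:w]
    sum_l = np.bincount(flat, weights=img.ravel(), minlength=n)
    sum_x = np.bincount(flat, weights=xs.ravel().astype(np.float64), minlength=n)
    sum_y = np.bincount(flat, weights=ys.ravel().astype(np.float64), minlength=n)
    new = centers.copy()
    nz = counts > 0
    new[nz, 0] = sum_l[nz] / counts[nz]
    new[nz, 1] = sum_x[nz] / counts[nz]
    new[nz, 2] = sum_y[nz] / counts[nz]
    residual = float(np.hypot(new[:, 1] - centers[:, 1], new[:, 2] - centers[:, 2]).sum())
    return new, residual


def slic_history(m: Micrograph | np.ndarray, p: SlicParams | None = None) -> list[SlicSnapshot]:
    """Run SLIC, recording a snapshot after every iteration (for diagnostics
    and for validating against brute-force reference implementations)."""
    img = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=np.float64)
    p = p or SlicParams()
    N = img.size
    k = p.k_superpixels if p.k_superpixels is not None else default_k(img.shape)
    if k > N:
        raise ParameterError(f"k_superpixels={k} exceeds the pixel count {N}")
    S = float(np.sqrt(N / k))
    centers = _init_centers(img, k)
    history: list[SlicSnapshot] = []
    for _ in range(p.max_iters):
        labels, best_d2 = _assign(img, centers, S, p.compactness)
        _fix_orphans(labels, best_d2, img, centers)
        cost = float(np.sqrt(best_d2).sum())
        cost_sq = float(best_d2.sum())
        centers, residual = _update_centers(img, labels, centers)
        history.append(SlicSnapshot(labels=labels + 1, centers=centers.copy(),
                                    cost=cost, cost_sq=cost_sq, residual=residual))
        if residual <= p.residual_tol:
            break
    return history


def slic(m: Micrograph | np.ndarray, p: SlicParams | None = None) -> SuperPixelMap:
    """SLIC over-segmentation.  See the module docstring for the algorithm."""
    img = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=np.float64)
    p = p or SlicParams()
    k = p.k_superpixels if p.k_superpixels is not None else default_k(img.shape)
    history = slic_history(img, replace(p, k_superpixels=k))
    last = history[-1]
    S = float(np.sqrt(img.size / k))
    return SuperPixelMap(labels=last.labels, centers=last.centers, grid_interval=S)


def posterize(m: Micrograph | np.ndarray, spm: SuperPixelMap) -> Micrograph:
    """Replace each pixel by its superpixel's mean intensity.

    Intensity-conserving per superpixel: the region mean of the output equals
    the region mean of the input.
    """
    img = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=np.float64)
    if spm.labels.shape != img.shape:
        raise ParameterError(
            f"superpixel map shape {spm.labels.shape} does not match image shape {img.shape}"
        )
    flat = spm.labels.ravel() - 1
    n = spm.n_superpixels
    counts = np.bincount(flat, minlength=n).astype(np.float64)
    sums = np.bincount(flat, weights=img.ravel(), minlength=n)
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    out = np.clip(means[flat].reshape(img.shape), 0.0, 1.0)
    src = m.source if isinstance(m, Micrograph) else ""
    return Micrograph(out, source=f"posterized:{src}")
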