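"""1-D intensity clusterers and the super-clustering variants.

Three interchangeable base clusterers operate on pixel intensities alone:

* **IBC** (intensity-based clustering): the cluster count K and the initial
  centers come from dividing the image's intensity range [v_min, v_max] into
  fixed-size intervals (default width 0.15); Lloyd iterations then refine the
  interval midpoints.
* **k-means**: Lloyd's algorithm on scalar intensities, initialized from the
  same IBC interval midpoints so the whole pipeline is deterministic.
* **FCM** (fuzzy c-means): soft memberships u_nk proportional to inverse
  distance ratios raised to 2/(fuzzifier-1), centers updated as
  membership^fuzzifier-weighted means; hard assignment by argmax.

Super-clustering runs SLIC, posterizes the image to superpixel means, and
clusters the posterized image instead of raw pixels.  The particle cluster is
then selected fully automatically as the binary mask with the smallest
positive count of 8-connected components — particles form few compact blobs
while background clusters shatter into many fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from skimage import measure

from .errors import DegenerateInputError, ParameterError
from .micrograph import Micrograph
from .superpixel import SlicParams, SuperPixelMap, posterize, slic

__all__ = [
    "IbcInit",
    "ClusterResult",
    "SuperClusterResult",
    "ibc_init",
    "ibc_init_from_range",
    "ibc_cluster",
    "kmeans_cluster",
    "fcm_cluster",
    "select_particle_cluster",
    "super_cluster",
    "base_cluster",
    "SUPER_METHODS",
    "BASE_METHODS",
]

BASE_METHODS = ("kmeans", "fcm", "ibc")
SUPER_METHODS = ("sp_kmeans", "sp_fcm", "sp_ibc")

_MAX_LLOYD_ITERS = 300


@dataclass(frozen=True)
class IbcInit:
    """IBC interval initialization: K ascending bins over [v_min, v_max]."""

    v_min: float
    v_max: float
    interval_size: float
    K: int
    boundaries: tuple[float, ...]
    centers: tuple[float, ...]


@dataclass
class ClusterResult:
    """Hard partition of an image into K intensity clusters.

    ``assignment`` holds 0-based cluster ids; ``memberships`` (FCM only) is a
    (K, h, w) stack of soft weights summing to 1 per pixel.
    """

    K: int
    centers: np.ndarray
    assignment: np.ndarray
    memberships: np.ndarray | None = None

    @cached_property
    def cluster_masks(self) -> list[np.ndarray]:
        """K pairwise-disjoint binary masks whose union is the full image."""
        return [self.assignment == k for k in range(self.K)]


@dataclass(frozen=True)
class SuperClusterResult:
    """Outcome of a super-clustering run: the base-clusterer result on the
    posterized image, the automatically selected particle mask, and the
    intermediate products for inspection."""

    cluster: ClusterResult
    selected_index: int
    mask: np.ndarray
    superpixels: SuperPixelMap
    posterized: Micrograph


# ---------------------------------------------------------------------------
# IBC initialization
# ---------------------------------------------------------------------------


def ibc_init_from_range(v_min: float, v_max: float, interval_size: float = 0.15) -> IbcInit:
    """Interval initialization from an explicit intensity range.

    K = round((v_max - v_min) / interval_size), at least 2.  Boundaries are
    v_min + j * interval_size with the last boundary clamped to v_max; centers
    are the interval midpoints.
    """
    if interval_size <= 0:
        raise ParameterError("interval_size must be positive")
    if not v_max > v_min:
        raise DegenerateInputError(
            f"degenerate intensity range [{v_min}, {v_max}]: cannot derive clusters from a flat image"
        )
    K = max(2, int(round((v_max - v_min) / interval_size)))
    boundaries = [v_min + j * interval_size for j in range(K + 1)]
    boundaries[-1] = v_max
    if boundaries[-1] <= boundaries[-2]:  # range shorter than K intervals
        boundaries = list(np.linspace(v_min, v_max, K + 1))
    centers = [(boundaries[j] + boundaries[j + 1]) / 2.0 for j in range(K)]
    return IbcInit(
        v_min=float(v_min),
        v_max=float(v_max),
        interval_size=float(interval_size),
        K=K,
        boundaries=tuple(float(b) for b in boundaries),
        centers=tuple(float(c) for c in centers),
    )


def ibc_init(m: Micrograph | np.ndarray, interval_size: float = 0.15) -> IbcInit:
    """Interval initialization from an image's observed intensity range."""
    img = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=np.float64)
    return ibc_init_from_range(float(img.min()), float(img.max()), interval_size)


# ---------------------------------------------------------------------------
# Lloyd-style hard clustering (shared by IBC and k-means)
# ---------------------------------------------------------------------------


def _compact(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse an image to (unique values, multiplicities, inverse map).

    Intensity clustering only depends on the value histogram, so iterating on
    weighted unique values is exactly equivalent to iterating on pixels and
    far cheaper on quantized or posterized images.
    """
    vals, inv, counts = np.unique(img.ravel(), return_inverse=True, return_counts=True)
    return vals, counts.astype(np.float64), inv


def _lloyd_1d(img: np.ndarray, centers0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd iterations on scalar intensities.

    Assignment: nearest center by absolute intensity difference, ties to the
    lowest cluster id.  Update: each center becomes the mean of its members;
    an empty cluster keeps its previous center.  Stops when no center changes.
    """
    vals, weights, inv = _compact(img)
    centers = np.asarray(centers0, dtype=np.float64).copy()
    K = centers.size
    labels = np.zeros(vals.size, dtype=np.int64)
    for _ in range(_MAX_LLOYD_ITERS):
        labels = np.argmin(np.abs(vals[:, None] - centers[None, :]), axis=1)
        counts = np.bincount(labels, weights=weights, minlength=K)
        sums = np.bincount(labels, weights=vals * weights, minlength=K)
        new = centers.copy()
        nz = counts > 0
        new[nz] = sums[nz] / counts[nz]
        if np.array_equal(new, centers):
            break
        centers = new
    return centers, labels[inv].reshape(img.shape)


def ibc_cluster(m: Micrograph | np.ndarray, init: IbcInit) -> ClusterResult:
    """Refine IBC interval midpoints with deterministic Lloyd iterations."""
    img = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=np.float64)
    centers, assignment = _lloyd_1d(img, np.asarray(init.centers))
    return ClusterResult(K=init.K, centers=centers, assignment=assignment)


def kmeans_cluster(m: Micrograph | np.ndarray, K: int, interval_size: float = 0.15) -> ClusterResult:
    """Deterministic 1-D k-means.

    Initialization uses the midpoints of K equal intervals spanning the
    image's intensity range (no random seeding anywhere), so repeated runs are
    bit-identical.
    """
    img = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=np.float64)
    if K < 2:
        raise ParameterError(f"K must be >= 2, got {K}")
    lo, hi = float(img.min()), float(img.max())
    if not hi > lo:
        raise DegenerateInputError("flat image: k-means on a single intensity is degenerate")
    n_distinct = np.unique(img).size
    if K > n_distinct:
        raise DegenerateInputError(
            f"K={K} exceeds the number of distinct intensities ({n_distinct})"
        )
    edges = np.linspace(lo, hi, K + 1)
    centers0 = (edges[:-1] + edges[1:]) / 2.0
    centers, assignment = _lloyd_1d(img, centers0)
    return ClusterResult(K=K, centers=centers, assignment=assignment)


# ---------------------------------------------------------------------------
# Fuzzy c-means
# ---------------------------------------------------------------------------


def fcm_cluster(
    m: Micrograph | np.ndarray,
    K: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    max_iters: int = _MAX_LLOYD_ITERS,
) -> ClusterResult:
    """Fuzzy c-means on scalar intensities.

    Membership of pixel n in cluster k:

        u_nk = [ sum_i (d(x_n, c_k) / d(x_n, c_i)) ** (2 / (fuzzifier - 1)) ] ** -1

    A pixel coinciding exactly with a center gets membership 1 there (split
    equally if several centers coincide).  Centers update to the
    u^fuzzifier-weighted mean; iteration stops when the largest center change
    is <= ``tol``.  Hard assignment is argmax membership, ties to the lowest
    cluster id.  Initialization: midpoints of K equal intensity intervals.
    """
    img = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=np.float64)
    if K < 2:
        raise ParameterError(f"K must be >= 2, got {K}")
    if fuzzifier <= 1:
        raise ParameterError(f"fuzzifier must be > 1, got {fuzzifier}")
    lo, hi = float(img.min()), float(img.max())
    if not hi > lo:
        raise DegenerateInputError("flat image: FCM on a single intensity is degenerate")
    vals, weights, inv_map = _compact(img)
    edges = np.linspace(lo, hi, K + 1)
    centers = ((edges[:-1] + edges[1:]) / 2.0).astype(np.float64)
    expo = 2.0 / (fuzzifier - 1.0)
    u = np.full((vals.size, K), 1.0 / K)
    for _ in range(max_iters):
        d = np.abs(vals[:, None] - centers[None, :])
        zero = d == 0.0
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d ** (-expo)
            u = inv / inv.sum(axis=1, keepdims=True)
        if any_zero.any():
            z = zero[any_zero]
            u[any_zero] = z / z.sum(axis=1, keepdims=True)
        um = (u**fuzzifier) * weights[:, None]
        new = (um * vals[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = float(np.abs(new - centers).max())
        centers = new
        if shift <= tol:
            break
    assignment = np.argmax(u, axis=1)[inv_map].reshape(img.shape)
    memberships = u[inv_map].T.reshape(K, *img.shape)
    return ClusterResult(K=K, centers=centers, assignment=assignment, memberships=memberships)


# ---------------------------------------------------------------------------
# Automated particle-cluster selection and super-clustering
# ---------------------------------------------------------------------------


def _component_count(mask: np.ndarray, connectivity: int) -> int:
    conn = 2 if connectivity == 8 else 1
    return int(measure.label(mask, connectivity=conn).max())


def select_particle_cluster(r: ClusterResult, connectivity: int = 8) -> int:
    """Pick the cluster whose binary mask has the fewest connected blobs.

    Particles cluster into a handful of compact components, while noise and
    background clusters fragment into many; the mask with the smallest
    positive component count is therefore the particle cluster.  Ties break by
    smaller total foreground area, then by lower cluster index.  Empty masks
    are ineligible.
    """
    if connectivity not in (4, 8):
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    best: tuple[int, int, int] | None = None
    for idx, mask in enumerate(r.cluster_masks):
        n = _component_count(mask, connectivity)
        if n == 0:
            continue
        key = (n, int(mask.sum()), idx)
        if best is None or key < best:
            best = key
    if best is None:
        raise DegenerateInputError("all cluster masks are empty: nothing to select")
    return best[2]


def base_cluster(
    m: Micrograph | np.ndarray,
    method: str,
    interval_size: float = 0.15,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    quantize_levels: int | None = 256,
) -> ClusterResult:
    """Dispatch one of the three base clusterers with the IBC-derived K.

    Intensities are first quantized to ``quantize_levels`` evenly spaced
    levels (default 256 — the native resolution of the 8-bit PNG micrographs
    the method consumes); clustering on the weighted value histogram is then
    exact and cheap.  Pass ``None`` to cluster the raw float intensities.
    """
    method = method.replace("-", "_")
    if method not in BASE_METHODS:
        raise ParameterError(f"unknown base method {method!r}; expected one of {BASE_METHODS}")
    img = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=np.float64)
    if quantize_levels is not None:
        if quantize_levels < 2:
            raise ParameterError("quantize_levels must be >= 2")
        img = np.round(img * (quantize_levels - 1)) / (quantize_levels - 1)
    init = ibc_init(img, interval_size)
    if method == "ibc":
        return ibc_cluster(img, init)
    if method == "kmeans":
        return kmeans_cluster(img, K=init.K, interval_size=interval_size)
    return fcm_cluster(img, K=init.K, fuzzifier=fuzzifier, tol=tol)


def super_cluster(
    m: Micrograph | np.ndarray,
    method: str,
    slic_params: SlicParams | None = None,
    interval_size: float = 0.15,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    connectivity: int = 8,
    superpixels: SuperPixelMap | None = None,
) -> SuperClusterResult:
    """SLIC -> posterize -> base clusterer -> automatic cluster selection.

    ``superpixels`` may carry a precomputed SLIC map (it must come from this
    image); otherwise SLIC runs here.  Fully automated: no interactive choice
    anywhere.
    """
    method = method.replace("-", "_")
    if method not in SUPER_METHODS:
        raise ParameterError(f"unknown super method {method!r}; expected one of {SUPER_METHODS}")
    spm = superpixels if superpixels is not None else slic(m, slic_params)
    post = posterize(m, spm)
    result = base_cluster(post, method.removeprefix("sp_"), interval_size, fuzzifier, tol)
    idx = select_particle_cluster(result, connectivity)
    return SuperClusterResult(
        cluster=result,
        selected_index=idx,
        mask=result.cluster_masks[idx],
        superpixels=spm,
        posterized=post,
    )
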