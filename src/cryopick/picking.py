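"""Particle detection and the end-to-end picking pipeline.

``detect_particles`` turns a cleaned binary mask into one particle per
connected component, with centroid, bounding box and area.  ``pick`` chains
the full pipeline — preprocess, (super-)cluster, automatic cluster selection,
mask cleaning (base methods only by default), detection — under one config
object, with no randomness anywhere.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, replace

import numpy as np
from skimage import measure

from .cluster import BASE_METHODS, SUPER_METHODS, base_cluster, select_particle_cluster, super_cluster
from .config import PipelineConfig
from .errors import ParameterError
from .mask import clean_mask
from .micrograph import Micrograph
from .preprocess import DEFAULT_STEPS, preprocess
from .superpixel import SuperPixelMap

logger = logging.getLogger(__name__)

__all__ = ["Particle", "ParticleSet", "detect_particles", "pick", "pick_with_report"]


@dataclass(frozen=True)
class Particle:
    """One picked particle in 0-based image coordinates (x = column)."""

    id: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (x, y, w, h)
    area: int
    touches_border: bool = False


@dataclass(frozen=True)
class ParticleSet:
    """All particles picked from one micrograph, ids consecutive from 1."""

    particles: list[Particle]
    image_shape: tuple[int, int]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.particles)

    def centroids(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids."""
        if not self.particles:
            return np.empty((0, 2))
        return np.asarray([p.centroid for p in self.particles], dtype=np.float64)


def detect_particles(
    mask: np.ndarray,
    box_mode: str = "tight",
    box_size: int | None = None,
    min_area: int = 1,
    provenance: str = "",
) -> ParticleSet:
    """One particle per 8-connected component of a cleaned binary mask.

    ``tight`` boxes hug the component; ``fixed`` centers a ``box_size`` square
    on the centroid, clipped at the image border.  Components are numbered in
    raster order of their first pixel.  Components touching the border are
    kept but flagged.  ``min_area`` enforces the particle contract that every
    emitted particle covers at least that many pixels — sub-particle debris
    (e.g. stray pixels of non-contiguous superpixels) is never a particle.
    """
    if box_mode not in ("tight", "fixed"):
        raise ParameterError(f"box_mode must be 'tight' or 'fixed', got {box_mode!r}")
    if box_mode == "fixed" and (box_size is None or box_size < 1):
        raise ParameterError("box_mode='fixed' requires a positive box_size")
    m = np.asarray(mask).astype(bool)
    h, w = m.shape
    labels = measure.label(m, connectivity=2)
    particles: list[Particle] = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        cy, cx = region.centroid
        if box_mode == "tight":
            bbox = (int(c0), int(r0), int(c1 - c0), int(r1 - r0))
        else:
            half = box_size // 2
            x0 = int(round(cx)) - half
            y0 = int(round(cy)) - half
            x0 = max(0, min(x0, w - box_size)) if box_size <= w else 0
            y0 = max(0, min(y0, h - box_size)) if box_size <= h else 0
            bbox = (x0, y0, min(box_size, w), min(box_size, h))
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        particles.append(
            Particle(
                id=len(particles) + 1,  # consecutive even when debris is skipped
                centroid=(float(cx), float(cy)),
                bbox=bbox,
                area=int(region.area),
                touches_border=touches,
            )
        )
    return ParticleSet(particles=particles, image_shape=(h, w), provenance=provenance)


def _scale_to_input(ps: ParticleSet, factor: float, shape: tuple[int, int]) -> ParticleSet:
    """Map particles from the downscaled working frame back to the input frame."""
    if factor == 1.0:
        return replace(ps, image_shape=shape)
    out = []
    off = (factor - 1.0) / 2.0  # center of the block a working pixel averages
    for p in ps.particles:
        cx, cy = p.centroid
        x, y, w, h = p.bbox
        x2 = int(round(x * factor))
        y2 = int(round(y * factor))
        out.append(
            replace(
                p,
                centroid=(cx * factor + off, cy * factor + off),
                bbox=(
                    min(x2, shape[1] - 1),
                    min(y2, shape[0] - 1),
                    min(int(round(w * factor)), shape[1] - x2),
                    min(int(round(h * factor)), shape[0] - y2),
                ),
            )
        )
    return ParticleSet(particles=out, image_shape=shape, provenance=ps.provenance)


def _effective_preprocess(cfg: PipelineConfig, is_super: bool):
    """Morphological localization is on for base clustering, off for
    super-clustering (whose posterized masks are already clean), unless
    ``morph_auto`` is disabled and the user's step list stands as given."""
    pre = cfg.preprocess
    if not pre.morph_auto:
        return pre
    steps = tuple(s for s in pre.steps_enabled if s != "morph")
    if not is_super:
        steps = steps + ("morph",)
    return replace(pre, steps_enabled=steps)


def pick_with_report(
    m: Micrograph,
    cfg: PipelineConfig | None = None,
    superpixels: SuperPixelMap | None = None,
) -> tuple[ParticleSet, dict]:
    """Run the full picking pipeline and return (particles, run report).

    The report carries per-stage wall times and counts (superpixels, clusters,
    components, particles) for the run manifest.
    """
    cfg = cfg or PipelineConfig()
    method = cfg.cluster.method.replace("-", "_")
    if method not in BASE_METHODS + SUPER_METHODS:
        raise ParameterError(
            f"unknown method {method!r}; expected one of {BASE_METHODS + SUPER_METHODS}"
        )
    is_super = method in SUPER_METHODS
    report: dict = {"method": method, "timings_s": {}, "counts": {}}

    t0 = time.perf_counter()
    work = preprocess(m.normalized(), _effective_preprocess(cfg, is_super))
    report["timings_s"]["preprocess"] = round(time.perf_counter() - t0, 4)

    t0 = time.perf_counter()
    if is_super:
        sc = super_cluster(
            work,
            method,
            slic_params=cfg.slic,
            interval_size=cfg.cluster.interval_size,
            fuzzifier=cfg.cluster.fuzzifier,
            tol=cfg.cluster.tol,
            connectivity=cfg.cluster.connectivity,
            superpixels=superpixels,
        )
        mask = sc.mask
        report["counts"]["superpixels"] = sc.superpixels.n_superpixels
        report["counts"]["clusters"] = sc.cluster.K
        report["counts"]["selected_cluster"] = sc.selected_index
    else:
        result = base_cluster(
            work, method, cfg.cluster.interval_size, cfg.cluster.fuzzifier, cfg.cluster.tol
        )
        idx = select_particle_cluster(result, cfg.cluster.connectivity)
        mask = result.cluster_masks[idx]
        report["counts"]["clusters"] = result.K
        report["counts"]["selected_cluster"] = idx
    report["timings_s"]["cluster"] = round(time.perf_counter() - t0, 4)

    t0 = time.perf_counter()
    params = cfg.cleaning_params()
    if cfg.clean is None and cfg.preprocess.downscale_factor != 1.0:
        # default min_area is stated in input-frame pixels; cleaning and
        # detection run in the downscaled working frame
        from .mask import min_area_for_radius

        params = dataclasses.replace(
            params,
            min_area=min_area_for_radius(
                cfg.expected_particle_radius / cfg.preprocess.downscale_factor
            ),
        )
    if (not is_super) or cfg.pick.clean_after_super:
        mask = clean_mask(mask, params)
    report["timings_s"]["clean"] = round(time.perf_counter() - t0, 4)

    t0 = time.perf_counter()
    ps = detect_particles(
        mask,
        box_mode=cfg.pick.box_mode,
        box_size=cfg.pick.box_size,
        min_area=params.min_area,
        provenance=f"{method}:{cfg.config_hash()}",
    )
    ps = _scale_to_input(ps, cfg.preprocess.downscale_factor, m.shape)
    report["timings_s"]["detect"] = round(time.perf_counter() - t0, 4)
    report["counts"]["particles"] = len(ps)
    logger.info("pick %s: %d particles (%s)", method, len(ps), report["timings_s"])
    return ps, report


def pick(
    m: Micrograph,
    cfg: PipelineConfig | None = None,
    superpixels: SuperPixelMap | None = None,
) -> ParticleSet:
    """End-to-end particle picking; see :func:`pick_with_report`."""
    ps, _ = pick_with_report(m, cfg, superpixels)
    return ps
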