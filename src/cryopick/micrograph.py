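"""Micrograph containers and file I/O.

A :class:`Micrograph` is a 2-D grid of float intensities with provenance.
Micrographs are read from MRC2014 voxel grids (the raw format used by
electron-microscopy archives) or from 8/16-bit grayscale PNGs, and global
intensity scaling brings them onto the [0, 1] working scale used by every
downstream stage.

Coordinate convention: 0-based, ``x`` = column, ``y`` = row, origin at the
top-left, matching array indexing.  EMAN-style ``.box`` export converts to the
lower-left origin that dialect expects.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import CryopickError, DegenerateInputError, FormatError, ParameterError

__all__ = [
    "Micrograph",
    "ScalingSpec",
    "read_micrograph",
    "write_png",
    "read_mrc",
    "write_mrc",
    "scale_intensity",
    "write_coordinates",
    "read_coordinates",
    "read_truth_csv",
    "write_truth_csv",
]


@dataclass(frozen=True)
class Micrograph:
    """A 2-D float intensity image plus provenance.

    Parameters
    ----------
    pixels : ndarray of float, shape (height, width)
    source : free-text provenance tag (file path, generator seed, ...).
    """

    pixels: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ParameterError(
                f"micrograph pixels must be a non-empty 2-D grid, got shape {px.shape}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def intensity_range(self) -> tuple[float, float]:
        return float(self.pixels.min()), float(self.pixels.max())

    def normalized(self) -> "Micrograph":
        """Min-max rescale to [0, 1]; a flat image maps to constant 0.5."""
        lo, hi = self.intensity_range
        if hi == lo:
            return replace(self, pixels=np.full_like(self.pixels, 0.5))
        return replace(self, pixels=(self.pixels - lo) / (hi - lo))


@dataclass(frozen=True)
class ScalingSpec:
    """Global intensity scaling: ``fixed`` multiplies by ``factor`` and
    saturates; ``sane`` auto-stretches by clamping to mean ± 3·std."""

    mode: str = "sane"
    factor: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "sane"):
            raise ParameterError(f"scaling mode must be 'fixed' or 'sane', got {self.mode!r}")
        if self.factor <= 0:
            raise ParameterError(f"scaling factor must be positive, got {self.factor}")


# ---------------------------------------------------------------------------
# MRC2014 I/O (minimal: modes 0, 1, 2, 6; little-endian)
# ---------------------------------------------------------------------------

_MRC_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_MRC_HEADER_BYTES = 1024


def read_mrc(path: str | Path) -> np.ndarray:
    """Read an MRC2014 file into an array of shape (nz, ny, nx) or (ny, nx)."""
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise CryopickError(f"cannot read micrograph file {path}: {exc}") from exc
    if len(raw) < _MRC_HEADER_BYTES:
        raise FormatError(f"{path}: too short to be an MRC file")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    if mode not in _MRC_DTYPES:
        raise FormatError(f"{path}: unsupported MRC mode {mode} (supported: 0, 1, 2, 6)")
    if min(nx, ny, nz) < 1:
        raise FormatError(f"{path}: invalid MRC dimensions ({nx}, {ny}, {nz})")
    dtype = np.dtype(_MRC_DTYPES[mode]).newbyteorder("<")
    offset = _MRC_HEADER_BYTES + nsymbt
    count = nx * ny * nz
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    if data.size != count:
        raise FormatError(f"{path}: truncated MRC data section")
    arr = data.reshape(nz, ny, nx)
    return arr[0] if nz == 1 else arr


def write_mrc(pixels: np.ndarray, path: str | Path) -> None:
    """Write a 2-D image or a (nz, ny, nx) stack as MRC2014 mode 2 (float32)."""
    arr = np.asarray(pixels, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ParameterError(f"write_mrc expects a 2-D image or 3-D stack, got ndim={arr.ndim}")
    nz, ny, nx = arr.shape
    header = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", header, 40, float(nx), float(ny), float(nz))  # cell
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # axis order
    struct.pack_into("<3f", header, 76, float(arr.min()), float(arr.max()), float(arr.mean()))
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian machine stamp
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(arr.astype("<f4").tobytes())


# ---------------------------------------------------------------------------
# Micrograph reading / PNG writing
# ---------------------------------------------------------------------------


def read_micrograph(path: str | Path, frame_reduce: str | None = None) -> Micrograph:
    """Read a micrograph from an MRC (2-D or multi-frame 3-D) or grayscale PNG.

    Parameters
    ----------
    frame_reduce : {"mean", "first"}, optional
        How to collapse a multi-frame MRC stack.  Required when the file holds
        more than one frame.

    Returns
    -------
    Micrograph with float64 pixels, un-normalized.
    """
    path = Path(path)
    if not path.exists():
        raise CryopickError(f"cannot read micrograph file {path}: no such file")
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".mrcs", ".map"):
        arr = read_mrc(path)
        if arr.ndim == 3:
            if frame_reduce is None:
                raise ParameterError(
                    f"{path} is a {arr.shape[0]}-frame MRC stack; pass "
                    "frame_reduce='mean' or frame_reduce='first' to choose a reducer"
                )
            if frame_reduce == "mean":
                arr = arr.mean(axis=0)
            elif frame_reduce == "first":
                arr = arr[0]
            else:
                raise ParameterError(f"frame_reduce must be 'mean' or 'first', got {frame_reduce!r}")
    elif suffix == ".png":
        try:
            arr = iio.imread(path)
        except Exception as exc:  # pragma: no cover - backend specific
            raise CryopickError(f"cannot read micrograph file {path}: {exc}") from exc
        if arr.ndim == 3:
            raise FormatError(f"{path}: RGB(A) PNG not supported; grayscale required")
    else:
        raise FormatError(f"{path}: unsupported micrograph format {suffix!r} (use .mrc or .png)")
    return Micrograph(np.asarray(arr, dtype=np.float64), source=str(path))


def write_png(m: Micrograph | np.ndarray, path: str | Path) -> None:
    """Write an image as 8-bit grayscale PNG.

    Values in [0, 1] are scaled by 255; values already on an 8-bit scale
    (max > 1) are rounded and written as-is, so PNG -> Micrograph -> PNG
    round-trips byte-identically.
    """
    px = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=np.float64)
    hi = px.max() if px.size else 0.0
    if hi <= 1.0:
        px = px * 255.0
    out = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), out)


# ---------------------------------------------------------------------------
# Intensity scaling
# ---------------------------------------------------------------------------


def scale_intensity(m: Micrograph, spec: ScalingSpec) -> Micrograph:
    """Apply global intensity scaling; output always lies in [0, 1].

    ``fixed`` mode: min-max normalize, multiply by ``spec.factor`` and saturate
    at 1 — large factors deliberately clip highlights, mimicking display-range
    truncation.  ``sane`` mode: clamp to [mean − 3·std, mean + 3·std]
    (intersected with the data range so an already-stretched image is a fixed
    point) and rescale that interval to [0, 1].
    """
    px = m.pixels
    if spec.mode == "fixed":
        lo, hi = float(px.min()), float(px.max())
        norm = np.full_like(px, 0.5) if hi == lo else (px - lo) / (hi - lo)
        out = np.clip(norm * spec.factor, 0.0, 1.0)
        return replace(m, pixels=out)
    # sane
    mean = float(px.mean())
    std = float(px.std())
    if std == 0.0:
        return replace(m, pixels=np.full_like(px, 0.5))
    lo = max(mean - 3.0 * std, float(px.min()))
    hi = min(mean + 3.0 * std, float(px.max()))
    if hi <= lo:  # pathological two-valued edge case
        return m.normalized()
    out = (np.clip(px, lo, hi) - lo) / (hi - lo)
    return replace(m, pixels=out)


# ---------------------------------------------------------------------------
# Coordinate files
# ---------------------------------------------------------------------------

_CSV_HEADER = "particle_id,centroid_x,centroid_y,bbox_x,bbox_y,bbox_w,bbox_h,area"


def write_coordinates(particles, path: str | Path, format: str = "csv") -> None:
    """Write a ParticleSet as CSV or EMAN-style ``.box`` coordinates.

    CSV columns: ``particle_id,centroid_x,centroid_y,bbox_x,bbox_y,bbox_w,
    bbox_h,area`` with integer-rounded centroids.  Box lines are
    ``x y w h`` with (x, y) the lower-left corner in 0-based pixels
    (y axis flipped relative to the internal top-left origin).
    An empty set writes a valid empty file (header only for CSV).
    """
    path = Path(path)
    lines: list[str] = []
    if format == "csv":
        lines.append(_CSV_HEADER)
        for p in particles.particles:
            cx, cy = int(round(p.centroid[0])), int(round(p.centroid[1]))
            x, y, w, h = p.bbox
            lines.append(f"{p.id},{cx},{cy},{x},{y},{w},{h},{p.area}")
    elif format == "box":
        height = particles.image_shape[0]
        for p in particles.particles:
            x, y, w, h = p.bbox
            y_ll = height - (y + h)
            lines.append(f"{x}\t{y_ll}\t{w}\t{h}")
    else:
        raise ParameterError(f"coordinate format must be 'csv' or 'box', got {format!r}")
    path.write_text("\n".join(lines) + "\n")


def read_coordinates(path: str | Path, format: str = "csv", image_shape: tuple[int, int] | None = None):
    """Read coordinates written by :func:`write_coordinates` back to a ParticleSet.

    Box files carry no centroid/area, so the centroid is reconstructed as the
    box center and the area as the box area; ``image_shape`` is required for
    the y-axis flip.
    """
    from .picking import Particle, ParticleSet  # local import to avoid a cycle

    path = Path(path)
    text = path.read_text().strip()
    particles: list[Particle] = []
    if format == "csv":
        rows = text.splitlines()
        if not rows or rows[0] != _CSV_HEADER:
            raise FormatError(f"{path}: missing coordinate CSV header")
        shape = image_shape or (0, 0)
        for row in rows[1:]:
            pid, cx, cy, x, y, w, h, area = (int(v) for v in row.split(","))
            particles.append(Particle(id=pid, centroid=(float(cx), float(cy)),
                                      bbox=(x, y, w, h), area=area))
        if image_shape is None:
            # tightest shape covering all boxes
            hmax = max((p.bbox[1] + p.bbox[3] for p in particles), default=0)
            wmax = max((p.bbox[0] + p.bbox[2] for p in particles), default=0)
            shape = (hmax, wmax)
        return ParticleSet(particles=particles, image_shape=shape, provenance=f"read:{path}")
    if format == "box":
        if image_shape is None:
            raise ParameterError("reading box files requires image_shape for the y-axis flip")
        for i, row in enumerate(filter(None, text.splitlines()), start=1):
            x, y_ll, w, h = (int(v) for v in row.split())
            y = image_shape[0] - (y_ll + h)
            particles.append(Particle(id=i, centroid=(x + w / 2.0, y + h / 2.0),
                                      bbox=(x, y, w, h), area=w * h))
        return ParticleSet(particles=particles, image_shape=image_shape, provenance=f"read:{path}")
    raise ParameterError(f"coordinate format must be 'csv' or 'box', got {format!r}")


def write_truth_csv(truth: list[tuple[float, float]], path: str | Path) -> None:
    """Write ground-truth centers as a two-column ``x,y`` CSV."""
    lines = ["x,y"] + [f"{x:.3f},{y:.3f}" for x, y in truth]
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_csv(path: str | Path) -> list[tuple[float, float]]:
    """Read ground-truth centers from a two-column ``x,y`` CSV (header optional)."""
    out: list[tuple[float, float]] = []
    for row in Path(path).read_text().strip().splitlines():
        row = row.strip()
        if not row or row.lower().startswith("x"):
            continue
        x, y = row.split(",")[:2]
        out.append((float(x), float(y)))
    return out
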