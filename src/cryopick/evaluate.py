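"""Image-quality and picking-quality metrics.

Image quality: SNR as the ratio of the signal RMS to the sample noise
standard deviation, in dB; MSE between two images; PSNR as
10*log10(MAX_i^2 / MSE).

Picking quality: detections are matched one-to-one to ground-truth centers
greedily by ascending centroid distance under a pixel tolerance, giving
TP/FN/FP, from which recall = TP/(TP+FN), precision = TP/(TP+FP),
accuracy = TP/(TP+FN+FP) and F1 = 2PR/(P+R).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .micrograph import Micrograph

__all__ = [
    "QualityMetrics",
    "PickingReport",
    "snr",
    "mse",
    "psnr",
    "quality_metrics",
    "match_particles",
    "picking_report",
    "evaluate_picking",
]


@dataclass(frozen=True)
class QualityMetrics:
    """Image-quality summary; ``psnr`` is infinite (flagged) when mse = 0."""

    psnr: float
    snr: float
    mse: float
    max_i: float
    psnr_infinite: bool = False


@dataclass(frozen=True)
class PickingReport:
    """Contingency counts and the four derived scores, in [0, 1].

    Ratios with a zero denominator are reported as 0 and listed in
    ``undefined``.
    """

    tp: int
    fn: int
    fp: int
    recall: float
    precision: float
    accuracy: float
    f1: float
    match_tolerance: float
    undefined: tuple[str, ...] = ()


def _pixels(m) -> np.ndarray:
    return m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=np.float64)


def snr(m) -> float:
    """Signal-to-noise ratio in dB: 20*log10(RMS / sample std).

    RMS = (mean of squared intensities)^(1/2); the noise estimate is the
    sample standard deviation with divisor n-1.
    """
    x = _pixels(m).ravel()
    if x.size < 2:
        raise DegenerateInputError("SNR needs at least 2 pixels")
    std = float(x.std(ddof=1))
    if std == 0.0:
        raise DegenerateInputError("SNR undefined for a zero-variance image")
    rms = float(np.sqrt(np.mean(x * x)))
    return 20.0 * math.log10(rms / std)


def mse(a, b) -> float:
    """Mean squared error between two same-shape images."""
    pa, pb = _pixels(a), _pixels(b)
    if pa.shape != pb.shape:
        raise ParameterError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    d = pa - pb
    return float(np.mean(d * d))


def psnr(a, b, max_i: float = 1.0) -> float:
    """Peak SNR in dB: 10*log10(max_i^2 / mse).  Identical images give +inf."""
    e = mse(a, b)
    if e == 0.0:
        return math.inf
    return 10.0 * math.log10(max_i * max_i / e)


def quality_metrics(a, b, max_i: float = 1.0) -> QualityMetrics:
    """PSNR/SNR/MSE bundle comparing image ``b`` against reference ``a``;
    SNR is measured on ``b``."""
    e = mse(a, b)
    p = psnr(a, b, max_i)
    return QualityMetrics(psnr=p, snr=snr(b), mse=e, max_i=float(max_i),
                          psnr_infinite=not math.isfinite(p))


def match_particles(detected, truth, tolerance: float) -> tuple[int, int, int]:
    """Greedy one-to-one matching by ascending centroid distance.

    ``detected`` may be a ParticleSet or an (n, 2) array of (x, y) centers;
    ``truth`` is a sequence of (x, y) centers.  A (detected, truth) pair is
    accepted iff its distance is <= ``tolerance`` and neither member is
    already matched; ties break deterministically by (distance, detected
    index, truth index).  Returns (tp, fn, fp).
    """
    if tolerance <= 0:
        raise ParameterError("tolerance must be positive")
    det = detected.centroids() if hasattr(detected, "centroids") else np.asarray(detected, dtype=np.float64)
    det = det.reshape(-1, 2)
    tru = np.asarray(list(truth), dtype=np.float64).reshape(-1, 2)
    if det.size == 0 or tru.size == 0:
        return 0, tru.shape[0], det.shape[0]
    d = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
    di, ti = np.nonzero(d <= tolerance)
    order = np.lexsort((ti, di, d[di, ti]))
    used_d = np.zeros(det.shape[0], dtype=bool)
    used_t = np.zeros(tru.shape[0], dtype=bool)
    tp = 0
    for idx in order:
        i, j = di[idx], ti[idx]
        if not used_d[i] and not used_t[j]:
            used_d[i] = used_t[j] = True
            tp += 1
    return tp, int((~used_t).sum()), int((~used_d).sum())


def picking_report(tp: int, fn: int, fp: int, tolerance: float = 0.0) -> PickingReport:
    """Derive recall/precision/accuracy/F1 from contingency counts."""
    if min(tp, fn, fp) < 0:
        raise ParameterError("counts must be non-negative")
    if tp + fn == 0:
        raise DegenerateInputError("no ground-truth particles: tp + fn = 0")
    undefined: list[str] = []
    recall = tp / (tp + fn)
    if tp + fp == 0:
        precision = 0.0
        undefined.append("precision")
    else:
        precision = tp / (tp + fp)
    accuracy = tp / (tp + fn + fp)
    if precision + recall == 0:
        f1 = 0.0
        undefined.append("f1")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return PickingReport(
        tp=tp, fn=fn, fp=fp,
        recall=recall, precision=precision, accuracy=accuracy, f1=f1,
        match_tolerance=float(tolerance), undefined=tuple(undefined),
    )


def evaluate_picking(detected, truth, tolerance: float) -> PickingReport:
    """Match then score in one call."""
    tp, fn, fp = match_particles(detected, truth, tolerance)
    return picking_report(tp, fn, fp, tolerance)
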