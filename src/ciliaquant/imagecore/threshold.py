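"""Histogram auto-thresholding: Yen, Shanbhag, and MinError(I).

All three operate on a 256-bin histogram (16-bit or float images are min–max
rescaled into the bins, following the ImageJ Auto_Threshold convention) and
return a bin index ``t``; pixels in bins strictly greater than ``t`` are
positive.

Criteria follow the published definitions: Yen's maximum-correlation
criterion (Yen, Chang & Chang 1995), Shanbhag's information measure
(Shanbhag 1994), and the iterated Kittler–Illingworth minimum-error fit
(Kittler & Illingworth 1986), started from the histogram mean.  The
minimum-error Gaussian-mixture criterion uses natural logarithms.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np

from ..errors import DegenerateImageError, InvalidInputError, InvalidParameterError
from .types import BinaryMask, Calibration

_METHODS = ("yen", "shanbhag", "minerror")
_EPS = 2.220446049250313e-16


def histogram_256(image: np.ndarray) -> Tuple[np.ndarray, float, float, bool]:
    """256-bin histogram of an image.

    Returns ``(counts, lo, hi, identity)``.  For non-negative integer images
    with max ≤ 255 the bins are the intensities themselves (``identity`` is
    True); otherwise intensities are linearly rescaled from the observed
    [lo, hi] range into bins 0..255.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise InvalidInputError("cannot histogram an empty image")
    lo = float(image.min())
    hi = float(image.max())
    if lo == hi:
        raise DegenerateImageError("constant image has no threshold")
    flat = image.ravel()
    if np.issubdtype(image.dtype, np.integer) and lo >= 0 and hi <= 255:
        counts = np.bincount(flat.astype(np.int64), minlength=256)[:256]
        return counts.astype(np.int64), 0.0, 255.0, True
    bins = np.clip(((flat - lo) * (256.0 / (hi - lo))).astype(np.int64), 0, 255)
    return np.bincount(bins, minlength=256)[:256], lo, hi, False


def _bin_index(image: np.ndarray, lo: float, hi: float, identity: bool) -> np.ndarray:
    if identity:
        return np.asarray(image, dtype=np.int64)
    return np.clip(
        ((np.asarray(image, dtype=float) - lo) * (256.0 / (hi - lo))).astype(np.int64),
        0,
        255,
    )


def yen_threshold(counts: np.ndarray) -> int:
    """Bin index maximizing Yen's maximum-correlation criterion.

    Candidates are restricted to the occupied histogram range (both classes
    non-empty); the first maximum wins on ties.
    """
    p = counts / counts.sum()
    P1 = np.cumsum(p)
    P1sq = np.cumsum(p**2)
    P2sq = (p**2).sum() - P1sq  # sum over bins > t
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(P1sq * P2sq > 0, -np.log(P1sq * P2sq), 0.0)
        inbetween = P1 * (1.0 - P1)
        term2 = np.where(inbetween > 0, 2.0 * np.log(inbetween), 0.0)
    crit = term1 + term2
    valid = np.nonzero(counts)[0]
    lo, hi = int(valid[0]), int(valid[-1])
    return lo + int(np.argmax(crit[lo:hi]))


def shanbhag_threshold(counts: np.ndarray) -> int:
    """Bin index minimizing Shanbhag's fuzzy-information distance."""
    p = counts / counts.sum()
    P1 = np.cumsum(p)
    P2 = 1.0 - P1
    valid = np.nonzero(counts)[0]
    first_bin, last_bin = int(valid[0]), int(valid[-1])
    best_t, best_dist = first_bin, math.inf
    for t in range(first_bin, last_bin + 1):
        if P1[t] < _EPS or P2[t] < _EPS:
            continue
        term = 0.5 / P1[t]
        ih = np.arange(1, t + 1)
        ent_back = -term * float(np.sum(p[ih] * np.log(1.0 - term * P1[ih - 1])))
        term = 0.5 / P2[t]
        ih = np.arange(t + 1, 256)
        ent_obj = -term * float(np.sum(p[ih] * np.log(1.0 - term * P2[ih])))
        dist = abs(ent_back - ent_obj)
        if dist < best_dist:
            best_dist = dist
            best_t = t
    return best_t


def _mean_bin(counts: np.ndarray) -> int:
    idx = np.arange(256)
    return int(round(float((idx * counts).sum() / counts.sum())))


def minerror_threshold(counts: np.ndarray, max_iter: int = 100) -> Tuple[int, bool]:
    """Iterated Kittler–Illingworth minimum-error threshold.

    Starts at the histogram mean and iterates the quadratic fixed-point
    update until the bin index stabilizes.  Returns ``(threshold,
    converged)``; on non-convergence (negative discriminant, degenerate
    class variance, oscillation) falls back to the mean threshold with
    ``converged=False``.
    """
    counts = np.asarray(counts, dtype=float)
    idx = np.arange(256, dtype=float)
    A = np.cumsum(idx * counts)
    B = np.cumsum(counts)
    C = np.cumsum(idx**2 * counts)
    Atot, Btot, Ctot = A[-1], B[-1], C[-1]
    mean_t = _mean_bin(counts)

    t = mean_t
    prev = -2
    for _ in range(max_iter):
        if t == prev:
            return t, True
        # keep both classes populated
        lo_valid, hi_valid = np.nonzero(counts)[0][[0, -1]]
        t = int(np.clip(t, lo_valid, hi_valid - 1))
        b1, b2 = B[t], Btot - B[t]
        if b1 <= 0 or b2 <= 0:
            return mean_t, False
        mu = A[t] / b1
        nu = (Atot - A[t]) / b2
        p_ = b1 / Btot
        q_ = b2 / Btot
        sigma2 = C[t] / b1 - mu**2
        tau2 = (Ctot - C[t]) / b2 - nu**2
        if sigma2 <= 0 or tau2 <= 0:
            return mean_t, False
        w0 = 1.0 / sigma2 - 1.0 / tau2
        w1 = mu / sigma2 - nu / tau2
        w2 = mu**2 / sigma2 - nu**2 / tau2 + math.log(
            (sigma2 * q_**2) / (tau2 * p_**2)
        )
        sqterm = w1**2 - w0 * w2
        if sqterm < 0:
            return mean_t, False
        if w0 == 0:
            # equal variances: the update degenerates to the midpoint rule
            new_t = 0.5 * (mu + nu) if w1 != 0 else float(t)
        else:
            new_t = (w1 + math.sqrt(sqterm)) / w0
        if not math.isfinite(new_t):
            return mean_t, False
        prev = t
        t = int(round(new_t))
    return mean_t, False


def auto_threshold(
    image: np.ndarray,
    method: str,
    calibration: Optional[Calibration] = None,
) -> BinaryMask:
    """Binarize an image with one of the named auto-threshold criteria.

    Pixels whose 256-bin index is strictly greater than the selected
    threshold are positive.  ``threshold_value`` on the returned mask is the
    threshold on the image's original intensity scale (the upper edge of the
    last negative bin).  Constant images raise DegenerateImageError.
    """
    method = method.lower()
    if method not in _METHODS:
        raise InvalidParameterError(f"method must be one of {_METHODS}")
    image = np.asarray(image)
    if image.ndim != 2:
        raise InvalidInputError("auto_threshold expects a 2D image")
    counts, lo, hi, identity = histogram_256(image)
    warning = None
    if method == "yen":
        t = yen_threshold(counts)
    elif method == "shanbhag":
        t = shanbhag_threshold(counts)
    else:
        t, converged = minerror_threshold(counts)
        if not converged:
            warning = "minerror did not converge; fell back to mean threshold"
    bins = _bin_index(image, lo, hi, identity)
    pixels = bins > t
    thr_value = float(t) if identity else lo + (t + 1) * (hi - lo) / 256.0
    return BinaryMask(
        pixels=pixels,
        calibration=calibration,
        threshold_value=thr_value,
        warning=warning,
    )
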