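"""Connected-component particle analysis and binary watershed separation.

Components are 8-connected.  The perimeter is a chain-code estimate from a
Moore boundary trace — straight steps count 1, diagonal (corner-cutting)
steps count √2 — and circularity 4πA/P² is capped at 1.0, so discretization
cannot push a convex blob above the cap.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_maxima
from skimage.segmentation import watershed

from ..errors import InvalidInputError, InvalidParameterError
from .types import BinaryMask, Particle

_SQRT2 = math.sqrt(2.0)
_EIGHT = np.ones((3, 3), dtype=int)
# clockwise Moore neighborhood starting W; even indices are straight steps
_NBRS = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))


def boundary_chain(mask: np.ndarray) -> List[int]:
    """Moore-trace the outer boundary of a single component; return move codes.

    ``mask`` must contain exactly one 8-connected component and a 1-px
    false border.  Returns [] for a single-pixel component.
    """
    ys, xs = np.nonzero(mask)
    if ys.size <= 1:
        return []
    y0 = int(ys.min())
    x0 = int(xs[ys == y0].min())
    cur = (y0, x0)
    backtrack = 0
    moves: List[int] = []
    first_transition = None
    for _ in range(4 * ys.size + 16):
        nxt = None
        for k in range(8):
            idx = (backtrack + k) % 8
            cand = (cur[0] + _NBRS[idx][0], cur[1] + _NBRS[idx][1])
            if mask[cand]:
                nxt = (cand, idx)
                break
        if nxt is None:
            break
        cand, idx = nxt
        if first_transition is None:
            first_transition = (cur, idx)
        elif (cur, idx) == first_transition:
            break
        moves.append(idx)
        backtrack = (idx + 5) % 8
        cur = cand
    return moves


def chain_perimeter(mask: np.ndarray) -> float:
    """Chain-code perimeter of a single padded component."""
    moves = boundary_chain(mask)
    if not moves:
        return 4.0  # isolated pixel: crack-boundary length
    straight = sum(1 for m in moves if m % 2 == 0)
    diagonal = len(moves) - straight
    return straight + _SQRT2 * diagonal


def _component_particle(
    labeled: np.ndarray,
    label: int,
    sl: Tuple[slice, slice],
    shape: Tuple[int, int],
    pixel_size_xy: Optional[float],
) -> Particle:
    sub = labeled[sl] == label
    padded = np.pad(sub, 1, mode="constant")
    perim = chain_perimeter(padded)
    area = int(sub.sum())
    circ = 1.0 if perim <= 0 else min(1.0, 4.0 * math.pi * area / perim**2)
    ys, xs = np.nonzero(sub)
    y_off, x_off = sl[0].start, sl[1].start
    ys = ys + y_off
    xs = xs + x_off
    touches = bool(
        (ys.min() == 0)
        or (xs.min() == 0)
        or (ys.max() == shape[0] - 1)
        or (xs.max() == shape[1] - 1)
    )
    return Particle(
        pixel_indices=frozenset(zip(ys.tolist(), xs.tolist())),
        area_px=area,
        perimeter_px=perim,
        circularity=circ,
        centroid=(float(xs.mean()), float(ys.mean())),
        touches_edge=touches,
        pixel_size_xy=pixel_size_xy,
    )


def particle_analysis(
    mask: Union[BinaryMask, np.ndarray],
    min_size_px: int = 1,
    circularity_range: Optional[Sequence[float]] = None,
    exclude_edges: bool = False,
    pixel_size_xy: Optional[float] = None,
) -> List[Particle]:
    """Label 8-connected components and filter them, FIJI Analyze-Particles style.

    Components smaller than ``min_size_px``, outside the inclusive
    ``circularity_range`` (when given), or touching any image border (when
    ``exclude_edges``) are dropped.  Survivors are returned in raster-scan
    order of their first pixel.
    """
    if min_size_px < 1:
        raise InvalidParameterError("min_size_px must be ≥ 1")
    if isinstance(mask, BinaryMask):
        if pixel_size_xy is None and mask.calibration is not None:
            pixel_size_xy = mask.calibration.pixel_size_xy
        arr = mask.pixels
    else:
        arr = np.asarray(mask, dtype=bool)
    if arr.ndim != 2:
        raise InvalidInputError("particle_analysis expects a 2D mask")

    labeled, n = ndi.label(arr, structure=_EIGHT)
    out: List[Particle] = []
    for label, sl in enumerate(ndi.find_objects(labeled), start=1):
        if sl is None:
            continue
        p = _component_particle(labeled, label, sl, arr.shape, pixel_size_xy)
        if p.area_px < min_size_px:
            continue
        if circularity_range is not None:
            lo, hi = circularity_range
            if not (lo <= p.circularity <= hi):
                continue
        if exclude_edges and p.touches_edge:
            continue
        out.append(p)
    return out


def watershed_separate(mask: Union[BinaryMask, np.ndarray]) -> BinaryMask:
    """Split touching convex blobs by distance-transform watershed.

    Seeds are the regional maxima of the (lightly smoothed) Euclidean
    distance map; 1-px separation lines between distinct catchment basins
    are erased.  Components with a single maximum are returned unchanged.
    """
    calibration = None
    if isinstance(mask, BinaryMask):
        calibration = mask.calibration
        arr = mask.pixels
    else:
        arr = np.asarray(mask, dtype=bool)
    if arr.ndim != 2:
        raise InvalidInputError("watershed_separate expects a 2D mask")
    if not arr.any():
        return BinaryMask(pixels=arr.copy(), calibration=calibration)

    edt = ndi.distance_transform_edt(arr)
    smoothed = ndi.gaussian_filter(edt, sigma=1.0)
    peaks = local_maxima(smoothed, connectivity=2) & arr
    markers, n_markers = ndi.label(peaks, structure=_EIGHT)
    if n_markers == 0:
        return BinaryMask(pixels=arr.copy(), calibration=calibration)
    labels = watershed(-smoothed, markers=markers, mask=arr, watershed_line=True)
    return BinaryMask(pixels=labels > 0, calibration=calibration)
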