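"""The five measurement pipelines.

Each pipeline composes the imagecore primitives in the order the
acquisition-matched FIJI protocol prescribes:

* ``lysotracker_size`` — per-ROI late-endosome/lysosome cross-sectional area
  (crop → smooth → MIP → rolling ball r=20 → Yen → particles ≥3 px,
  circularity 0.50–1, edge particles excluded).
* ``actin_clearing`` — ratio of apical cortical actin directly above a basal
  body (±0.3 µm laterally) to flanking cortex (2–4 µm), from a mean-1
  normalized, vertically averaged side-view profile in an 8×5 µm ROI.
* ``percent_ciliation`` — cilium puncta count over nucleus count from MIPs
  (variant-specific thresholds and size filters for MDCK vs RPE1).
* ``basal_body_enrichment`` — positive-pixel density in a 3×2 µm basal-body
  ROI over density in a freehand cytosol ROI, on a Yen-binarized side view
  (rolling ball r=75), with near-uniform slices excluded.
* ``manders_overlap`` — M1/M2 area-overlap fractions of two Yen-binarized
  channels (rolling ball r=100) in a 30×30 µm ROI at one mid-apical slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    BoundsError,
    DegenerateImageError,
    InvalidParameterError,
    UndefinedStatisticError,
)
from .imagecore.filters import (
    crop_roi,
    max_project,
    rolling_ball_subtract,
    smooth,
)
from .imagecore.particles import particle_analysis, watershed_separate
from .imagecore.threshold import auto_threshold
from .imagecore.types import (
    Calibration,
    ImageStack,
    Particle,
    PolyROI,
    RectROI,
    um_to_px,
)

# ---------------------------------------------------------------------------
# result containers


@dataclass
class VesicleStats:
    """Particle statistics of one LysoTracker ROI."""

    particles: List[Particle]
    n_particles: int
    mean_area_um2: Optional[float]
    roi_id: str
    skipped: bool = False
    skip_reason: Optional[str] = None


@dataclass
class IntensityProfile:
    """Laterally resolved, vertically averaged, mean-normalized intensity."""

    distance_um: np.ndarray  # signed lateral distance from the ROI center
    value: np.ndarray
    normalized: bool = True


@dataclass
class ClearingResult:
    ratio: float
    profile_actin: IntensityProfile
    profile_gtub: Optional[IntensityProfile]
    bb_id: str = ""


@dataclass
class CiliationResult:
    n_cilia: int
    n_nuclei: int
    percent_ciliated: float
    variant: str
    manual_nuclei_override: Optional[int] = None


@dataclass
class EnrichmentResult:
    density_bb: Optional[float]
    density_cyto: Optional[float]
    fold_enrichment: Optional[float]
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    cell_id: str = ""


@dataclass
class OverlapResult:
    m1: Optional[float]
    m2: Optional[float]
    roi_id: str = ""
    flags: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# LysoTracker compartment size


def lysotracker_size(
    stack: ImageStack,
    channel: str = "vesicles",
    rois: Optional[Sequence[RectROI]] = None,
    rolling_ball_radius_px: int = 20,
    min_size_px: int = 3,
    circularity_range: Tuple[float, float] = (0.50, 1.0),
) -> List[VesicleStats]:
    """Mean equatorial cross-sectional area of LE/L compartments per ROI.

    ROIs default to the full image.  ROIs whose thresholding is degenerate
    (e.g. pure background) are flagged and skipped rather than failing the
    whole field.
    """
    cal = stack.calibration
    vol = stack.channel(channel)
    if rois is None:
        ny, nx = vol.shape[1:]
        rois = [
            RectROI(center=(nx / 2, ny / 2), width=nx * cal.pixel_size_xy,
                    height=ny * cal.pixel_size_xy, unit="px")
        ]
    out: List[VesicleStats] = []
    for i, roi in enumerate(rois):
        roi_id = f"roi{i}"
        sub = crop_roi(vol, roi, cal)
        mip = max_project(smooth(sub))
        bgsub = rolling_ball_subtract(mip, rolling_ball_radius_px)
        try:
            mask = auto_threshold(bgsub, "yen", calibration=cal)
        except DegenerateImageError as exc:
            out.append(
                VesicleStats([], 0, None, roi_id, skipped=True, skip_reason=str(exc))
            )
            continue
        particles = particle_analysis(
            mask,
            min_size_px=min_size_px,
            circularity_range=circularity_range,
            exclude_edges=True,
        )
        mean_area = (
            float(np.mean([p.area_um2 for p in particles])) if particles else None
        )
        out.append(VesicleStats(particles, len(particles), mean_area, roi_id))
    return out


# ---------------------------------------------------------------------------
# apical cortical actin clearing


def _profile(
    image: np.ndarray,
    cx: int,
    cz: int,
    half_w_px: int,
    half_h_px: int,
    pixel_size: float,
) -> IntensityProfile:
    nz, nx = image.shape
    x0, x1 = cx - half_w_px, cx + half_w_px + 1
    z0, z1 = cz - half_h_px, cz + half_h_px + 1
    if x0 < 0 or z0 < 0 or x1 > nx or z1 > nz:
        raise BoundsError("clearing ROI does not fit inside the side view")
    roi = image[z0:z1, x0:x1].astype(float)
    values = roi.mean(axis=0)  # vertical average per column
    mean = values.mean()
    if mean <= 0:
        raise UndefinedStatisticError("profile mean is zero; cannot normalize")
    distances = (np.arange(x0, x1) - cx) * pixel_size
    return IntensityProfile(distance_um=distances, value=values / mean)


def clearing_ratio_from_profile(
    profile: IntensityProfile,
    center_halfwidth_um: float = 0.3,
    flank_um: Tuple[float, float] = (2.0, 4.0),
) -> float:
    """Center-window mean over pooled-flank mean, inclusive bounds."""
    d = np.abs(profile.distance_um)
    eps = 1e-9
    center = profile.value[d <= center_halfwidth_um + eps]
    flank = profile.value[(d >= flank_um[0] - eps) & (d <= flank_um[1] + eps)]
    if center.size == 0 or flank.size == 0:
        raise UndefinedStatisticError("profile windows are empty")
    flank_mean = flank.mean()
    if flank_mean <= 0:
        raise UndefinedStatisticError("flanking cortex intensity is zero")
    return float(center.mean() / flank_mean)


def actin_clearing(
    actin_sideview: np.ndarray,
    bb_center: Tuple[int, int],
    calibration: Calibration,
    gtub_sideview: Optional[np.ndarray] = None,
    bb_id: str = "",
    roi_width_um: float = 8.0,
    roi_height_um: float = 5.0,
) -> ClearingResult:
    """Fraction of cortical actin remaining above one basal body.

    ``bb_center`` is the (x, z) pixel anchor of the basal body in the
    side-view slice.  An 8 µm × 5 µm ROI centered on the anchor is vertically
    averaged into a lateral profile, normalized to mean 1, and the ratio of
    the |d| ≤ 0.3 µm window to the pooled 2–4 µm flanks is returned.  The
    γ-tubulin profile, when the channel is supplied, is computed for QC but
    does not enter the ratio.
    """
    psz = calibration.pixel_size_xy
    cx, cz = int(round(bb_center[0])), int(round(bb_center[1]))
    half_w = um_to_px(roi_width_um / 2.0, psz)
    half_h = um_to_px(roi_height_um / 2.0, psz)
    prof_actin = _profile(np.asarray(actin_sideview), cx, cz, half_w, half_h, psz)
    prof_gtub = None
    if gtub_sideview is not None:
        prof_gtub = _profile(np.asarray(gtub_sideview), cx, cz, half_w, half_h, psz)
    ratio = clearing_ratio_from_profile(prof_actin)
    return ClearingResult(ratio, prof_actin, prof_gtub, bb_id=bb_id)


# ---------------------------------------------------------------------------
# percent ciliation


_CILIA_PARAMS = {
    "mdck": {"method": "shanbhag", "min_size_px": 2},
    "rpe1": {"method": "yen", "min_size_px": 5},
}


def percent_ciliation(
    stack: ImageStack,
    cilia_channel: str = "cilia",
    nuclei_channel: str = "nuclei",
    variant: str = "mdck",
    manual_nuclei_override: Optional[int] = None,
    rolling_ball_radius_px: int = 100,
    nuclei_min_size_px: int = 150,
) -> CiliationResult:
    """Percent of cells carrying a cilium-marker punctum.

    Cilia: MIP → rolling ball → Shanbhag (MDCK) or Yen (RPE1) → particles
    ≥2 px (MDCK) or ≥5 px (RPE1), no circularity filter, edges included.
    Nuclei: MIP → smooth → rolling ball → MinError(I) → watershed →
    particles ≥150 px.  ``manual_nuclei_override`` replaces the automated
    nucleus count, mirroring manual correction of poor segmentations.
    """
    if variant not in _CILIA_PARAMS:
        raise InvalidParameterError("variant must be 'mdck' or 'rpe1'")
    params = _CILIA_PARAMS[variant]
    cal = stack.calibration

    cilia_mip = max_project(stack.channel(cilia_channel))
    cilia_bg = rolling_ball_subtract(cilia_mip, rolling_ball_radius_px)
    try:
        cilia_mask = auto_threshold(cilia_bg, params["method"], calibration=cal)
        n_cilia = len(
            particle_analysis(cilia_mask, min_size_px=params["min_size_px"])
        )
    except DegenerateImageError:
        n_cilia = 0  # featureless channel: no cilia

    if manual_nuclei_override is not None:
        n_nuclei = int(manual_nuclei_override)
    else:
        nuc_mip = max_project(stack.channel(nuclei_channel))
        nuc_bg = rolling_ball_subtract(smooth(nuc_mip), rolling_ball_radius_px)
        nuc_mask = auto_threshold(nuc_bg, "minerror", calibration=cal)
        separated = watershed_separate(nuc_mask)
        n_nuclei = len(
            particle_analysis(separated, min_size_px=nuclei_min_size_px)
        )
    if n_nuclei == 0:
        raise UndefinedStatisticError("nucleus count is zero; percentage undefined")
    return CiliationResult(
        n_cilia=n_cilia,
        n_nuclei=n_nuclei,
        percent_ciliated=100.0 * n_cilia / n_nuclei,
        variant=variant,
        manual_nuclei_override=manual_nuclei_override,
    )


# ---------------------------------------------------------------------------
# basal-body enrichment


def enrichment_from_mask(
    positive: np.ndarray,
    bb_anchor: Tuple[int, int],
    cytosol_roi: PolyROI,
    calibration: Calibration,
    bb_width_um: float = 3.0,
    bb_height_um: float = 2.0,
    uniform_high: float = 0.99,
    uniform_low: float = 0.005,
    cell_id: str = "",
) -> EnrichmentResult:
    """Densities and fold enrichment from an already-binarized side view."""
    positive = np.asarray(positive, dtype=bool)
    nz, nx = positive.shape
    psz = calibration.pixel_size_xy
    ax, az = int(round(bb_anchor[0])), int(round(bb_anchor[1]))
    w = um_to_px(bb_width_um, psz)
    h = um_to_px(bb_height_um, psz)
    x0 = ax - w // 2
    x1 = x0 + w
    z0, z1 = az, az + h  # upper edge at the anchor, extending basally (down)
    if x0 < 0 or z0 < 0 or x1 > nx or z1 > nz:
        raise BoundsError("basal-body ROI does not fit inside the slice")
    cyto_mask = cytosol_roi.mask(positive.shape)
    if not cyto_mask.any():
        raise BoundsError("cytosol ROI rasterized to zero pixels")

    density_cyto = float(positive[cyto_mask].mean())
    if density_cyto > uniform_high or density_cyto < uniform_low:
        return EnrichmentResult(
            density_bb=None,
            density_cyto=density_cyto,
            fold_enrichment=None,
            excluded=True,
            exclusion_reason=(
                f"near-uniform threshold result (cytosol positive fraction "
                f"{density_cyto:.4f})"
            ),
            cell_id=cell_id,
        )
    density_bb = float(positive[z0:z1, x0:x1].mean())
    if density_cyto == 0:
        raise UndefinedStatisticError("cytosol density is zero; ratio undefined")
    return EnrichmentResult(
        density_bb=density_bb,
        density_cyto=density_cyto,
        fold_enrichment=density_bb / density_cyto,
        cell_id=cell_id,
    )


def basal_body_enrichment(
    sideview_slice: np.ndarray,
    bb_anchor: Tuple[int, int],
    cytosol_roi: PolyROI,
    calibration: Calibration,
    rolling_ball_radius_px: int = 75,
    cell_id: str = "",
    **roi_kwargs,
) -> EnrichmentResult:
    """Fold enrichment of a punctate marker at the basal body.

    ``sideview_slice`` is one (z, x) marker-channel slice with the apical
    surface at the top; ``bb_anchor`` is the (x, z) pixel position of the
    apical end of the basal body.  The slice is background-subtracted
    (rolling ball, r=75), Yen-binarized, and positive-pixel densities are
    compared between a 3×2 µm basal-body box and the freehand cytosol
    polygon.  Cells whose binarization is near-uniform are excluded.
    """
    bgsub = rolling_ball_subtract(np.asarray(sideview_slice, float),
                                  rolling_ball_radius_px)
    try:
        mask = auto_threshold(bgsub, "yen", calibration=calibration)
    except DegenerateImageError as exc:
        return EnrichmentResult(
            density_bb=None, density_cyto=None, fold_enrichment=None,
            excluded=True, exclusion_reason=f"degenerate threshold: {exc}",
            cell_id=cell_id,
        )
    return enrichment_from_mask(
        mask.pixels, bb_anchor, cytosol_roi, calibration, cell_id=cell_id,
        **roi_kwargs,
    )


# ---------------------------------------------------------------------------
# Manders overlap


def manders_from_masks(mask_a: np.ndarray, mask_b: np.ndarray,
                       roi_id: str = "") -> OverlapResult:
    """M1/M2 on binary masks: area-overlap fractions."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise InvalidParameterError("masks must share a shape")
    inter = float(np.sum(a & b))
    flags = []
    if a.any():
        m1 = inter / a.sum()
    else:
        m1, flags = None, flags + ["channel A empty; M1 undefined"]
    if b.any():
        m2 = inter / b.sum()
    else:
        m2, flags = None, flags + ["channel B empty; M2 undefined"]
    return OverlapResult(m1=m1, m2=m2, roi_id=roi_id, flags=flags)


def manders_overlap(
    stack: ImageStack,
    channel_a: str,
    channel_b: str,
    roi: Optional[RectROI] = None,
    slice_z: int = 0,
    rolling_ball_radius_px: int = 100,
    roi_id: str = "",
) -> OverlapResult:
    """Manders coefficients between two Yen-binarized channels in one slice.

    Background subtraction runs on the full selected slice before cropping,
    matching the acquisition protocol order (subtract, crop, select slice,
    binarize).
    """
    cal = stack.calibration
    if roi is None:
        ny, nx = stack.shape_zyx[1:]
        roi = RectROI(center=(nx / 2, ny / 2), width=nx * cal.pixel_size_xy,
                      height=ny * cal.pixel_size_xy, unit="px")
    masks = []
    for name in (channel_a, channel_b):
        vol = stack.channel(name)
        if not (0 <= slice_z < vol.shape[0]):
            raise BoundsError(f"slice_z={slice_z} outside stack of {vol.shape[0]}")
        bgsub = rolling_ball_subtract(vol[slice_z].astype(float),
                                      rolling_ball_radius_px)
        sub = crop_roi(bgsub, roi, cal)
        masks.append(auto_threshold(sub, "yen", calibration=cal).pixels)
    return manders_from_masks(masks[0], masks[1], roi_id=roi_id)


# ---------------------------------------------------------------------------
# helper: automatic basal-body detection (optional; anchors are normally inputs)


def detect_basal_bodies(
    gtub_sideview: np.ndarray, n_peaks: int = 1, min_separation_px: int = 5
) -> List[Tuple[int, int]]:
    """Brightest γ-tubulin puncta in a side-view slice, as (x, z) anchors.

    A convenience for synthetic data and quick looks; on real data basal
    bodies are selected manually and passed in as anchors.
    """
    from skimage.feature import peak_local_max

    img = np.asarray(gtub_sideview, dtype=float)
    peaks = peak_local_max(
        img, min_distance=min_separation_px, num_peaks=n_peaks
    )
    return [(int(x), int(z)) for z, x in peaks]
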