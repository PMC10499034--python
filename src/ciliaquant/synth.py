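"""Synthetic confocal z-stacks of polarized epithelial monolayers.

Generates multi-channel volumes that emulate the statistical structure the
measurement pipelines assume: a confluent cell grid with apically docked
basal bodies, an apical actin cortex with circular clearings above the basal
bodies, rod-shaped cilia in a tunable fraction of cells, a LysoTracker-like
vesicle channel with lognormally sized blobs, and a punctate membrane-traffic
marker channel whose mass is partitioned between basal body, vesicle rims and
cytosol.  Every generator is deterministic given its seed and records full
ground truth.

The optical model is deliberately simple — an isotropic Gaussian PSF and a
scaled-Poisson + Gaussian-read-noise camera over a constant background — so
each pipeline's recovery can be checked against analytically known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import GeometryError, InvalidParameterError, PackingError
from .imagecore.types import Calibration, ImageStack

# fluorophore amplitudes (arbitrary intensity units, 16-bit scale)
_AMP = {
    "nuclei": 120.0,
    "actin": 150.0,
    "junction": 60.0,
    "gtubulin": 200.0,
    "cilia": 160.0,
    "vesicles": 140.0,
    "rab19": 180.0,
}

CHANNELS = ("nuclei", "actin", "gtubulin", "cilia", "vesicles", "rab19")


# ---------------------------------------------------------------------------
# specs and ground truth


@dataclass
class MonolayerSpec:
    """Parameters of a simulated polarized monolayer.

    Defaults describe a confluent MDCK-like sheet: 10 µm cells, a 1 µm
    apical cortex topping a 10 µm tall monolayer, 40% ciliation, a 60%
    actin-intensity clearing of radius 1 µm above each basal body, ~4
    LysoTracker-positive vesicles per cell with lognormal radii (median
    0.35 µm), and a punctum channel split 30/40/30% between basal body,
    vesicle rims and cytosol.
    """

    n_cells_x: int = 10
    n_cells_y: int = 10
    cell_diameter: float = 10.0  # µm
    calibration: Calibration = field(default_factory=lambda: Calibration(0.28, 0.28))
    stack_shape: Optional[Tuple[int, int, int]] = None  # (z, y, x) px; auto if None
    monolayer_height: float = 10.0  # µm, basal surface to cortex top
    cortex_thickness: float = 1.0  # µm
    ciliation_fraction: float = 0.4
    cilium_length_range: Tuple[float, float] = (2.0, 5.0)  # µm
    cilium_tilt_deg_range: Tuple[float, float] = (15.0, 60.0)  # from the z axis
    # per-cell lognormal (median, sigma) cytoplasmic background in the cilia
    # channel: axoneme markers also stain the cytoplasmic microtubule network
    cilia_stain_haze: Tuple[float, float] = (12.0, 0.4)
    # discrete cytoplasmic microtubule filaments in the cilia channel; these
    # small-scale, intermediate-intensity structures survive rolling-ball
    # subtraction the way real cytoskeletal staining does
    cilia_filaments_per_cell: float = 8.0
    cilia_filament_amp: Tuple[float, float] = (20.0, 0.3)  # lognormal (median, sigma)
    clearing_depth: float = 0.6  # fractional cortex-intensity reduction
    clearing_radius: float = 1.0  # µm
    vesicles_per_cell: float = 4.0
    vesicle_radius_lognormal: Tuple[float, float] = (math.log(0.35), 0.3)
    marker_puncta_per_cell: int = 12
    marker_partition: Tuple[float, float, float] = (0.3, 0.4, 0.3)
    psf_sigma: float = 0.15  # µm
    background_level: float = 10.0
    poisson_scale: float = 5.0  # photons per intensity unit
    gaussian_read_sd: float = 2.0
    keep_noiseless: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.marker_partition
        if any(not (0.0 <= x <= 1.0) for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise InvalidParameterError(
                "marker_partition fractions must lie in [0,1] and sum to 1"
            )
        if not (0.0 <= self.ciliation_fraction <= 1.0):
            raise InvalidParameterError("ciliation_fraction must be in [0, 1]")
        if not (0.0 <= self.clearing_depth <= 1.0):
            raise InvalidParameterError("clearing_depth must be in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.n_cells_x * self.n_cells_y

    def resolved_shape(self) -> Tuple[int, int, int]:
        if self.stack_shape is not None:
            return tuple(self.stack_shape)
        psz = self.calibration.pixel_size_xy
        nx = int(math.ceil(self.n_cells_x * self.cell_diameter / psz))
        ny = int(math.ceil(self.n_cells_y * self.cell_diameter / psz))
        z_extent = self.monolayer_height + self.cilium_length_range[1] + 2.0
        nz = int(math.ceil(z_extent / self.calibration.z_step)) + 1
        return (nz, ny, nx)


@dataclass
class CellTruth:
    center_xy_um: Tuple[float, float]
    basal_body_xyz_um: Tuple[float, float, float]  # (x, y, z)
    has_cilium: bool
    clearing_depth_true: float
    cilium_length_um: float = 0.0


@dataclass
class VesicleTruth:
    center_xyz_um: Tuple[float, float, float]
    radius_um: float

    @property
    def area_um2(self) -> float:
        """Equatorial cross-sectional area."""
        return math.pi * self.radius_um**2


@dataclass
class PunctumTruth:
    position_xyz_um: Tuple[float, float, float]
    compartment: str  # basal_body | vesicle | cytosol
    cell_index: int


@dataclass
class GroundTruth:
    cells: List[CellTruth] = field(default_factory=list)
    vesicles: List[VesicleTruth] = field(default_factory=list)
    puncta: List[PunctumTruth] = field(default_factory=list)
    noiseless: Optional[Dict[str, np.ndarray]] = None
    expected_overlap: Optional[Tuple[float, float]] = None

    @property
    def realized_ciliation_fraction(self) -> float:
        if not self.cells:
            raise InvalidParameterError("no cells in ground truth")
        return sum(c.has_cilium for c in self.cells) / len(self.cells)


# ---------------------------------------------------------------------------
# drawing helpers (z, y, x pixel coordinates; additive patches)


def _patch(vol: np.ndarray, center: Sequence[float], half: Sequence[int]):
    slices, grids = [], []
    for ax, (c, h) in enumerate(zip(center, half)):
        lo = max(0, int(math.floor(c)) - h)
        hi = min(vol.shape[ax], int(math.ceil(c)) + h + 1)
        slices.append(slice(lo, hi))
        grids.append(np.arange(lo, hi, dtype=float) - c)
    return tuple(slices), grids


def _add_gaussian(vol, center_zyx, sigma_px, amp) -> None:
    h = max(2, int(math.ceil(4 * sigma_px)))
    sl, (gz, gy, gx) = _patch(vol, center_zyx, (h, h, h))
    if any(g.size == 0 for g in (gz, gy, gx)):
        return
    d2 = (
        gz[:, None, None] ** 2 + gy[None, :, None] ** 2 + gx[None, None, :] ** 2
    )
    vol[sl] += amp * np.exp(-d2 / (2 * sigma_px**2))


def _add_ellipsoid(vol, center_zyx, radii_zyx, amp) -> None:
    h = [int(math.ceil(r)) + 1 for r in radii_zyx]
    sl, (gz, gy, gx) = _patch(vol, center_zyx, h)
    if any(g.size == 0 for g in (gz, gy, gx)):
        return
    rz, ry, rx = radii_zyx
    inside = (
        (gz[:, None, None] / rz) ** 2
        + (gy[None, :, None] / ry) ** 2
        + (gx[None, None, :] / rx) ** 2
    ) <= 1.0
    vol[sl] += amp * inside


def _add_rod(vol, base_zyx, end_zyx, radius_px, amp, supersample: int = 3) -> None:
    """Uniform-density cylinder between two points (pixel coordinates).

    Each voxel receives ``amp`` times its volume fraction inside the
    cylinder, estimated by ``supersample``³ sub-voxel samples.  Area
    sampling conserves flux along the axis, so a rod thinner than the
    voxel pitch stays continuous after PSF blurring instead of beating
    against the sampling grid.
    """
    base = np.asarray(base_zyx, dtype=float)
    end = np.asarray(end_zyx, dtype=float)
    axis = end - base
    length = float(np.linalg.norm(axis))
    d = axis / length if length > 0 else np.array([1.0, 0.0, 0.0])
    r = max(radius_px, 0.5)
    lo = np.maximum(np.floor(np.minimum(base, end) - r - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(base, end) + r + 1).astype(int) + 1, vol.shape)
    if np.any(hi <= lo):
        return
    gz, gy, gx = np.meshgrid(
        *[np.arange(l, h, dtype=float) for l, h in zip(lo, hi)], indexing="ij"
    )
    centers = np.stack([gz, gy, gx], axis=-1)
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    cover = np.zeros(centers.shape[:-1], dtype=np.float64)
    for oz in offs:
        for oy in offs:
            for ox in offs:
                pts = centers + np.array([oz, oy, ox]) - base
                t = np.clip(pts @ d, 0.0, length)
                dist2 = ((pts - t[..., None] * d) ** 2).sum(axis=-1)
                cover += dist2 <= r * r
    cover /= supersample**3
    vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amp * cover


def _camera(
    noiseless: np.ndarray,
    background: float,
    poisson_scale: float,
    read_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    lam = np.clip(noiseless + background, 0.0, None) * poisson_scale
    out = rng.poisson(lam).astype(np.float32) / poisson_scale
    out += rng.normal(0.0, read_sd, size=noiseless.shape).astype(np.float32)
    return np.clip(out, 0.0, 65535.0).astype(np.float32)


# ---------------------------------------------------------------------------
# generators


def generate_monolayer(spec: MonolayerSpec) -> Tuple[ImageStack, GroundTruth]:
    """Render a polarized monolayer stack with full per-cell ground truth.

    The z index increases apically: z=0 is the basal surface, the actin
    cortex tops the monolayer, and cilia protrude into the z-slices above it.
    """
    rng = np.random.default_rng(spec.seed)
    psz = spec.calibration.pixel_size_xy
    zst = spec.calibration.z_step
    nz, ny, nx = spec.resolved_shape()

    # geometry checks: grid must fit laterally, cortex + cilia must fit in z
    if spec.n_cells_x * spec.cell_diameter > nx * psz + 1e-6 or (
        spec.n_cells_y * spec.cell_diameter > ny * psz + 1e-6
    ):
        raise GeometryError("cell grid does not fit the stack laterally")
    z_needed = spec.monolayer_height + spec.cilium_length_range[1]
    if z_needed > nz * zst:
        raise GeometryError(
            f"monolayer + cilia need {z_needed:.1f} µm in z, stack has {nz * zst:.1f}"
        )

    cortex_top_um = spec.monolayer_height
    cortex_bot_um = cortex_top_um - spec.cortex_thickness
    bb_z_um = cortex_bot_um  # basal body docked just under the cortex

    # jittered square grid of cell centers
    cells: List[CellTruth] = []
    jit = 0.1 * spec.cell_diameter
    n_cilia = int(round(spec.ciliation_fraction * spec.n_cells))
    ciliated = set(rng.permutation(spec.n_cells)[:n_cilia].tolist())
    idx = 0
    for iy in range(spec.n_cells_y):
        for ix in range(spec.n_cells_x):
            cx = (ix + 0.5) * spec.cell_diameter + rng.uniform(-jit, jit)
            cy = (iy + 0.5) * spec.cell_diameter + rng.uniform(-jit, jit)
            has_cil = idx in ciliated
            length = rng.uniform(*spec.cilium_length_range) if has_cil else 0.0
            cells.append(
                CellTruth(
                    center_xy_um=(cx, cy),
                    basal_body_xyz_um=(cx, cy, bb_z_um),
                    has_cilium=has_cil,
                    clearing_depth_true=spec.clearing_depth,
                    cilium_length_um=length,
                )
            )
            idx += 1

    chans = {name: np.zeros((nz, ny, nx), dtype=np.float32) for name in CHANNELS}

    # --- actin: apical cortical slab with clearings, plus junction walls
    yy, xx = np.mgrid[0:ny, 0:nx]
    yy_um = yy * psz
    xx_um = xx * psz
    centers = np.array([c.center_xy_um for c in cells])  # (n, 2) = (x, y)
    d2 = (xx_um[..., None] - centers[None, None, :, 0]) ** 2 + (
        yy_um[..., None] - centers[None, None, :, 1]
    ) ** 2
    d_sorted = np.sort(np.sqrt(d2, dtype=np.float32), axis=-1)
    wall = (d_sorted[..., 1] - d_sorted[..., 0]) < 0.6  # µm ridge width
    nearest_bb = d_sorted[..., 0]
    del d2, d_sorted

    slab = np.ones((ny, nx), dtype=np.float32)
    slab[nearest_bb <= spec.clearing_radius] = 1.0 - spec.clearing_depth
    z_cortex = slice(int(round(cortex_bot_um / zst)), int(round(cortex_top_um / zst)) + 1)
    chans["actin"][z_cortex] += _AMP["actin"] * slab[None, :, :]
    z_lateral = slice(int(round(1.0 / zst)), z_cortex.start)
    chans["actin"][z_lateral, wall] += _AMP["junction"]

    # --- per-cell structures
    vesicle_by_cell: List[List[int]] = [[] for _ in cells]
    truth = GroundTruth(cells=cells)
    sig_psf_px = spec.psf_sigma / psz
    cilia_haze = np.zeros((ny, nx), dtype=np.float32)
    for ci, cell in enumerate(cells):
        cx_um, cy_um = cell.center_xy_um
        cx, cy = cx_um / psz, cy_um / psz
        bb_z = bb_z_um / zst

        _add_ellipsoid(
            chans["nuclei"],
            (4.0 / zst, cy, cx),
            (2.5 / zst, 3.0 / psz, 3.0 / psz),
            _AMP["nuclei"],
        )
        _add_gaussian(chans["gtubulin"], (bb_z, cy, cx), 0.15 / psz, _AMP["gtubulin"])
        if spec.cilia_stain_haze[0] > 0:
            haze_amp = rng.lognormal(
                math.log(spec.cilia_stain_haze[0]), spec.cilia_stain_haze[1]
            )
            sig_cell = 0.45 * spec.cell_diameter / psz
            cilia_haze += haze_amp * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sig_cell**2)
            ).astype(np.float32)
        for _ in range(rng.poisson(spec.cilia_filaments_per_cell)):
            fl = rng.uniform(2.0, 4.0)  # µm
            fang = rng.uniform(0.0, 2.0 * math.pi)
            fz = rng.uniform(2.0, cortex_bot_um)
            fx = cx_um + rng.uniform(-0.3, 0.3) * spec.cell_diameter
            fy = cy_um + rng.uniform(-0.3, 0.3) * spec.cell_diameter
            fdz = rng.uniform(-0.15, 0.15) * fl
            fbase = (fz / zst, fy / psz, fx / psz)
            fend = (
                (fz + fdz) / zst,
                (fy + fl * math.sin(fang)) / psz,
                (fx + fl * math.cos(fang)) / psz,
            )
            _add_rod(
                chans["cilia"],
                fbase,
                fend,
                0.1 / psz,
                float(rng.lognormal(math.log(spec.cilia_filament_amp[0]),
                                    spec.cilia_filament_amp[1])),
                supersample=2,
            )
        if cell.has_cilium:
            # fixed cilia lie at varied angles; the tilt sets the lateral
            # footprint the cilium projects into a maximum projection
            tilt = math.radians(rng.uniform(*spec.cilium_tilt_deg_range))
            azim = rng.uniform(0.0, 2.0 * math.pi)
            length = cell.cilium_length_um
            base = (cortex_top_um / zst, cy, cx)
            end = (
                (cortex_top_um + length * math.cos(tilt)) / zst,
                cy + length * math.sin(tilt) * math.sin(azim) / psz,
                cx + length * math.sin(tilt) * math.cos(azim) / psz,
            )
            _add_rod(chans["cilia"], base, end, 0.2 / psz, _AMP["cilia"])

        n_ves = rng.poisson(spec.vesicles_per_cell)
        for _ in range(n_ves):
            r_um = float(
                np.clip(rng.lognormal(*spec.vesicle_radius_lognormal), 0.1, 1.5)
            )
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0, 0.35 * spec.cell_diameter)
            vx = cx_um + rad * math.cos(ang)
            vy = cy_um + rad * math.sin(ang)
            vz = rng.uniform(1.5, cortex_bot_um - 1.0)
            _add_ellipsoid(
                chans["vesicles"],
                (vz / zst, vy / psz, vx / psz),
                (r_um / zst, r_um / psz, r_um / psz),
                float(rng.lognormal(math.log(_AMP["vesicles"]), 0.8)),
            )
            vesicle_by_cell[ci].append(len(truth.vesicles))
            truth.vesicles.append(VesicleTruth((vx, vy, vz), r_um))

        counts = rng.multinomial(spec.marker_puncta_per_cell, spec.marker_partition)
        for comp, n_p in zip(("basal_body", "vesicle", "cytosol"), counts):
            for _ in range(n_p):
                if comp == "basal_body":
                    px_um = cx_um + rng.normal(0, 0.15)
                    py_um = cy_um + rng.normal(0, 0.15)
                    pz_um = bb_z_um + rng.normal(0, 0.15)
                elif comp == "vesicle" and vesicle_by_cell[ci]:
                    ves = truth.vesicles[rng.choice(vesicle_by_cell[ci])]
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    px_um = ves.center_xyz_um[0] + ves.radius_um * u[0]
                    py_um = ves.center_xyz_um[1] + ves.radius_um * u[1]
                    pz_um = ves.center_xyz_um[2] + ves.radius_um * u[2]
                else:  # cytosol (also the fallback when the cell has no vesicle)
                    comp = "cytosol"
                    ang = rng.uniform(0, 2 * math.pi)
                    rad = rng.uniform(0, 0.4 * spec.cell_diameter)
                    px_um = cx_um + rad * math.cos(ang)
                    py_um = cy_um + rad * math.sin(ang)
                    pz_um = rng.uniform(1.5, cortex_bot_um - 0.5)
                _add_gaussian(
                    chans["rab19"],
                    (pz_um / zst, py_um / psz, px_um / psz),
                    0.12 / psz,
                    _AMP["rab19"],
                )
                truth.puncta.append(PunctumTruth((px_um, py_um, pz_um), comp, ci))

    # cytoplasmic microtubule haze fills the subapical cell body
    z_haze = slice(int(round(1.0 / zst)), int(round(cortex_top_um / zst)) + 1)
    chans["cilia"][z_haze] += cilia_haze[None, :, :]

    # --- optics + camera
    sigma = (spec.psf_sigma / zst, sig_psf_px, sig_psf_px)
    noiseless = {}
    for name in CHANNELS:
        blurred = ndi.gaussian_filter(chans[name], sigma=sigma)
        noiseless[name] = blurred
        chans[name] = _camera(
            blurred,
            spec.background_level,
            spec.poisson_scale,
            spec.gaussian_read_sd,
            rng,
        )
    if spec.keep_noiseless:
        truth.noiseless = noiseless

    stack = ImageStack(
        voxels=np.stack([chans[n] for n in CHANNELS]),
        channel_names=list(CHANNELS),
        calibration=spec.calibration,
        bit_depth=16,
    )
    return stack, truth


def _place_disks(
    n: int,
    radii_px: np.ndarray,
    shape_yx: Tuple[int, int],
    rng: np.random.Generator,
    existing: Optional[List[Tuple[float, float, float]]] = None,
    margin_px: float = 3.0,
    separation_px: float = 2.0,
    max_tries: int = 20000,
) -> List[Tuple[float, float, float]]:
    """Rejection-sample non-overlapping disk centers; (y, x, r) in px."""
    placed: List[Tuple[float, float, float]] = []
    avoid = list(existing or [])
    tries = 0
    ny, nx = shape_yx
    for r in radii_px:
        while True:
            tries += 1
            if tries > max_tries:
                raise PackingError(
                    f"could not place {n} non-overlapping vesicles in {shape_yx}"
                )
            y = rng.uniform(r + margin_px, ny - 1 - r - margin_px)
            x = rng.uniform(r + margin_px, nx - 1 - r - margin_px)
            ok = all(
                math.hypot(y - oy, x - ox) >= r + orr + separation_px
                for oy, ox, orr in placed + avoid
            )
            if ok:
                placed.append((y, x, r))
                break
    return placed


def generate_vesicle_field(
    n_vesicles: int,
    radius_lognormal: Tuple[float, float] = (math.log(0.35), 0.3),
    field_shape: Tuple[int, int] = (238, 238),
    calibration: Calibration = Calibration(0.21, 0.21),
    background_level: float = 10.0,
    poisson_scale: float = 5.0,
    gaussian_read_sd: float = 2.0,
    psf_sigma: float = 0.15,
    amplitude_lognormal: Tuple[float, float] = (math.log(140.0), 0.8),
    seed: int = 0,
) -> Tuple[ImageStack, GroundTruth]:
    """A single-slice LysoTracker-like field of non-overlapping round vesicles.

    Disk radii are lognormal in µm (σ=0 gives exact radii); ground truth
    records each exact equatorial area πr².  Per-vesicle brightness is
    lognormal (acidic compartments accumulate the dye to very different
    degrees — roughly a ten-fold spread with the default σ=0.8).
    """
    if n_vesicles < 0:
        raise InvalidParameterError("n_vesicles must be ≥ 0")
    rng = np.random.default_rng(seed)
    psz = calibration.pixel_size_xy
    radii_um = np.clip(
        rng.lognormal(radius_lognormal[0], radius_lognormal[1], size=n_vesicles),
        0.1,
        3.0,
    )
    placed = _place_disks(n_vesicles, radii_um / psz, field_shape, rng)

    img = np.zeros(field_shape, dtype=np.float32)
    truth = GroundTruth()
    yy, xx = np.mgrid[0 : field_shape[0], 0 : field_shape[1]]
    amps = rng.lognormal(*amplitude_lognormal, size=n_vesicles)
    for (y, x, r), r_um, amp in zip(placed, radii_um, amps):
        img[(yy - y) ** 2 + (xx - x) ** 2 <= r**2] += amp
        truth.vesicles.append(VesicleTruth((x * psz, y * psz, 0.0), float(r_um)))

    blurred = ndi.gaussian_filter(img, sigma=psf_sigma / psz)
    noisy = _camera(blurred, background_level, poisson_scale, gaussian_read_sd, rng)
    stack = ImageStack(
        voxels=noisy[None, None, :, :],
        channel_names=["vesicles"],
        calibration=calibration,
        bit_depth=16,
    )
    return stack, truth


def generate_coloc_pair(
    n_objects: int,
    overlap_fraction: float,
    field_shape: Tuple[int, int] = (250, 250),
    calibration: Calibration = Calibration(0.12, 0.12),
    radius_range_um: Tuple[float, float] = (0.25, 0.6),
    background_level: float = 5.0,
    poisson_scale: float = 5.0,
    gaussian_read_sd: float = 1.0,
    psf_sigma: float = 0.12,
    seed: int = 0,
) -> Tuple[ImageStack, GroundTruth]:
    """Two-channel field where channel B duplicates a fraction of channel A.

    ``expected_overlap`` in the ground truth holds (M1, M2) computed by
    pixel counting on the noiseless binary masks.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise InvalidParameterError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    psz = calibration.pixel_size_xy
    radii_a = rng.uniform(*radius_range_um, size=n_objects) / psz
    placed_a = _place_disks(n_objects, radii_a, field_shape, rng)

    n_shared = int(round(overlap_fraction * n_objects))
    shared_idx = rng.permutation(n_objects)[:n_shared]
    placed_b = [placed_a[i] for i in shared_idx]
    n_new = n_objects - n_shared
    radii_b = rng.uniform(*radius_range_um, size=n_new) / psz
    placed_b += _place_disks(
        n_new, radii_b, field_shape, rng, existing=placed_a + placed_b
    )

    yy, xx = np.mgrid[0 : field_shape[0], 0 : field_shape[1]]

    def render(placed):
        img = np.zeros(field_shape, dtype=np.float32)
        mask = np.zeros(field_shape, dtype=bool)
        for y, x, r in placed:
            disk = (yy - y) ** 2 + (xx - x) ** 2 <= r**2
            img[disk] += _AMP["vesicles"]
            mask |= disk
        return img, mask

    img_a, mask_a = render(placed_a)
    img_b, mask_b = render(placed_b)
    inter = float(np.sum(mask_a & mask_b))
    m1 = inter / mask_a.sum() if mask_a.any() else 0.0
    m2 = inter / mask_b.sum() if mask_b.any() else 0.0

    sig = psf_sigma / psz
    vox = np.stack(
        [
            _camera(
                ndi.gaussian_filter(img, sig),
                background_level,
                poisson_scale,
                gaussian_read_sd,
                rng,
            )[None, :, :]
            for img in (img_a, img_b)
        ]
    )
    truth = GroundTruth(
        expected_overlap=(m1, m2),
        noiseless={"chan_a_mask": mask_a, "chan_b_mask": mask_b},
    )
    stack = ImageStack(
        voxels=vox,
        channel_names=["chan_a", "chan_b"],
        calibration=calibration,
        bit_depth=16,
    )
    return stack, truth


def generate_replicate_study(
    n_conditions: int,
    n_biorep: int,
    n_techrep: int,
    group_means: Sequence[float],
    group_sds: Sequence[float],
    tech_sds: Optional[Sequence[float]] = None,
    outlier_spec: Optional[Sequence[Tuple[int, int, float]]] = None,
    seed: int = 0,
    condition_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Tidy (condition, bio_rep, tech_rep, value) table with Gaussian structure.

    Each biological replicate draws its mean from N(group_mean, group_sd);
    technical replicates then scatter around it with ``tech_sds`` (default:
    half the group sd).  ``outlier_spec`` entries (condition_idx,
    biorep_idx, value) force a gross-outlier bio-rep mean; injected outliers
    are recorded in ``df.attrs['injected_outliers']``.
    """
    if not (len(group_means) == len(group_sds) == n_conditions):
        raise InvalidParameterError("group_means/group_sds must match n_conditions")
    if tech_sds is None:
        tech_sds = [s / 2.0 for s in group_sds]
    if condition_names is None:
        condition_names = [f"cond{i}" for i in range(n_conditions)]
    rng = np.random.default_rng(seed)
    forced = {(c, b): v for c, b, v in (outlier_spec or [])}

    rows = []
    for ci in range(n_conditions):
        for bi in range(n_biorep):
            mean_b = forced.get(
                (ci, bi), rng.normal(group_means[ci], group_sds[ci])
            )
            for ti in range(n_techrep):
                rows.append(
                    {
                        "condition": condition_names[ci],
                        "bio_rep": f"bio{bi}",
                        "tech_rep": f"tech{ti}",
                        "value": float(rng.normal(mean_b, tech_sds[ci])),
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["injected_outliers"] = [
        (condition_names[c], f"bio{b}", v) for (c, b), v in forced.items()
    ]
    return df
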