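"""TIFF/OME-TIFF stack I/O, run configuration, and tidy result output.

Calibration is taken from OME metadata when present; a config override wins
over file metadata (with a logged warning).  Every run writes a tidy CSV,
a JSON manifest (config hash, seed, package version) and a log file, so an
analysis is reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import InvalidInputError
from .imagecore.types import Calibration, ImageStack
from .synth import GroundTruth

logger = logging.getLogger("ciliaquant")

# Defaults follow the acquisition-matched protocol values: rolling-ball radii
# in pixels (tuned for 0.21/0.28/0.12 µm pixel sizes and deliberately NOT
# rescaled by calibration), particle size cutoffs in pixels, ROI geometries
# in µm, ROUT Q = 2%.
DEFAULTS: Dict[str, Dict[str, Any]] = {
    "lyso": {
        "rolling_ball_radius_px": 20,
        "min_size_px": 3,
        "circularity_range": [0.50, 1.0],
        "roi_size_um": 50.0,
    },
    "clearing": {
        "roi_width_um": 8.0,
        "roi_height_um": 5.0,
        "center_halfwidth_um": 0.3,
        "flank_um": [2.0, 4.0],
    },
    "ciliation": {
        "rolling_ball_radius_px": 100,
        "variant": "mdck",
        "nuclei_min_size_px": 150,
    },
    "enrichment": {
        "rolling_ball_radius_px": 75,
        "bb_width_um": 3.0,
        "bb_height_um": 2.0,
        "uniform_high": 0.99,
        "uniform_low": 0.005,
    },
    "coloc": {"rolling_ball_radius_px": 100, "roi_size_um": 30.0},
    "stats": {"rout_q": 0.02, "comparisons": "all-pairs", "control": None},
}


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    ``channels`` maps pipeline roles (e.g. "vesicles", "cilia", "nuclei")
    to channel names in the input stack.  ``params`` holds per-pipeline
    parameter overrides on top of the protocol defaults.
    """

    input: Optional[str] = None
    channels: Dict[str, str] = field(default_factory=dict)
    pixel_size_xy: Optional[float] = None
    z_step: Optional[float] = None
    params: Dict[str, Dict[str, Any]] = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "results"

    def pipeline_params(self, pipeline: str) -> Dict[str, Any]:
        merged = dict(DEFAULTS.get(pipeline, {}))
        merged.update(self.params.get(pipeline, {}))
        return merged

    def calibration_override(self) -> Optional[Calibration]:
        if self.pixel_size_xy is None:
            return None
        return Calibration(self.pixel_size_xy, self.z_step or self.pixel_size_xy)

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: Union[str, Path]) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# stacks


def write_stack(stack: ImageStack, path: Union[str, Path]) -> None:
    """Write an ImageStack as OME-TIFF with physical calibration metadata."""
    vox = np.asarray(stack.voxels)
    if vox.dtype.kind == "f":
        vox = np.round(vox).astype(np.uint16 if stack.bit_depth == 16 else np.uint8)
    # content-derived UUID so identical stacks produce byte-identical files
    import uuid as _uuid

    digest = hashlib.sha256(vox.tobytes()).hexdigest()
    file_uuid = str(_uuid.uuid5(_uuid.NAMESPACE_URL, digest))
    tifffile.imwrite(
        str(path),
        vox,
        ome=True,
        metadata={
            "UUID": f"urn:uuid:{file_uuid}",
            "Creator": "ciliaquant",
            "axes": "CZYX",
            "PhysicalSizeX": stack.calibration.pixel_size_xy,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.calibration.pixel_size_xy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.calibration.z_step,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def _ome_calibration(tif: tifffile.TiffFile) -> Optional[Calibration]:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        if px is None:
            return None
        sx = px.get("PhysicalSizeX")
        sz = px.get("PhysicalSizeZ")
        if sx is None:
            return None
        return Calibration(float(sx), float(sz) if sz else float(sx))
    except Exception:  # missing/malformed metadata is not fatal
        return None


def _ome_channel_names(tif: tifffile.TiffFile, n: int) -> Optional[List[str]]:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        names = [c.get("Name") for c in root.findall(".//ome:Channel", ns)]
        if len(names) == n and all(names):
            return names
    except Exception:
        pass
    return None


def read_stack(
    path: Union[str, Path],
    channel_names: Optional[Sequence[str]] = None,
    calibration: Optional[Calibration] = None,
    bit_depth: Optional[int] = None,
) -> ImageStack:
    """Read a single- or multi-channel TIFF/OME-TIFF stack.

    Explicit ``calibration``/``channel_names`` arguments (e.g. from a
    RunConfig) override file metadata; a conflict is logged.  A file without
    calibration metadata and without an override is an error.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. 'CZYX', 'ZYX', 'YX'
        file_cal = _ome_calibration(tif) if tif.is_ome else None

    # normalize to (C, Z, Y, X)
    axes = axes.replace("S", "C")
    for missing_ax, pos in (("C", 0), ("Z", 1)):
        if missing_ax not in axes:
            data = np.expand_dims(data, axis=0)
            axes = missing_ax + axes
    order = [axes.index(a) for a in "CZYX"]
    if sorted(order) != list(range(data.ndim)):
        raise InvalidInputError(f"unsupported TIFF axes {axes!r}")
    data = np.transpose(data, order)

    if calibration is not None and file_cal is not None:
        if not (
            np.isclose(calibration.pixel_size_xy, file_cal.pixel_size_xy)
            and np.isclose(calibration.z_step, file_cal.z_step)
        ):
            logger.warning(
                "calibration override %s conflicts with file metadata %s; "
                "using the override",
                calibration,
                file_cal,
            )
        cal = calibration
    else:
        cal = calibration or file_cal
    if cal is None:
        raise InvalidInputError(
            f"{path} has no calibration metadata; supply a config override"
        )

    n_chan = data.shape[0]
    if channel_names is None:
        with tifffile.TiffFile(str(path)) as tif:
            channel_names = (
                _ome_channel_names(tif, n_chan) if tif.is_ome else None
            )
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_chan)]
    if len(channel_names) != n_chan:
        raise InvalidInputError(
            f"{len(channel_names)} channel names for {n_chan} channels"
        )
    if bit_depth is None:
        bit_depth = 8 if data.dtype == np.uint8 else 16
    return ImageStack(
        voxels=data,
        channel_names=list(channel_names),
        calibration=cal,
        bit_depth=bit_depth,
    )


# ---------------------------------------------------------------------------
# ground truth sidecar


def write_ground_truth(truth: GroundTruth, path: Union[str, Path]) -> None:
    """JSON sidecar with the generator's ground truth (volumes excluded)."""
    payload = {
        "cells": [
            {
                "center_xy_um": list(c.center_xy_um),
                "basal_body_xyz_um": list(c.basal_body_xyz_um),
                "has_cilium": c.has_cilium,
                "clearing_depth_true": c.clearing_depth_true,
                "cilium_length_um": c.cilium_length_um,
            }
            for c in truth.cells
        ],
        "vesicles": [
            {
                "center_xyz_um": list(v.center_xyz_um),
                "radius_um": v.radius_um,
                "area_um2": v.area_um2,
            }
            for v in truth.vesicles
        ],
        "puncta": [
            {
                "position_xyz_um": list(p.position_xyz_um),
                "compartment": p.compartment,
                "cell_index": p.cell_index,
            }
            for p in truth.puncta
        ],
        "expected_overlap": (
            list(truth.expected_overlap) if truth.expected_overlap else None
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# results


def write_results(
    results: Union[pd.DataFrame, List[Dict[str, Any]]],
    out_dir: Union[str, Path],
    name: str,
    config: Optional[RunConfig] = None,
    seed: Optional[int] = None,
    columns: Optional[Sequence[str]] = None,
) -> Path:
    """Write a tidy CSV plus a JSON run manifest; returns the CSV path.

    The CSV is deterministic for a given (results, config, seed) — no
    timestamps — so reruns with the same seed are byte-identical.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = (
        results
        if isinstance(results, pd.DataFrame)
        else pd.DataFrame(results, columns=columns)
    )
    csv_path = out_dir / f"{name}.csv"
    df.to_csv(csv_path, index=False)
    manifest = {
        "pipeline": name,
        "seed": seed,
        "config_hash": config.content_hash() if config else None,
        "config": config.to_dict() if config else None,
        "version": __version__,
        "n_rows": int(len(df)),
    }
    (out_dir / f"{name}.manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("wrote %s (%d rows)", csv_path, len(df))
    return csv_path
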