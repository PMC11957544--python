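"""Reading and writing volumes as TIFF / OME-TIFF with physical metadata.

Spacing is embedded in the ImageJ-compatible TIFF metadata on write
(x/y resolution tags plus the ``spacing`` key for z) so files round-trip
through this module and open with correct calibration in ImageJ/Fiji.
A plain-text YAML sidecar (``<stem>.yaml``) carrying ``spacing`` and
``expansion_factor`` is honoured when present and written alongside.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .grid import VoxelGrid

logger = logging.getLogger(__name__)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml") if path.is_dir() else path.with_suffix(".yaml")


def write_volume(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a grid as a multi-page TIFF; dtype is preserved exactly.

    Returns the written path.  Spacing goes into ImageJ metadata and a
    YAML sidecar (which also records the expansion factor, for which
    TIFF has no standard tag).
    """
    path = Path(path)
    dz, dy, dx = grid.spacing
    tifffile.imwrite(
        path,
        grid.data,
        imagej=grid.data.dtype in (np.dtype("uint8"), np.dtype("uint16"), np.dtype("float32")),
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        yaml.safe_dump(
            {"spacing": [dz, dy, dx], "expansion_factor": grid.expansion_factor},
            sort_keys=False,
        )
    )
    return path


def _spacing_from_tiff(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Extract (dz, dy, dx) µm from ImageJ/OME metadata if present."""
    try:
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            for el in root.iter():
                if el.tag.endswith("Pixels"):
                    a = el.attrib
                    if all(k in a for k in ("PhysicalSizeX", "PhysicalSizeY", "PhysicalSizeZ")):
                        return (
                            float(a["PhysicalSizeZ"]),
                            float(a["PhysicalSizeY"]),
                            float(a["PhysicalSizeX"]),
                        )
    except Exception:  # pragma: no cover - malformed OME-XML
        pass
    ij = tf.imagej_metadata
    dz = ij.get("spacing") if ij else None
    page = tf.pages[0]
    dx = dy = None
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is not None and xres.value[0]:
        dx = xres.value[1] / xres.value[0]
    if yres is not None and yres.value[0]:
        dy = yres.value[1] / yres.value[0]
    if dz is not None and dx is not None and dy is not None:
        return (float(dz), float(dy), float(dx))
    return None


def read_volume(
    path: str | Path,
    spacing: tuple[float, float, float] | None = None,
    expansion_factor: float | None = None,
) -> VoxelGrid:
    """Read a TIFF/OME-TIFF stack (or a directory of per-slice TIFFs).

    Spacing resolution order: explicit argument > YAML sidecar > image
    metadata > ``(1, 1, 1)`` with a warning.  Explicit spacing that
    contradicts metadata wins, with a logged warning.  Integer intensity
    values are preserved bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not slices:
            raise FileNotFoundError(f"no TIFF slices in directory {path}")
        data = np.stack([tifffile.imread(p) for p in slices], axis=0)
        meta_spacing = None
    else:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta_spacing = _spacing_from_tiff(tf)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {data.shape}")

    sidecar = _sidecar_path(path)
    side = {}
    if sidecar.exists():
        side = yaml.safe_load(sidecar.read_text()) or {}
    side_spacing = tuple(side["spacing"]) if "spacing" in side else None

    resolved = spacing or side_spacing or meta_spacing
    if resolved is None:
        logger.warning("%s: no spacing metadata found; assuming (1, 1, 1) µm", path)
        resolved = (1.0, 1.0, 1.0)
    elif spacing is not None and meta_spacing is not None:
        if any(abs(a - b) > 1e-6 * max(abs(a), 1) for a, b in zip(spacing, meta_spacing)):
            logger.warning(
                "%s: explicit spacing %s overrides metadata spacing %s", path, spacing, meta_spacing
            )
    ef = expansion_factor if expansion_factor is not None else float(side.get("expansion_factor", 1.0))
    return VoxelGrid(data, spacing=tuple(float(s) for s in resolved), expansion_factor=ef)
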