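"""Calibrated image, trace-annotation and table I/O.

This module owns the on-disk schema every other stage consumes:

* grayscale micrographs as 8/16-bit TIFF or PNG plus a user-supplied
  calibration in nm/pixel (microscope pixel sizes are acquisition metadata
  the file formats do not carry, so calibration is always explicit);
* boundary traces as JSON polylines (inner primary-wall boundary, the
  primary-wall/cuticle interface, the cuticle outer edge) with an
  extracellular background polygon and an orientation flag naming the side
  of the interface on which the cuticle lies;
* measurement records as plain CSV.

Physical lengths are always nanometres; the single nm/pixel conversion
happens here.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

from ._geometry import (
    ORIENTATION_VECTORS,
    as_points,
    polygon_signed_area,
)
from .exceptions import (
    FormatError,
    GeometryError,
    SchemaError,
    TraceValidationError,
)

logger = logging.getLogger(__name__)

_TRACE_POLYLINES = ("inner_pw", "interface", "outer_edge")


@dataclass
class Micrograph:
    """A calibrated grayscale micrograph.

    ``pixels`` keeps the raw intensity grid (never rescaled on load);
    ``pixel_size_nm`` is the physical edge length of one pixel.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    bit_depth: int = 8
    id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(
                f"micrograph must be single-channel 2-D, got {self.pixels.ndim}-D"
            )
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixel_size_nm <= 0:
            raise FormatError("pixel_size_nm must be positive")
        if self.pixels.size and float(self.pixels.min()) < 0:
            raise FormatError("negative intensities are not valid")
        if self.pixels.size and float(self.pixels.max()) > 2**self.bit_depth - 1:
            raise FormatError(
                f"intensities exceed the {self.bit_depth}-bit range"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def intensity_max(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class BoundaryTrace:
    """Operator-traced boundaries of the primary-wall/cuticle band.

    Polylines are ordered ``[x, y]`` point lists in image coordinates
    (sub-pixel allowed). ``orientation`` states on which side of
    ``interface`` the cuticle (and hence ``outer_edge``) lies.
    """

    inner_pw: np.ndarray
    interface: np.ndarray
    outer_edge: np.ndarray
    background_region: np.ndarray
    orientation: str
    pixel_size_nm: float | None = None

    def __post_init__(self):
        for name in _TRACE_POLYLINES:
            pts = as_points(getattr(self, name))
            if len(pts) < 2:
                raise TraceValidationError(f"polyline {name!r} needs >= 2 points")
            if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
                raise TraceValidationError(
                    f"polyline {name!r} has consecutive duplicate points"
                )
            setattr(self, name, pts)
        self.background_region = as_points(self.background_region)
        if len(self.background_region) < 3:
            raise TraceValidationError("background_region needs >= 3 vertices")
        if abs(polygon_signed_area(self.background_region)) <= 0:
            raise TraceValidationError("background_region has zero area")
        if self.orientation not in ORIENTATION_VECTORS:
            raise TraceValidationError(
                f"unknown orientation {self.orientation!r}; expected one of "
                f"{sorted(ORIENTATION_VECTORS)}"
            )
        if self.pixel_size_nm is not None and self.pixel_size_nm <= 0:
            raise TraceValidationError("pixel_size_nm must be positive")
        self._check_orientation_consistency()
        self._check_background_disjoint()

    def _check_orientation_consistency(self):
        vec = ORIENTATION_VECTORS[self.orientation]
        offset = self.outer_edge.mean(axis=0) - self.interface.mean(axis=0)
        if float(offset @ vec) <= 0:
            raise TraceValidationError(
                f"orientation {self.orientation!r} inconsistent with geometry: "
                "outer_edge does not lie on the declared side of the interface"
            )

    def _check_background_disjoint(self):
        band = _ShapelyPolygon(
            np.concatenate([self.inner_pw, self.outer_edge[::-1]])
        )
        if not band.is_valid:
            band = band.buffer(0)
        bg = _ShapelyPolygon(self.background_region)
        if not bg.is_valid:
            bg = bg.buffer(0)
        if band.intersection(bg).area > 1e-9:
            raise TraceValidationError(
                "background_region overlaps the traced wall/cuticle band"
            )


@dataclass
class StainImage:
    """RGB brightfield picture of a dissected embryo plus its binary mask."""

    rgb_pixels: np.ndarray
    mask: np.ndarray
    id: str = ""

    def __post_init__(self):
        self.rgb_pixels = np.asarray(self.rgb_pixels)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.rgb_pixels.ndim != 3 or self.rgb_pixels.shape[2] != 3:
            raise FormatError("stain image must be H x W x 3 RGB")
        if self.mask.shape != self.rgb_pixels.shape[:2]:
            raise FormatError("mask shape must match the image")
        if not self.mask.any():
            raise FormatError("embryo mask is empty")


# ---------------------------------------------------------------------------
# raster I/O


def load_micrograph(path, pixel_size_nm: float, id: str | None = None) -> Micrograph:
    """Read an 8/16-bit grayscale TIFF or PNG with the stated calibration.

    Intensities are kept exactly as stored (16-bit data is not rescaled).
    Multi-channel rasters are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = iio.imread(path)
    if pixels.ndim == 3:
        raise FormatError(
            f"{path.name}: expected single-channel grayscale, "
            f"got {pixels.shape[-1]} channels"
        )
    if pixels.dtype == np.uint8:
        depth = 8
    elif pixels.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(
            f"{path.name}: unsupported dtype {pixels.dtype}; expected uint8/uint16"
        )
    return Micrograph(
        pixels=pixels,
        pixel_size_nm=float(pixel_size_nm),
        bit_depth=depth,
        id=id if id is not None else path.stem,
    )


def save_micrograph(micrograph: Micrograph, path) -> None:
    """Write pixels to TIFF/PNG, quantizing floats to the declared bit depth."""
    path = Path(path)
    pixels = micrograph.pixels
    dtype = np.uint8 if micrograph.bit_depth == 8 else np.uint16
    if not np.issubdtype(pixels.dtype, np.integer):
        pixels = np.rint(np.clip(pixels, 0, micrograph.intensity_max))
    pixels = pixels.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)


# ---------------------------------------------------------------------------
# trace JSON


def load_trace(path, pixel_size_nm: float | None = None) -> BoundaryTrace:
    """Read a trace-annotation JSON document.

    When both the file and the *pixel_size_nm* argument specify a
    calibration, the file wins and a warning is logged (the annotation
    travels with the image it measured).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such trace file: {path}")
    with open(path) as fh:
        doc = json.load(fh)
    missing = [
        key
        for key in (*_TRACE_POLYLINES, "background_region", "orientation")
        if key not in doc
    ]
    if missing:
        raise SchemaError(f"{path.name}: missing required field(s) {missing}")
    file_px = doc.get("pixel_size_nm")
    if file_px is not None and pixel_size_nm is not None and file_px != pixel_size_nm:
        logger.warning(
            "%s: trace file pixel_size_nm=%g overrides supplied %g",
            path.name,
            file_px,
            pixel_size_nm,
        )
        warnings.warn(
            f"{path.name}: trace file pixel_size_nm={file_px} overrides "
            f"supplied {pixel_size_nm}",
            stacklevel=2,
        )
    effective_px = file_px if file_px is not None else pixel_size_nm
    return BoundaryTrace(
        inner_pw=doc["inner_pw"],
        interface=doc["interface"],
        outer_edge=doc["outer_edge"],
        background_region=doc["background_region"],
        orientation=doc["orientation"],
        pixel_size_nm=effective_px,
    )


def save_trace(trace: BoundaryTrace, path) -> None:
    doc = {
        "inner_pw": trace.inner_pw.tolist(),
        "interface": trace.interface.tolist(),
        "outer_edge": trace.outer_edge.tolist(),
        "background_region": trace.background_region.tolist(),
        "orientation": trace.orientation,
    }
    if trace.pixel_size_nm is not None:
        doc["pixel_size_nm"] = trace.pixel_size_nm
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# cell outline JSON (same coordinate dialect as traces)


@dataclass
class CellOutline:
    """A manually delineated cell contour with its grouping labels."""

    id: str
    vertices: np.ndarray
    region: str = ""
    timepoint: str = ""

    def __post_init__(self):
        self.vertices = as_points(self.vertices)
        if len(self.vertices) < 3:
            raise GeometryError(f"cell {self.id!r}: polygon needs >= 3 vertices")


def load_cell_outlines(path) -> tuple[list[CellOutline], float]:
    """Read ``{"pixel_size_nm": .., "cells": [{id, region, timepoint,
    vertices}, ..]}`` and return the outlines plus the calibration."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if "cells" not in doc or "pixel_size_nm" not in doc:
        raise SchemaError(f"{path.name}: outline file needs 'pixel_size_nm' and 'cells'")
    cells = []
    for i, entry in enumerate(doc["cells"]):
        if "vertices" not in entry:
            raise SchemaError(f"{path.name}: cell #{i} lacks 'vertices'")
        cells.append(
            CellOutline(
                id=str(entry.get("id", i)),
                vertices=entry["vertices"],
                region=str(entry.get("region", "")),
                timepoint=str(entry.get("timepoint", "")),
            )
        )
    return cells, float(doc["pixel_size_nm"])


# ---------------------------------------------------------------------------
# tabular results


def _record_to_dict(record) -> dict:
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        return dataclasses.asdict(record)
    if isinstance(record, dict):
        return dict(record)
    raise SchemaError(f"unsupported record type {type(record).__name__}")


def write_table(records: list, path, columns: list[str] | None = None) -> None:
    """Write homogeneous measurement records as CSV (header always present).

    Column order follows the first record (or *columns* for an empty list);
    floats are written at full precision so a round-trip read reproduces the
    values exactly.
    """
    dicts = [_record_to_dict(r) for r in records]
    if dicts:
        columns = list(dicts[0])
        for i, d in enumerate(dicts[1:], start=1):
            if list(d) != columns:
                raise SchemaError(
                    f"heterogeneous records: row {i} fields {list(d)} != {columns}"
                )
        frame = pd.DataFrame(dicts, columns=columns)
    else:
        frame = pd.DataFrame(columns=columns if columns is not None else [])
    frame.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
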