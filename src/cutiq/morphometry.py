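"""Width, area and stain-intensity morphometry.

Three unrelated measurement families share this module because they are all
"measure a traced geometry / masked region" operations:

* cuticle and primary-wall widths from a boundary trace, absolute (nm) and
  relative (cuticle as % of primary wall), estimated per micrograph as the
  average of measurements at two interior arc positions;
* cell areas from operator-supplied polygon outlines (shoelace formula),
  with a percent-expansion comparison between two timepoints;
* embryo stain scoring as mean blue dominance over the embryo mask.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from ._geometry import first_hit, normals_toward, resample_polyline, unit_tangents
from .cohort_stats import GroupComparison, MeanSem, compare_groups, mean_sem
from .exceptions import GeometryError, InputError, MeasurementError
from .image_io import BoundaryTrace, CellOutline, Micrograph, StainImage


@dataclass
class WidthMeasurement:
    image_id: str
    w_cuticle_nm: float
    w_pw_nm: float
    relative_pct: float
    n_positions: int

    def __post_init__(self):
        if self.w_cuticle_nm <= 0 or self.w_pw_nm <= 0:
            raise MeasurementError("widths must be positive")


@dataclass
class WidthSummary:
    cuticle: MeanSem
    pw: MeanSem
    relative_pct: MeanSem
    n: int


@dataclass
class CellAreaRecord:
    image_id: str
    cell_id: str
    region: str
    timepoint: str
    area_um2: float

    def __post_init__(self):
        if self.area_um2 <= 0:
            raise InputError(f"cell {self.cell_id!r}: area must be positive")


@dataclass
class ExpansionResult:
    percent_change: float
    comparison: GroupComparison


@dataclass
class StainScore:
    image_id: str
    score: float  # mean blue dominance over the mask, in [-1, 1]


# ---------------------------------------------------------------------------
# widths


def measure_widths(
    image: Micrograph | None,
    trace: BoundaryTrace,
    positions: tuple[float, ...] = (1 / 3, 2 / 3),
    pixel_size_nm: float | None = None,
) -> WidthMeasurement:
    """Cuticle and primary-wall widths at the given interface arc fractions.

    At each arc fraction the interface normal is followed outward to the
    cuticle outer edge (cuticle width) and inward to the inner primary-wall
    boundary (wall width); the per-image value is the mean over positions
    and ``relative_pct = 100 * w_cuticle / w_pw``. Positions whose
    perpendicular misses a boundary are skipped; if all are skipped a
    :class:`MeasurementError` is raised.

    *image* supplies the calibration and the record's id; widths themselves
    are purely geometric, so ``image=None`` with an explicit
    *pixel_size_nm* is accepted.
    """
    if not positions or not all(0 < f < 1 for f in positions):
        raise InputError("arc fractions must lie strictly inside (0, 1)")
    px = pixel_size_nm
    if px is None:
        px = trace.pixel_size_nm
    if px is None and image is not None:
        px = image.pixel_size_nm
    if px is None or px <= 0:
        raise InputError("pixel_size_nm required")

    fine, arc = resample_polyline(trace.interface, 0.5)
    normals = normals_toward(unit_tangents(fine), trace.orientation)
    total = arc[-1]
    cut_w, pw_w = [], []
    for f in positions:
        target = f * total
        origin = np.array(
            [np.interp(target, arc, fine[:, 0]), np.interp(target, arc, fine[:, 1])]
        )
        n = np.array(
            [np.interp(target, arc, normals[:, 0]), np.interp(target, arc, normals[:, 1])]
        )
        n /= np.linalg.norm(n)
        t_out = first_hit(origin, n, trace.outer_edge)
        t_in = first_hit(origin, -n, trace.inner_pw)
        if t_out is None or t_in is None:
            continue
        cut_w.append(t_out * px)
        pw_w.append(t_in * px)
    if not cut_w:
        raise MeasurementError(
            "no arc position yielded both boundary intersections"
        )
    w_c = float(np.mean(cut_w))
    w_p = float(np.mean(pw_w))
    return WidthMeasurement(
        image_id=image.id if image is not None else "",
        w_cuticle_nm=w_c,
        w_pw_nm=w_p,
        relative_pct=100.0 * w_c / w_p,
        n_positions=len(cut_w),
    )


def summarize_widths(records: list[WidthMeasurement]) -> WidthSummary:
    """Cohort mean +/- SEM of widths and relative thickness over micrographs.

    Relative thickness is averaged per image (mean of per-image ratios),
    not computed as the ratio of cohort means.
    """
    if not records:
        raise InputError("no width records")
    return WidthSummary(
        cuticle=mean_sem([r.w_cuticle_nm for r in records]),
        pw=mean_sem([r.w_pw_nm for r in records]),
        relative_pct=mean_sem([r.relative_pct for r in records]),
        n=len(records),
    )


# ---------------------------------------------------------------------------
# cell areas


def polygon_area(outline, pixel_size_nm: float) -> float:
    """Polygon area in um^2 (shoelace on continuous vertex coordinates).

    Orientation-independent; degenerate polygons (under 3 distinct
    non-collinear vertices) raise :class:`GeometryError`.
    """
    vertices = np.asarray(outline, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 3:
        raise GeometryError("polygon needs at least 3 [x, y] vertices")
    if pixel_size_nm <= 0:
        raise InputError("pixel_size_nm must be positive")
    area_px2 = _ShapelyPolygon(vertices).area
    if area_px2 <= 0:
        raise GeometryError("polygon has zero area (collinear vertices?)")
    return float(area_px2 * (pixel_size_nm / 1000.0) ** 2)


def areas_from_outlines(
    outlines: list[CellOutline], pixel_size_nm: float, image_id: str = ""
) -> list[CellAreaRecord]:
    return [
        CellAreaRecord(
            image_id=image_id,
            cell_id=cell.id,
            region=cell.region,
            timepoint=cell.timepoint,
            area_um2=polygon_area(cell.vertices, pixel_size_nm),
        )
        for cell in outlines
    ]


def expansion_analysis(group_t1, group_t2) -> ExpansionResult:
    """Percent change of mean cell area between two timepoints plus a
    significance test (advisory KS normality check, then Student t-test).

    ``percent_change = 100 * (mean_t2 - mean_t1) / mean_t1``. Groups may be
    lists of :class:`CellAreaRecord` or plain area arrays.
    """

    def _areas(group):
        if len(group) == 0:
            raise InputError("empty cell-area group")
        if isinstance(group[0], CellAreaRecord):
            return np.array([r.area_um2 for r in group])
        return np.asarray(group, dtype=float)

    a1, a2 = _areas(group_t1), _areas(group_t2)
    comparison = compare_groups(a1, a2)
    change = 100.0 * (a2.mean() - a1.mean()) / a1.mean()
    return ExpansionResult(percent_change=float(change), comparison=comparison)


# ---------------------------------------------------------------------------
# stain scoring


def stain_score(image: StainImage) -> StainScore:
    """Mean blue dominance ``(B - (R+G)/2) / intensity_max`` over the mask.

    0 for a neutral gray embryo, +1 for saturated pure blue, negative for
    yellow-dominant pixels; pixels outside the mask never contribute. The
    exact formula for published "blue intensity" bar charts is rarely
    stated; blue dominance is used here because raw blue is high in
    white/gray pixels and therefore not monotone in staining.
    """
    rgb = image.rgb_pixels
    if np.issubdtype(rgb.dtype, np.integer):
        scale = float(np.iinfo(rgb.dtype).max)
    else:
        scale = 1.0
    rgb = rgb.astype(float)
    dominance = rgb[..., 2] - 0.5 * (rgb[..., 0] + rgb[..., 1])
    return StainScore(
        image_id=image.id, score=float(dominance[image.mask].mean() / scale)
    )
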