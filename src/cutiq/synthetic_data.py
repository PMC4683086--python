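"""Synthetic micrographs with known ground truth.

The raw transmission-electron micrographs behind the seed-cuticle
measurements are not publicly deposited, so this module generates images
that emulate them: an extracellular background of known intensity, a cuticle
band whose optical density follows a known template on the normalized 0-100
depth coordinate, a primary-wall band, an interior region, and additive
Gaussian detector noise. Every generated scene comes with its exact trace
annotation and a :class:`GroundTruth` record, so each downstream stage can
be tested as a recovery problem.

Two "phenotypes" of defect are available, mirroring the qualitative
contrast between wild-type-like and cutin-mutant-like cuticles:

* ``cavernous`` — low-density elliptical inclusions inside the cuticle band
  (intensity pulled toward background, i.e. locally lower OD);
* ``near_interface_shift`` — optical-density mass moved toward position 0
  (a bump at the primary-wall/cuticle interface balanced by a small, broad
  decrease toward the outer edge).

The generator is deliberately not a physical TEM model: no point-spread
function, no section-thickness effects. Band boundaries are anti-aliased
over one pixel to avoid staircase artifacts in width recovery.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._geometry import polygon_signed_area
from .exceptions import GeometryError, InputError
from .image_io import BoundaryTrace, Micrograph, StainImage

__all__ = [
    "SyntheticCuticleParams",
    "GroundTruth",
    "CellFieldTruth",
    "StainTruth",
    "col0_like_template",
    "constant_template",
    "generate_cuticle_micrograph",
    "generate_cohort",
    "generate_cell_field",
    "generate_stain_image",
]

POSITIONS = np.arange(101)


def col0_like_template(s):
    """Default wild-type-like OD template on the 0-100 cuticle coordinate.

    Smooth, electron-dense mid-cuticle (peak OD 0.6), OD 0.3 at the
    primary-wall interface and OD 0 at the outer edge, with zero slope at
    both ends: the synthetic scene is then C1-continuous with the primary
    wall on one side and the extracellular background on the other, so the
    pre-measurement blur introduces no edge artifact into the band (real
    cuticle edges are likewise diffuse at this scale).
    """
    u = np.asarray(s, dtype=float) / 100.0
    ramp = u * u * u * (10.0 + u * (-15.0 + 6.0 * u))  # quintic smoothstep
    return 0.3 * (1.0 - ramp) + 0.45 * np.sin(np.pi * u) ** 2


def constant_template(level: float) -> Callable[[np.ndarray], np.ndarray]:
    """A flat OD template at *level* (handy for closed-form checks)."""

    def template(s):
        return np.full_like(np.asarray(s, dtype=float), float(level))

    return template


@dataclass
class SyntheticCuticleParams:
    """Parameters of one synthetic cuticle scene.

    Defaults emulate the measured wild-type seed conditions: 315 nm cuticle,
    primary wall sized so the cuticle/wall width ratio is 34%, 8-bit
    intensities with background 200 and detector noise of 5% of background.
    """

    wall_geometry: str = "line"  # "line" | "arc"
    wall_radius_nm: float = 20000.0  # arc geometry only
    w_cuticle_nm: float = 315.0
    w_pw_nm: float = 315.0 / 0.34
    od_template: Callable[[np.ndarray], np.ndarray] = col0_like_template
    background_intensity: float = 200.0
    interior_intensity: float = 150.0
    noise_sd: float = 10.0
    defect_mode: str = "none"  # "none" | "cavernous" | "near_interface_shift"
    cavern_count_mean: float = 25.0
    cavern_size_range_nm: tuple[float, float] = (20.0, 90.0)
    cavern_intensity_factor: float = 0.7
    shift_gain_od: float = 0.15
    shift_scale_positions: float = 12.0
    shift_outer_loss_od: float = 0.0005
    pixel_size_nm: float = 5.0
    image_size: tuple[int, int] = (352, 512)  # (rows, cols)
    bit_depth: int = 8
    background_depth_px: float = 70.0  # rows of background above the outer edge
    seed: int = 0

    def validate(self) -> None:
        if self.wall_geometry not in ("line", "arc"):
            raise InputError(f"unknown wall_geometry {self.wall_geometry!r}")
        if min(self.w_cuticle_nm, self.w_pw_nm, self.background_intensity) <= 0:
            raise InputError("widths and background intensity must be positive")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if self.pixel_size_nm <= 0:
            raise InputError("pixel_size_nm must be positive")
        if self.defect_mode not in ("none", "cavernous", "near_interface_shift"):
            raise InputError(f"unknown defect_mode {self.defect_mode!r}")
        od = np.asarray(self.od_template(POSITIONS.astype(float)))
        if od.shape != (101,) or np.any(od < 0) or not np.all(np.isfinite(od)):
            raise InputError("od_template must be finite and >= 0 on [0, 100]")


@dataclass
class GroundTruth:
    """What the generator actually drew (the recovery-test oracle)."""

    w_cuticle_nm: float
    w_pw_nm: float
    od_template: np.ndarray  # effective OD at positions 0..100 (defects folded in
    #                          for near_interface_shift; caverns listed separately)
    background_intensity: float
    noise_sd: float
    defect_mode: str
    defect_info: dict = field(default_factory=dict)
    pixel_size_nm: float = 5.0
    seed: int = 0
    jitter: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["od_template"] = np.asarray(self.od_template).tolist()
        return doc


def _effective_template(params: SyntheticCuticleParams) -> Callable:
    base = params.od_template
    if params.defect_mode != "near_interface_shift":
        return base

    def shifted(s):
        s = np.asarray(s, dtype=float)
        bump = params.shift_gain_od * np.exp(-((s / params.shift_scale_positions) ** 2))
        loss = params.shift_outer_loss_od * np.clip((s - 60.0) / 20.0, 0.0, 1.0)
        return np.clip(base(s) + bump - loss, 0.0, None)

    return shifted


def _depth_field(params: SyntheticCuticleParams) -> tuple[np.ndarray, dict]:
    """Signed depth (px) of each pixel relative to the PW/cuticle interface.

    Positive depths run from the interface toward the outer edge (the
    cuticle occupies ``0 < depth <= w_cuticle_px``), negative depths into
    the primary wall and interior.
    """
    rows, cols = params.image_size
    px = params.pixel_size_nm
    w_c = params.w_cuticle_nm / px
    w_pw = params.w_pw_nm / px
    y_outer = params.background_depth_px
    y_interface = y_outer + w_c
    if y_interface + w_pw + 8 > rows:
        raise GeometryError(
            f"bands ({w_c:.1f}+{w_pw:.1f} px) plus margins exceed image height {rows}"
        )
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    if params.wall_geometry == "line":
        depth = y_interface - yy
        geo = {"y_interface": y_interface, "y_outer": y_outer, "w_c": w_c, "w_pw": w_pw}
    else:
        r_int = params.wall_radius_nm / px
        cx = (cols - 1) / 2.0
        cy = y_interface + r_int
        depth = np.hypot(xx - cx, yy - cy) - r_int
        geo = {
            "y_interface": y_interface,
            "y_outer": y_outer,
            "w_c": w_c,
            "w_pw": w_pw,
            "cx": cx,
            "cy": cy,
            "r_int": r_int,
        }
    return depth, geo


def _trace_for(params: SyntheticCuticleParams, geo: dict) -> BoundaryTrace:
    rows, cols = params.image_size
    w_c, w_pw = geo["w_c"], geo["w_pw"]
    if params.wall_geometry == "line":
        xs = np.linspace(0.0, cols - 1.0, max(int(cols / 16), 2))

        def line_at(y):
            return np.column_stack([xs, np.full_like(xs, y)])

        interface = line_at(geo["y_interface"])
        outer = line_at(geo["y_outer"])
        inner = line_at(geo["y_interface"] + w_pw)
        bg_top = 2.0
        bg_bottom = geo["y_outer"] - 6.0
    else:
        cx, cy, r_int = geo["cx"], geo["cy"], geo["r_int"]
        half_span = min((cols - 1) / 2.0 - 1.0, 0.6 * r_int)
        xs = np.linspace(cx - half_span, cx + half_span, max(int(2 * half_span / 4), 8))

        def arc_at(radius):
            ys = cy - np.sqrt(radius**2 - (xs - cx) ** 2)
            return np.column_stack([xs, ys])

        interface = arc_at(r_int)
        outer = arc_at(r_int + w_c)
        inner = arc_at(r_int - w_pw)
        bg_top = 2.0
        bg_bottom = float(outer[:, 1].min()) - 6.0
    if bg_bottom <= bg_top + 2:
        raise GeometryError("not enough background rows for the background region")
    background = np.array(
        [[4.0, bg_top], [cols - 5.0, bg_top], [cols - 5.0, bg_bottom], [4.0, bg_bottom]]
    )
    return BoundaryTrace(
        inner_pw=inner,
        interface=interface,
        outer_edge=outer,
        background_region=background,
        orientation="decreasing-y",
        pixel_size_nm=params.pixel_size_nm,
    )


def _paint_caverns(
    image: np.ndarray,
    depth: np.ndarray,
    params: SyntheticCuticleParams,
    geo: dict,
    rng: np.random.Generator,
) -> list[dict]:
    """Superimpose low-density elliptical inclusions inside the cuticle band."""
    rows, cols = image.shape
    px = params.pixel_size_nm
    w_c = geo["w_c"]
    count = int(rng.poisson(params.cavern_count_mean))
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    caverns = []
    for _ in range(count):
        s_center = rng.uniform(15.0, 85.0)
        x_center = rng.uniform(0.0, cols - 1.0)
        a_nm, b_nm = rng.uniform(*params.cavern_size_range_nm, size=2)
        # locate the pixel at normalized depth s_center on this column
        target_depth = s_center / 100.0 * w_c
        if params.wall_geometry == "line":
            y_center = geo["y_interface"] - target_depth
        else:
            cx, cy, r_int = geo["cx"], geo["cy"], geo["r_int"]
            r = r_int + target_depth
            if abs(x_center - cx) >= r:
                continue
            y_center = cy - np.sqrt(r**2 - (x_center - cx) ** 2)
        a_px, b_px = a_nm / px / 2.0, b_nm / px / 2.0
        ellipse = ((xx - x_center) / a_px) ** 2 + ((yy - y_center) / b_px) ** 2 <= 1.0
        inside = ellipse & (depth > 0) & (depth < w_c)
        image[inside] += params.cavern_intensity_factor * (
            params.background_intensity - image[inside]
        )
        caverns.append(
            {
                "x_px": float(x_center),
                "y_px": float(y_center),
                "s_center": float(s_center),
                "axes_nm": [float(a_nm), float(b_nm)],
            }
        )
    return caverns


def generate_cuticle_micrograph(
    params: SyntheticCuticleParams,
) -> tuple[Micrograph, BoundaryTrace, GroundTruth]:
    """Render one synthetic scene and its exact annotation.

    From outside in: background at the true intensity, the cuticle band
    (intensity ``I_bg * 10**(-od(s))`` at normalized depth ``s``), the
    primary-wall band (continuous with the cuticle at the interface), and
    the cell interior. Identical parameters and seed give bit-identical
    output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    depth, geo = _depth_field(params)
    od_eff = _effective_template(params)
    bg = params.background_intensity
    w_c = geo["w_c"]

    s = np.clip(100.0 * depth / w_c, 0.0, 100.0)
    cuticle_like = bg * np.power(10.0, -np.asarray(od_eff(s), dtype=float))
    pw_intensity = float(bg * 10.0 ** (-float(np.asarray(od_eff(0.0)))))

    image = np.full(depth.shape, params.interior_intensity, dtype=float)
    # blend interior -> primary wall -> cuticle -> background, each boundary
    # anti-aliased with a 1-pixel linear ramp on the signed depth
    a = np.clip(depth + geo["w_pw"] + 0.5, 0.0, 1.0)
    image = image * (1 - a) + pw_intensity * a
    b = np.clip(depth + 0.5, 0.0, 1.0)
    image = image * (1 - b) + cuticle_like * b
    c = np.clip(depth - w_c + 0.5, 0.0, 1.0)
    image = image * (1 - c) + bg * c

    defect_info: dict = {}
    if params.defect_mode == "cavernous":
        defect_info["caverns"] = _paint_caverns(image, depth, params, geo, rng)
    elif params.defect_mode == "near_interface_shift":
        defect_info = {
            "gain_od": params.shift_gain_od,
            "scale_positions": params.shift_scale_positions,
            "outer_loss_od": params.shift_outer_loss_od,
        }

    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 2**params.bit_depth - 1)

    micrograph = Micrograph(
        pixels=image,
        pixel_size_nm=params.pixel_size_nm,
        bit_depth=params.bit_depth,
        id=f"syn-{params.wall_geometry}-{params.defect_mode}-{params.seed}",
    )
    trace = _trace_for(params, geo)
    truth = GroundTruth(
        w_cuticle_nm=params.w_cuticle_nm,
        w_pw_nm=params.w_pw_nm,
        od_template=np.asarray(od_eff(POSITIONS.astype(float)), dtype=float),
        background_intensity=bg,
        noise_sd=params.noise_sd,
        defect_mode=params.defect_mode,
        defect_info=defect_info,
        pixel_size_nm=params.pixel_size_nm,
        seed=params.seed,
    )
    return micrograph, trace, truth


def generate_cohort(
    params: SyntheticCuticleParams,
    n_images: int,
    base_seed: int | None = None,
    geometry_jitter: float = 0.05,
) -> list[tuple[Micrograph, BoundaryTrace, GroundTruth]]:
    """Generate a cohort of scenes with per-image geometry jitter.

    Per-image seeds derive deterministically from *base_seed*. Band widths
    are jittered uniformly by +/- *geometry_jitter* (relative) and the band
    offset by a few pixels, emulating section-to-section variability; the
    OD template itself is shared so the cohort has a single well-defined
    profile ground truth (the jitter is recorded per image).
    """
    if n_images < 1:
        raise InputError("n_images must be >= 1")
    params.validate()
    if base_seed is None:
        base_seed = params.seed
    children = np.random.SeedSequence(base_seed).spawn(n_images)
    out = []
    for i, child in enumerate(children):
        jrng = np.random.default_rng(child)
        jc = 1.0 + jrng.uniform(-geometry_jitter, geometry_jitter)
        jp = 1.0 + jrng.uniform(-geometry_jitter, geometry_jitter)
        dy = jrng.uniform(-8.0, 8.0)
        img_seed = int(jrng.integers(2**31))
        p_i = dataclasses.replace(
            params,
            w_cuticle_nm=params.w_cuticle_nm * jc,
            w_pw_nm=params.w_pw_nm * jp,
            background_depth_px=max(params.background_depth_px + dy, 20.0),
            seed=img_seed,
        )
        micrograph, trace, truth = generate_cuticle_micrograph(p_i)
        micrograph.id = f"syn-{base_seed}-{i:03d}"
        truth.jitter = {
            "cuticle_factor": jc,
            "pw_factor": jp,
            "offset_px": dy,
            "index": i,
            "base_seed": int(base_seed),
        }
        out.append((micrograph, trace, truth))
    return out


# ---------------------------------------------------------------------------
# cell fields (endosperm morphometry material)


@dataclass
class CellFieldTruth:
    areas_um2: list[float]
    vacuole_fraction: float
    seed: int


def _random_convex_polygon(rng: np.random.Generator, n_vertices: int) -> np.ndarray:
    """Star polygon around the origin with unit nominal radius.

    Vertex angles are evenly spaced with bounded jitter, which keeps the
    polygon fat enough that rescaling it to any target area stays inside a
    grid slot of known size.
    """
    jitter = rng.uniform(-0.3, 0.3, size=n_vertices)
    angles = 2 * np.pi * (np.arange(n_vertices) + jitter) / n_vertices
    radii = rng.uniform(0.65, 1.0, size=n_vertices)
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])


def generate_cell_field(
    n_cells: int,
    area_range_um2: tuple[float, float] = (80.0, 120.0),
    vacuole_fraction: float = 0.0,
    pixel_size_nm: float = 1000.0,
    seed: int = 0,
) -> tuple[Micrograph, list[np.ndarray], CellFieldTruth]:
    """Lay out *n_cells* non-overlapping cells with exactly known areas.

    Cells are random convex polygons rescaled to a target area drawn
    uniformly from *area_range_um2*, placed on a jittered grid (which
    guarantees non-overlap for feasible parameters). Interiors are densely
    "stained" dark; when ``vacuole_fraction > 0`` bright circular blobs are
    added until they cover that fraction of each cell's area, emulating the
    watery transparent spaces of expanding cells.
    """
    if n_cells < 1:
        raise InputError("n_cells must be >= 1")
    lo, hi = area_range_um2
    if not (0 < lo <= hi):
        raise InputError("invalid area range")
    if not 0.0 <= vacuole_fraction <= 1.0:
        raise InputError("vacuole_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    px_per_um = 1000.0 / pixel_size_nm
    max_area_px2 = hi * px_per_um**2
    slot = int(np.ceil(2.0 * 1.35 * np.sqrt(max_area_px2))) + 8
    k = int(np.ceil(np.sqrt(n_cells)))
    side = k * slot + 16
    if side > 8192:
        raise GeometryError(
            f"cannot place {n_cells} cells of up to {hi} um^2 at "
            f"{pixel_size_nm} nm/px without an oversized raster"
        )
    image = np.full((side, side), 230.0)
    polygons: list[np.ndarray] = []
    areas: list[float] = []
    for i in range(n_cells):
        row, col = divmod(i, k)
        center = np.array(
            [8 + col * slot + slot / 2.0, 8 + row * slot + slot / 2.0]
        ) + rng.uniform(-2.0, 2.0, size=2)
        target_um2 = rng.uniform(lo, hi)
        target_px2 = target_um2 * px_per_um**2
        base = _random_convex_polygon(rng, int(rng.integers(6, 13)))
        scale = np.sqrt(target_px2 / abs(polygon_signed_area(base)))
        if scale > slot / 2.0 - 4.0:
            raise GeometryError("cell does not fit in its grid slot")
        poly = base * scale + center
        polygons.append(poly)
        areas.append(abs(polygon_signed_area(poly)) * (pixel_size_nm / 1000.0) ** 2)
        _paint_cell(image, poly, vacuole_fraction, rng)
    image = np.clip(image + rng.normal(0.0, 3.0, size=image.shape), 0.0, 255.0)
    micrograph = Micrograph(
        pixels=image, pixel_size_nm=pixel_size_nm, bit_depth=8, id=f"cells-{seed}"
    )
    return micrograph, polygons, CellFieldTruth(areas, vacuole_fraction, seed)


def _paint_cell(image, poly, vacuole_fraction, rng):
    from ._geometry import polygon_pixel_mask

    mask = polygon_pixel_mask(poly, image.shape)
    image[mask] = 90.0
    if vacuole_fraction <= 0 or not mask.any():
        return
    cell_area = int(mask.sum())
    r_cell = np.sqrt(cell_area / np.pi)
    vac = np.zeros_like(mask)
    yy, xx = np.nonzero(mask)
    for _ in range(300):
        if vac.sum() >= vacuole_fraction * cell_area:
            break
        j = rng.integers(len(yy))
        cy, cx = yy[j], xx[j]
        r = rng.uniform(0.1, 0.25) * r_cell
        r0, r1 = int(max(cy - r - 1, 0)), int(cy + r + 2)
        c0, c1 = int(max(cx - r - 1, 0)), int(cx + r + 2)
        sub_y, sub_x = np.mgrid[r0 : min(r1, image.shape[0]), c0 : min(c1, image.shape[1])]
        disk = (sub_y - cy) ** 2 + (sub_x - cx) ** 2 <= r**2
        sel = np.zeros_like(mask)
        sel[sub_y[disk], sub_x[disk]] = True
        vac |= sel & mask
    image[vac] = 210.0


# ---------------------------------------------------------------------------
# stain images (embryo permeability assay material)


@dataclass
class StainTruth:
    blue_level: float
    seed: int


def generate_stain_image(
    blue_level: float,
    mask_shape: tuple[int, int] = (96, 128),
    seed: int = 0,
) -> tuple[StainImage, StainTruth]:
    """An embryo-shaped mask stained toward blue by *blue_level* in [0, 1].

    Pixel colors inside the mask mix a noisy gray body with pure blue:
    ``(1-b)*gray + b*(0, 0, 255)``, so the expected blue-dominance score of
    the embryo equals *blue_level* and is strictly monotone in it.
    """
    if not 0.0 <= blue_level <= 1.0:
        raise InputError("blue_level must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows, cols = mask_shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    mask = ((xx - cx) / (0.38 * cols)) ** 2 + ((yy - cy) / (0.30 * rows)) ** 2 <= 1.0
    gray = np.clip(150.0 + rng.normal(0.0, 8.0, size=mask_shape), 30.0, 220.0)
    rgb = np.empty((rows, cols, 3), dtype=float)
    rgb[..., 0] = rgb[..., 1] = rgb[..., 2] = 215.0  # neutral background
    body = (1.0 - blue_level) * gray[mask]
    rgb[..., 0][mask] = body
    rgb[..., 1][mask] = body
    rgb[..., 2][mask] = body + blue_level * 255.0
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return (
        StainImage(rgb_pixels=rgb, mask=mask, id=f"stain-{blue_level:g}-{seed}"),
        StainTruth(blue_level=float(blue_level), seed=seed),
    )
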