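import numpy as np
import pytest

from cutiq.image_io import BoundaryTrace, Micrograph


def make_parallel_trace(
    width_px: int = 256,
    y_outer: float = 40.0,
    w_cuticle_px: float = 30.0,
    w_pw_px: float = 90.0,
    pixel_size_nm: float | None = 10.0,
) -> BoundaryTrace:
    """Straight horizontal bands: outer edge above the interface (cuticle on
    the decreasing-y side), matching the synthetic generator's layout."""
    xs = np.linspace(0.0, width_px - 1.0, 17)

    def line(y):
        return np.column_stack([xs, np.full_like(xs, y)])

    y_interface = y_outer + w_cuticle_px
    return BoundaryTrace(
        inner_pw=line(y_interface + w_pw_px),
        interface=line(y_interface),
        outer_edge=line(y_outer),
        background_region=[
            [4, 4],
            [width_px - 5, 4],
            [width_px - 5, y_outer - 8],
            [4, y_outer - 8],
        ],
        orientation="decreasing-y",
        pixel_size_nm=pixel_size_nm,
    )


def make_band_image(
    width_px: int = 256,
    height_px: int = 220,
    y_outer: float = 40.0,
    w_cuticle_px: float = 30.0,
    band_intensity: float = 50.0,
    background: float = 200.0,
    pixel_size_nm: float = 10.0,
) -> Micrograph:
    """Sharp-edged horizontal band of *band_intensity* in a background."""
    img = np.full((height_px, width_px), background)
    y0 = int(round(y_outer))
    y1 = int(round(y_outer + w_cuticle_px))
    img[y0:y1, :] = band_intensity
    return Micrograph(pixels=img, pixel_size_nm=pixel_size_nm, bit_depth=8, id="band")


@pytest.fixture
def parallel_trace():
    return make_parallel_trace()


@pytest.fixture
def band_image():
    return make_band_image()
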