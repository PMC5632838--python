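import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, map_coordinates

from hifutrack.geometry import DeformationField, GeomImage, axis_aligned_affine
from hifutrack.phantom import PhantomSpec, ProtocolConfig, acquire_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def textured_2d(rng):
    """Smooth random texture on a 2 mm grid: generic registration input."""
    img = gaussian_filter(rng.normal(size=(48, 48)), 2.0)
    img = (img - img.min()) / np.ptp(img)
    return GeomImage(img, axis_aligned_affine((2.0, 2.0)))


@pytest.fixture
def small_spec():
    """Down-scaled grid phantom for unit tests."""
    return PhantomSpec(
        shape=(48, 48, 20),
        cylinder_radius_mm=40.0,
        cylinder_height_mm=28.0,
        border_margin_mm=6.0,
    )


@pytest.fixture(scope="session")
def tiny_session():
    """Small full session shared by framework-level tests."""
    spec = PhantomSpec(
        shape=(48, 48, 20),
        cylinder_radius_mm=40.0,
        cylinder_height_mm=28.0,
        border_margin_mm=6.0,
    )
    # distortion magnitudes scaled with the phantom's halved field of view
    protocol = ProtocolConfig(
        n_anchors=4, n_bundles=2, n_dynamics=4,
        distortion_mean_mm=3.0, distortion_max_mm=4.0,
    )
    session, truth = acquire_session(spec, None, protocol, seed=7)
    return spec, protocol, session, truth


def translate_image(img: GeomImage, shift_mm, order=3) -> GeomImage:
    """Render img rigidly displaced by shift_mm: J(r) = I(r - d).

    The registration truth for fixed=img, moving=J is then exactly +d.
    """
    shift_mm = np.asarray(shift_mm, dtype=float)
    idx = img.index_grid()
    coords = np.moveaxis(idx - shift_mm / img.voxel_size_mm, -1, 0)
    return GeomImage(
        map_coordinates(img.data, coords, order=order, mode="nearest"), img.affine
    )


def warp_by_true_field(img: GeomImage, u_mm: np.ndarray, order=3) -> GeomImage:
    """Render J such that img(r) = J(r + u(r)) holds exactly.

    Uses the fixed-point inverse of (id + u); u must be a smooth field
    given on img's grid in mm.
    """
    sp = img.voxel_size_mm
    idx = img.index_grid()
    p = idx.copy()
    for _ in range(50):
        uv = np.stack(
            [
                map_coordinates(
                    u_mm[..., c], np.moveaxis(p, -1, 0), order=1, mode="nearest"
                )
                for c in range(img.ndim)
            ],
            axis=-1,
        )
        p = idx - uv / sp
    return GeomImage(
        map_coordinates(img.data, np.moveaxis(p, -1, 0), order=order, mode="nearest"),
        img.affine,
    )
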