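import numpy as np
import pytest

from endicom.geometry import VolumeGeometry
from endicom.phantom import Phantom, PhantomSpec, make_phantom

AXIS_ALIGNED = dict(
    row_direction=np.array([0.0, 1.0, 0.0]),
    column_direction=np.array([1.0, 0.0, 0.0]),
    slice_direction=np.array([0.0, 0.0, 1.0]),
)


def identity_geometry(shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0), origin=(0, 0, 0)):
    return VolumeGeometry(origin=np.asarray(origin, float), spacing=np.asarray(spacing),
                          shape=shape, **AXIS_ALIGNED)


def random_orthogonal_geometry(rng, shape=(8, 9, 10)):
    """Geometry with random origin, anisotropic spacing and oblique (but
    mutually orthogonal) axes."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    return VolumeGeometry(
        origin=rng.uniform(-100, 100, 3),
        row_direction=q[:, 0], column_direction=q[:, 1], slice_direction=q[:, 2],
        spacing=rng.uniform(0.3, 3.0, 3),
        shape=shape,
    )


def small_phantom_spec(**overrides) -> PhantomSpec:
    """Quarter-size phantom for fast IO-heavy tests."""
    defaults = dict(
        shape=(32, 64, 64),
        head_axes_mm=(24.0, 28.0, 13.0),
        shell_thickness_mm=3.0,
        tumors=(((9.0, 12.0, -5.0), 5.0, 300.0),),
        fiducials=((24.0, 0.0, -2.0), (-24.0, 0.0, -2.0),
                   (0.0, 27.0, 0.0), (0.0, -20.0, 9.0)),
        seed=0,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_phantom() -> Phantom:
    return make_phantom(small_phantom_spec())


@pytest.fixture(scope="session")
def default_phantom() -> Phantom:
    return make_phantom(PhantomSpec())
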