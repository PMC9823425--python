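"""Shared fixtures: all test inputs are generated programmatically."""

import warnings

import numpy as np
import pytest

import csifem as cf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_box():
    """60 mm box at h = 20 mm: 27 hexes, 162 tets."""
    return cf.build_box_mesh((0.06, 0.06, 0.06), 0.02)


@pytest.fixture(scope="session")
def small_fixture():
    """Coarse homogeneous-head consistency fixture (same mesh, 4 antennas).

    Same construction as the accuracy experiments but at h = 20 mm so the
    whole bundle builds in seconds; used by every test that only needs
    consistent forward fields, operators and data.
    """
    return cf.homogeneous_head_fixture(h=0.02, n_antennas=4, solver="direct")


@pytest.fixture(scope="session")
def small_contrast(small_fixture):
    from csifem.operators import contrast_from_materials

    return contrast_from_materials(small_fixture.materials,
                                   small_fixture.head_mask)


@pytest.fixture(scope="session")
def small_ops(small_fixture):
    from csifem.operators import CSIOperators

    fx = small_fixture
    return CSIOperators(fx.system, fx.msense, fx.mesh, fx.materials.kb2,
                        fx.head_mask, variant="edge", eval_mode="linear")


def _stroke_scenario(data_h, inversion_h, n_antennas=6, low_contrast=False,
                     seed=11):
    dom = (0.12, 0.12, 0.12)
    c = (0.06, 0.06, 0.06)
    phantom = cf.PhantomSpec(
        layers=[cf.Layer(c, (0.04, 0.04, 0.04), 45.37, 0.77)], domain=dom
    )
    if low_contrast:
        stroke = cf.StrokeSpec(center=(0.071, 0.06, 0.06),
                               semi_axes=(0.016, 0.014, 0.014),
                               eps_r=52.0, sigma=1.0)
    else:
        stroke = cf.StrokeSpec(center=(0.072, 0.06, 0.06),
                               semi_axes=(0.014, 0.012, 0.012))
    acq = cf.AcquisitionSpec(n_antennas=n_antennas, ring_radius=0.05,
                             ring_center=c, data_h=data_h,
                             inversion_h=inversion_h)
    same = np.isclose(data_h, inversion_h)
    with warnings.catch_warnings():
        if same:
            warnings.simplefilter("ignore", UserWarning)
        ds = cf.generate_dataset(phantom, stroke, acq, seed=seed,
                                 allow_inverse_crime=same)
    return phantom, stroke, ds


@pytest.fixture(scope="session")
def same_mesh_stroke():
    """Inverse-crime stroke dataset where the exact solution is attainable."""
    return _stroke_scenario(0.01, 0.01)

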