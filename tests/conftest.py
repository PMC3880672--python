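"""Shared fixtures: material parameters, the default opening-angle tube,
and residual stress fields.  Expensive solves are session-scoped."""
import numpy as np
import pytest

import resmyo as rm


@pytest.fixture(scope="session")
def params():
    return rm.MaterialParams.default()


@pytest.fixture(scope="session")
def sector():
    """The reference opened sector: alpha = 85 deg, R_i = 2.5, R_o = 4.2 cm."""
    return rm.CylinderGeometry.from_degrees(R_i=2.5, R_o=4.2, alpha_deg=85.0,
                                            lambda_z=1.0)


@pytest.fixture(scope="session")
def oa_profile(sector, params):
    return rm.solve_residual_field(sector, params)


@pytest.fixture(scope="session")
def tube(oa_profile):
    """The closed, unloaded tube produced by the opening-angle solve."""
    return rm.TubeGeometry(r_i=oa_profile.r_i, r_o=oa_profile.r_o)


@pytest.fixture(scope="session")
def oa_field(oa_profile):
    return rm.TauField.from_opening_angle(oa_profile)


@pytest.fixture(scope="session")
def strain_fixture():
    return rm.generate_strain_fixture(seed=0)


@pytest.fixture(scope="session")
def strain_field(strain_fixture, params):
    return rm.TauField.from_strain_profile(strain_fixture, params)


def random_isochoric_F(rng, scale=0.15):
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    d = np.linalg.det(F)
    if d <= 0:  # reroll orientation-reversing draws
        return random_isochoric_F(rng, scale)
    return F / np.cbrt(d)


def random_frame(rng):
    v = rng.standard_normal(3)
    f0 = v / np.linalg.norm(v)
    w = rng.standard_normal(3)
    w -= (w @ f0) * f0
    return rm.FibreFrame.from_fs(f0, w / np.linalg.norm(w))


def random_sym(rng, scale=0.3):
    A = scale * rng.standard_normal((3, 3))
    return (A + A.T) / 2
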