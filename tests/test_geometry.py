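"""Superposition and symmetry-axis extraction."""

import numpy as np
import pytest

from igproto.geometry import (SingularConfigurationError, rotation_angle_deg,
                              strand_direction, superpose_points,
                              symmetry_axis)

from .conftest import random_rigid_motion
from .oracles import min_rmsd_quaternion


def _rot_z(deg):
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@pytest.fixture
def cloud():
    return np.random.default_rng(11).normal(scale=5.0, size=(12, 3))


def test_self_superposition_is_identity(cloud):
    sp = superpose_points(cloud, cloud)
    assert sp.rmsd == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(sp.rotation, np.eye(3), atol=1e-9)
    assert sp.n_pairs == len(cloud)


def test_known_rotation_recovered():
    P = np.random.default_rng(5).normal(scale=4.0, size=(5, 3))
    R = _rot_z(37.0)
    Q = P @ R.T + np.array([1.0, -2.0, 3.0])
    sp = superpose_points(P, Q)
    assert sp.rmsd == pytest.approx(0.0, abs=1e-9)
    assert rotation_angle_deg(sp.rotation) == pytest.approx(37.0, abs=1e-8)


def test_rotation_is_proper(cloud):
    # a mirrored target must still yield det(R) = +1 (reflection excluded)
    Q = cloud.copy()
    Q[:, 0] *= -1
    sp = superpose_points(cloud, Q)
    assert np.linalg.det(sp.rotation) == pytest.approx(1.0, abs=1e-9)
    assert sp.rmsd > 0.1


def test_rmsd_symmetric_in_arguments(cloud):
    rng = np.random.default_rng(3)
    Q = cloud + rng.normal(scale=0.8, size=cloud.shape)
    assert superpose_points(cloud, Q).rmsd == \
        pytest.approx(superpose_points(Q, cloud).rmsd, abs=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_rigid_motion_invariance(cloud, seed):
    rng = np.random.default_rng(seed)
    Q = cloud + rng.normal(scale=0.5, size=cloud.shape)
    base = superpose_points(cloud, Q).rmsd
    R, t = random_rigid_motion(rng)
    assert superpose_points(cloud @ R.T + t, Q).rmsd == \
        pytest.approx(base, abs=1e-9)
    assert superpose_points(cloud, Q @ R.T + t).rmsd == \
        pytest.approx(base, abs=1e-9)


def test_degenerate_inputs_rejected():
    line = np.outer(np.arange(5.0), [1.0, 0, 0])
    with pytest.raises(SingularConfigurationError):
        superpose_points(line, line)
    with pytest.raises(SingularConfigurationError):
        superpose_points(np.zeros((2, 3)), np.zeros((2, 3)))


@pytest.mark.parametrize("seed", range(20))
def test_rmsd_matches_quaternion_minimizer(seed):
    """Closed-form solution equals brute-force numeric minimisation over
    quaternion-parameterised rotations (independent oracle)."""
    rng = np.random.default_rng(seed)
    P = rng.normal(scale=6.0, size=(20, 3))
    R, t = random_rigid_motion(rng)
    Q = P @ R.T + t + rng.normal(scale=0.5, size=P.shape)
    ours = superpose_points(P, Q).rmsd
    oracle = min_rmsd_quaternion(P, Q, seed=seed)
    assert ours == pytest.approx(oracle, abs=1e-6)


@pytest.mark.parametrize("seed", range(10))
def test_rmsd_matches_biotite(seed):
    """Second independent oracle: biotite's superimpose on the same pairs."""
    import biotite.structure as struc
    rng = np.random.default_rng(seed)
    P = rng.normal(scale=6.0, size=(15, 3))
    R, t = random_rigid_motion(rng)
    Q = P @ R.T + t + rng.normal(scale=0.4, size=P.shape)
    ours = superpose_points(P, Q).rmsd
    fitted, _tr = struc.superimpose(Q, P)
    ref = float(np.sqrt(((fitted - Q) ** 2).sum() / len(P)))
    assert ours == pytest.approx(ref, abs=1e-6)


def test_exact_c2_axis():
    P = np.random.default_rng(2).normal(scale=5.0, size=(10, 3))
    R = _rot_z(180.0)
    Q = P @ R.T
    sp = superpose_points(P, Q)
    ax = symmetry_axis(sp, (P.mean(axis=0), Q.mean(axis=0)))
    assert ax.order_label == "C2"
    assert ax.angle == pytest.approx(180.0, abs=1e-8)
    assert abs(ax.direction[2]) == pytest.approx(1.0, abs=1e-8)
    assert ax.screw == pytest.approx(0.0, abs=1e-8)
    # the z axis passes through the origin
    assert ax.distance_to_point(np.zeros(3)) == pytest.approx(0.0, abs=1e-6)


def test_identity_transform_has_no_axis(cloud):
    sp = superpose_points(cloud, cloud)
    assert symmetry_axis(sp, (cloud.mean(axis=0), cloud.mean(axis=0))) is None


def test_screw_component():
    P = np.random.default_rng(9).normal(scale=5.0, size=(8, 3))
    Q = P @ _rot_z(180.0).T + np.array([0.0, 0.0, 2.5])
    sp = superpose_points(P, Q)
    ax = symmetry_axis(sp, (P.mean(axis=0), Q.mean(axis=0)))
    assert abs(ax.screw) == pytest.approx(2.5, abs=1e-6)


def test_strand_direction_points_n_to_c():
    pts = np.array([[0, 0, z] for z in (0.0, 3.4, 6.8, 10.2)])
    d = strand_direction(pts)
    assert d[2] > 0.99
    assert strand_direction(pts[::-1])[2] < -0.99
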