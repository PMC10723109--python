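"""Analytic coincidence-response model and sensitivity."""

import numpy as np
import pytest

from cztpet.geometry import MODULE_HALF, DetectorVoxelIndex, SystemGeometry
from cztpet.system_model import (
    p_coincidence,
    p_first_photon,
    sensitivity_at,
    sensitivity_on_grid,
)
from cztpet.image import ActivityImage


def _central_voxel(module_id=0, doi=0, D=1):
    return DetectorVoxelIndex(module_id, 50, 50, doi, D)


def test_inverse_square_scaling(geometry):
    idx = _central_voxel(module_id=0, doi=0, D=10)
    centre = geometry.voxel_centre_global(idx)
    u = centre / np.linalg.norm(centre)
    near = centre - u * 40.0
    far = centre - u * 80.0
    p_near = p_first_photon(geometry, near, idx)
    p_far = p_first_photon(geometry, far, idx)
    assert p_near / p_far == pytest.approx(4.0, rel=0.01)


def test_zero_attenuation_means_zero_interaction(geometry, monkeypatch):
    import cztpet.system_model as sm
    monkeypatch.setattr(sm, "MU_511", 0.0)
    idx = _central_voxel(D=10)
    assert p_first_photon(geometry, [0.0, 0.0, 0.0], idx) == 0.0


def test_p_first_photon_matches_monte_carlo(geometry, monkeypatch):
    """The sublayer interaction probability agrees with a transport estimate.

    Importance sampling: rays are aimed at points drawn uniformly over the
    voxel's front face, each carrying the solid-angle weight
    A cos(phi) / (4 pi d^2); the weighted fraction whose *first* interaction
    falls inside the front-sublayer column estimates p(I1, n | i).
    """
    import cztpet.system_model as sm
    from cztpet.materials import default_table
    from cztpet.transport import BoxSet, transport_batch

    # evaluate the model with the transport attenuation so both sides of the
    # comparison use identical physics (coherent excluded)
    mu_t = default_table().cross_sections(511.0).transport_total / 10.0
    monkeypatch.setattr(sm, "MU_511", mu_t)

    idx = DetectorVoxelIndex(0, 50, 50, 0, 10)  # front 1-mm sublayer
    src = np.zeros(3)
    p_model = p_first_photon(geometry, src, idx)

    rng = np.random.default_rng(31)
    boxes = BoxSet.from_geometry(geometry)
    R = boxes.rotations[0]
    c_local = geometry.voxel_centre_local(idx)
    half = 0.209 / 2.0
    n = 400_000
    # rays through points drawn on the voxel's central slice: the model
    # assigns a ray to the voxel whose central slice it crosses, so the MC
    # counts first interactions within the sublayer's depth range along
    # those rays (the lateral coordinate may drift out of the column)
    uv = rng.uniform(-half, half, (n, 2))
    slice_local = np.column_stack([c_local[0] + uv[:, 0], c_local[1] + uv[:, 1],
                                   np.full(n, c_local[2])])
    target = slice_local @ R.T + boxes.centres[0]
    dirs = target - src
    dist = np.linalg.norm(dirs, axis=1)
    dirs /= dist[:, None]
    w = (0.209**2) * np.abs(dirs @ R[:, 2]) / (4.0 * np.pi * dist**2)

    rec = transport_batch(boxes, np.tile(src, (n, 1)), dirs, 511.0, rng,
                          doppler=False)
    first = np.r_[True, rec.photon[1:] != rec.photon[:-1]]
    pos_local = (rec.position[first] - boxes.centres[0]) @ R
    hit = ((pos_local[:, 2] < -MODULE_HALF[2] + 1.0)
           & (rec.module[first] == 0))
    photons_hit = rec.photon[first][hit]
    x = np.zeros(n)
    x[photons_hit] = w[photons_hit]
    p_mc = x.mean()
    sigma = x.std() / np.sqrt(n)
    assert p_model == pytest.approx(p_mc, abs=3 * sigma)


def test_p_coincidence_full_overlap_and_off_axis(geometry):
    i1 = DetectorVoxelIndex(0, 50, 50, 0, 1)
    # voxel facing i1 through the FOV centre lies on module 10 (mirrored)
    i2 = DetectorVoxelIndex(10, 50, 49, 0, 1)
    c1 = geometry.voxel_centre_global(i1)
    c2 = geometry.voxel_centre_global(i2)
    mid = (c1 + c2) / 2.0
    p_on = p_coincidence(geometry, mid, i1, i2, D=1)
    assert p_on > 0
    # at the midpoint the back-projected slice fully overlaps (S'/S2 = 1),
    # so p(A|i) = p(I1|i) times photon 2's plain interaction term
    from cztpet.materials import default_table
    p1 = p_first_photon(geometry, mid, i1)
    mu = default_table().cross_sections(511.0).total / 10.0
    u = (c2 - mid) / np.linalg.norm(c2 - mid)
    n2 = np.array([-1.0, 0.0, 0.0])  # depth axis of the -x panel
    cos2 = abs(float(u @ n2))
    f2 = 1.0 - np.exp(-mu * 10.0 / cos2)
    assert p_on == pytest.approx(p1 * f2, rel=1e-6)
    # a source far off the joining line yields zero overlap
    off = mid + np.array([0.0, 8.0, 8.0])
    assert p_coincidence(geometry, off, i1, i2, D=1) == 0.0


def test_p_coincidence_same_panel_error(geometry):
    i1 = DetectorVoxelIndex(0, 50, 50, 0, 1)
    i2 = DetectorVoxelIndex(1, 50, 50, 0, 1)
    with pytest.raises(ValueError):
        p_coincidence(geometry, np.zeros(3), i1, i2)


def test_sublayer_refinement_converges(geometry):
    """Increasing D refines p(A|i): D=10 is closer to D=20 than D=1 is."""
    i1 = DetectorVoxelIndex(0, 50, 50, 0, 1)
    i2 = DetectorVoxelIndex(10, 50, 49, 0, 1)
    c1 = geometry.voxel_centre_global(i1)
    c2 = geometry.voxel_centre_global(i2)
    src = c1 + 0.62 * (c2 - c1)  # on the joining line, off-centre
    vals = {D: p_coincidence(geometry, src, i1, i2, D=D) for D in (1, 10, 20)}
    assert vals[1] > 0
    assert abs(vals[10] - vals[20]) < abs(vals[1] - vals[20])


def test_sensitivity_peaks_at_centre_and_rotational_symmetry(geometry):
    pts = np.array([[0, 0, 0], [3.0, 0, 0], [0, 3.0, 0], [-3.0, 0, 0],
                    [0, -3.0, 0], [0, 0, 30.0]])
    s = sensitivity_at(geometry, pts, D=4, lateral_step=4)
    assert s[0] == max(s)
    # 90-degree rotational symmetry of the four-panel ring
    assert s[1] == pytest.approx(s[2], rel=1e-6)
    assert s[1] == pytest.approx(s[3], rel=1e-6)
    assert s[1] == pytest.approx(s[4], rel=1e-6)
    # far outside the panels axially: essentially no sensitivity
    assert s[5] < 0.01 * s[0]


def test_sensitivity_on_grid_interpolates_smoothly(geometry):
    img = ActivityImage.empty((9, 9, 5), 0.5)
    v = sensitivity_on_grid(geometry, img, D=2, lateral_step=10, step_mm=1.5)
    direct = sensitivity_at(geometry, [[0.25, 0.25, 0.25]], D=2,
                            lateral_step=10, convention="physical")
    centre_val = v.reshape(9, 9, 5)[4, 4, 2]
    assert centre_val == pytest.approx(direct[0], rel=0.02)
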