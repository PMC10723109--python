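"""Near-field Compton response matrix F and derived quantities."""

import numpy as np
import pytest

from cztpet.kinematics import compton_scatter, kinematic_angle
from cztpet.response import (
    angular_uncertainty_map,
    build_response_matrix,
    compton_event_probability,
    marginalize_d2,
)


def test_normalisation(response_F):
    assert response_F.prob.sum() == pytest.approx(1.0)
    assert np.all(response_F.counts >= 0)


def test_minimum_history_requirement():
    with pytest.raises(ValueError):
        build_response_matrix(10_000, rng=np.random.default_rng(0))


def test_blur_free_matrix_concentrates_on_kinematic_curve(response_ideal):
    """Without blur or Doppler the (E1, theta) support is the Compton line.

    Checked per theta bin: the occupied E1 bins must lie within the deposit
    range the Compton relation implies for the bin's angular extent (plus one
    bin of quantisation on each side).
    """
    F = response_ideal
    counts2d = marginalize_d2(F).counts[:, :, 0]
    checked = 0
    for j in range(counts2d.shape[1]):
        col = np.nonzero(counts2d[:, j] > 0)[0]
        if col.size == 0:
            continue
        th_lo = np.radians(j * F.dtheta)
        th_hi = np.radians((j + 1) * F.dtheta)
        e_lo = F.E0 - compton_scatter(F.E0, th_lo)
        e_hi = F.E0 - compton_scatter(F.E0, th_hi)
        i_lo = int(e_lo / F.de) - 1
        i_hi = int(e_hi / F.de) + 1
        assert col.min() >= i_lo and col.max() <= i_hi
        checked += 1
    assert checked > 50


def test_blur_free_angle_matches_kinematics_eventwise(response_ideal):
    """Per bin: the geometric angle axis agrees with kinematic_angle(E1)."""
    F = response_ideal
    i, j, k = np.nonzero(F.counts)
    theta_kin = kinematic_angle(F.e1_centres()[i], F.E0)
    ok = np.isfinite(theta_kin)
    dev = np.abs(F.theta_centres()[j[ok]] - theta_kin[ok])
    # within bin quantisation of both axes
    frac_close = np.average(dev <= 2.0, weights=F.counts[i[ok], j[ok], k[ok]])
    assert frac_close > 0.99


def test_d2_marginal_has_decaying_tail(response_F):
    """The inter-site distance falls off beyond a few mm (attenuation)."""
    d2_marginal = response_F.prob.sum(axis=(0, 1))[:-1]  # drop overflow
    centres = response_F.d2_centres()[:-1]
    far = centres > 6.0
    # compare with exponential decay at the dominant scattered-photon
    # attenuation scale: monotone decreasing beyond the peak
    peak = d2_marginal.argmax()
    tail = d2_marginal[peak:]
    assert np.all(np.diff(tail) <= 1e-3)
    assert d2_marginal[far][-1] < 0.2 * d2_marginal.max()


def test_event_probability_terms(response_F):
    i, j, k = np.nonzero(response_F.counts)
    b = (int(i[0]), int(j[0]), int(k[0]))
    p_near = compton_event_probability(40.0, 1.0, b, response_F)
    p_far = compton_event_probability(80.0, 1.0, b, response_F)
    assert p_near / p_far == pytest.approx(4.0)
    zero_bin = (0, response_F.counts.shape[1] - 1, 0)
    if response_F.counts[zero_bin] == 0:
        assert compton_event_probability(40.0, 1.0, zero_bin, response_F) == 0.0


def test_event_probability_matches_interaction_frequency():
    """p1 = n0 sigma V / (4 pi d1^2) agrees with a transport estimate."""
    from cztpet.materials import default_table
    from cztpet.transport import BoxSet, transport_batch

    d1 = 40.0
    side = 1.0  # 1 mm cube
    mu_c = default_table().cross_sections(511.0).incoherent / 10.0
    p1 = mu_c * side**3 / (4.0 * np.pi * d1**2)
    # MC: rays over the cube's subtended cone, Compton interaction inside
    rng = np.random.default_rng(41)
    box = BoxSet.single_slab((side / 2, side / 2, side / 2), centre=(0, 0, d1))
    n = 300_000
    uv = rng.uniform(-side / 2, side / 2, (n, 2))
    target = np.column_stack([uv, np.full(n, d1 - side / 2)])
    dirs = target / np.linalg.norm(target, axis=1, keepdims=True)
    dist = np.linalg.norm(target, axis=1)
    w = side**2 * np.abs(dirs[:, 2]) / (4 * np.pi * dist**2)
    rec = transport_batch(box, np.zeros((n, 3)), dirs, 511.0, rng, doppler=False)
    first = np.r_[True, rec.photon[1:] != rec.photon[:-1]]
    compton_first = rec.photon[first][rec.kind[first] == 0]
    x = np.zeros(n)
    x[compton_first] = w[compton_first]
    sigma = x.std() / np.sqrt(n)
    assert p1 == pytest.approx(x.mean(), abs=3 * sigma)


def test_angular_uncertainty_shrinks_with_distance(response_F):
    groups, d2, fwhm, valid = angular_uncertainty_map(response_F)
    g90 = np.argmin(np.abs(groups - 90.0))
    near = np.nonzero(valid[g90] & (d2 < 2.5))[0]
    far = np.nonzero(valid[g90] & (d2 > 8.0))[0]
    assert near.size and far.size
    assert fwhm[g90, near].min() > fwhm[g90, far].max()


def test_blur_free_angular_uncertainty_is_bin_limited(response_ideal):
    """No blur, no Doppler: the angular spread is pure bin quantisation.

    Restricted to mid-range scattering angles; toward backscatter the E1-bin
    width alone spans several degrees of angle (dtheta/dE1 diverges), which
    is a sampling-grid effect rather than a physical uncertainty.
    """
    groups, d2, fwhm, valid = angular_uncertainty_map(response_ideal)
    mid = (groups > 20.0) & (groups < 120.0)
    sel = valid & mid[:, None]
    assert sel.any()
    assert np.nanmax(fwhm[sel]) <= 2.0 * response_ideal.dtheta + 1e-6


def test_doubling_position_blur_broadens_small_d2():
    from cztpet.detector import DetectorModel

    rng = np.random.default_rng(42)
    F1 = build_response_matrix(0, rng=rng, target_events=120_000)
    rng = np.random.default_rng(42)
    F2 = build_response_matrix(0, rng=rng, target_events=120_000,
                               model=DetectorModel(position_fwhm=1.0))
    g1, d2, f1, v1 = angular_uncertainty_map(F1)
    g2, _, f2, v2 = angular_uncertainty_map(F2)
    g90 = np.argmin(np.abs(g1 - 90.0))
    small = (d2 < 4.0)
    both = v1[g90] & v2[g90] & small
    assert both.any()
    assert np.nanmean(f2[g90, both]) > np.nanmean(f1[g90, both])


def test_marginalize_d2_normalised_and_shape(response_F):
    M = marginalize_d2(response_F)
    assert M.prob.sum() == pytest.approx(1.0)
    assert M.counts.shape[2] == 1
    np.testing.assert_allclose(M.counts[:, :, 0],
                               response_F.counts.sum(axis=2))


def test_conventional_fwhm_between_near_field_extremes(response_F):
    """The d2-marginal angular width lies within the near-field range."""
    groups, d2, fwhm, valid = angular_uncertainty_map(response_F)
    gM, _, fM, vM = angular_uncertainty_map(marginalize_d2(response_F))
    g90 = np.argmin(np.abs(groups - 90.0))
    if vM[g90, 0] and valid[g90].any():
        lo = np.nanmin(fwhm[g90, valid[g90]])
        hi = np.nanmax(fwhm[g90, valid[g90]])
        assert lo <= fM[g90, 0] <= hi


def test_rebuild_with_other_seed_statistically_compatible(response_F):
    rng = np.random.default_rng(4242)
    F2 = build_response_matrix(0, rng=rng, target_events=60_000,
                               de=response_F.de, dtheta=response_F.dtheta,
                               dd2=response_F.dd2)
    # compare angular marginals via a z-test
    p1 = response_F.prob.sum(axis=(0, 2))
    c2 = F2.counts.sum(axis=(0, 2))
    n2 = F2.counts.sum()
    exp = p1 * n2
    sig = np.sqrt(np.maximum(exp * (1 - p1), 1.0))
    z = (c2 - exp) / sig
    assert np.nanmax(np.abs(z[exp > 50])) < 5.0


def test_save_load_roundtrip(tmp_path, response_ideal):
    path = tmp_path / "F.h5"
    response_ideal.save(path)
    from cztpet.response import ComptonResponseMatrix
    back = ComptonResponseMatrix.load(path)
    np.testing.assert_array_equal(back.counts, response_ideal.counts)
    assert back.de == response_ideal.de
    assert back.n_events == response_ideal.n_events
    assert back.blur == response_ideal.blur
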