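"""List-mode OS-EM reconstruction and image metrics."""

import numpy as np
import pytest

from cztpet.image import ActivityImage
from cztpet.recon import (
    ReconstructionConfig,
    build_system_rows,
    decay_adjusted_sensitivity,
    gaussian_postfilter,
    normalized_sd,
    osem_reconstruct,
    peak_to_valley,
    profile_fwhm,
)
from cztpet.rejection import classify_events
from cztpet.phantoms import PhantomSpec, make_phantom
from cztpet.simulate import simulate_coincidences


@pytest.fixture(scope="module")
def point_events(geometry):
    rng = np.random.default_rng(61)
    ph = make_phantom(PhantomSpec("point", total_activity=3e5,
                                  centre=(1.0, 0.5, 0.0), diameter=0.25), 0.1)
    lm = simulate_coincidences(ph, geometry, 0.25, rng)
    cat, in_win = classify_events(lm)
    return lm.select((cat == 0) & in_win & ~lm.truth["is_random"])


@pytest.fixture(scope="module")
def point_recon(point_events, geometry):
    cfg = ReconstructionConfig(doi_bin_mm=1.0, voxel_size=0.25,
                               shape=(32, 32, 32), iterations=4)
    imgs, info = osem_reconstruct(point_events, geometry, cfg)
    return imgs, info, cfg


def test_single_event_update_supported_on_lor(geometry, point_events):
    cfg = ReconstructionConfig(doi_bin_mm=1.0, voxel_size=0.5,
                               shape=(24, 24, 24), iterations=1)
    one = point_events.select(np.array([0]))
    grid = ActivityImage.empty(cfg.shape, cfg.voxel_size, cfg.centre)
    mat, skipped = build_system_rows(one, geometry, grid, cfg)
    assert skipped == 0
    row = mat[0].toarray().ravel()
    assert (row > 0).any()
    # the supported voxels hug the line between the two endpoints
    idx = np.nonzero(row)[0]
    pts = grid.voxel_centres()[idx]
    from cztpet.recon import event_endpoints
    ends, _ = event_endpoints(one, geometry, cfg)
    a, b = ends[0], ends[1]
    d = (b - a) / np.linalg.norm(b - a)
    off = (pts - a) - np.outer((pts - a) @ d, d)
    assert np.linalg.norm(off, axis=1).max() < 4 * cfg.voxel_size


def test_point_source_centroid_recovered(point_recon):
    imgs, info, cfg = point_recon
    img = imgs[-1]
    dat = img.data
    com = (img.voxel_centres() * dat.ravel()[:, None]).sum(axis=0) / dat.sum()
    assert np.abs(com - np.array([1.0, 0.5, 0.0])).max() < 0.25  # one voxel


def test_total_intensity_stabilises(point_recon):
    imgs, _, _ = point_recon
    totals = np.array([im.data.sum() for im in imgs])
    # after the first iteration the total changes by under a few percent
    rel = np.abs(np.diff(totals[1:])) / totals[1]
    assert np.all(rel < 0.03)


def test_nonnegativity_and_zero_sensitivity_frozen(point_recon):
    imgs, _, _ = point_recon
    assert np.all(imgs[-1].data >= 0)


def test_one_subset_iteration_equals_dense_mlem(geometry, point_events):
    """OS-EM with one subset reproduces a direct dense MLEM step."""
    cfg = ReconstructionConfig(doi_bin_mm=2.5, voxel_size=1.0,
                               shape=(8, 8, 8), iterations=1,
                               tube_cutoff_voxels=50.0,
                               sensitivity_D=2, sensitivity_lateral_step=10)
    sub = point_events.select(np.arange(min(40, point_events.n_events)))
    grid = ActivityImage.empty(cfg.shape, cfg.voxel_size, cfg.centre)
    mat, _ = build_system_rows(sub, geometry, grid, cfg)
    from cztpet.system_model import sensitivity_on_grid
    s = sensitivity_on_grid(geometry, grid, D=2, lateral_step=10)
    imgs, _ = osem_reconstruct(sub, geometry, cfg, sensitivity=s)
    # dense oracle
    A = mat.toarray()
    f0 = np.ones(A.shape[1])
    f0[s <= 0] = 0.0
    proj = A @ f0
    good = proj > 0
    back = A[good].T @ (1.0 / proj[good])
    f1 = np.where(s > 0, f0 * back / np.where(s > 0, s, 1.0), 0.0)
    np.testing.assert_allclose(imgs[0].data.ravel(), f1, rtol=1e-10, atol=1e-12)


def test_decay_adjusted_sensitivity():
    s = np.array([1.0, 2.0, 3.0])
    out = decay_adjusted_sensitivity(s, [100, 100, 100])
    for o in out:
        np.testing.assert_allclose(o, s)
    out = decay_adjusted_sensitivity(s, [100, 50])
    np.testing.assert_allclose(out[1], s * 0.5)
    with pytest.raises(ValueError):
        decay_adjusted_sensitivity(s, [0, 10])


def test_gaussian_postfilter_properties():
    img = ActivityImage.empty((21, 21, 21), 0.1)
    img.data[10, 10, 10] = 1.0
    assert gaussian_postfilter(img, 0.0).data[10, 10, 10] == 1.0
    sm = gaussian_postfilter(img, 0.40)
    assert sm.data.sum() == pytest.approx(1.0, rel=1e-3)
    prof = sm.data[:, 10, 10]
    xs = (np.arange(21) + 0.5) * 0.1
    assert profile_fwhm(prof, xs) == pytest.approx(0.40, abs=0.05)


def test_profile_fwhm_gaussian_and_flat():
    xs = np.linspace(-5, 5, 101)
    prof = np.exp(-0.5 * (xs / 0.5) ** 2)
    assert profile_fwhm(prof, xs) == pytest.approx(2.355 * 0.5, abs=1e-3)
    with pytest.raises(ValueError):
        profile_fwhm(np.ones(50))


def test_peak_to_valley():
    prof = np.array([0.0, 1.13, 1.0, 1.50, 0.0])
    assert peak_to_valley(prof, [1, 3], 2) == pytest.approx(1.13)
    assert peak_to_valley(np.array([1.0, 0.0, 1.0]), [0, 2], 1) == np.inf


def test_normalized_sd_cases():
    img = ActivityImage.empty((10, 1, 1), 1.0)
    img.data[:, 0, 0] = 5.0
    roi = (slice(0, 5), 0, 0)
    assert normalized_sd(img, [roi]) == 0.0
    img.data[:5, 0, 0] = [4, 5, 6, 5, 5]
    v = img.data[:5, 0, 0]
    expected = v.std() / v.mean()
    assert normalized_sd(img, [roi]) == pytest.approx(expected)
    # two ROIs with equal means: simple average of the two SD/mean values
    img.data[5:, 0, 0] = [3, 7, 5, 5, 5]
    roi2 = (slice(5, 10), 0, 0)
    v2 = img.data[5:, 0, 0]
    expected2 = 0.5 * (v.std() / v.mean() + v2.std() / v2.mean())
    assert normalized_sd(img, [roi, roi2]) == pytest.approx(expected2)
    img.data[5:, 0, 0] = 0.0
    with pytest.raises(ValueError):
        normalized_sd(img, [roi2])
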