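"""Phantom rasterisation, list-mode I/O, and the CLI."""

import numpy as np
import pytest

from cztpet.io import read_listmode, write_listmode
from cztpet.phantoms import (
    HOT_ROD_DIAMETERS,
    HOT_ROD_PITCHES,
    PhantomSpec,
    hot_rod_centres,
    make_phantom,
)


def test_point_phantom_support_and_normalisation():
    spec = PhantomSpec("point", total_activity=1000.0, diameter=0.25)
    img = make_phantom(spec, 0.05)
    assert img.total_activity == pytest.approx(1000.0, rel=1e-6)
    idx = np.nonzero(img.data)
    pts = img.voxel_centres().reshape(*img.shape, 3)[idx]
    assert np.linalg.norm(pts, axis=1).max() <= 0.125 + 0.05 * np.sqrt(3)


def test_voxel_too_coarse_raises():
    with pytest.raises(ValueError):
        make_phantom(PhantomSpec("point", diameter=0.25), 0.2)


def test_hot_rod_sector_geometry():
    sectors = hot_rod_centres()
    assert len(sectors) == 4
    for (dia, centres), pitch in zip(sectors, HOT_ROD_PITCHES):
        assert dia in HOT_ROD_DIAMETERS
        assert len(centres) >= 3
        # all rods inside the 14-mm cylinder with the rod radius margin
        r = np.linalg.norm(centres, axis=1)
        assert np.all(r + dia / 2.0 <= 7.0)
        # nearest-neighbour distance equals the stated pitch
        d = np.linalg.norm(centres[:, None] - centres[None, :], axis=2)
        d[d == 0] = np.inf
        assert d.min() == pytest.approx(pitch, rel=1e-6)
        # rods never overlap
        assert d.min() >= dia - 1e-9
    # sectors are disjoint in azimuth
    for s, (dia, centres) in enumerate(sectors):
        ang = np.degrees(np.arctan2(centres[:, 1], centres[:, 0])) % 360
        lo, hi = 90.0 * s, 90.0 * (s + 1)
        assert np.all((ang >= lo) & (ang <= hi))


def test_hot_rod_rasterisation_converges():
    spec = PhantomSpec("hot-rod", total_activity=1.0)
    coarse = make_phantom(spec, 0.175)
    fine = make_phantom(spec, 0.0875)

    def sector_fractions(img):
        pts = img.voxel_centres().reshape(*img.shape, 3)
        ang = np.degrees(np.arctan2(pts[..., 1], pts[..., 0])) % 360
        rods = pts[..., 2] < img.origin[2] + img.data.shape[2] * img.spacing[2] - 2.5
        out = []
        for s in range(4):
            m = (ang >= 90 * s) & (ang < 90 * (s + 1)) & rods
            out.append(img.data[m].sum())
        return np.array(out) / img.data.sum()

    fc = sector_fractions(coarse)
    ff = sector_fractions(fine)
    assert np.abs(fc - ff).max() < 0.01


def test_uniform_cap_present():
    spec = PhantomSpec("hot-rod", total_activity=1.0, uniform_cap=2.0)
    img = make_phantom(spec, 0.175)
    zs = img.origin[2] + (np.arange(img.shape[2]) + 0.5) * img.spacing[2]
    top = zs > 5.0 - 2.0 + 0.2
    bottom = zs < 5.0 - 2.0 - 0.2
    # the cap slice is a full disc: much more active area than rod slices
    area_top = (img.data[:, :, top][:, :, 0] > 0).sum()
    area_bot = (img.data[:, :, bottom][:, :, -1] > 0).sum()
    assert area_top > 3 * area_bot


def test_listmode_roundtrip_bit_identical(tmp_path, mixed_stream):
    path = tmp_path / "lm.h5"
    write_listmode(mixed_stream, path)
    back = read_listmode(path)
    for table, orig in (("events", mixed_stream.events),
                        ("photons", mixed_stream.photons),
                        ("sites", mixed_stream.sites)):
        for k, v in orig.items():
            np.testing.assert_array_equal(getattr(back, table)[k], v)
    for k, v in mixed_stream.truth.items():
        np.testing.assert_array_equal(back.truth[k], v)


def test_listmode_without_truth(tmp_path, mixed_stream):
    path = tmp_path / "lm_exp.h5"
    write_listmode(mixed_stream, path, include_truth=False)
    back = read_listmode(path)
    assert back.truth is None
    assert back.n_events == mixed_stream.n_events


def test_listmode_error_modes(tmp_path, mixed_stream):
    import h5py
    path = tmp_path / "bad.h5"
    write_listmode(mixed_stream, path)
    with h5py.File(path, "a") as fh:
        del fh.attrs["format"]
    with pytest.raises(ValueError, match="format"):
        read_listmode(path)

    path2 = tmp_path / "trunc.h5"
    write_listmode(mixed_stream, path2)
    with h5py.File(path2, "a") as fh:
        del fh["sites"]
    with pytest.raises(ValueError, match="sites"):
        read_listmode(path2)

    path3 = tmp_path / "units.h5"
    write_listmode(mixed_stream, path3)
    with h5py.File(path3, "a") as fh:
        import json
        h = json.loads(fh.attrs["header_json"])
        h["units"] = {"length": "cm", "energy": "keV", "time": "ns"}
        fh.attrs["header_json"] = json.dumps(h)
    with pytest.raises(ValueError, match="unit"):
        read_listmode(path3)


def test_geometry_serialisation_roundtrip(tmp_path, geometry):
    import numpy as np
    path = tmp_path / "geom.json"
    g = geometry.copy()
    a = g.alpha
    a[:6] += [0.3, -0.2, 0.1, 0.2, -0.3, 0.15]
    g.alpha = a
    g.to_json(path)
    from cztpet.geometry import SystemGeometry
    back = SystemGeometry.from_json(path)
    np.testing.assert_allclose(back.alpha, g.alpha)
    np.testing.assert_allclose(back.module_transforms()[0],
                               g.module_transforms()[0])
    with pytest.raises(ValueError):
        bad = tmp_path / "bad.json"
        bad.write_text('{"format": "something-else"}')
        SystemGeometry.from_json(bad)


def test_simulation_is_deterministic_under_seed(geometry):
    from cztpet.simulate import simulate_coincidences
    ph = make_phantom(PhantomSpec("point", total_activity=1e5,
                                  diameter=0.25), 0.1)
    a = simulate_coincidences(ph, geometry, 0.02, np.random.default_rng(77))
    b = simulate_coincidences(ph, geometry, 0.02, np.random.default_rng(77))
    assert a.n_events == b.n_events
    np.testing.assert_array_equal(a.sites["energy"], b.sites["energy"])
    np.testing.assert_array_equal(a.photons["time"], b.photons["time"])


def test_cli_simulate_and_reject(tmp_path):
    from click.testing import CliRunner
    from cztpet.cli import build_response, reject, simulate

    runner = CliRunner()
    out = tmp_path / "sim"
    res = runner.invoke(simulate, ["--phantom", "point", "--activity", "2e5",
                                   "--duration", "0.02", "--seed", "3",
                                   "--out", str(out)], catch_exceptions=False)
    assert res.exit_code == 0
    assert (out / "listmode.h5").exists()
    assert (out / "run.json").exists()

    fdir = tmp_path / "resp"
    res = runner.invoke(build_response, ["--events", "120000", "--seed", "4",
                                         "--out", str(fdir)],
                        catch_exceptions=False)
    assert res.exit_code == 0

    rdir = tmp_path / "rej"
    res = runner.invoke(reject, ["--listmode", str(out / "listmode.h5"),
                                 "--response", str(fdir / "response.h5"),
                                 "--out", str(rdir)], catch_exceptions=False)
    assert res.exit_code == 0
    assert (rdir / "categories.csv").exists()
    assert (rdir / "rejection.csv").exists()
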