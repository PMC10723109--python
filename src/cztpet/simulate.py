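"""Coincidence-acquisition simulator: decays, transport, timing, pairing.

Annihilation photon pairs are emitted back-to-back in isotropic random
directions (perfect collinearity; positron range is not modelled) from
positions sampled proportionally to the phantom's voxel activity.  Detected
photons receive a timestamp equal to the decay time plus Gaussian timing
jitter (100 ns FWHM by default), and coincidences are formed in
post-processing: clusters of detected photons separated by less than the
pairing window are paired when they contain exactly two photons and dropped
as pile-up otherwise.  Photons from different annihilations paired this way
are random coincidences; the ground-truth label is kept in the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import HALF_LIFE_S
from .detector import FWHM_TO_SIGMA, DetectorModel, process_sites_batch
from .geometry import MODULES_PER_PANEL, SystemGeometry
from .transport import BoxSet, isotropic_directions, ray_box_entries, transport_batch

TIMING_FWHM_NS = 100.0
DEFAULT_WINDOW_NS = 250.0  # half-width of the pairing window

_PANEL_BOUNDS_CACHE: dict = {}


def _panel_bounds(geometry) -> BoxSet:
    """One slightly inflated bounding box per panel (for ray pre-culling)."""
    key = id(geometry)
    cached = _PANEL_BOUNDS_CACHE.get(key)
    if cached is not None:
        return cached
    Rs, ts = geometry.module_transforms()
    from .geometry import MODULE_HALF, MODULES_PER_PANEL, N_PANELS
    corners = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                        for sz in (-1, 1)]) * MODULE_HALF
    centres, halves = [], []
    for p in range(N_PANELS):
        pts = []
        for m in range(MODULES_PER_PANEL):
            i = p * MODULES_PER_PANEL + m
            pts.append(corners @ Rs[i].T + ts[i])
        pts = np.concatenate(pts)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        centres.append((lo + hi) / 2.0)
        halves.append((hi - lo) / 2.0 + 0.5)
    out = BoxSet(np.broadcast_to(np.eye(3), (N_PANELS, 3, 3)).copy(),
                 np.array(centres), np.array(halves))
    _PANEL_BOUNDS_CACHE[key] = out
    return out


@dataclass
class ListModeData:
    """List-mode coincidence dataset (structure of arrays).

    ``events`` holds one row per coincidence; ``photons`` two rows per event
    (side 0, side 1, contiguous) with ``site_start``/``site_count`` indexing
    into ``sites``.  The ``truth`` block (simulation only) carries the
    random/true label, the emission point, and the ground-truth first-site
    index per photon; experimental-style files simply omit it.
    """

    events: dict = field(default_factory=dict)
    photons: dict = field(default_factory=dict)
    sites: dict = field(default_factory=dict)
    truth: dict | None = None
    header: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return 0 if not self.events else int(np.asarray(self.events["subset"]).size)

    def photon_energy(self) -> np.ndarray:
        """Summed observed energy [keV] per photon row."""
        start = np.asarray(self.photons["site_start"], dtype=int)
        count = np.asarray(self.photons["site_count"], dtype=int)
        csum = np.r_[0.0, np.cumsum(self.sites["energy"])]
        return csum[start + count] - csum[start]

    def site_positions(self) -> np.ndarray:
        return np.column_stack([self.sites["x"], self.sites["y"], self.sites["z"]])

    def photon_sites(self, photon_row: int) -> slice:
        s = int(self.photons["site_start"][photon_row])
        return slice(s, s + int(self.photons["site_count"][photon_row]))

    def select(self, mask) -> "ListModeData":
        """Sub-dataset with the events where ``mask`` is True (or by index)."""
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        ev = {k: np.asarray(v)[idx] for k, v in self.events.items()}
        ph_rows = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
        starts = np.asarray(self.photons["site_start"], dtype=int)[ph_rows]
        counts = np.asarray(self.photons["site_count"], dtype=int)[ph_rows]
        site_rows = (np.concatenate([np.arange(s, s + c) for s, c in zip(starts, counts)])
                     if ph_rows.size else np.zeros(0, int))
        ph = {k: np.asarray(v)[ph_rows] for k, v in self.photons.items()}
        ph["site_start"] = np.r_[0, np.cumsum(counts)[:-1]].astype(int) if ph_rows.size \
            else np.zeros(0, int)
        ph["event"] = np.repeat(np.arange(idx.size), 2)
        st = {k: np.asarray(v)[site_rows] for k, v in self.sites.items()}
        truth = None
        if self.truth is not None:
            truth = {}
            for k, v in self.truth.items():
                v = np.asarray(v)
                truth[k] = v[ph_rows] if v.shape[0] == 2 * self.n_events else v[idx]
        return ListModeData(events=ev, photons=ph, sites=st, truth=truth,
                            header=dict(self.header))


def sample_emissions(phantom, n, rng):
    """Sample ``n`` emission positions [mm] proportional to voxel activity."""
    act = np.asarray(phantom.data, dtype=float).ravel()
    p = act / act.sum()
    vox = rng.choice(act.size, size=n, p=p)
    ijk = np.column_stack(np.unravel_index(vox, phantom.data.shape)).astype(float)
    ijk += rng.random((n, 3))
    return phantom.origin + ijk * phantom.spacing


def simulate_photon_pool(phantom, geometry: SystemGeometry, rng,
                         model: DetectorModel | None = None,
                         doppler: bool = True, n_subsets: int = 1,
                         angle_step_deg: float = 0.0,
                         isotope: str | None = None,
                         activity: float | None = None,
                         duration: float = 1.0):
    """Simulate decays and return the pool of detected photons (unpaired).

    Returns ``(photons, sites, subset_decays)`` where ``photons`` maps
    panel/time/decay/subset/emit arrays over detected photons and ``sites``
    maps group/pos/energy/module/chrono arrays over their observed sites.
    """
    model = model or DetectorModel()
    activity = float(getattr(phantom, "total_activity", 0.0)
                     if activity is None else activity)
    if activity <= 0 or np.asarray(phantom.data).sum() <= 0:
        raise ValueError("phantom must carry positive activity")
    boxes = BoxSet.from_geometry(geometry)
    half_life = HALF_LIFE_S.get(isotope) if isotope else None

    per = duration / n_subsets
    ph_parts, site_parts = [], []
    decay_offset = 0
    photon_offset = 0
    subset_decays = []
    for s in range(n_subsets):
        act_s = activity * (0.5 ** (s * per / half_life) if half_life else 1.0)
        n_dec = int(rng.poisson(act_s * per))
        subset_decays.append(n_dec)
        if n_dec == 0:
            continue
        origin = sample_emissions(phantom, n_dec, rng)
        if angle_step_deg and s:
            a = np.radians(angle_step_deg * s)
            rot = np.array([[np.cos(a), -np.sin(a), 0.0],
                            [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]])
            origin = origin @ rot.T
        t_decay = rng.uniform(s * per * 1e9, (s + 1) * per * 1e9, n_dec)  # ns
        d = isotropic_directions(rng, n_dec)
        orig2 = np.repeat(origin, 2, axis=0)
        dirs2 = np.empty_like(orig2)
        dirs2[0::2] = d
        dirs2[1::2] = -d
        # cheap cull: photons whose ray misses every panel bounding box
        # cannot produce sites; transport only the rest
        tin_c, _ = ray_box_entries(orig2, dirs2, _panel_bounds(geometry))
        cand = np.nonzero(np.isfinite(tin_c).any(axis=1))[0]
        rec = transport_batch(boxes, orig2[cand], dirs2[cand], 511.0, rng,
                              doppler=doppler)
        rec.photon = cand[rec.photon]  # back to the full photon numbering
        obs = process_sites_batch(rec, boxes, model, rng)
        if obs["photon"].size == 0:
            continue

        panel = (obs["module"] // MODULES_PER_PANEL).astype(int)
        key = np.column_stack([obs["photon"], panel])
        _, first_idx, inv = np.unique(key, axis=0, return_index=True,
                                      return_inverse=True)
        order = np.argsort(first_idx, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(order.size)
        inv = rank[inv]
        ng = order.size
        history = np.zeros(ng, dtype=int)
        ppanel = np.zeros(ng, dtype=int)
        history[inv] = obs["photon"]
        ppanel[inv] = panel
        decay = history // 2
        t = t_decay[decay] + rng.standard_normal(ng) * TIMING_FWHM_NS * FWHM_TO_SIGMA
        ph_parts.append({
            "panel": ppanel, "time": t, "decay": decay + decay_offset,
            "subset": np.full(ng, s, dtype=int), "emit": origin[decay],
        })
        site_parts.append({
            "group": inv + photon_offset, "pos": obs["pos"],
            "energy": obs["energy"], "module": obs["module"].astype(int),
            "chrono": obs["chrono_row"].astype(int),
        })
        decay_offset += n_dec
        photon_offset += ng

    if not ph_parts:
        return None, None, subset_decays
    photons = {k: np.concatenate([p[k] for p in ph_parts]) for k in ph_parts[0]}
    sites = {k: np.concatenate([s[k] for s in site_parts]) for k in site_parts[0]}
    return photons, sites, subset_decays


def simulate_coincidences(phantom, geometry: SystemGeometry, duration: float,
                          rng, window_ns: float = DEFAULT_WINDOW_NS,
                          model: DetectorModel | None = None,
                          doppler: bool = True,
                          n_subsets: int = 1, angle_step_deg: float = 0.0,
                          isotope: str | None = None,
                          activity: float | None = None) -> ListModeData:
    """Simulate a list-mode acquisition of ``duration`` seconds.

    ``activity`` [Bq] defaults to ``phantom.total_activity``.  With
    ``n_subsets`` > 1 the acquisition is split into equal-length angle steps:
    the object is rotated by ``angle_step_deg`` between steps and the
    activity decays with the isotope half-life across steps.
    """
    photons, sites, subset_decays = simulate_photon_pool(
        phantom, geometry, rng, model=model, doppler=doppler,
        n_subsets=n_subsets, angle_step_deg=angle_step_deg, isotope=isotope,
        activity=activity, duration=duration)
    if photons is None:
        data = _empty_listmode(window_ns)
    else:
        t_order = np.argsort(photons["time"], kind="stable")
        ts = photons["time"][t_order]
        new_cluster = np.r_[True, np.diff(ts) > window_ns]
        cluster_id = np.cumsum(new_cluster) - 1
        csize = np.bincount(cluster_id)
        good = csize[cluster_id] == 2
        pair_rows = t_order[good]
        data = _assemble_pairs(photons, sites, pair_rows[0::2], pair_rows[1::2],
                               window_ns, rng)
    data.header.update({
        "format": "cztpet-listmode-1",
        "duration_s": duration,
        "activity_bq": float(getattr(phantom, "total_activity", 0.0)
                             if activity is None else activity),
        "window_ns": window_ns, "n_subsets": n_subsets,
        "angle_step_deg": angle_step_deg, "isotope": isotope or "",
        "subset_decays": subset_decays,
        "units": {"length": "mm", "energy": "keV", "time": "ns"},
    })
    return data


def random_coincidence_stream(phantom, geometry: SystemGeometry, n_pairs: int,
                              rng, window_ns: float = DEFAULT_WINDOW_NS,
                              model: DetectorModel | None = None,
                              doppler: bool = True) -> ListModeData:
    """A pure random-coincidence stream: pairs of photons from different decays.

    Detected photons from independent annihilations are paired uniformly at
    random (distinct decays, distinct panels), emulating the chance pairings a
    high singles flux produces within the timing window.
    """
    got = 0
    parts = []
    while got < n_pairs:
        need = n_pairs - got
        duration = max(need, 100) / max(phantom.total_activity * 0.05, 1.0)
        photons, sites, _ = simulate_photon_pool(
            phantom, geometry, rng, model=model, doppler=doppler,
            duration=duration)
        if photons is None:
            continue
        n = photons["panel"].size
        perm = rng.permutation(n)
        a = perm[0::2][: n // 2]
        b = perm[1::2][: n // 2]
        ok = (photons["decay"][a] != photons["decay"][b]) & \
             (photons["panel"][a] != photons["panel"][b])
        a, b = a[ok][:need], b[ok][:need]
        if a.size == 0:
            continue
        chunk = _assemble_pairs(photons, sites, a, b, window_ns, rng)
        chunk.truth["is_random"][:] = True
        chunk.events["dt"] = rng.uniform(-window_ns, window_ns, a.size)
        parts.append(chunk)
        got += a.size
    out = concatenate_listmode(parts)
    out.header["format"] = "cztpet-listmode-1"
    out.header["units"] = {"length": "mm", "energy": "keV", "time": "ns"}
    return out


def concatenate_listmode(parts: list) -> ListModeData:
    """Concatenate event streams (site offsets re-based)."""
    parts = [p for p in parts if p.n_events]
    if not parts:
        return _empty_listmode(DEFAULT_WINDOW_NS)
    ev = {k: np.concatenate([p.events[k] for p in parts]) for k in parts[0].events}
    ph = {k: np.concatenate([p.photons[k] for p in parts]) for k in parts[0].photons}
    st = {k: np.concatenate([p.sites[k] for p in parts]) for k in parts[0].sites}
    ev_off = np.cumsum([0] + [p.n_events for p in parts][:-1])
    site_off = np.cumsum([0] + [p.sites["energy"].size for p in parts][:-1])
    ph["event"] = np.concatenate([p.photons["event"] + o
                                  for p, o in zip(parts, ev_off)])
    ph["site_start"] = np.concatenate([p.photons["site_start"] + o
                                       for p, o in zip(parts, site_off)])
    truth = None
    if all(p.truth is not None for p in parts):
        truth = {k: np.concatenate([p.truth[k] for p in parts])
                 for k in parts[0].truth}
    return ListModeData(events=ev, photons=ph, sites=st, truth=truth,
                        header=dict(parts[0].header))


def _empty_listmode(window_ns: float) -> ListModeData:
    return ListModeData(
        events={"subset": np.zeros(0, np.int16), "dt": np.zeros(0)},
        photons={"event": np.zeros(0, int), "side": np.zeros(0, int),
                 "panel": np.zeros(0, int), "time": np.zeros(0),
                 "site_start": np.zeros(0, int), "site_count": np.zeros(0, int)},
        sites={"x": np.zeros(0), "y": np.zeros(0), "z": np.zeros(0),
               "energy": np.zeros(0), "module": np.zeros(0, int)},
        truth={"is_random": np.zeros(0, bool),
               "emit": np.zeros((0, 3)), "first_site": np.zeros(0, int)},
        header={"window_ns": window_ns},
    )


def _assemble_pairs(photons, sites, p_a, p_b, window_ns, rng) -> ListModeData:
    """Build a dataset from explicit photon-row pairs (p_a side 0, p_b side 1)."""
    panel = photons["panel"]
    time = photons["time"]
    decay = photons["decay"]
    subset = photons["subset"]
    emit = photons["emit"]
    s_group = sites["group"]
    s_pos = sites["pos"]
    s_energy = sites["energy"]
    s_module = sites["module"]
    s_chrono = sites["chrono"]

    # group sites contiguously per photon
    site_order = np.argsort(s_group, kind="stable")
    s_group = s_group[site_order]
    s_pos, s_energy = s_pos[site_order], s_energy[site_order]
    s_module, s_chrono = s_module[site_order], s_chrono[site_order]
    n_photons = panel.size
    counts = np.bincount(s_group, minlength=n_photons)
    starts = np.r_[0, np.cumsum(counts)[:-1]]

    n_ev = p_a.size
    if n_ev == 0:
        return _empty_listmode(window_ns)

    ph_rows = np.stack([p_a, p_b], axis=1).ravel()
    out_counts = counts[ph_rows]
    out_starts = np.r_[0, np.cumsum(out_counts)[:-1]]
    idx_sites = np.concatenate([np.arange(starts[r], starts[r] + counts[r])
                                for r in ph_rows])
    # shuffle site order within each photon so storage order carries no
    # ground-truth sequence information
    jitter = rng.random(idx_sites.size)
    owner = np.repeat(np.arange(ph_rows.size), out_counts)
    reorder = np.lexsort((jitter, owner))
    idx_sites = idx_sites[reorder]

    chrono = s_chrono[idx_sites]
    first_site = np.zeros(ph_rows.size, dtype=int)
    for_min = np.full(ph_rows.size, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(for_min, owner, chrono)
    is_first_site = chrono == for_min[owner]
    # position within the photon block
    within = np.arange(idx_sites.size) - out_starts[owner]
    # earliest chronological site wins (unique since chrono rows are unique)
    first_site[owner[is_first_site]] = within[is_first_site]

    events = {
        "subset": subset[p_a].astype(np.int16),
        "dt": time[p_b] - time[p_a],
    }
    photons = {
        "event": np.repeat(np.arange(n_ev), 2),
        "side": np.tile([0, 1], n_ev),
        "panel": panel[ph_rows],
        "time": time[ph_rows],
        "site_start": out_starts.astype(int),
        "site_count": out_counts.astype(int),
    }
    sites = {
        "x": s_pos[idx_sites, 0], "y": s_pos[idx_sites, 1],
        "z": s_pos[idx_sites, 2], "energy": s_energy[idx_sites],
        "module": s_module[idx_sites],
    }
    truth = {
        "is_random": decay[p_a] != decay[p_b],
        "emit": emit[p_a],
        "first_site": first_site,
    }
    return ListModeData(events=events, photons=photons, sites=sites,
                        truth=truth, header={"window_ns": window_ns})
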