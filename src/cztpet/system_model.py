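"""Analytic coincidence-response model with DOI sublayers, and the sensitivity map.

The probability of a coincidence in the detector-voxel pair (I1, I2) from a
source voxel i combines, over all sublayer pairs (n, m),

* the first-photon term: solid angle of the sublayer's central slice times
  attenuation before it and interaction inside it,
  ``S1 cos(phi) / (4 pi d^2) * exp(-mu l) * (1 - exp(-mu l0))``;
* the conditional second-photon term: the back-projected overlap fraction
  S'/S2 of the first slice through the source onto the second slice's plane,
  times the same attenuation/interaction structure along the mirrored ray.

Attenuation uses the transport coefficient (photoelectric + incoherent) of
CZT at 511 keV.  The sensitivity map additionally folds in, per photon, the
probability that an interacting photon deposits its full energy inside the
panel within the energy window — a factor estimated once per geometry by
Monte Carlo (the analytic terms model interaction only).
"""

from __future__ import annotations

import numpy as np

from .detector import DetectorModel, process_sites_batch
from .geometry import (
    MODULE_HALF,
    MODULES_PER_PANEL,
    N_PANELS,
    VOXEL_PITCH,
    DetectorVoxelIndex,
    SystemGeometry,
)
from .materials import default_table
from .polygon import clip_quads_to_rect
from .transport import BoxSet, isotropic_directions, ray_box_entries, transport_batch

MU_511 = None  # lazy


def _mu() -> float:
    """Linear attenuation coefficient of CZT at 511 keV [1/mm].

    The coincidence-response equations use the total attenuation (coherent
    included), matching their definition of mu for CZT.
    """
    global MU_511
    if MU_511 is None:
        MU_511 = default_table().cross_sections(511.0).total / 10.0
    return MU_511


def _module_entry_path(boxes: BoxSet, module, src, targets):
    """Path [mm] inside the owning module before reaching each target point.

    ``src`` (3,), ``targets`` (N, 3); ``module`` scalar or (N,) box indices.
    """
    diff = targets - src
    dist = np.linalg.norm(diff, axis=1)
    dirs = diff / dist[:, None]
    module = np.broadcast_to(module, (targets.shape[0],))
    R = boxes.rotations[module]
    c = boxes.centres[module]
    o = np.einsum("nk,nkj->nj", src - c, R)
    d = np.einsum("nk,nkj->nj", dirs, R)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-boxes.halves[module] - o) / d
        t2 = (boxes.halves[module] - o) / d
    lo = np.minimum(t1, t2)
    hi = np.maximum(t1, t2)
    par = np.abs(d) < 1e-12
    lo = np.where(par, -np.inf, lo)
    hi = np.where(par, np.inf, hi)
    tin = lo.max(axis=1)
    tout = hi.min(axis=1)
    return np.clip(dist - np.maximum(tin, 0.0), 0.0, None), tin, tout, dist, dirs


def p_first_photon(geometry: SystemGeometry, source, index: DetectorVoxelIndex,
                   sublayer: int | None = None) -> float:
    """Eq.-style first-photon probability p(I1, n | i) for one sublayer.

    ``index.doi`` selects the sublayer ``n`` (of ``index.D``); returns 0 when
    the slice is not visible from the source (cos(phi) <= 0 cannot occur for
    outward panels, but a degenerate grazing ray yields 0).
    """
    if sublayer is not None:
        index = DetectorVoxelIndex(index.module_id, index.u, index.v,
                                   sublayer, index.D)
    boxes = BoxSet.from_geometry(geometry)
    src = np.asarray(source, float)
    centre = geometry.voxel_centre_global(index)
    mu = _mu()
    layer = 2.0 * MODULE_HALF[2] / index.D
    n_axis = boxes.rotations[index.module_id][:, 2]
    diff = centre - src
    d = np.linalg.norm(diff)
    u = diff / d
    cos_phi = abs(float(u @ n_axis))
    if cos_phi < 1e-9:
        return 0.0
    S1 = VOXEL_PITCH * VOXEL_PITCH
    solid = S1 * cos_phi / (4.0 * np.pi * d * d)
    l_centre, *_ = _module_entry_path(boxes, index.module_id, src, centre[None])
    l0 = layer / cos_phi
    # l runs to the sublayer's entry face; the interaction term covers l0
    l_before = max(l_centre[0] - l0 / 2.0, 0.0)
    if mu == 0.0:
        return 0.0
    return float(solid * np.exp(-mu * l_before) * (1.0 - np.exp(-mu * l0)))


def _slice_quad_global(geometry, boxes, index: DetectorVoxelIndex):
    """Corner points (4, 3) of the voxel's sublayer central slice, global."""
    c_local = geometry.voxel_centre_local(index)
    h = VOXEL_PITCH / 2.0
    corners = np.array([[-h, -h, 0], [h, -h, 0], [h, h, 0], [-h, h, 0]]) + c_local
    R = boxes.rotations[index.module_id]
    t = boxes.centres[index.module_id]
    return corners @ R.T + t


def p_coincidence(geometry: SystemGeometry, source, I1: DetectorVoxelIndex,
                  I2: DetectorVoxelIndex, D: int | None = None) -> float:
    """p(A | i): coincidence probability for a detector-voxel pair (Eq. 1-3)."""
    if geometry.panel_of_module(I1.module_id) == geometry.panel_of_module(I2.module_id):
        raise ValueError("detector voxels must lie on different panels")
    D = D or I1.D
    boxes = BoxSet.from_geometry(geometry)
    src = np.asarray(source, float)
    mu = _mu()
    layer = 2.0 * MODULE_HALF[2] / D
    R2 = boxes.rotations[I2.module_id]
    t2 = boxes.centres[I2.module_id]
    S2 = VOXEL_PITCH * VOXEL_PITCH
    total = 0.0
    for n in range(D):
        i1 = DetectorVoxelIndex(I1.module_id, I1.u, I1.v, n, D)
        p1 = p_first_photon(geometry, src, i1)
        if p1 <= 0.0:
            continue
        quad = _slice_quad_global(geometry, boxes, i1)
        for m in range(D):
            i2 = DetectorVoxelIndex(I2.module_id, I2.u, I2.v, m, D)
            c2_local = geometry.voxel_centre_local(i2)
            # project the first slice's corners through the source onto the
            # plane z_local = c2_local[2] of module 2
            q_local = (quad - t2) @ R2
            s_local = (src - t2) @ R2
            dz = q_local[:, 2] - s_local[2]
            plane_z = c2_local[2]
            with np.errstate(divide="ignore", invalid="ignore"):
                t_par = (plane_z - s_local[2]) / dz
            # photon 2 travels opposite photon 1: the back-projected point
            # sits at negative line parameter
            if np.any(~np.isfinite(t_par)) or np.any(t_par >= 0):
                continue
            proj = s_local[None, :2] + t_par[:, None] * (q_local[:, :2] - s_local[None, :2])
            rel = proj - c2_local[:2]
            s_prime = clip_quads_to_rect(rel[None], VOXEL_PITCH / 2.0,
                                         VOXEL_PITCH / 2.0)[0]
            if s_prime <= 0.0:
                continue
            # attenuation/interaction for photon 2 along the mirrored ray
            c2_global = c2_local @ R2.T + t2
            diff = c2_global - src
            d2 = np.linalg.norm(diff)
            u = diff / d2
            cos_phi2 = abs(float(u @ R2[:, 2]))
            if cos_phi2 < 1e-9:
                continue
            l_centre2, *_ = _module_entry_path(boxes, I2.module_id, src,
                                               c2_global[None])
            l0p = layer / cos_phi2
            l_before2 = max(l_centre2[0] - l0p / 2.0, 0.0)
            p2 = (s_prime / S2) * np.exp(-mu * l_before2) * (1.0 - np.exp(-mu * l0p))
            total += p1 * p2
    return float(total)


# ---------------------------------------------------------------------------
# sensitivity
# ---------------------------------------------------------------------------

def full_energy_factor(geometry: SystemGeometry, rng, n_photons: int = 200_000,
                       model: DetectorModel | None = None,
                       window=(500.0, 540.0), doppler: bool = True) -> float:
    """P(full-energy deposit in the struck panel | photon interacts), by MC.

    Photons are emitted isotropically from the FOV centre; for each photon
    that interacts at all, the observed (merged, blurred) energies in the
    panel of its first interaction are summed and tested against the window.
    """
    model = model or DetectorModel()
    boxes = BoxSet.from_geometry(geometry)
    dirs = isotropic_directions(rng, n_photons)
    rec = transport_batch(boxes, np.zeros((n_photons, 3)), dirs, 511.0, rng,
                          doppler=doppler)
    if len(rec) == 0:
        return 0.0
    n_interacting = np.unique(rec.photon).size
    obs = process_sites_batch(rec, boxes, model, rng)
    if obs["photon"].size == 0:
        return 0.0
    panel = (obs["module"] // MODULES_PER_PANEL).astype(int)
    photon = obs["photon"].astype(int)
    # panel of the first observed site per photon
    order = np.lexsort((obs["chrono_row"], photon))
    ph_sorted = photon[order]
    head = np.r_[True, ph_sorted[1:] != ph_sorted[:-1]]
    first_panel = np.full(photon.max() + 1, -1)
    first_panel[ph_sorted[head]] = panel[order][head]
    in_first = panel == first_panel[photon]
    sums = np.bincount(photon[in_first], weights=obs["energy"][in_first],
                       minlength=photon.max() + 1)
    detected = first_panel >= 0
    vals = sums[detected]
    n_full = int(((vals >= window[0]) & (vals <= window[1])).sum())
    return n_full / n_interacting


def panel_interaction_probability(boxes: BoxSet, src, dirs, panel: int,
                                  mu: float | None = None) -> np.ndarray:
    """P(photon interacts in the panel's modules) along each ray from ``src``."""
    mu = _mu() if mu is None else mu
    mods = np.arange(panel * MODULES_PER_PANEL, (panel + 1) * MODULES_PER_PANEL)
    sub = BoxSet(boxes.rotations[mods], boxes.centres[mods], boxes.halves[mods])
    origins = np.broadcast_to(np.asarray(src, float), dirs.shape)
    tin, tout = ray_box_entries(origins, dirs, sub)
    # combine chords through up to 4 modules: survival = exp(-mu * total chord)
    chord = np.zeros_like(tin)
    m = np.isfinite(tin)
    chord[m] = tout[m] - np.maximum(tin[m], 0.0)
    return 1.0 - np.exp(-mu * chord.sum(axis=1))


def sensitivity_at(geometry: SystemGeometry, points, D: int = 10,
                   lateral_step: int = 4,
                   efficiency: float = 1.0,
                   convention: str = "pair",
                   mu_override: float | None = None) -> np.ndarray:
    """Coincidence sensitivity at the given source points, shape (N,).

    Sums the first-photon term over all detector columns (downsampled by
    ``lateral_step``) and sublayers of every panel, times the opposite
    photon's interaction probability along the mirrored ray, times
    ``efficiency`` (e.g. a squared full-energy window factor).

    ``convention="pair"`` returns the coincidence-response sum over unordered
    detector-voxel pairs with a designated first photon — the quantity the
    analytic model defines, equal to half the physical coincidence rate.
    ``convention="physical"`` returns the full rate (each coincidence counted
    once, either photon may strike either detector), which is what a
    Monte-Carlo count of detected coincidences per decay measures.
    """
    boxes = BoxSet.from_geometry(geometry)
    mu = _mu() if mu_override is None else mu_override
    points = np.atleast_2d(np.asarray(points, float))
    layer = 2.0 * MODULE_HALF[2] / D
    ds = lateral_step
    n_lat = 100 // ds
    # lateral columns span the full crystal: the monolithic CZT is active out
    # to its rim, with rim interactions recorded by the edge voxels
    pitch = 2.0 * MODULE_HALF[0] / n_lat
    g = -MODULE_HALF[0] + (np.arange(n_lat) + 0.5) * pitch
    gu, gv = np.meshgrid(g, g, indexing="ij")
    zc = -MODULE_HALF[2] + (np.arange(D) + 0.5) * layer
    local = np.column_stack([
        np.repeat(gu.ravel(), D), np.repeat(gv.ravel(), D),
        np.tile(zc, gu.size)])  # (n_lat^2 * D, 3)
    S1 = pitch * pitch

    n_pts = points.shape[0]
    out = np.zeros(n_pts)
    C = local.shape[0]
    chunk = max(1, int(6e5 // C))
    for lo in range(0, n_pts, chunk):
        pts = points[lo:lo + chunk]  # (P, 3)
        P = pts.shape[0]
        s_total = np.zeros(P)
        for panel in range(N_PANELS):
            opp = geometry.opposite_panel(panel)
            for m in range(MODULES_PER_PANEL):
                mod = panel * MODULES_PER_PANEL + m
                R = boxes.rotations[mod]
                c = boxes.centres[mod]
                centres = local @ R.T + c  # (C, 3)
                diff = centres[None, :, :] - pts[:, None, :]  # (P, C, 3)
                d = np.linalg.norm(diff, axis=2)
                u = diff / d[:, :, None]
                cos_phi = np.abs(u @ R[:, 2])
                solid = S1 * cos_phi / (4.0 * np.pi * d**2)
                # exact entry point of the ray into this module's box
                o_loc = (pts - c) @ R  # (P, 3)
                d_loc = u @ R          # (P, C, 3)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ta = (-MODULE_HALF[None, None, :] - o_loc[:, None, :]) / d_loc
                    tb = (MODULE_HALF[None, None, :] - o_loc[:, None, :]) / d_loc
                tin = np.minimum(ta, tb).max(axis=2)
                l_centre = np.clip(d - np.maximum(tin, 0.0), 0.0, None)
                with np.errstate(divide="ignore"):
                    l0 = np.where(cos_phi > 1e-9, layer / cos_phi, 0.0)
                l_before = np.clip(l_centre - l0 / 2.0, 0.0, None)
                p1 = solid * np.exp(-mu * l_before) * (1.0 - np.exp(-mu * l0))
                p2 = panel_interaction_probability(
                    boxes, np.repeat(pts, C, axis=0), (-u).reshape(-1, 3),
                    opp, mu=mu).reshape(P, C)
                s_total += (p1 * p2).sum(axis=1)
        out[lo:lo + chunk] = s_total * efficiency
    if convention == "pair":
        out *= 0.5
    elif convention != "physical":
        raise ValueError("convention must be 'pair' or 'physical'")
    return out


def sensitivity_on_grid(geometry: SystemGeometry, grid, D: int = 4,
                        lateral_step: int = 4, step_mm: float = 2.0,
                        rotation_deg: float = 0.0,
                        convention: str = "physical") -> np.ndarray:
    """Sensitivity interpolated from a coarse lattice onto a fine grid.

    The sensitivity varies on the centimetre scale, so it is evaluated on a
    lattice of ~``step_mm`` spacing covering the grid and interpolated
    trilinearly onto the voxel centres; returns a flat array over the grid.
    """
    from scipy.interpolate import RegularGridInterpolator

    axes = [grid.origin[d] + (np.arange(grid.shape[d]) + 0.5) * grid.spacing[d]
            for d in range(3)]
    coarse_axes = []
    for d in range(3):
        lo, hi = axes[d][0], axes[d][-1]
        n = max(int(np.ceil((hi - lo) / step_mm)) + 1, 2)
        coarse_axes.append(np.linspace(lo - 1e-6, hi + 1e-6, n))
    cg = np.meshgrid(*coarse_axes, indexing="ij")
    pts = np.column_stack([a.ravel() for a in cg])
    if rotation_deg:
        a = np.radians(rotation_deg)
        rot = np.array([[np.cos(a), -np.sin(a), 0.0],
                        [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]])
        pts = pts @ rot.T
    vals = sensitivity_at(geometry, pts, D=D, lateral_step=lateral_step,
                          convention=convention)
    interp = RegularGridInterpolator(coarse_axes, vals.reshape(cg[0].shape),
                                     bounds_error=False, fill_value=None)
    fine = np.meshgrid(*axes, indexing="ij")
    return interp(np.column_stack([a.ravel() for a in fine]))


def sensitivity_map(geometry: SystemGeometry, grid, D: int = 10,
                    lateral_step: int = 4, rng=None,
                    include_full_energy: bool = False,
                    full_energy_mc: int = 200_000,
                    rotation_deg: float = 0.0,
                    convention: str = "pair"):
    """Per-voxel sensitivity over an ActivityImage-style grid.

    ``grid`` is an :class:`~cztpet.image.ActivityImage` (its voxel centres are
    used) and the result is returned as a new image.  The default is the raw
    coincidence-response sum (interaction sensitivity, pair convention —
    the quantity whose peak at the FOV centre is the system's quoted
    sensitivity); with ``include_full_energy`` the squared MC full-energy
    window factor is folded in, giving the in-window detected-coincidence
    sensitivity instead.  ``rotation_deg`` rotates the source grid about z
    (for per-subset maps of a rotated object).
    """
    pts = grid.voxel_centres()
    if rotation_deg:
        a = np.radians(rotation_deg)
        rot = np.array([[np.cos(a), -np.sin(a), 0.0],
                        [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]])
        pts = pts @ rot.T
    eff = 1.0
    if include_full_energy:
        rng = rng if rng is not None else np.random.default_rng(0)
        f = full_energy_factor(geometry, rng, n_photons=full_energy_mc)
        eff = f * f
    s = sensitivity_at(geometry, pts, D=D, lateral_step=lateral_step,
                       efficiency=eff, convention=convention)
    return grid.copy_with(s.reshape(grid.shape))
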