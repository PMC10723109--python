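"""Detector response: anode-pixel merging and finite-resolution blurring.

Interactions that fall inside the same 1.9-mm anode pixel of a module cannot
be separated by the readout and are merged — energy-weighted centroid
position, summed energy — *before* any blurring.  Each merged site then
receives an independent Gaussian energy blur (FWHM interpolated between the
measured anchors 3 keV @ 200 keV, 4.5 keV @ 450 keV, 5.4 keV @ 511 keV) and
an isotropic 3-D Gaussian position blur (0.5 mm FWHM by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import Interaction, PhotonEvent
from .geometry import N_PIXELS, PIXEL_PITCH
from .transport import KIND_COMPTON, SiteRecord

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class DetectorModel:
    """Resolution model of one CZT module."""

    energy_anchors: tuple = ((200.0, 3.0), (450.0, 4.5), (511.0, 5.4))
    position_fwhm: float = 0.5  # mm
    pixel_pitch: float = PIXEL_PITCH
    n_pixels: int = N_PIXELS
    crystal_half: np.ndarray = field(default_factory=lambda: np.array([11.0, 11.0, 5.0]))
    #: per-pixel trigger threshold [keV]: merged deposits below it are not read
    #: out (their energy is lost), as in real pixelated CZT readouts
    site_threshold: float = 50.0

    def energy_fwhm(self, energy):
        """FWHM [keV] at ``energy`` [keV]; piecewise-linear through the anchors."""
        e = np.array([a[0] for a in self.energy_anchors])
        f = np.array([a[1] for a in self.energy_anchors])
        energy = np.asarray(energy, dtype=float)
        out = np.interp(energy, e, f)
        # linear extrapolation keeps the function monotone outside the anchors
        lo = energy < e[0]
        hi = energy > e[-1]
        out = np.where(lo, f[0] + (energy - e[0]) * (f[1] - f[0]) / (e[1] - e[0]), out)
        out = np.where(hi, f[-1] + (energy - e[-1]) * (f[-1] - f[-2]) / (e[-1] - e[-2]), out)
        out = np.maximum(out, 0.0)
        return out if out.ndim else float(out)

    @classmethod
    def ideal(cls) -> "DetectorModel":
        """Noise-free detector: zero energy and position blur (merging kept)."""
        return cls(energy_anchors=((200.0, 0.0), (450.0, 0.0), (511.0, 0.0)),
                   position_fwhm=0.0, site_threshold=0.0)

    def pixel_index(self, local_xy):
        """Anode pixel (u, v) for module-frame lateral coordinates (N, 2)."""
        half = self.n_pixels * self.pixel_pitch / 2.0
        idx = np.floor((np.asarray(local_xy) + half) / self.pixel_pitch).astype(int)
        return np.clip(idx, 0, self.n_pixels - 1)


def merge_sites_arrays(group_key, positions, energies, first_flag=None):
    """Merge flat site arrays by ``group_key`` rows (lexicographic groups).

    Returns (merged positions, merged energies, inverse group ids) where
    merging uses the energy-weighted centroid and summed energy.  Groups are
    ordered by first appearance so chronological ordering is preserved.
    """
    key = np.ascontiguousarray(group_key)
    _, first_idx, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    # re-order groups by first appearance (np.unique sorts lexicographically)
    order = np.argsort(first_idx, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    inverse = rank[inverse]
    n_groups = order.size
    e_sum = np.bincount(inverse, weights=energies, minlength=n_groups)
    pos = np.empty((n_groups, 3))
    for j in range(3):
        pos[:, j] = np.bincount(inverse, weights=positions[:, j] * energies,
                                minlength=n_groups) / e_sum
    return pos, e_sum, inverse


def apply_detector_model(sites, model: DetectorModel, rng, frame=None) -> PhotonEvent:
    """Observed photon event from the true sites of one photon in one crystal.

    ``frame`` optionally maps global to module-local coordinates as
    ``(rotation, centre)``; identity by default (sites already local).
    Blur FWHMs of zero reproduce the true quantities exactly.  Returns None
    when no merged site reaches the trigger threshold.
    """
    if not sites:
        raise ValueError("no interaction sites")
    pos = np.array([s.position for s in sites], dtype=float)
    energies = np.array([s.energy for s in sites], dtype=float)
    module_id = sites[0].module_id
    if frame is not None:
        R, c = frame
        local = (pos - np.asarray(c)) @ np.asarray(R)
    else:
        local = pos
    uv = model.pixel_index(local[:, :2])
    key = np.column_stack([uv[:, 0], uv[:, 1]])
    mpos, men, _ = merge_sites_arrays(key, local, energies)
    keep = men >= model.site_threshold
    if not keep.any():
        return None  # no merged site crosses the trigger threshold
    mpos, men = mpos[keep], men[keep]

    sigma_e = np.asarray(model.energy_fwhm(men)) * FWHM_TO_SIGMA
    sigma_x = model.position_fwhm * FWHM_TO_SIGMA
    obs_E = men + rng.standard_normal(men.size) * sigma_e
    obs_pos = mpos + rng.standard_normal(mpos.shape) * sigma_x
    if frame is not None:
        R, c = frame
        obs_pos = obs_pos @ np.asarray(R).T + np.asarray(c)
    observed = [
        Interaction(position=obs_pos[i], energy=float(max(obs_E[i], 1e-6)),
                    kind="observed", module_id=module_id, is_true=False)
        for i in range(men.size)
    ]
    return PhotonEvent(sites=observed)


def process_sites_batch(rec: SiteRecord, boxes, model: DetectorModel, rng):
    """Vectorised merge + blur of a transport batch.

    Returns a dict of flat arrays over merged observed sites:
    ``photon`` (history index), ``module``, ``pos`` (global, blurred),
    ``true_pos`` (merged, unblurred), ``energy`` (blurred), ``true_energy``,
    ``is_first`` (contains the chronologically first true site of its photon,
    evaluated per (photon, module) group), ``first_kind`` (interaction kind of
    that first true site).
    """
    if len(rec) == 0:
        return {k: np.zeros(0) for k in
                ("photon", "module", "energy", "true_energy", "is_first")} | {
                    "pos": np.zeros((0, 3)), "true_pos": np.zeros((0, 3))}
    local = np.einsum("nk,nkj->nj", rec.position - boxes.centres[rec.module],
                      boxes.rotations[rec.module])
    uv = model.pixel_index(local[:, :2])
    key = np.column_stack([rec.photon, rec.module, uv[:, 0], uv[:, 1]])
    mpos_local, men, inverse = merge_sites_arrays(key, local, rec.energy)

    n_groups = men.size
    photon = np.zeros(n_groups, dtype=int)
    module = np.zeros(n_groups, dtype=int)
    photon[inverse] = rec.photon
    module[inverse] = rec.module
    # chronological rank: earliest constituent row of each group
    # (rec is sorted by photon then step)
    group_first_row = np.full(n_groups, len(rec), dtype=int)
    np.minimum.at(group_first_row, inverse, np.arange(len(rec)))
    group_kind = rec.kind[group_first_row]

    # trigger threshold: sub-threshold merged deposits are not read out
    keep = men >= model.site_threshold
    mpos_local, men = mpos_local[keep], men[keep]
    photon, module = photon[keep], module[keep]
    group_first_row, group_kind = group_first_row[keep], group_kind[keep]
    n_groups = men.size

    # first surviving site of each photon, in chronological order
    order = np.lexsort((group_first_row, photon))
    sorted_photon = photon[order]
    head = np.r_[True, sorted_photon[1:] != sorted_photon[:-1]] if n_groups else \
        np.zeros(0, bool)
    is_first = np.zeros(n_groups, dtype=bool)
    is_first[order[head]] = True
    first_kind = np.where(is_first, group_kind, -1).astype(np.int8)

    sigma_e = np.asarray(model.energy_fwhm(men)) * FWHM_TO_SIGMA
    sigma_x = model.position_fwhm * FWHM_TO_SIGMA
    obs_E = men + rng.standard_normal(n_groups) * sigma_e
    obs_local = mpos_local + rng.standard_normal((n_groups, 3)) * sigma_x
    # back to global
    pos = np.einsum("nj,nkj->nk", obs_local, boxes.rotations[module]) + boxes.centres[module]
    true_pos = np.einsum("nj,nkj->nk", mpos_local, boxes.rotations[module]) + boxes.centres[module]
    return {
        "photon": photon, "module": module, "pos": pos, "true_pos": true_pos,
        "energy": np.maximum(obs_E, 1e-6), "true_energy": men,
        "is_first": is_first, "first_kind": first_kind, "kind": group_kind,
        "chrono_row": group_first_row,
        "local": obs_local, "true_local": mpos_local,
    }
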