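"""Vectorised Monte-Carlo photon transport through sets of CZT boxes.

Free paths are sampled from the exponential law with the transport attenuation
coefficient (photoelectric + incoherent; coherent scattering is excluded — it
deposits no energy and contributes ~2% of the total at 511 keV).  Interaction
types are chosen by cross-section ratio; Compton chains are followed until
photoelectric absorption, escape, or the photon energy falls below the 50-keV
table floor (at which point the remainder is deposited on the spot — the mean
free path there is well below the position resolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import TRANSPORT_ENERGY_CUTOFF
from .kinematics import sample_compton
from .materials import AttenuationTable, default_table

KIND_COMPTON = 0
KIND_PHOTOELECTRIC = 1

_EPS = 1e-9
_SKIN = 1e-6  # mm advanced past a boundary when leaving a box


@dataclass
class BoxSet:
    """Oriented boxes: x_global = R @ x_local + centre, |x_local| <= half."""

    rotations: np.ndarray  # (M, 3, 3)
    centres: np.ndarray    # (M, 3)
    halves: np.ndarray     # (M, 3)

    @classmethod
    def from_geometry(cls, geometry) -> "BoxSet":
        from .geometry import MODULE_HALF
        Rs, ts = geometry.module_transforms()
        halves = np.broadcast_to(MODULE_HALF, (Rs.shape[0], 3)).copy()
        return cls(Rs, ts, halves)

    @classmethod
    def single_slab(cls, half, centre=(0.0, 0.0, 0.0)) -> "BoxSet":
        return cls(np.eye(3)[None], np.asarray(centre, float)[None],
                   np.asarray(half, float)[None])


@dataclass
class SiteRecord:
    """Flat arrays of true interaction sites from one transport batch."""

    photon: np.ndarray    # history index, sorted; sites of one history contiguous
    position: np.ndarray  # (n, 3) global mm
    energy: np.ndarray    # keV deposited
    kind: np.ndarray      # KIND_COMPTON / KIND_PHOTOELECTRIC
    module: np.ndarray    # box index

    def __len__(self):
        return self.photon.size


def ray_box_entries(origins, directions, boxes: BoxSet):
    """Entry/exit distances (N, M) of rays into each box (inf when missed)."""
    # into box frames: x_local = R^T (x - c)
    o = np.einsum("nk,mkj->nmj", origins, boxes.rotations) - np.einsum(
        "mk,mkj->mj", boxes.centres, boxes.rotations)[None]
    d = np.einsum("nk,mkj->nmj", directions, boxes.rotations)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-boxes.halves[None] - o) / d
        t2 = (boxes.halves[None] - o) / d
    lo = np.minimum(t1, t2)
    hi = np.maximum(t1, t2)
    # handle rays parallel to an axis: inside -> (-inf, inf), outside -> miss
    par = np.abs(d) < _EPS
    inside = np.abs(o) <= boxes.halves[None]
    lo = np.where(par, np.where(inside, -np.inf, np.inf), lo)
    hi = np.where(par, np.where(inside, np.inf, -np.inf), hi)
    tin = lo.max(axis=2)
    tout = hi.min(axis=2)
    miss = tout <= np.maximum(tin, 0.0) + _EPS
    tin = np.where(miss, np.inf, tin)
    tout = np.where(miss, np.inf, tout)
    return tin, tout


def transport_batch(boxes: BoxSet, origins, directions, energies, rng,
                    doppler: bool = True, table: AttenuationTable | None = None,
                    max_steps: int = 60) -> SiteRecord:
    """Transport ``N`` photons; returns all true interaction sites."""
    table = table or default_table()
    pos = np.array(origins, dtype=float, copy=True).reshape(-1, 3)
    dirs = np.array(directions, dtype=float, copy=True).reshape(-1, 3)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    E = np.broadcast_to(np.asarray(energies, float), (pos.shape[0],)).copy()
    n = pos.shape[0]
    alive = np.ones(n, dtype=bool)
    idx_all = np.arange(n)

    rec_photon, rec_pos, rec_E, rec_kind, rec_mod, rec_step = [], [], [], [], [], []

    for step in range(max_steps):
        if not alive.any():
            break
        ai = idx_all[alive]
        tin, tout = ray_box_entries(pos[ai], dirs[ai], boxes)
        entry = np.maximum(tin, 0.0)
        box = np.argmin(entry, axis=1)
        sel = np.arange(ai.size)
        e_sel = entry[sel, box]
        t_out = tout[sel, box]
        hit = np.isfinite(e_sel)
        # photons that intersect nothing escape
        alive[ai[~hit]] = False
        if not hit.any():
            break
        ai = ai[hit]
        box = box[hit]
        e_sel = e_sel[hit]
        chord = t_out[hit] - e_sel

        mu = table.mu_transport(E[ai]) / 10.0  # 1/cm -> 1/mm
        s = rng.exponential(1.0, size=ai.size) / mu
        interact = s < chord

        # pass through: advance just past the exit face and retry
        out = ai[~interact]
        pos[out] += dirs[out] * (t_out[hit][~interact] + _SKIN)[:, None]

        ii = ai[interact]
        if ii.size:
            ipos = pos[ii] + dirs[ii] * (e_sel[interact] + s[interact])[:, None]
            pos[ii] = ipos
            is_compton = rng.random(ii.size) < table.compton_fraction(E[ii])

            # photoelectric: deposit everything
            pe = ii[~is_compton]
            if pe.size:
                rec_photon.append(pe)
                rec_pos.append(ipos[~is_compton])
                rec_E.append(E[pe].copy())
                rec_kind.append(np.full(pe.size, KIND_PHOTOELECTRIC, dtype=np.int8))
                rec_mod.append(box[interact][~is_compton])
                rec_step.append(np.full(pe.size, step, dtype=np.int32))
                alive[pe] = False

            co = ii[is_compton]
            if co.size:
                co_box = box[interact][is_compton]
                theta, E1 = sample_compton(E[co], rng, doppler=doppler,
                                           size=co.shape)
                rec_photon.append(co)
                rec_pos.append(ipos[is_compton])
                rec_E.append(E1.copy())
                rec_kind.append(np.full(co.size, KIND_COMPTON, dtype=np.int8))
                rec_mod.append(co_box)
                rec_step.append(np.full(co.size, step, dtype=np.int32))
                E[co] -= E1
                dirs[co] = _scatter_directions(dirs[co], theta, rng)
                # sub-threshold remainder is absorbed locally
                low_mask = E[co] < TRANSPORT_ENERGY_CUTOFF
                low = co[low_mask]
                if low.size:
                    rec_photon.append(low)
                    rec_pos.append(pos[low].copy())
                    rec_E.append(E[low].copy())
                    rec_kind.append(np.full(low.size, KIND_PHOTOELECTRIC, dtype=np.int8))
                    rec_mod.append(co_box[low_mask])
                    rec_step.append(np.full(low.size, step, dtype=np.int32))
                    alive[low] = False

    if not rec_photon:
        z3 = np.zeros((0, 3))
        return SiteRecord(np.zeros(0, int), z3, np.zeros(0), np.zeros(0, np.int8),
                          np.zeros(0, int))
    photon = np.concatenate(rec_photon)
    position = np.concatenate(rec_pos)
    energy = np.concatenate(rec_E)
    kind = np.concatenate(rec_kind)
    module = np.concatenate([np.asarray(m, dtype=int) for m in rec_mod])
    step_no = np.concatenate(rec_step)
    order = np.lexsort((step_no, photon))
    return SiteRecord(photon[order], position[order], energy[order], kind[order],
                      module[order])


def _scatter_directions(dirs, theta, rng):
    """Rotate unit vectors by polar angle theta with uniform azimuth."""
    a = np.where(np.abs(dirs[:, 0:1]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    e1 = np.cross(dirs, a)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(dirs, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=dirs.shape[0])
    st = np.sin(theta)[:, None]
    new = (np.cos(theta)[:, None] * dirs
           + st * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2))
    return new / np.linalg.norm(new, axis=1, keepdims=True)


def isotropic_directions(rng, size):
    """Uniform random unit vectors, shape (size, 3)."""
    z = rng.uniform(-1.0, 1.0, size)
    phi = rng.uniform(0.0, 2.0 * np.pi, size)
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def transport_photon(geometry, origin, direction, E0, rng, doppler=True):
    """Transport one photon through the system; list of true interactions.

    Convenience wrapper over :func:`transport_batch` for a single history;
    returns ``[]`` for a miss or escape without interaction.
    """
    from .events import Interaction
    boxes = geometry if isinstance(geometry, BoxSet) else BoxSet.from_geometry(geometry)
    rec = transport_batch(boxes, np.asarray(origin, float)[None],
                          np.asarray(direction, float)[None],
                          np.array([float(E0)]), rng, doppler=doppler)
    return [
        Interaction(position=rec.position[i], energy=float(rec.energy[i]),
                    kind="compton" if rec.kind[i] == KIND_COMPTON else "photoelectric",
                    time=0.0, module_id=int(rec.module[i]), is_true=True)
        for i in range(len(rec))
    ]
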