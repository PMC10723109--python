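"""Batch convex-polygon clipping against axis-aligned rectangles.

Used for the back-projected overlap area S' in the conditional coincidence
probability: the projected detector-voxel slice (a convex quadrilateral in
the target slice plane) is clipped against the target voxel's central slice.
Vectorised Sutherland-Hodgman: every clip stage emits up to two vertices per
input edge into fixed slots, then compacts them with a stable argsort, so no
per-row Python work is needed.  Degenerate rows pad with their first vertex,
which contributes nothing to the shoelace area.
"""

from __future__ import annotations

import numpy as np


try:
    from numba import njit

    @njit(cache=True)
    def _clip_areas_serial(quads, half_u, half_v):  # pragma: no cover - jit
        n = quads.shape[0]
        out = np.zeros(n)
        buf_a = np.empty((16, 2))
        buf_b = np.empty((16, 2))
        for row in range(n):
            cur = buf_a
            nxt = buf_b
            nv = 4
            for k in range(4):
                cur[k, 0] = quads[row, k, 0]
                cur[k, 1] = quads[row, k, 1]
            for plane in range(4):
                axis = 0 if plane < 2 else 1
                sign = 1.0 if plane % 2 == 0 else -1.0
                bound = half_u if axis == 0 else half_v
                m = 0
                for i in range(nv):
                    j = (i + 1) % nv
                    di = sign * cur[i, axis] - bound
                    dj = sign * cur[j, axis] - bound
                    if di <= 0.0:
                        nxt[m, 0] = cur[i, 0]
                        nxt[m, 1] = cur[i, 1]
                        m += 1
                    if (di <= 0.0) != (dj <= 0.0):
                        t = di / (di - dj)
                        nxt[m, 0] = cur[i, 0] + t * (cur[j, 0] - cur[i, 0])
                        nxt[m, 1] = cur[i, 1] + t * (cur[j, 1] - cur[i, 1])
                        m += 1
                tmp = cur
                cur = nxt
                nxt = tmp
                nv = m
                if nv == 0:
                    break
            if nv >= 3:
                area = 0.0
                for i in range(nv):
                    j = (i + 1) % nv
                    area += cur[i, 0] * cur[j, 1] - cur[j, 0] * cur[i, 1]
                out[row] = abs(area) / 2.0
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba always present in practice
    _HAVE_NUMBA = False


def clip_quads_to_rect(quads: np.ndarray, half_u: float, half_v: float) -> np.ndarray:
    """Area of each convex quad clipped to the rectangle [-hu, hu] x [-hv, hv].

    ``quads``: (N, 4, 2) vertices in slice-plane coordinates (any winding).
    Returns the clipped areas, shape (N,).
    """
    verts = np.ascontiguousarray(np.asarray(quads, float))
    if _HAVE_NUMBA:
        return _clip_areas_serial(verts, float(half_u), float(half_v))
    valid = np.ones(verts.shape[:2], dtype=bool)
    for axis, sign, bound in ((0, 1.0, half_u), (0, -1.0, half_u),
                              (1, 1.0, half_v), (1, -1.0, half_v)):
        verts, valid = _clip_halfplane(verts, valid, axis, sign, bound)
    return _shoelace(verts, valid)


def _clip_halfplane(verts, valid, axis, sign, bound):
    """Keep the region sign * x[axis] <= bound; fully vectorised."""
    n, v, _ = verts.shape
    d = sign * verts[:, :, axis] - bound  # <= 0 inside
    # treat invalid slots as copies of the row's cyclic successor by marking
    # them outside and dropping their emissions
    nxt = _next_valid_index(valid)
    vj = np.take_along_axis(verts, nxt[:, :, None], axis=1)
    dj = np.take_along_axis(d, nxt, axis=1)
    inside_i = (d <= 0) & valid
    inside_j = dj <= 0
    cross = valid & (inside_i != inside_j)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d / (d - dj)
    inter = verts + t[:, :, None] * (vj - verts)
    # slot layout: [v_0, x_0, v_1, x_1, ...]
    out = np.empty((n, 2 * v, 2))
    out[:, 0::2] = verts
    out[:, 1::2] = np.where(cross[:, :, None], inter, np.nan)
    ok = np.empty((n, 2 * v), dtype=bool)
    ok[:, 0::2] = inside_i
    ok[:, 1::2] = cross
    # stable compaction: valid slots first, order preserved
    order = np.argsort(~ok, axis=1, kind="stable")
    out = np.take_along_axis(out, order[:, :, None], axis=1)
    ok = np.take_along_axis(ok, order, axis=1)
    width = int(max(ok.sum(axis=1).max(initial=0), 3))
    return out[:, :width], ok[:, :width]


def _next_valid_index(valid):
    """Cyclic successor among valid slots (vectorised, few passes)."""
    n, v = valid.shape
    idx = np.arange(v)
    # positions of valid slots in order per row; successor of the k-th valid
    # slot is the (k+1 mod count)-th valid slot
    order = np.argsort(~valid, axis=1, kind="stable")  # valid slots first
    counts = valid.sum(axis=1)
    rank = np.zeros((n, v), dtype=int)
    np.put_along_axis(rank, order, np.broadcast_to(idx, (n, v)), axis=1)
    succ_rank = np.where(counts[:, None] > 0,
                         (rank + 1) % np.maximum(counts, 1)[:, None], 0)
    nxt = np.take_along_axis(order, succ_rank, axis=1)
    return np.where(valid, nxt, idx[None, :])


def _shoelace(verts, valid):
    n, v, _ = verts.shape
    counts = valid.sum(axis=1)
    # pad invalid slots with the row's first valid vertex (degenerate edges
    # add zero area); rows with < 3 vertices get zero area automatically
    first = verts[:, 0:1, :]
    pts = np.where(valid[:, :, None], verts, np.broadcast_to(first, verts.shape))
    pts = np.nan_to_num(pts)
    x = pts[:, :, 0]
    y = pts[:, :, 1]
    x2 = np.roll(x, -1, axis=1)
    y2 = np.roll(y, -1, axis=1)
    area = np.abs(np.sum(x * y2 - x2 * y, axis=1)) / 2.0
    return np.where(counts >= 3, area, 0.0)
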