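"""List-mode OS-EM reconstruction with DOI binning, plus image metrics.

The update is the classic list-mode OS-EM

    f_k <- (f_k / s_k) * sum_{j in subset} p(A_j | k) / sum_i p(A_j | i) f_i

with subsets grouped by acquisition angle and ``s_k`` the per-subset
sensitivity (optionally decay-adjusted by the subset count ratio).  The
system-matrix element p(A_j | k) is evaluated on the fly from the analytic
coincidence-response model: each event's two endpoints are quantised to
detector voxels laterally and to the configured DOI bin in depth; for a
source voxel the weight combines the first slice's solid angle and
attenuation, the back-projected slice-overlap fraction, and the second
side's attenuation/interaction term.  Voxels farther than a cutoff from the
LOR axis are treated as zero (tube of response); the overlap is averaged
over the source voxel by Gauss quadrature so the sub-voxel-width tube is
sampled smoothly.

Only near-axis-aligned geometries (the nominal four-panel setup) are
supported by the fast separable-overlap projector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.optimize import curve_fit

from .detector import FWHM_TO_SIGMA
from .geometry import MODULE_HALF, MODULES_PER_PANEL, VOXEL_PITCH, SystemGeometry
from .image import ActivityImage
from .system_model import _mu
from .transport import BoxSet

_GAUSS3 = np.array([-np.sqrt(0.6), 0.0, np.sqrt(0.6)]) / 2.0  # nodes on [-1/2, 1/2]
_GW3 = np.array([5.0, 8.0, 5.0]) / 18.0


@dataclass
class ReconstructionConfig:
    doi_bin_mm: float = 1.0          # in {1, 2.5, 5, 10}
    voxel_size: float = 0.25         # mm, isotropic
    shape: tuple = (66, 66, 80)
    centre: tuple = (0.0, 0.0, 0.0)
    iterations: int = 6
    postfilter_fwhm: float = 0.40    # mm
    positioning: str = "predicted-first-site"
    # {predicted-first-site, energy-weighted-centroid, cathode-nearest}
    tube_cutoff_voxels: float = 3.0
    sensitivity_lateral_step: int = 4
    sensitivity_D: int = 4

    def __post_init__(self):
        if not np.isclose((2 * MODULE_HALF[2]) % self.doi_bin_mm, 0.0) and \
                not np.isclose((2 * MODULE_HALF[2]) % self.doi_bin_mm, self.doi_bin_mm):
            raise ValueError("DOI bin size must divide the 10 mm thickness")


# ---------------------------------------------------------------------------
# event endpoint selection
# ---------------------------------------------------------------------------

def event_endpoints(data, geometry: SystemGeometry, config: ReconstructionConfig,
                    first_site=None):
    """Endpoint position [mm] and module id per photon row, (2N, 3) and (2N,).

    ``first_site`` optionally gives, per photon row, the site index (within
    the photon) to use as the interaction position for multi-site photons
    (e.g. the Compton-predicted first site, or the ground truth).  Without it
    the configured positioning rule applies.
    """
    counts = np.asarray(data.photons["site_count"], int)
    starts = np.asarray(data.photons["site_start"], int)
    pos = data.site_positions()
    energy = np.asarray(data.sites["energy"], float)
    modules = np.asarray(data.sites["module"], int)
    boxes = BoxSet.from_geometry(geometry)
    n = counts.size
    out = np.zeros((n, 3))
    out_mod = np.zeros(n, dtype=int)
    for r in range(n):
        s, c = starts[r], counts[r]
        if c == 1:
            out[r] = pos[s]
            out_mod[r] = modules[s]
            continue
        if first_site is not None and first_site[r] >= 0:
            k = s + int(first_site[r])
        elif config.positioning == "energy-weighted-centroid":
            w = energy[s:s + c]
            out[r] = (pos[s:s + c] * w[:, None]).sum(axis=0) / w.sum()
            out_mod[r] = modules[s + int(np.argmax(w))]
            continue
        elif config.positioning == "cathode-nearest":
            local = np.einsum("nk,kj->nj",
                              pos[s:s + c] - boxes.centres[modules[s]],
                              boxes.rotations[modules[s]])
            k = s + int(np.argmin(local[:, 2]))
        else:  # predicted-first-site without prediction: first stored site
            k = s
        out[r] = pos[k]
        out_mod[r] = modules[k]
    return out, out_mod


# ---------------------------------------------------------------------------
# system-matrix rows
# ---------------------------------------------------------------------------

def _quantise_endpoint(boxes: BoxSet, pos, module, doi_bin):
    """Snap an endpoint to its detector-voxel lateral centre and DOI-bin centre."""
    local = (pos - boxes.centres[module]) @ boxes.rotations[module]
    half = MODULE_HALF
    u = np.clip(np.floor((local[0] + 10.45) / VOXEL_PITCH), 0, 99)
    v = np.clip(np.floor((local[1] + 10.45) / VOXEL_PITCH), 0, 99)
    n_doi = int(round(2 * half[2] / doi_bin))
    w = np.clip(np.floor((local[2] + half[2]) / doi_bin), 0, n_doi - 1)
    centre_local = np.array([
        -10.45 + (u + 0.5) * VOXEL_PITCH,
        -10.45 + (v + 0.5) * VOXEL_PITCH,
        -half[2] + (w + 0.5) * doi_bin,
    ])
    return boxes.rotations[module] @ centre_local + boxes.centres[module]


def event_row(grid: ActivityImage, c1, c2, n1, n2, doi_bin, mu,
              cutoff_mm, depth1, depth2):
    """Sparse system-matrix row for one event: (voxel indices, weights).

    ``c1``/``c2``: slice centres [mm]; ``n1``/``n2``: outward depth-axis unit
    vectors of the two modules; ``depth1``/``depth2``: slice-centre depth from
    the cathode face [mm].
    """
    axis = int(np.argmax(np.abs(n1)))
    lat = [d for d in range(3) if d != axis]
    if abs(n1[axis]) < 0.99:
        raise ValueError("fast projector requires axis-aligned panels")
    w = VOXEL_PITCH
    # voxel candidates: march along the LOR through the grid
    o, sp, shape = grid.origin, grid.spacing, grid.data.shape
    d_axis = c2[axis] - c1[axis]
    if abs(d_axis) < 1.0:  # same-panel pairing: no usable LOR
        return np.zeros(0, int), np.zeros(0)
    n_ax = shape[axis]
    idx_ax = np.arange(n_ax)
    x_ax = o[axis] + (idx_ax + 0.5) * sp[axis]
    t = (x_ax - c1[axis]) / d_axis
    inside = (t > 0.0) & (t < 1.0)
    if not inside.any():
        return np.zeros(0, int), np.zeros(0)
    idx_ax = idx_ax[inside]
    t = t[inside]
    line = c1[None, :] + t[:, None] * (c2 - c1)[None, :]
    r = int(np.ceil(cutoff_mm / sp[lat[0]]))
    offs = np.arange(-r, r + 1)
    # build (n_ax, n_off, n_off) candidate lattice in the two lateral dims
    i1 = np.clip(((line[:, lat[0]] - o[lat[0]]) / sp[lat[0]] - 0.5).round().astype(int)[:, None]
                 + offs[None, :], 0, shape[lat[0]] - 1)
    i2 = np.clip(((line[:, lat[1]] - o[lat[1]]) / sp[lat[1]] - 0.5).round().astype(int)[:, None]
                 + offs[None, :], 0, shape[lat[1]] - 1)
    na, no = idx_ax.size, offs.size
    A = np.broadcast_to(idx_ax[:, None, None], (na, no, no)).ravel()
    L1 = np.broadcast_to(i1[:, :, None], (na, no, no)).ravel()
    L2 = np.broadcast_to(i2[:, None, :], (na, no, no)).ravel()
    # voxel centres
    xa = o[axis] + (A + 0.5) * sp[axis]
    x1 = o[lat[0]] + (L1 + 0.5) * sp[lat[0]]
    x2 = o[lat[1]] + (L2 + 0.5) * sp[lat[1]]

    # separable projected-overlap, quadrature-averaged over the voxel
    def overlap(xl, c1l, c2l, spl):
        acc = np.zeros_like(xl)
        m = (c2[axis] - xa) / (c1[axis] - xa)  # magnification (negative)
        for node, gw in zip(_GAUSS3, _GW3):
            s = xl + node * spl
            centre = s + (c1l - s) * m
            half_w = 0.5 * w * np.abs(m)
            lo = np.maximum(centre - half_w, c2l - 0.5 * w)
            hi = np.minimum(centre + half_w, c2l + 0.5 * w)
            acc += gw * np.clip(hi - lo, 0.0, None)
        return acc

    O1 = overlap(x1, c1[lat[0]], c2[lat[0]], sp[lat[0]])
    O2 = overlap(x2, c1[lat[1]], c2[lat[1]], sp[lat[1]])
    frac = O1 * O2 / (w * w)
    keep = frac > 0
    if not keep.any():
        return np.zeros(0, int), np.zeros(0)
    A, L1, L2 = A[keep], L1[keep], L2[keep]
    xa, x1, x2 = xa[keep], x1[keep], x2[keep]
    frac = frac[keep]

    pt = np.zeros((A.size, 3))
    pt[:, axis] = xa
    pt[:, lat[0]] = x1
    pt[:, lat[1]] = x2
    d1v = c1[None] - pt
    d2v = c2[None] - pt
    d1 = np.linalg.norm(d1v, axis=1)
    d2n = np.linalg.norm(d2v, axis=1)
    cos1 = np.abs(d1v[:, axis]) / d1
    cos2 = np.abs(d2v[:, axis]) / d2n
    p1 = (w * w) * cos1 / (4.0 * np.pi * d1**2) \
        * np.exp(-mu * depth1 / cos1) * (1.0 - np.exp(-mu * doi_bin / cos1))
    p2 = np.exp(-mu * depth2 / cos2) * (1.0 - np.exp(-mu * doi_bin / cos2))
    wgt = p1 * frac * p2
    flat = np.ravel_multi_index(
        tuple(np.stack([A, L1, L2])[np.argsort([axis, lat[0], lat[1]])]), shape)
    keep = wgt > 0
    return flat[keep], wgt[keep]


def build_system_rows(data, geometry: SystemGeometry, grid: ActivityImage,
                      config: ReconstructionConfig, first_site=None):
    """CSR matrix (events x voxels) of p(A_j | k) and the skipped-event count.

    Event endpoints of subset ``s`` are rotated back by ``-s * angle_step``
    (the object rotates on the stage; reconstruction is in the object frame).
    """
    boxes = BoxSet.from_geometry(geometry)
    mu = _mu()
    ends, mods = event_endpoints(data, geometry, config, first_site=first_site)
    n_ev = data.n_events
    subset = np.asarray(data.events["subset"], int)
    angle = float(data.header.get("angle_step_deg", 0.0) or 0.0)
    cutoff = config.tube_cutoff_voxels * config.voxel_size
    indptr = [0]
    indices, values = [], []
    skipped = 0
    for e in range(n_ev):
        ra, rb = 2 * e, 2 * e + 1
        ma, mb = mods[ra], mods[rb]
        c1 = _quantise_endpoint(boxes, ends[ra], ma, config.doi_bin_mm)
        c2 = _quantise_endpoint(boxes, ends[rb], mb, config.doi_bin_mm)
        n1 = boxes.rotations[ma][:, 2]
        n2 = boxes.rotations[mb][:, 2]
        la = (ends[ra] - boxes.centres[ma]) @ boxes.rotations[ma]
        lb = (ends[rb] - boxes.centres[mb]) @ boxes.rotations[mb]
        nd = int(round(2 * MODULE_HALF[2] / config.doi_bin_mm))
        dep1 = (np.clip(np.floor((la[2] + 5.0) / config.doi_bin_mm), 0, nd - 1)
                + 0.5) * config.doi_bin_mm - config.doi_bin_mm / 2.0
        dep2 = (np.clip(np.floor((lb[2] + 5.0) / config.doi_bin_mm), 0, nd - 1)
                + 0.5) * config.doi_bin_mm - config.doi_bin_mm / 2.0
        if angle and subset[e]:
            a = np.radians(-angle * subset[e])
            rot = np.array([[np.cos(a), -np.sin(a), 0.0],
                            [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]])
            c1 = rot @ c1
            c2 = rot @ c2
            n1 = rot @ n1
            n2 = rot @ n2
        if abs(n1[np.argmax(np.abs(n1))]) < 0.99 or \
                np.argmax(np.abs(n1)) != np.argmax(np.abs(n2)):
            skipped += 1
            indptr.append(indptr[-1])
            continue
        try:
            idx, wgt = event_row(grid, c1, c2, n1, n2, config.doi_bin_mm, mu,
                                 cutoff, dep1, dep2)
        except ValueError:
            idx, wgt = np.zeros(0, int), np.zeros(0)
        if idx.size == 0:
            skipped += 1
        indices.append(idx)
        values.append(wgt)
        indptr.append(indptr[-1] + idx.size)
    mat = sparse.csr_matrix(
        (np.concatenate(values) if values else np.zeros(0),
         np.concatenate(indices) if indices else np.zeros(0, int),
         np.array(indptr)),
        shape=(n_ev, int(np.prod(grid.data.shape))))
    return mat, skipped


# ---------------------------------------------------------------------------
# OS-EM
# ---------------------------------------------------------------------------

def decay_adjusted_sensitivity(s: np.ndarray, subset_counts) -> list:
    """Per-subset sensitivity: s scaled by N_sub / N_1 to absorb source decay."""
    subset_counts = np.asarray(subset_counts, float)
    if subset_counts[0] <= 0:
        raise ValueError("first subset has no events")
    return [s * (n / subset_counts[0]) for n in subset_counts]


def osem_reconstruct(data, geometry: SystemGeometry,
                     config: ReconstructionConfig,
                     sensitivity=None, first_site=None,
                     decay_adjust: bool = False, verbose: bool = False):
    """List-mode OS-EM; returns (list of per-iteration images, info dict).

    ``sensitivity`` may be a single array/image (used for every subset) or a
    list per subset; by default it is computed from the analytic model on the
    reconstruction grid (coarse detector sampling; see config).
    """
    from .system_model import sensitivity_on_grid

    grid = ActivityImage.empty(config.shape, config.voxel_size, config.centre)
    subset = np.asarray(data.events["subset"], int)
    subsets = np.unique(subset)
    angle = float(data.header.get("angle_step_deg", 0.0) or 0.0)

    mat, skipped = build_system_rows(data, geometry, grid, config,
                                     first_site=first_site)

    if sensitivity is None:
        sens = []
        for s in subsets:
            v = sensitivity_on_grid(geometry, grid, D=config.sensitivity_D,
                                    lateral_step=config.sensitivity_lateral_step,
                                    rotation_deg=angle * s)
            sens.append(v)
    elif isinstance(sensitivity, (list, tuple)):
        sens = [np.asarray(getattr(s, "data", s)).ravel() for s in sensitivity]
    else:
        s0 = np.asarray(getattr(sensitivity, "data", sensitivity)).ravel()
        sens = [s0 for _ in subsets]
    if decay_adjust:
        counts = [int((subset == s).sum()) for s in subsets]
        base = sens
        sens = [b * (n / counts[0]) for b, n in zip(base, counts)]

    n_vox = mat.shape[1]
    f = np.ones(n_vox)
    support = np.zeros(n_vox, dtype=bool)
    for s in sens:
        support |= s > 0
    f[~support] = 0.0

    images = []
    for it in range(config.iterations):
        for si, s in enumerate(subsets):
            rows = np.nonzero(subset == s)[0]
            A = mat[rows]
            proj = A @ f
            good = proj > 0
            ratio = np.zeros_like(proj)
            ratio[good] = 1.0 / proj[good]
            back = A.T @ ratio
            upd = np.zeros_like(f)
            m = support & (sens[si] > 0)
            upd[m] = f[m] * back[m] / sens[si][m]
            f = upd
        images.append(grid.copy_with(f.reshape(config.shape).copy()))
        if verbose:
            print(f"iteration {it + 1}: total intensity {f.sum():.6g}")
    info = {"skipped_events": skipped, "support_voxels": int(support.sum())}
    return images, info


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def gaussian_postfilter(image: ActivityImage, fwhm_mm: float) -> ActivityImage:
    """Separable Gaussian smoothing; total intensity preserved (edge-renormalised)."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return image.copy_with(image.data.copy())
    sigma = fwhm_mm * FWHM_TO_SIGMA / image.spacing
    out = ndimage.gaussian_filter(image.data, sigma=sigma, mode="constant")
    total = image.data.sum()
    if out.sum() > 0:
        out *= total / out.sum()
    return image.copy_with(out)


def profile_fwhm(profile, coords=None) -> float:
    """FWHM [same units as coords] of a single-peak 1-D profile (Gaussian fit)."""
    profile = np.asarray(profile, float)
    coords = np.arange(profile.size, dtype=float) if coords is None \
        else np.asarray(coords, float)
    if profile.max() <= 0 or np.ptp(profile) < 1e-12 * max(profile.max(), 1.0):
        raise ValueError("profile has no peak to fit")

    def gauss(x, a, mu, sig, b):
        return a * np.exp(-0.5 * ((x - mu) / sig) ** 2) + b

    i0 = int(np.argmax(profile))
    p0 = [profile.max() - profile.min(), coords[i0],
          max((coords[-1] - coords[0]) / 6.0, 1e-6), profile.min()]
    try:
        popt, _ = curve_fit(gauss, coords, profile, p0=p0, maxfev=5000)
    except RuntimeError as exc:
        raise ValueError("Gaussian fit failed") from exc
    if popt[0] <= 0:
        raise ValueError("profile has no positive peak")
    return float(abs(popt[2]) / FWHM_TO_SIGMA)


def peak_to_valley(profile, peak_indices, valley_index) -> float:
    """Lower-peak height over valley height; inf when the valley is zero."""
    profile = np.asarray(profile, float)
    peaks = [profile[i] for i in peak_indices]
    valley = profile[valley_index]
    if valley <= 0:
        return np.inf
    return float(min(peaks) / valley)


def normalized_sd(image: ActivityImage, rois) -> float:
    """Activity-weighted sum of per-ROI SD/mean over the given voxel-index ROIs.

    Each ROI is a tuple/list of voxel-index arrays (as accepted by ndarray
    fancy indexing) or a boolean mask.
    """
    vals = []
    means = []
    for roi in rois:
        v = image.data[roi]
        if v.size == 0:
            raise ValueError("empty ROI")
        m = v.mean()
        if m == 0:
            raise ValueError("ROI has zero mean activity")
        vals.append(v.std() / m)
        means.append(m)
    means = np.asarray(means)
    return float(np.sum(np.asarray(vals) * means / means.sum()))
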