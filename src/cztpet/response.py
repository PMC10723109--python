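"""The near-field Compton response matrix F over (E1_obs, theta_obs, d2_obs).

F is built from pencil-beam histories in an idealised 4 x 4 x 1 cm CZT slab:
only histories with a Compton scatter followed by photoelectric absorption
and full energy deposition are kept.  True positions and energies are blurred
by the detector resolution model, then the *observed* first-interaction
energy (at the true first site), the *observed* geometric scattering angle
(between the beam axis and the vector joining the blurred sites) and the
*observed* inter-site distance are histogrammed.  No pixel merging is applied
in the slab so that F covers small inter-site distances; the event selector
downstream applies the pixel-level acceptance.

After normalisation ``F.prob`` sums to one over all detected two-site events;
the last d2 bin is an overflow bin (included in the normalisation, excluded
from angular-uncertainty fits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detector import FWHM_TO_SIGMA, DetectorModel
from .kinematics import kinematic_angle, max_deposit
from .materials import default_table
from .transport import KIND_COMPTON, KIND_PHOTOELECTRIC, BoxSet, transport_batch

SLAB_HALF = np.array([20.0, 20.0, 5.0])  # mm: the 4 x 4 x 1 cm slab


@dataclass
class ComptonResponseMatrix:
    counts: np.ndarray  # (n_E1, n_theta, n_d2), raw event counts
    de: float           # keV
    dtheta: float       # degrees
    dd2: float          # mm
    E0: float
    d2_max: float       # finite range; the last bin collects d2 > d2_max
    n_events: int
    blur: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def prob(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    # ---- binning -----------------------------------------------------
    def e1_bin(self, E1):
        idx = np.floor(np.asarray(E1, float) / self.de).astype(int)
        return np.clip(idx, 0, self.counts.shape[0] - 1)

    def theta_bin(self, theta_deg):
        idx = np.floor(np.asarray(theta_deg, float) / self.dtheta).astype(int)
        return np.clip(idx, 0, self.counts.shape[1] - 1)

    def d2_bin(self, d2):
        idx = np.floor(np.asarray(d2, float) / self.dd2).astype(int)
        return np.clip(idx, 0, self.counts.shape[2] - 1)

    def theta_centres(self) -> np.ndarray:
        return (np.arange(self.counts.shape[1]) + 0.5) * self.dtheta

    def e1_centres(self) -> np.ndarray:
        return (np.arange(self.counts.shape[0]) + 0.5) * self.de

    def d2_centres(self) -> np.ndarray:
        return (np.arange(self.counts.shape[2]) + 0.5) * self.dd2

    # ---- slice statistics used by the rejection logic ----------------
    def slice_max(self) -> np.ndarray:
        """max over theta per (E1, d2) slice, shape (n_E1, n_d2)."""
        return self.counts.max(axis=1)

    def slice_sum(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_probability(self, i, j, k):
        """F(i, j, k) normalised by the slice maximum over the angle axis."""
        m = self.slice_max()[i, k]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts[i, j, k] / m
        return np.where(m > 0, out, 0.0)

    def rebin(self, fe: int = 2, ft: int = 2, fd: int = 2) -> "ComptonResponseMatrix":
        """Coarsen the binning by integer factors (energy, angle, distance).

        Groups of adjacent bins are summed; the d2 overflow bin is kept as
        its own final bin.  Useful when the per-cell occupancy is too low for
        stable slice-relative thresholds (empty cells make the sequencing
        screen reject true events for lack of statistics, an artefact rather
        than physics).
        """
        c = self.counts
        ne = (c.shape[0] + fe - 1) // fe
        nt = (c.shape[1] + ft - 1) // ft
        nd_fin = c.shape[2] - 1  # finite d2 bins
        ndc = (nd_fin + fd - 1) // fd
        out = np.zeros((ne, nt, ndc + 1))
        pe = np.pad(c, ((0, ne * fe - c.shape[0]), (0, nt * ft - c.shape[1]),
                        (0, 0)))
        fin = np.pad(pe[:, :, :nd_fin],
                     ((0, 0), (0, 0), (0, ndc * fd - nd_fin)))
        out[:, :, :ndc] = fin.reshape(ne, fe, nt, ft, ndc, fd).sum(axis=(1, 3, 5))
        out[:, :, ndc] = pe.reshape(ne, fe, nt, ft, -1)[..., -1].sum(axis=(1, 3))
        return ComptonResponseMatrix(
            counts=out, de=self.de * fe, dtheta=self.dtheta * ft,
            dd2=self.dd2 * fd, E0=self.E0, d2_max=self.d2_max,
            n_events=self.n_events, blur=dict(self.blur), seed=self.seed)

    # ---- persistence -------------------------------------------------
    def save(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as fh:
            fh.create_dataset("counts", data=self.counts, compression="gzip")
            fh.attrs["format"] = "cztpet-response-1"
            for k in ("de", "dtheta", "dd2", "E0", "d2_max", "n_events"):
                fh.attrs[k] = getattr(self, k)
            fh.attrs["seed"] = -1 if self.seed is None else self.seed
            for k, v in self.blur.items():
                fh.attrs[f"blur_{k}"] = v

    @classmethod
    def load(cls, path) -> "ComptonResponseMatrix":
        import h5py
        with h5py.File(path, "r") as fh:
            if fh.attrs.get("format") != "cztpet-response-1":
                raise ValueError("not a response-matrix file")
            blur = {k[5:]: fh.attrs[k] for k in fh.attrs if k.startswith("blur_")}
            seed = int(fh.attrs["seed"])
            return cls(counts=fh["counts"][()],
                       de=float(fh.attrs["de"]), dtheta=float(fh.attrs["dtheta"]),
                       dd2=float(fh.attrs["dd2"]), E0=float(fh.attrs["E0"]),
                       d2_max=float(fh.attrs["d2_max"]),
                       n_events=int(fh.attrs["n_events"]), blur=blur,
                       seed=None if seed < 0 else seed)


def build_response_matrix(n_histories: int, E0: float = 511.0,
                          model: DetectorModel | None = None,
                          rng=None, doppler: bool = True,
                          de: float = 1.0, dtheta: float = 1.0,
                          dd2: float = 0.5, d2_max: float = 20.0,
                          batch: int = 2_000_000,
                          target_events: int | None = None) -> ComptonResponseMatrix:
    """Build F from pencil-beam photons at ``E0`` [keV].

    ``n_histories`` counts incident photons; with ``target_events`` set, the
    build continues until that many retained (two-interaction, full-energy)
    events have been accumulated instead.
    """
    if target_events is None and n_histories < 1e5:
        raise ValueError("need at least 1e5 histories for a usable matrix")
    model = model or DetectorModel()
    rng = rng if rng is not None else np.random.default_rng()
    slab = BoxSet.single_slab(SLAB_HALF, centre=(0.0, 0.0, SLAB_HALF[2]))

    n_e = int(np.ceil(max_deposit(E0) / de)) + 1
    n_t = int(np.ceil(180.0 / dtheta))
    n_d = int(np.ceil(d2_max / dd2)) + 1  # + overflow
    counts = np.zeros((n_e, n_t, n_d))
    total = 0

    sigma_x = model.position_fwhm * FWHM_TO_SIGMA
    done = 0
    while (total < target_events) if target_events else (done < n_histories):
        n = int(batch if target_events else min(batch, n_histories - done))
        done += n
        orig = np.tile([0.0, 0.0, -50.0], (n, 1))
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
        rec = transport_batch(slab, orig, dirs, E0, rng, doppler=doppler)
        if len(rec) == 0:
            continue
        # exactly two sites: Compton then photoelectric, full energy
        n_sites = np.bincount(rec.photon, minlength=n)
        first_row = np.r_[True, rec.photon[1:] != rec.photon[:-1]]
        rows = np.nonzero(first_row)[0]
        two = rows[n_sites[rec.photon[rows]] == 2]
        ok = (rec.kind[two] == KIND_COMPTON) & (rec.kind[two + 1] == KIND_PHOTOELECTRIC)
        two = two[ok]
        E1t, E2t = rec.energy[two], rec.energy[two + 1]
        full = np.abs(E1t + E2t - E0) < 1e-6
        seen = (E1t >= model.site_threshold) & (E2t >= model.site_threshold)
        two = two[full & seen]
        if two.size == 0:
            continue
        r1 = rec.position[two] + rng.standard_normal((two.size, 3)) * sigma_x
        r2 = rec.position[two + 1] + rng.standard_normal((two.size, 3)) * sigma_x
        e1 = rec.energy[two] + rng.standard_normal(two.size) * \
            np.asarray(model.energy_fwhm(rec.energy[two])) * FWHM_TO_SIGMA
        dvec = r2 - r1
        d2 = np.linalg.norm(dvec, axis=1)
        with np.errstate(invalid="ignore"):
            theta = np.degrees(np.arccos(np.clip(dvec[:, 2] / d2, -1.0, 1.0)))
        dummy = ComptonResponseMatrix(counts, de, dtheta, dd2, E0, d2_max, 0)
        i = dummy.e1_bin(np.clip(e1, 0.0, None))
        j = dummy.theta_bin(theta)
        k = dummy.d2_bin(d2)
        np.add.at(counts, (i, j, k), 1.0)
        total += two.size

    if total == 0:
        raise ValueError("no surviving two-interaction full-energy events")
    return ComptonResponseMatrix(
        counts=counts, de=de, dtheta=dtheta, dd2=dd2, E0=E0, d2_max=d2_max,
        n_events=total,
        blur={"position_fwhm": model.position_fwhm,
              "energy_fwhm_511": float(model.energy_fwhm(511.0)),
              "doppler": bool(doppler),
              "site_threshold": model.site_threshold})


def compton_event_probability(d1_mm: float, volume_mm3: float,
                              obs_bins: tuple, F: ComptonResponseMatrix,
                              czt_path_mm: float = 0.0) -> float:
    """p = p' * p1 * p2 for one observed Compton event.

    ``p'`` is the survival probability over ``czt_path_mm`` of CZT upstream of
    the element, ``p1 = n0 sigma V / (4 pi d1^2)`` the Compton-interaction
    probability of the element (volume in mm^3, distance in mm), and ``p2``
    the response-matrix mass at the observation's (E1, theta, d2) bins.
    """
    cs = default_table().cross_sections(F.E0)
    mu_t = cs.transport_total / 10.0  # 1/mm
    mu_c = cs.incoherent / 10.0
    p_prime = np.exp(-mu_t * czt_path_mm)
    p1 = mu_c * volume_mm3 / (4.0 * np.pi * d1_mm**2)
    i, j, k = obs_bins
    p2 = F.prob[i, j, k]
    return float(p_prime * p1 * p2)


def marginalize_d2(F: ComptonResponseMatrix) -> ComptonResponseMatrix:
    """Conventional response: sum F over the d2 axis (single d2 bin)."""
    counts = F.counts.sum(axis=2, keepdims=True)
    return ComptonResponseMatrix(
        counts=counts, de=F.de, dtheta=F.dtheta, dd2=np.inf, E0=F.E0,
        d2_max=np.inf, n_events=F.n_events, blur=dict(F.blur), seed=F.seed)


def angular_uncertainty_map(F: ComptonResponseMatrix,
                            theta_group_deg: float = 10.0,
                            min_events: int = 50,
                            offset_range_deg: float = 45.0):
    """FWHM of the observed-angle spread vs (kinematic angle, d2).

    For every (E1, d2) slice the angle distribution is re-centred on the
    kinematic angle implied by the E1 bin centre, accumulated into groups of
    kinematic angle, and fitted with a Gaussian; cells with fewer than
    ``min_events`` events are flagged invalid (NaN).  Returns
    ``(theta_group_centres, d2_centres, fwhm[groups, d2], valid)``;
    the d2 overflow bin is excluded.
    """
    from scipy.optimize import curve_fit

    theta_kin = kinematic_angle(F.e1_centres(), F.E0)
    n_groups = int(np.ceil(180.0 / theta_group_deg))
    n_off = 2 * int(np.ceil(offset_range_deg / F.dtheta)) + 1
    off0 = n_off // 2
    # drop the d2 overflow bin (absent in a d2-marginalised matrix)
    n_d = max(F.counts.shape[2] - 1, 1) if np.isfinite(F.d2_max) \
        else F.counts.shape[2]
    hist = np.zeros((n_groups, n_off, n_d))

    valid_i = np.nonzero(np.isfinite(theta_kin))[0]
    g_of_i = np.clip((theta_kin[valid_i] / theta_group_deg).astype(int), 0, n_groups - 1)
    theta_c = F.theta_centres()
    for ii, gg in zip(valid_i, g_of_i):
        off = np.round((theta_c - theta_kin[ii]) / F.dtheta).astype(int) + off0
        ok = (off >= 0) & (off < n_off)
        np.add.at(hist[gg], off[ok], F.counts[ii, ok, :n_d])

    x = (np.arange(n_off) - off0) * F.dtheta
    fwhm = np.full((n_groups, n_d), np.nan)
    valid = np.zeros((n_groups, n_d), dtype=bool)

    def gauss(t, a, mu, sig):
        return a * np.exp(-0.5 * ((t - mu) / sig) ** 2)

    for g in range(n_groups):
        for k in range(n_d):
            y = hist[g, :, k]
            n = y.sum()
            if n < min_events:
                continue
            mu0 = float((x * y).sum() / n)
            sig0 = float(np.sqrt(((x - mu0) ** 2 * y).sum() / n)) or F.dtheta
            try:
                popt, _ = curve_fit(gauss, x, y, p0=[y.max(), mu0, sig0],
                                    maxfev=2000)
                fwhm[g, k] = abs(popt[2]) / FWHM_TO_SIGMA
                valid[g, k] = True
            except Exception:
                pass
    groups = (np.arange(n_groups) + 0.5) * theta_group_deg
    return groups, F.d2_centres()[:n_d], fwhm, valid
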