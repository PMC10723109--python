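"""Compton kinematics, Klein-Nishina sampling, and Doppler broadening.

The scattered-photon energy at angle ``theta`` for an incident energy ``E0``
follows the free-electron Compton relation

    E' = E0 / (1 + (E0 / m_e c^2) (1 - cos theta))

and the deposited (recoil-electron) energy is ``E1 = E0 - E'``.  Doppler
broadening — the smearing of ``E1`` at fixed ``theta`` by the momentum of the
bound target electron — is modelled in the impulse approximation with
hydrogenic shell momentum profiles (see :func:`sample_doppler_shift`).
"""

from __future__ import annotations

import numpy as np

from .constants import ALPHA_FS, ATOMIC_NUMBER, CZT_STOICHIOMETRY, MEC2, R_E_CM


def compton_scatter(E0, theta):
    """Scattered-photon energy [keV] for incident ``E0`` [keV] at ``theta`` [rad].

    Raises ``ValueError`` outside ``E0 > 0`` or ``theta`` outside [0, pi].
    """
    E0 = np.asarray(E0, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(E0 <= 0):
        raise ValueError("incident energy must be positive")
    if np.any((theta < 0) | (theta > np.pi + 1e-12)):
        raise ValueError("scattering angle must lie in [0, pi]")
    out = E0 / (1.0 + (E0 / MEC2) * (1.0 - np.cos(theta)))
    return out if out.ndim else float(out)


def max_deposit(E0):
    """Compton-edge energy: the largest kinematically allowed deposit [keV]."""
    E0 = np.asarray(E0, dtype=float)
    out = E0 * 2.0 * E0 / (MEC2 + 2.0 * E0)
    return out if out.ndim else float(out)


def kinematic_angle(E1, E0, degrees=True):
    """Scattering angle implied by a first-interaction deposit ``E1`` at ``E0``.

    Inverts the Compton relation: ``cos theta = 1 - m_e c^2 (1/(E0-E1) - 1/E0)``.
    Kinematically forbidden deposits (``E1 <= 0`` or beyond the Compton edge)
    yield NaN so callers can flag the event instead of crashing on arrays.
    """
    E1 = np.asarray(E1, dtype=float)
    scalar = E1.ndim == 0
    E1 = np.atleast_1d(E1)
    Ep = E0 - E1
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_t = 1.0 - MEC2 * (1.0 / Ep - 1.0 / E0)
    bad = (E1 <= 0) | (E1 >= E0) | (cos_t < -1.0 - 1e-9) | (cos_t > 1.0 + 1e-9)
    cos_t = np.where(bad, np.nan, np.clip(cos_t, -1.0, 1.0))
    theta = np.arccos(cos_t)
    if degrees:
        theta = np.degrees(theta)
    return float(theta[0]) if scalar else theta


def klein_nishina_dsigma_dtheta(E0, theta):
    """Unnormalised Klein-Nishina density over theta (includes sin(theta) Jacobian)."""
    k = E0 / MEC2
    ct = np.cos(theta)
    r = 1.0 / (1.0 + k * (1.0 - ct))  # E'/E0
    kn = r**2 * (r + 1.0 / r - 1.0 + ct**2)
    return kn * np.sin(theta)


def klein_nishina_total(E0):
    """Total Klein-Nishina cross section per electron [cm^2] at ``E0`` [keV]."""
    k = np.asarray(E0, dtype=float) / MEC2
    t1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - np.log(1.0 + 2.0 * k) / k)
    t2 = np.log(1.0 + 2.0 * k) / (2.0 * k)
    t3 = (1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    out = 2.0 * np.pi * R_E_CM**2 * (t1 + t2 - t3)
    return out if out.ndim else float(out)


def sample_klein_nishina(E0, rng, size=None):
    """Sample scattering angles theta [rad] from the Klein-Nishina density.

    Uses Kahn's composition-rejection method, vectorised; works for scalar or
    per-photon ``E0``.
    """
    E0 = np.asarray(E0, dtype=float)
    if size is None:
        size = E0.shape if E0.ndim else 1
    alpha = np.broadcast_to(E0 / MEC2, size).copy().ravel()
    n = alpha.size
    x = np.empty(n)  # x = E0/E'
    todo = np.ones(n, dtype=bool)
    while todo.any():
        idx = np.nonzero(todo)[0]
        a = alpha[idx]
        r1, r2, r3 = rng.random((3, idx.size))
        branch1 = r1 <= (1.0 + 2.0 * a) / (9.0 + 2.0 * a)
        xx = np.where(branch1, 1.0 + 2.0 * a * r2, (1.0 + 2.0 * a) / (1.0 + 2.0 * a * r2))
        cos_t = 1.0 - (xx - 1.0) / a
        acc1 = r3 <= 4.0 * (1.0 / xx - 1.0 / xx**2)
        acc2 = r3 <= 0.5 * (cos_t**2 + 1.0 / xx)
        accept = np.where(branch1, acc1, acc2)
        ok = idx[accept]
        x[ok] = xx[accept]
        todo[ok] = False
    cos_theta = np.clip(1.0 - (x - 1.0) / alpha, -1.0, 1.0)
    theta = np.arccos(cos_theta)
    return theta.reshape(size) if np.ndim(size) or not np.isscalar(size) else theta


# ---------------------------------------------------------------------------
# Doppler broadening: hydrogenic impulse-approximation momentum profiles
# ---------------------------------------------------------------------------

# Slater effective charges per (principal quantum number, occupancy) shell.
# Each entry: (n, occupancy, Z_eff).  Derived from Slater's screening rules;
# this gives each shell a hydrogenic momentum scale p_n = Z_eff/n [a.u.].
def _slater_shells(Z):
    # fill order and grouping (s+p pooled per Slater convention, d separate)
    groups = []  # (n, l_group, capacity)
    order = [
        (1, "sp", 2), (2, "sp", 8), (3, "sp", 8), (3, "d", 10),
        (4, "sp", 8), (4, "d", 10), (5, "sp", 8),
    ]
    remaining = Z
    filled = []
    for n, g, cap in order:
        if remaining <= 0:
            break
        occ = min(cap, remaining)
        filled.append((n, g, occ))
        remaining -= occ
    for i, (n, g, occ) in enumerate(filled):
        s = 0.0
        for j, (n2, g2, occ2) in enumerate(filled):
            if j == i:
                s += 0.35 * (occ - 1) if n > 1 else 0.30 * (occ - 1)
            elif g == "d" and (n2 < n or (n2 == n and g2 == "sp")):
                s += 1.00 * occ2
            elif g == "sp" and n2 == n - 1:
                s += 0.85 * occ2
            elif n2 < n - 1 or (n2 == n - 1 and g == "d"):
                s += 1.00 * occ2
            elif n2 == n and j != i:
                s += 0.35 * occ2
        zeff = max(Z - s, 0.65)
        groups.append((n, occ, zeff))
    return groups


def _czt_shell_table():
    """Momentum scales [units of m_e c] and electron weights for CZT shells."""
    scales, weights = [], []
    for el, stoich in CZT_STOICHIOMETRY.items():
        for n, occ, zeff in _slater_shells(ATOMIC_NUMBER[el]):
            scales.append(zeff / n * ALPHA_FS)
            weights.append(stoich * occ)
    scales = np.array(scales)
    weights = np.array(weights)
    return scales, weights / weights.sum()


_SHELL_SCALES, _SHELL_WEIGHTS = _czt_shell_table()


def sample_electron_pz(rng, size):
    """Sample the projected electron momentum p_z (units of m_e c) for CZT.

    A shell is drawn with probability proportional to its occupancy, then p_z
    is drawn from a heavy-tailed hydrogenic-like profile J(p) ~ (1+(p/p_n)^2)^-3
    (realised as a scaled Student-t with 5 degrees of freedom), with momentum
    scale p_n = Z_eff/n atomic units from Slater screening.
    """
    shell = rng.choice(_SHELL_SCALES.size, size=size, p=_SHELL_WEIGHTS)
    t = rng.standard_t(5, size=size)
    return _SHELL_SCALES[shell] * t / np.sqrt(5.0)


def doppler_shift(E0, theta, pz):
    """First-order Doppler shift of the scattered-photon energy [keV].

    For electron momentum projection ``pz`` (units of m_e c) on the scattering
    vector, the scattered energy moves off the Compton line by
    ``dE' = pz * m_e c^2 * q / (E0 (1-cos theta) + m_e c^2)`` where ``q`` is the
    momentum transfer (in energy units) evaluated on the Compton line.
    """
    ct = np.cos(theta)
    Ep = E0 / (1.0 + (E0 / MEC2) * (1.0 - ct))
    q = np.sqrt(E0**2 + Ep**2 - 2.0 * E0 * Ep * ct)
    return pz * MEC2 * q / (E0 * (1.0 - ct) + MEC2)


def sample_compton(E0, rng, doppler=True, size=None):
    """Draw (theta [rad], deposited energy E1 [keV]) for Compton scattering.

    theta follows Klein-Nishina; with ``doppler`` the deposit is additionally
    broadened around the Compton-line value (clipped to (0, E0)).  With
    ``doppler=False`` the deposit is exactly ``E0 - compton_scatter(E0, theta)``.
    """
    theta = sample_klein_nishina(E0, rng, size=size)
    E1 = np.asarray(E0 - compton_scatter(E0, theta), dtype=float)
    if doppler:
        pz = sample_electron_pz(rng, np.shape(theta))
        shift = doppler_shift(np.asarray(E0, dtype=float), theta, pz)
        # a positive shift of E' reduces the deposit
        E1 = np.clip(E1 - shift, 1e-6, np.asarray(E0) - 1e-6)
    return theta, E1
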