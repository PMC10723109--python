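"""Compton-kinematics sequencing, random/scatter rejection, and NECR gain.

For a coincidence with a two-site (Compton) photon on one side, each candidate
interaction ordering fixes the observed first-interaction energy E1 and the
inter-site distance d2.  Assuming the annihilation photons travel back-to-back,
the line through the assumed first site and the opposite photon's position
gives the implied scattering angle; the response matrix F, normalised by its
per-(E1, d2)-slice maximum over angles, turns that angle into a relative
probability.  An event is accepted when any (side, ordering) combination
reaches the rejection threshold; the argmax fixes the predicted first site.

The probability of falsely rejecting a *true* Compton coincidence at a given
threshold follows from F alone: per (E1, d2) slice, the angular mass lying
below threshold x slice-maximum, combined over slices by the law of total
probability with the slice masses as weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .response import ComptonResponseMatrix

ENERGY_WINDOW = (500.0, 540.0)  # keV

CAT_SINGLE_SINGLE = 0
CAT_COMPTON_ONE = 1
CAT_COMPTON_BOTH = 2
CAT_OTHER = 3
CATEGORY_NAMES = {
    CAT_SINGLE_SINGLE: "single-single",
    CAT_COMPTON_ONE: "compton-one-side",
    CAT_COMPTON_BOTH: "compton-both-sides",
    CAT_OTHER: "other",
}


@dataclass
class RejectionDecision:
    """Outcome of Compton-based screening for one event."""

    accepted: bool
    threshold: float
    probabilities: tuple  # relative probability per (side, ordering) candidate
    chosen_side: int | None = None      # photon side carrying the chosen ordering
    chosen_ordering: int | None = None  # 0: storage order, 1: swapped


# ---------------------------------------------------------------------------
# event classification
# ---------------------------------------------------------------------------

def classify_events(data, window=ENERGY_WINDOW):
    """Category code per event and the both-sides-in-window flag."""
    counts = np.asarray(data.photons["site_count"], int).reshape(-1, 2)
    e = data.photon_energy().reshape(-1, 2)
    in_win = ((e >= window[0]) & (e <= window[1])).all(axis=1)
    cat = np.full(counts.shape[0], CAT_OTHER, dtype=int)
    cat[(counts == 1).all(axis=1)] = CAT_SINGLE_SINGLE
    one = ((counts == 2).sum(axis=1) == 1) & (counts.max(axis=1) == 2)
    cat[one] = CAT_COMPTON_ONE
    cat[(counts == 2).all(axis=1)] = CAT_COMPTON_BOTH
    return cat, in_win


def classify_and_tabulate(data, window=ENERGY_WINDOW) -> pd.DataFrame:
    """Event counts per category, split by the energy window (Table-style)."""
    cat, in_win = classify_events(data, window)
    rows = {}
    for code, name in CATEGORY_NAMES.items():
        m = cat == code
        rows[name] = {
            "out_of_window": int((m & ~in_win).sum()),
            "within_window": int((m & in_win).sum()),
            "total": int(m.sum()),
        }
    df = pd.DataFrame(rows).T
    df["within_window_proportion"] = np.where(
        df["total"] > 0, df["within_window"] / df["total"], 0.0)
    return df


# ---------------------------------------------------------------------------
# sequencing and rejection
# ---------------------------------------------------------------------------

def _relative_probs(F: ComptonResponseMatrix, first_pos, second_pos, e_first,
                    other_pos):
    """Vectorised relative probability for candidate orderings (arrays (N, .))."""
    u = first_pos - other_pos
    d1 = np.linalg.norm(u, axis=1)
    v = second_pos - first_pos
    d2 = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ct = np.einsum("ij,ij->i", u, v) / (d1 * d2)
    theta = np.degrees(np.arccos(np.clip(ct, -1.0, 1.0)))
    i = F.e1_bin(e_first)
    j = F.theta_bin(theta)
    k = F.d2_bin(d2)
    rel = F.relative_probability(i, j, k)
    rel = np.where(e_first <= 0, 0.0, rel)
    return np.nan_to_num(rel)


def _compton_candidates(data, F: ComptonResponseMatrix):
    """Relative probabilities for all (side, ordering) candidates per event.

    Returns ``(probs, side, ordering, event)`` flat arrays; events without a
    usable two-site photon produce no rows.
    """
    counts = np.asarray(data.photons["site_count"], int)
    starts = np.asarray(data.photons["site_start"], int)
    pos = data.site_positions()
    energy = np.asarray(data.sites["energy"])
    n_ev = data.n_events

    # energy-weighted centroid of every photon (reference point for the
    # opposite side)
    owner = np.repeat(np.arange(counts.size), counts)
    wsum = np.bincount(owner, weights=energy, minlength=counts.size)
    centroid = np.column_stack([
        np.bincount(owner, weights=pos[:, c] * energy, minlength=counts.size)
        for c in range(3)]) / wsum[:, None]

    out_p, out_side, out_ord, out_ev = [], [], [], []
    for side in (0, 1):
        rows = np.arange(n_ev) * 2 + side
        usable = counts[rows] == 2
        ev = np.nonzero(usable)[0]
        if ev.size == 0:
            continue
        r = rows[usable]
        s0 = starts[r]
        p_a = pos[s0]
        p_b = pos[s0 + 1]
        e_a = energy[s0]
        e_b = energy[s0 + 1]
        other = centroid[np.arange(n_ev) * 2 + (1 - side)][ev]
        for ordering, (pf, ps, ef) in enumerate(((p_a, p_b, e_a), (p_b, p_a, e_b))):
            out_p.append(_relative_probs(F, pf, ps, ef, other))
            out_side.append(np.full(ev.size, side))
            out_ord.append(np.full(ev.size, ordering))
            out_ev.append(ev)
    if not out_p:
        z = np.zeros(0)
        return z, z.astype(int), z.astype(int), z.astype(int)
    return (np.concatenate(out_p), np.concatenate(out_side).astype(int),
            np.concatenate(out_ord).astype(int), np.concatenate(out_ev).astype(int))


def sequence_probabilities(data, F: ComptonResponseMatrix, event: int):
    """Relative probability of both orderings of one event's Compton photon.

    The event must have exactly one two-site photon (use the batch helpers for
    compton-both events).  Returns (p_order0, p_order1) where order 0 takes
    the stored first site as the first interaction.
    """
    sub = data.select(np.array([event]))
    probs, side, ordering, _ = _compton_candidates(sub, F)
    if probs.size == 0:
        raise ValueError("event has no two-site photon")
    sides = np.unique(side)
    if sides.size != 1:
        raise ValueError("event has Compton photons on both sides; "
                         "use reject_event / evaluate_stream")
    return float(probs[ordering == 0][0]), float(probs[ordering == 1][0])


def evaluate_stream(data, F: ComptonResponseMatrix):
    """Best relative probability and arg-max candidate per event.

    Events without any usable Compton side get probability NaN (pass-through).
    """
    probs, side, ordering, ev = _compton_candidates(data, F)
    best = np.full(data.n_events, np.nan)
    best_side = np.full(data.n_events, -1)
    best_ord = np.full(data.n_events, -1)
    order = np.argsort(probs, kind="stable")
    best[ev[order]] = probs[order]
    best_side[ev[order]] = side[order]
    best_ord[ev[order]] = ordering[order]
    return best, best_side, best_ord


def reject_event(data, F: ComptonResponseMatrix, threshold: float,
                 event: int = 0) -> RejectionDecision:
    """Accept/reject one event: max over (side, ordering) against threshold."""
    sub = data.select(np.array([event]))
    probs, side, ordering, _ = _compton_candidates(sub, F)
    if probs.size == 0:  # single-single or no usable Compton side
        return RejectionDecision(accepted=True, threshold=threshold,
                                 probabilities=())
    k = int(np.argmax(probs))
    return RejectionDecision(
        accepted=bool(probs[k] >= threshold), threshold=threshold,
        probabilities=tuple(probs), chosen_side=int(side[k]),
        chosen_ordering=int(ordering[k]))


def reject_stream(data, F: ComptonResponseMatrix, threshold: float):
    """Vectorised accept mask over all events (pass-through for non-Compton)."""
    best, _, _ = evaluate_stream(data, F)
    return ~(best < threshold)  # NaN -> accepted


def predict_first_sites(data, F: ComptonResponseMatrix) -> np.ndarray:
    """Per-photon-row predicted first-site index (-1 for single/unusable).

    For every two-site photon the ordering with the larger relative
    probability (each side evaluated independently) fixes the predicted
    first interaction.
    """
    probs, side, ordering, ev = _compton_candidates(data, F)
    n_rows = 2 * data.n_events
    out = np.full(n_rows, -1, dtype=int)
    rows = 2 * ev + side
    order = np.argsort(probs, kind="stable")
    out[rows[order]] = ordering[order]  # last write per row wins: the argmax
    return out


# ---------------------------------------------------------------------------
# accuracy accounting and NECR
# ---------------------------------------------------------------------------

def false_rejection_probability(F: ComptonResponseMatrix, threshold: float) -> float:
    """P(falsely rejecting a true Compton coincidence) from F alone.

    Per (E1, d2) slice: mass of angle bins below threshold x slice max over
    the slice mass, weighted by the slice mass over the total (law of total
    probability) — equivalently the total matrix mass below the slice-relative
    threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if threshold == 0.0:
        return 0.0
    sm = F.slice_max()
    below = F.counts < threshold * sm[:, None, :]
    return float(np.where(below, F.counts, 0.0).sum() / F.counts.sum())


def necr_gain(false_rejection_rate: float, rejection_rate: float) -> float:
    """NECR'/NECR = (1 - false rejection rate)^2 / (1 - rejection rate)."""
    if not (0.0 <= rejection_rate < 1.0):
        raise ValueError("rejection rate must lie in [0, 1)")
    if not (0.0 <= false_rejection_rate <= 1.0):
        raise ValueError("false rejection rate must lie in [0, 1]")
    return (1.0 - false_rejection_rate) ** 2 / (1.0 - rejection_rate)


def true_rejection_rate(n_rejected: int, n_known_random: int) -> float:
    """Fraction of known-random events rejected (e.g. 137428/202597 = 0.678)."""
    if n_known_random <= 0:
        raise ValueError("no known-random events")
    return n_rejected / n_known_random


def optimize_threshold(F: ComptonResponseMatrix, data,
                       thresholds=None, window=ENERGY_WINDOW):
    """Scan thresholds: empirical rejection rate of the Compton stream and
    Eq-based false-rejection probability maximise NECR'/NECR.

    Returns ``(best_threshold, table)`` with the full curve as a DataFrame.
    """
    thresholds = np.arange(0.0, 1.0 + 1e-9, 0.01) if thresholds is None \
        else np.asarray(thresholds, float)
    cat, in_win = classify_events(data, window)
    stream = data.select(np.isin(cat, (CAT_COMPTON_ONE, CAT_COMPTON_BOTH)) & in_win)
    if stream.n_events == 0:
        raise ValueError("no Compton-containing events in the stream")
    best, _, _ = evaluate_stream(stream, F)
    sm = F.slice_max()
    total = F.counts.sum()
    rows = []
    for t in thresholds:
        rej = float(np.mean(np.nan_to_num(best, nan=np.inf) < t))
        if t == 0.0:
            fr = 0.0
        else:
            fr = float(np.where(F.counts < t * sm[:, None, :], F.counts, 0).sum()
                       / total)
        gain = necr_gain(fr, rej) if rej < 1.0 else np.nan
        rows.append((t, rej, fr, gain))
    table = pd.DataFrame(rows, columns=["threshold", "rejection_rate",
                                        "false_rejection", "necr_gain"])
    best_t = float(table.loc[table["necr_gain"].idxmax(), "threshold"])
    return best_t, table


def lor_misses_object(data, radius: float, z_half: float,
                      margin: float = 1.0) -> np.ndarray:
    """True when every candidate line of response misses the object cylinder.

    Candidate LORs connect any site of side 0 with any site of side 1; an LOR
    "passes" the object when its closest approach to the z-axis (in the x-y
    projection) is within ``radius + margin`` and the corresponding z lies
    within ``z_half + margin``.  This is the experiment-style surrogate for
    labelling random coincidences.
    """
    counts = np.asarray(data.photons["site_count"], int)
    starts = np.asarray(data.photons["site_start"], int)
    pos = data.site_positions()
    misses = np.ones(data.n_events, dtype=bool)
    for e in range(data.n_events):
        ra, ca = starts[2 * e], counts[2 * e]
        rb, cb = starts[2 * e + 1], counts[2 * e + 1]
        hit = False
        for i in range(ra, ra + ca):
            for j in range(rb, rb + cb):
                p, q = pos[i], pos[j]
                d = q - p
                nxy = np.hypot(d[0], d[1])
                if nxy < 1e-12:
                    dist = np.hypot(p[0], p[1])
                    tz = 0.5
                else:
                    t = -(p[0] * d[0] + p[1] * d[1]) / (nxy * nxy)
                    t = np.clip(t, 0.0, 1.0)
                    c = p[:2] + t * d[:2]
                    dist = np.hypot(*c)
                    tz = t
                zc = p[2] + tz * d[2]
                if dist <= radius + margin and abs(zc) <= z_half + margin:
                    hit = True
                    break
            if hit:
                break
        misses[e] = not hit
    return misses


def tabulate_rejection(data, F: ComptonResponseMatrix, threshold: float,
                       object_radius: float, object_z_half: float,
                       window=ENERGY_WINDOW) -> pd.DataFrame:
    """Accuracy accounting per subset, mirroring the accuracy tables.

    Columns: single-single count (in window), Compton-containing count,
    accepted Compton events, known randoms (LOR misses the object), rejected
    known randoms, and the resulting true-rejection rate.
    """
    cat, in_win = classify_events(data, window)
    compton = np.isin(cat, (CAT_COMPTON_ONE, CAT_COMPTON_BOTH)) & in_win
    subsets = np.asarray(data.events["subset"], int)
    rows = []
    for s in np.unique(subsets):
        sel = subsets == s
        ss = int(((cat == CAT_SINGLE_SINGLE) & in_win & sel).sum())
        stream = data.select(compton & sel)
        acc = reject_stream(stream, F, threshold)
        known = lor_misses_object(stream, object_radius, object_z_half)
        n_known = int(known.sum())
        n_rej_known = int((known & ~acc).sum())
        rows.append({
            "subset": int(s), "single_single": ss,
            "compton_events": stream.n_events,
            "accepted_compton": int(acc.sum()),
            "known_random": n_known,
            "rejected_known_random": n_rej_known,
            "true_rejection_rate": (n_rej_known / n_known) if n_known else np.nan,
        })
    return pd.DataFrame(rows)
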