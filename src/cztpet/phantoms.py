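"""Phantom definitions and partial-volume-aware rasterisation.

Available phantoms mirror the objects used to characterise the prototype:

* ``point`` — a 0.25-mm diameter sphere (Na-22 style point source);
* ``two-lines`` — two parallel capillaries of 0.65-mm inner diameter;
* ``hot-rod`` — a 14-mm diameter, 10-mm long resolution phantom with four
  sectors of rods (0.35, 0.5, 0.75, 1 mm diameter; centre-to-centre pitches
  0.7, 1.0, 1.5, 1.6 mm);
* ``iq`` — the NU-4 image-quality phantom scaled by 70% (rod diameters
  0.50, 0.80, 1.10, 1.50, 1.80 mm) with its uniform region;
* ``uniform-cylinder`` — a plain cylinder.

Rasterisation is exact along z for extruded shapes and supersampled 4x4 in
the lateral plane for voxels straddling a circular boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import ActivityImage

HOT_ROD_DIAMETERS = (1.0, 0.75, 0.5, 0.35)
HOT_ROD_PITCHES = (1.6, 1.5, 1.0, 0.7)
IQ_ROD_DIAMETERS = (0.50, 0.80, 1.10, 1.50, 1.80)
IQ_SCALE = 0.70


@dataclass
class PhantomSpec:
    kind: str  # point | two-lines | hot-rod | iq | uniform-cylinder
    total_activity: float = 9.25e5  # Bq (25 uCi)
    isotope: str = "Cu-64"
    centre: tuple = (0.0, 0.0, 0.0)
    # kind-specific geometry [mm]
    diameter: float | None = None
    length: float = 10.0
    line_separation: float = 3.0
    rod_diameters: tuple = HOT_ROD_DIAMETERS
    rod_pitches: tuple = HOT_ROD_PITCHES
    #: length of the continuous-solution (uniform) section at the top of the
    #: hot-rod and iq phantoms; the rest of the length holds the rods
    uniform_cap: float = 2.0

    def smallest_feature(self) -> float:
        if self.kind == "point":
            return self.diameter or 0.25
        if self.kind == "two-lines":
            return 0.65
        if self.kind == "hot-rod":
            return min(self.rod_diameters)
        if self.kind == "iq":
            return min(IQ_ROD_DIAMETERS)
        if self.kind == "uniform-cylinder":
            return self.diameter or 10.0
        raise ValueError(f"unknown phantom kind {self.kind!r}")


def hot_rod_centres(diameters=HOT_ROD_DIAMETERS, pitches=HOT_ROD_PITCHES,
                    outer_diameter: float = 14.0):
    """Rod centres per sector: list of (diameter, (n, 2) centres).

    Each sector is a 90-degree wedge; rods sit on a triangular lattice with
    the stated centre-to-centre pitch, kept one clearance away from the
    sector boundaries and the phantom rim.
    """
    R = outer_diameter / 2.0
    sectors = []
    for s, (dia, pitch) in enumerate(zip(diameters, pitches)):
        bisector = np.radians(45.0 + 90.0 * s)
        u = np.array([np.cos(bisector), np.sin(bisector)])
        v = np.array([-np.sin(bisector), np.cos(bisector)])
        rad = dia / 2.0
        clear = max(pitch - 2.0 * rad, rad) / 2.0 + rad
        h = pitch * np.sqrt(3.0) / 2.0
        centres = []
        r0 = pitch  # apex offset from the phantom centre
        for i in range(40):
            y = r0 + i * h
            for j in range(i + 1):
                x = (j - i / 2.0) * pitch
                c = y * u + x * v
                r_c = np.hypot(*c)
                if r_c + rad > R - 0.5:
                    continue
                ang = np.arctan2(c[1], c[0]) - bisector
                ang = (ang + np.pi) % (2 * np.pi) - np.pi
                # distance to the two wedge boundary half-planes
                if r_c * np.sin(np.radians(45.0) - np.abs(ang)) < clear:
                    continue
                centres.append(c)
            if r0 + i * h > R:
                break
        sectors.append((dia, np.array(centres).reshape(-1, 2)))
    return sectors


def iq_rod_centres():
    """NU-4 rod positions scaled by 70%: rods on a 7-mm radius ring."""
    ring = 7.0 * IQ_SCALE
    out = []
    for k, dia in enumerate(IQ_ROD_DIAMETERS):
        ang = np.radians(90.0 + 72.0 * k)
        out.append((dia, ring * np.array([np.cos(ang), np.sin(ang)])))
    return out


def _circle_fraction(xc, yc, r, gx, gy, voxel):
    """Lateral coverage fraction of each grid voxel by a circle (4x4 subsample)."""
    dx = gx - xc
    dy = gy - yc
    d = np.hypot(dx, dy)
    half_diag = voxel * np.sqrt(0.5)
    frac = np.zeros_like(d)
    frac[d <= r - half_diag] = 1.0
    border = (d < r + half_diag) & (d > r - half_diag)
    if border.any():
        off = (np.arange(4) + 0.5) / 4.0 - 0.5
        ox, oy = np.meshgrid(off, off)
        sub = np.zeros(border.sum())
        bx = dx[border]
        by = dy[border]
        for a, b in zip(ox.ravel(), oy.ravel()):
            sub += (np.hypot(bx + a * voxel, by + b * voxel) <= r)
        frac[border] = sub / 16.0
    return frac


def _z_fraction(z_axis, dz, z0, z1):
    lo = np.clip((z1 - z_axis) / dz, 0.0, 1.0)
    hi = np.clip((z_axis + dz - z0) / dz, 0.0, 1.0)
    return np.clip(lo + hi - 1.0, 0.0, 1.0)


def make_phantom(spec: PhantomSpec, voxel_size: float) -> ActivityImage:
    """Rasterise ``spec`` onto an isotropic grid of ``voxel_size`` mm."""
    if voxel_size > spec.smallest_feature() / 2.0 + 1e-12:
        raise ValueError("voxel size must be at most half the smallest feature")
    pad = 2 * voxel_size
    if spec.kind == "point":
        dia = spec.diameter or 0.25
        extent = np.array([dia + pad, dia + pad, dia + pad])
    elif spec.kind == "two-lines":
        extent = np.array([spec.line_separation + 0.65 + pad, 0.65 + pad,
                           spec.length + pad])
    elif spec.kind == "hot-rod":
        d = spec.diameter or 14.0
        extent = np.array([d + pad, d + pad, spec.length + pad])
    elif spec.kind == "iq":
        d = (spec.diameter or 30.0 * IQ_SCALE)
        extent = np.array([d + pad, d + pad, spec.length + pad])
    elif spec.kind == "uniform-cylinder":
        d = spec.diameter or 10.0
        extent = np.array([d + pad, d + pad, spec.length + pad])
    else:
        raise ValueError(f"unknown phantom kind {spec.kind!r}")

    shape = np.ceil(extent / voxel_size).astype(int)
    img = ActivityImage.empty(shape, voxel_size, centre=spec.centre)
    xs = img.origin[0] + (np.arange(shape[0]) + 0.5) * voxel_size
    ys = img.origin[1] + (np.arange(shape[1]) + 0.5) * voxel_size
    zs = img.origin[2] + np.arange(shape[2]) * voxel_size  # lower edges
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    cx, cy, cz = spec.centre
    zfrac = _z_fraction(zs, voxel_size, cz - spec.length / 2.0,
                        cz + spec.length / 2.0)

    if spec.kind == "point":
        dia = spec.diameter or 0.25
        img.data[:] = _sphere_fraction(img, np.asarray(spec.centre), dia / 2.0)
    elif spec.kind == "two-lines":
        lat = np.zeros_like(gx)
        for sgn in (-1.0, 1.0):
            lat += _circle_fraction(cx + sgn * spec.line_separation / 2.0, cy,
                                    0.325, gx, gy, voxel_size)
        img.data[:] = lat[:, :, None] * zfrac[None, None, :]
    elif spec.kind in ("hot-rod", "iq"):
        lat = np.zeros_like(gx)
        if spec.kind == "hot-rod":
            rods = [(dia, c) for dia, centres in
                    hot_rod_centres(spec.rod_diameters, spec.rod_pitches,
                                    spec.diameter or 14.0) for c in centres]
        else:
            rods = iq_rod_centres()
        for dia, c in rods:
            lat += _circle_fraction(cx + c[0], cy + c[1], dia / 2.0,
                                    gx, gy, voxel_size)
        lat = np.clip(lat, 0, 1)
        cap = min(spec.uniform_cap, spec.length)
        z_cap0 = cz + spec.length / 2.0 - cap
        zfrac_rod = _z_fraction(zs, voxel_size, cz - spec.length / 2.0, z_cap0)
        zfrac_cap = _z_fraction(zs, voxel_size, z_cap0, cz + spec.length / 2.0)
        disc = _circle_fraction(cx, cy, (spec.diameter or
                                         (14.0 if spec.kind == "hot-rod"
                                          else 30.0 * IQ_SCALE)) / 2.0,
                                gx, gy, voxel_size)
        img.data[:] = (lat[:, :, None] * zfrac_rod[None, None, :]
                       + disc[:, :, None] * zfrac_cap[None, None, :])
    elif spec.kind == "uniform-cylinder":
        d = spec.diameter or 10.0
        lat = _circle_fraction(cx, cy, d / 2.0, gx, gy, voxel_size)
        img.data[:] = lat[:, :, None] * zfrac[None, None, :]

    total = img.data.sum()
    if total <= 0:
        raise ValueError("phantom rasterised to zero activity")
    img.data *= spec.total_activity / total
    return img


def make_line_uniform_phantom(voxel_size: float, total_activity: float = 9.25e5,
                              line_offset: float = 2.0,
                              line_concentration: float = 20.0,
                              centre=(0.0, 0.0, 0.0)) -> ActivityImage:
    """Composite QC phantom: one hot capillary line plus a uniform cylinder.

    A 0.65-mm inner-diameter capillary (axis along z, offset ``line_offset``
    in x, 6 mm long) under a 10-mm diameter, 3-mm long uniform cylinder.
    The capillary concentration is ``line_concentration`` times the uniform
    region's so a line-spread measurement and a uniformity ROI coexist at
    modest event counts.  Used by the resolution-matched dataset comparison.
    """
    cx, cy, cz = centre
    extent = np.array([12.0, 12.0, 10.0])
    shape = np.ceil(extent / voxel_size).astype(int)
    img = ActivityImage.empty(shape, voxel_size, centre=centre)
    xs = img.origin[0] + (np.arange(shape[0]) + 0.5) * voxel_size
    ys = img.origin[1] + (np.arange(shape[1]) + 0.5) * voxel_size
    zs = img.origin[2] + np.arange(shape[2]) * voxel_size
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    line_lat = _circle_fraction(cx + line_offset, cy, 0.325, gx, gy, voxel_size)
    line_z = _z_fraction(zs, voxel_size, cz - 5.0, cz + 1.0)
    disc = _circle_fraction(cx, cy, 5.0, gx, gy, voxel_size)
    disc_z = _z_fraction(zs, voxel_size, cz + 1.5, cz + 4.5)
    img.data[:] = (line_concentration * line_lat[:, :, None] * line_z[None, None, :]
                   + disc[:, :, None] * disc_z[None, None, :])
    img.data *= total_activity / img.data.sum()
    return img


def _sphere_fraction(img: ActivityImage, centre, radius):
    """Voxel coverage of a sphere, 4x4x4 subsampling at the boundary."""
    pts = img.voxel_centres().reshape(*img.shape, 3)
    d = np.linalg.norm(pts - centre, axis=-1)
    half_diag = np.linalg.norm(img.spacing) / 2.0
    frac = np.zeros(img.shape)
    frac[d <= radius - half_diag] = 1.0
    border = (d < radius + half_diag) & (d > radius - half_diag)
    if border.any():
        off = (np.arange(4) + 0.5) / 4.0 - 0.5
        ox, oy, oz = np.meshgrid(off, off, off, indexing="ij")
        offs = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()]) * img.spacing
        bpts = pts[border]
        acc = np.zeros(bpts.shape[0])
        for o in offs:
            acc += np.linalg.norm(bpts + o - centre, axis=-1) <= radius
        frac[border] = acc / offs.shape[0]
    return frac
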