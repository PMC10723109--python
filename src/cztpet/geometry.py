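"""System geometry: four CZT panels of 2x2 modules, poses, and voxel indexing.

Coordinate conventions (right-handed, units mm/degrees):

* global frame: origin at the centre of the field of view, ``z`` along the
  rotation axis, panel normals in the x-y plane;
* each panel has a local frame (6 pose parameters: translation + xyz Euler
  rotation) whose ``w`` axis points from the cathode (front, FOV-facing) face
  toward the anode; DOI is measured from the cathode face toward the anode;
* each module has a pose inside its panel frame; the module frame is centred
  on its 22 x 22 x 10 mm crystal, with ``z_local`` the depth axis (cathode
  face at ``z_local = -5``).

The full parameter vector ``alpha`` has 130 entries:
4 panels x (6 panel-pose + 4 modules x 6 module-pose) = 120, plus 7 for the
rotation stage (3 rotation, 3 translation, radius) and 3 for the direction of
the vertical translation stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

MODULE_HALF = np.array([11.0, 11.0, 5.0])  # mm, crystal half-extents
MODULES_PER_PANEL = 4
N_PANELS = 4
PIXEL_PITCH = 1.9  # mm
N_PIXELS = 11
LATERAL_VOXELS = 100
#: lateral detector-voxel pitch: the 20.9 mm pixelated area over 100 voxels
VOXEL_PITCH = N_PIXELS * PIXEL_PITCH / LATERAL_VOXELS  # 0.209 mm
ACTIVE_HALF = N_PIXELS * PIXEL_PITCH / 2.0  # 10.45 mm
N_ALPHA = 130


def _euler_matrix(angles_deg):
    return Rotation.from_euler("xyz", np.asarray(angles_deg, float), degrees=True).as_matrix()


@dataclass
class Pose:
    """Rigid transform: x_global = R(rotation) @ base @ x_local + translation.

    ``rotation`` is a rotation vector in degrees applied on top of the fixed
    ``base`` orientation.  Parametrising the adjustable part as a rotation
    vector around the nominal pose keeps the parametrisation non-singular
    (xyz Euler angles are gimbal-locked at the panels' 90-degree pitch).
    """

    translation: np.ndarray
    rotation: np.ndarray  # rotation vector, degrees
    base: np.ndarray = None

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.base = np.eye(3) if self.base is None else np.asarray(self.base, float)

    @property
    def matrix(self) -> np.ndarray:
        delta = Rotation.from_rotvec(np.radians(self.rotation)).as_matrix()
        return delta @ self.base

    def params(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation])


@dataclass
class DetectorVoxelIndex:
    """Index of one detector voxel: module, lateral (u, v), DOI sublayer."""

    module_id: int
    u: int
    v: int
    doi: int = 0
    D: int = 1

    def __post_init__(self):
        if not (0 <= self.u < LATERAL_VOXELS and 0 <= self.v < LATERAL_VOXELS):
            raise ValueError("lateral voxel index out of range")
        if not 0 <= self.doi < self.D:
            raise ValueError("DOI sublayer index out of range")


@dataclass
class SystemGeometry:
    panel_poses: list[Pose]
    module_poses: list[list[Pose]]  # [panel][module], in the panel frame
    stage_rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    stage_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    stage_radius: float = 5.0
    vertical_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    separation: float = 80.0

    # ------------------------------------------------------------------
    @classmethod
    def nominal(cls, separation: float = 80.0) -> "SystemGeometry":
        """Four panels at +-x/+-y, opposite front faces ``separation`` apart."""
        half_gap = separation / 2.0
        centre_dist = half_gap + MODULE_HALF[2]  # crystal-centre distance
        panel_poses = []
        # panel w (depth) axis points away from the FOV; Euler angles chosen so
        # that R @ ez_local = outward normal
        specs = [
            ((centre_dist, 0, 0), (0.0, 90.0, 0.0)),   # +x
            ((0, centre_dist, 0), (-90.0, 0.0, 0.0)),  # +y
            ((-centre_dist, 0, 0), (0.0, -90.0, 0.0)), # -x
            ((0, -centre_dist, 0), (90.0, 0.0, 0.0)),  # -y
        ]
        for t, r in specs:
            panel_poses.append(Pose(np.array(t, float), np.zeros(3),
                                    base=_euler_matrix(r)))
        module_poses = []
        for _ in range(N_PANELS):
            mods = []
            for (du, dv) in ((-11, -11), (11, -11), (-11, 11), (11, 11)):
                mods.append(Pose(np.array([du, dv, 0.0]), np.zeros(3)))
            module_poses.append(mods)
        return cls(panel_poses=panel_poses, module_poses=module_poses,
                   separation=separation)

    # ------------------------------------------------------------------
    @property
    def n_modules(self) -> int:
        return N_PANELS * MODULES_PER_PANEL

    def opposite_panel(self, panel: int) -> int:
        return (panel + 2) % N_PANELS

    def panel_of_module(self, module_id: int) -> int:
        return module_id // MODULES_PER_PANEL

    def module_transforms(self):
        """Global poses of all 24 modules: rotations (24,3,3), centres (24,3)."""
        Rs, ts = [], []
        for p in range(N_PANELS):
            Rp, tp = self.panel_poses[p].matrix, self.panel_poses[p].translation
            for m in range(MODULES_PER_PANEL):
                Rm, tm = self.module_poses[p][m].matrix, self.module_poses[p][m].translation
                Rs.append(Rp @ Rm)
                ts.append(Rp @ tm + tp)
        return np.array(Rs), np.array(ts)

    # ------------------------------------------------------------------
    # alpha packing
    @property
    def alpha(self) -> np.ndarray:
        parts = []
        for p in range(N_PANELS):
            parts.append(self.panel_poses[p].params())
            for m in range(MODULES_PER_PANEL):
                parts.append(self.module_poses[p][m].params())
        parts.append(self.stage_rotation)
        parts.append(self.stage_translation)
        parts.append([self.stage_radius])
        parts.append(self.vertical_direction)
        alpha = np.concatenate([np.asarray(x, float).ravel() for x in parts])
        assert alpha.size == N_ALPHA
        return alpha

    @alpha.setter
    def alpha(self, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.size != N_ALPHA:
            raise ValueError(f"alpha must have {N_ALPHA} entries")
        k = 0
        for p in range(N_PANELS):
            self.panel_poses[p] = Pose(values[k:k + 3], values[k + 3:k + 6],
                                       base=self.panel_poses[p].base); k += 6
            for m in range(MODULES_PER_PANEL):
                self.module_poses[p][m] = Pose(
                    values[k:k + 3], values[k + 3:k + 6],
                    base=self.module_poses[p][m].base); k += 6
        self.stage_rotation = values[k:k + 3]; k += 3
        self.stage_translation = values[k:k + 3]; k += 3
        self.stage_radius = float(values[k]); k += 1
        self.vertical_direction = values[k:k + 3]; k += 3

    def copy(self) -> "SystemGeometry":
        g = SystemGeometry.nominal(self.separation)
        g.alpha = self.alpha
        return g

    # ------------------------------------------------------------------
    # voxel indexing
    def position_to_voxel(self, module_id, local_pos, D: int = 1):
        """Map module-frame positions (N,3) to (u, v, doi) integer indices."""
        local_pos = np.atleast_2d(local_pos)
        u = np.clip(((local_pos[:, 0] + ACTIVE_HALF) / VOXEL_PITCH).astype(int), 0, LATERAL_VOXELS - 1)
        v = np.clip(((local_pos[:, 1] + ACTIVE_HALF) / VOXEL_PITCH).astype(int), 0, LATERAL_VOXELS - 1)
        depth = local_pos[:, 2] + MODULE_HALF[2]  # DOI from cathode face
        layer = 2.0 * MODULE_HALF[2] / D
        doi = np.clip((depth / layer).astype(int), 0, D - 1)
        return u, v, doi

    def voxel_centre_local(self, index: DetectorVoxelIndex) -> np.ndarray:
        """Module-frame centre of a detector voxel's central slice."""
        x = -ACTIVE_HALF + (index.u + 0.5) * VOXEL_PITCH
        y = -ACTIVE_HALF + (index.v + 0.5) * VOXEL_PITCH
        layer = 2.0 * MODULE_HALF[2] / index.D
        z = -MODULE_HALF[2] + (index.doi + 0.5) * layer
        return np.array([x, y, z])

    def voxel_centre_global(self, index: DetectorVoxelIndex) -> np.ndarray:
        Rs, ts = self.module_transforms()
        return Rs[index.module_id] @ self.voxel_centre_local(index) + ts[index.module_id]

    def local_to_global(self, module_id: int, pos) -> np.ndarray:
        Rs, ts = self.module_transforms()
        return (np.atleast_2d(pos) @ Rs[module_id].T) + ts[module_id]

    def global_to_local(self, module_id: int, pos) -> np.ndarray:
        Rs, ts = self.module_transforms()
        return (np.atleast_2d(pos) - ts[module_id]) @ Rs[module_id]

    # ------------------------------------------------------------------
    # serialization
    def to_json(self, path) -> None:
        payload = {
            "format": "cztpet-geometry-1",
            "units": {"length": "mm", "angle": "deg"},
            "separation_mm": self.separation,
            "alpha": self.alpha.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SystemGeometry":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "cztpet-geometry-1":
            raise ValueError("unrecognised geometry file format")
        geom = cls.nominal(payload.get("separation_mm", 80.0))
        geom.alpha = np.array(payload["alpha"], dtype=float)
        return geom
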