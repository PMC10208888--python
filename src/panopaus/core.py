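"""Shared data containers for the panoramic PA/US pipeline.

Axis conventions used throughout the package:

* 2D frames are ``(axial z, lateral x)`` arrays; z increases with depth.
* 3D volumes are ``(z, x, y)`` arrays where y is the elevation (mechanical
  scan) direction.
* Physical coordinates are right-handed ``(x, y, z)`` in millimetres, with
  the transducer face at z = 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


def _normalize_angle_deg(a: float) -> float:
    """Reduce an angle to the interval (-180, 180]."""
    r = ((float(a) + 180.0) % 360.0) - 180.0
    if r == -180.0:
        r = 180.0
    return r


@dataclass(frozen=True)
class RigidPose6DOF:
    """A rigid 6-DOF pose: three translations plus three rotations.

    Rotations are intrinsic Euler angles applied in z-y-x order about the
    centre of the volume being posed.  ``translation_mm`` and
    ``rotation_deg`` are ordered as the physical axes (x, y, z) =
    (lateral, elevation, axial).
    """

    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.translation_mm)
        r = tuple(_normalize_angle_deg(v) for v in self.rotation_deg)
        if len(t) != 3 or len(r) != 3:
            raise ValueError("pose requires 3 translations and 3 rotations")
        object.__setattr__(self, "translation_mm", t)
        object.__setattr__(self, "rotation_deg", r)

    @property
    def is_identity(self) -> bool:
        return all(v == 0.0 for v in self.translation_mm) and all(
            v == 0.0 for v in self.rotation_deg
        )

    def rotation(self) -> Rotation:
        rx, ry, rz = self.rotation_deg
        return Rotation.from_euler("ZYX", [rz, ry, rx], degrees=True)

    def rotation_matrix(self) -> np.ndarray:
        """3x3 matrix acting on physical (x, y, z) column vectors."""
        return self.rotation().as_matrix()

    def apply_points(self, points_xyz: np.ndarray, center_xyz) -> np.ndarray:
        """Map physical points: p' = R (p - c) + c + t."""
        p = np.atleast_2d(np.asarray(points_xyz, dtype=float))
        c = np.asarray(center_xyz, dtype=float)
        t = np.asarray(self.translation_mm)
        out = (self.rotation_matrix() @ (p - c).T).T + c + t
        return out.reshape(np.shape(points_xyz))

    def inverse(self) -> "RigidPose6DOF":
        """Pose undoing this one when applied about the same centre."""
        rinv = self.rotation().inv()
        rz, ry, rx = rinv.as_euler("ZYX", degrees=True)
        t_inv = -rinv.apply(np.asarray(self.translation_mm))
        return RigidPose6DOF(tuple(t_inv), (rx, ry, rz))

    def compose(self, first: "RigidPose6DOF") -> "RigidPose6DOF":
        """Pose equivalent to applying ``first`` then ``self``.

        Valid when both poses rotate about the same centre point:
        R = R2 R1, t = R2 t1 + t2.
        """
        r2 = self.rotation()
        r = r2 * first.rotation()
        rz, ry, rx = r.as_euler("ZYX", degrees=True)
        t = r2.apply(np.asarray(first.translation_mm)) + np.asarray(
            self.translation_mm
        )
        return RigidPose6DOF(tuple(t), (rx, ry, rz))


IDENTITY_POSE = RigidPose6DOF()


@dataclass
class RFFrame:
    """One elevational position's multi-channel RF data.

    ``channels`` is an (element, time sample) array of signed amplitudes.
    ``pulse_energy`` is the recorded per-shot laser energy (relative units,
    nominal 1) used for energy calibration downstream.
    """

    channels: np.ndarray
    pulse_energy: float = 1.0
    wavelength_nm: float | None = None
    position_index: int = 0
    elevation_mm: float = 0.0

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2:
            raise ValueError("RF channel data must be 2D (element x sample)")
        if self.pulse_energy <= 0:
            raise ValueError("pulse_energy must be positive")

    @property
    def n_elements(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]


@dataclass
class BeamformedFrame:
    """A reconstructed 2D cross-section (axial x lateral envelope image)."""

    image: np.ndarray
    axial_spacing_mm: float
    lateral_spacing_mm: float
    wavelength_nm: float | None = None
    elevation_mm: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("beamformed image must be 2D (axial x lateral)")
        if self.axial_spacing_mm <= 0 or self.lateral_spacing_mm <= 0:
            raise ValueError("pixel spacings must be positive")


@dataclass
class Volume:
    """A 3D scalar grid with per-axis spacings, pose, and provenance.

    Data axes are (z, x, y).  When the elevation grid is non-uniform (a raw
    scotch-yoke stack before resampling) the true per-frame elevations are
    carried in ``y_coords_mm`` and the y entry of ``spacing_mm`` is the mean
    step; after resampling ``y_coords_mm`` is None.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "pa"
    wavelength_nm: float | None = None
    pose: RigidPose6DOF = field(default_factory=RigidPose6DOF)
    y_coords_mm: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D (z, x, y)")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(s) for s in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacings must be positive")
        if self.y_coords_mm is not None:
            self.y_coords_mm = np.asarray(self.y_coords_mm, dtype=float)
            if self.y_coords_mm.shape != (self.data.shape[2],):
                raise ValueError("y_coords_mm must have one entry per frame")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Grid coordinates (mm) along a data axis (0=z, 1=x, 2=y)."""
        if axis == 2 and self.y_coords_mm is not None:
            return self.origin_mm[2] + self.y_coords_mm
        n = self.data.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(n)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size (z, x, y) spanned by the voxel centres."""
        return tuple(
            float(self.axis_coords(ax)[-1] - self.axis_coords(ax)[0])
            for ax in range(3)
        )

    def center_xyz_mm(self) -> np.ndarray:
        """Physical (x, y, z) centre of the grid."""
        zc, xc, yc = (
            0.5 * (self.axis_coords(ax)[0] + self.axis_coords(ax)[-1])
            for ax in range(3)
        )
        return np.array([xc, yc, zc])

    def with_data(self, data: np.ndarray, **overrides) -> "Volume":
        """Copy of this volume with new data (and optional field overrides)."""
        kwargs = dict(
            spacing_mm=self.spacing_mm,
            origin_mm=self.origin_mm,
            modality=self.modality,
            wavelength_nm=self.wavelength_nm,
            pose=self.pose,
            y_coords_mm=None
            if self.y_coords_mm is None
            else self.y_coords_mm.copy(),
            provenance=list(self.provenance),
        )
        kwargs.update(overrides)
        return Volume(data, **kwargs)

    def log(self, step: str) -> None:
        self.provenance.append(step)


@dataclass(frozen=True)
class GridSpec:
    """Shape, spacing, and origin of a (z, x, y) voxel grid."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(
            self, "spacing_mm", tuple(float(s) for s in self.spacing_mm)
        )
        object.__setattr__(
            self, "origin_mm", tuple(float(s) for s in self.origin_mm)
        )
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape entries must be >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("grid spacings must be positive")

    @classmethod
    def from_volume(cls, volume: Volume) -> "GridSpec":
        return cls(volume.shape, volume.spacing_mm, volume.origin_mm)

    def center_xyz_mm(self) -> np.ndarray:
        zc, xc, yc = (
            self.origin_mm[ax] + 0.5 * self.spacing_mm[ax] * (self.shape[ax] - 1)
            for ax in range(3)
        )
        return np.array([xc, yc, zc])


def asdict_pose(pose: RigidPose6DOF) -> dict:
    return dataclasses.asdict(pose)
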