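"""Mosaic stitching of PA/US volumes: 6-DOF placement, blending, rendering.

Each acquired volume carries a rigid 6-DOF pose (3 translations + 3
rotations, intrinsic z-y-x Euler about the volume centre) placing it in a
common panorama frame.  Volumes are resampled (trilinear) onto the union
grid — the panoramic analogue of zero-padding every volume to the overall
size — and overlaps are blended with apodization (window) weighting to
suppress seams.  Rendering helpers produce maximum amplitude/intensity
projections, depth-encoded images, and the cumulative online-preview MAP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import GridSpec, RigidPose6DOF, Volume

__all__ = [
    "RigidPose6DOF",
    "Panorama",
    "apply_pose",
    "union_extent",
    "blend",
    "map_projection",
    "depth_encode",
    "cumulative_map",
]


def _index_to_phys_matrix(spacing_mm) -> np.ndarray:
    """Matrix B mapping (i_z, i_x, i_y) index vectors to (x, y, z) mm."""
    dz, dx, dy = spacing_mm
    perm = np.array([[0.0, 1.0, 0.0],
                     [0.0, 0.0, 1.0],
                     [1.0, 0.0, 0.0]])
    return perm @ np.diag([dz, dx, dy])


def _origin_phys(origin_mm) -> np.ndarray:
    z0, x0, y0 = origin_mm
    return np.array([x0, y0, z0])


def apply_pose(
    volume: Volume,
    pose: RigidPose6DOF,
    target_grid: GridSpec | None = None,
    order: int = 1,
    center_xyz_mm: np.ndarray | None = None,
) -> Volume:
    """Rigidly transform a volume and resample it onto a target grid.

    The pose maps physical points as ``p' = R (p - c) + c + t`` where c is
    the input volume's centre (or an explicit ``center_xyz_mm``).
    Resampling is trilinear (``order=1``); nearest-neighbour (``order=0``)
    is available for label masks.  Voxels outside the transformed
    footprint are zero.
    """
    if target_grid is None:
        target_grid = GridSpec.from_volume(volume)
    if any(n < 1 for n in target_grid.shape):
        raise ValueError("degenerate target grid")
    c = (volume.center_xyz_mm() if center_xyz_mm is None
         else np.asarray(center_xyz_mm, dtype=float))
    R = pose.rotation_matrix()
    t = np.asarray(pose.translation_mm)
    B_in = _index_to_phys_matrix(volume.spacing_mm)
    B_t = _index_to_phys_matrix(target_grid.spacing_mm)
    B_in_inv = np.linalg.inv(B_in)
    A = B_in_inv @ R.T @ B_t
    b = B_in_inv @ (
        R.T @ (_origin_phys(target_grid.origin_mm) - c - t)
        + c
        - _origin_phys(volume.origin_mm)
    )
    data = ndimage.affine_transform(
        volume.data, A, offset=b, output_shape=target_grid.shape,
        order=order, mode="constant", cval=0.0,
    )
    out = Volume(
        data=data,
        spacing_mm=target_grid.spacing_mm,
        origin_mm=target_grid.origin_mm,
        modality=volume.modality,
        wavelength_nm=volume.wavelength_nm,
        provenance=list(volume.provenance),
    )
    out.log(f"apply_pose(t={pose.translation_mm}, r={pose.rotation_deg})")
    return out


def _transformed_corners(volume: Volume, pose: RigidPose6DOF) -> np.ndarray:
    nz, nx, ny = volume.shape
    corners_idx = np.array(
        [(i, j, k) for i in (0, nz - 1) for j in (0, nx - 1)
         for k in (0, ny - 1)],
        dtype=float,
    )
    B = _index_to_phys_matrix(volume.spacing_mm)
    phys = (B @ corners_idx.T).T + _origin_phys(volume.origin_mm)
    return pose.apply_points(phys, volume.center_xyz_mm())


def union_extent(
    volumes_poses: list[tuple[Volume, RigidPose6DOF]],
) -> GridSpec:
    """Axis-aligned bounding grid of all posed volumes.

    Spacing is the finest input spacing per axis; the box is padded to
    whole voxels.
    """
    if not volumes_poses:
        raise ValueError("at least one volume is required")
    all_corners = np.vstack(
        [_transformed_corners(v, p) for v, p in volumes_poses]
    )
    lo = all_corners.min(axis=0)  # (x, y, z)
    hi = all_corners.max(axis=0)
    spacing = tuple(
        min(v.spacing_mm[ax] for v, _ in volumes_poses) for ax in range(3)
    )  # (dz, dx, dy)
    extent_phys = hi - lo  # (x, y, z)
    extent_zxy = np.array([extent_phys[2], extent_phys[0], extent_phys[1]])
    shape = tuple(
        int(np.ceil(extent_zxy[ax] / spacing[ax] - 1e-9)) + 1
        for ax in range(3)
    )
    origin = (float(lo[2]), float(lo[0]), float(lo[1]))  # (z, x, y)
    return GridSpec(shape=shape, spacing_mm=spacing, origin_mm=origin)


@dataclass
class Panorama:
    """A set of posed volumes blended onto a common grid."""

    volumes: list[tuple[Volume, RigidPose6DOF]]
    extent: GridSpec
    blended: Volume | None = None
    weights: list[np.ndarray] = field(default_factory=list)


def _apodization_weights(
    volume: Volume, apodization: str, ramp_mm: float | None
) -> np.ndarray:
    """Per-voxel blending weight on the input grid (before posing).

    The weight ramps up from every face of the volume over ``ramp_mm``
    (default: half the axis extent, i.e. a full-width window) with the
    chosen profile, and is floored at a tiny positive value so single-
    coverage voxels always normalize back to their own data.
    """
    if apodization == "none":
        return np.ones(volume.shape)
    w = np.ones(volume.shape)
    for ax in range(3):
        coords = volume.axis_coords(ax)
        extent = coords[-1] - coords[0]
        if extent <= 0:
            continue
        half = extent / 2.0
        ramp = half if ramp_mm is None else min(ramp_mm, half)
        d = np.minimum(coords - coords[0], coords[-1] - coords)
        u = np.clip(d / ramp, 0.0, 1.0)
        if apodization == "linear":
            prof = u
        elif apodization == "hann":
            prof = np.sin(0.5 * np.pi * u) ** 2
        else:
            raise ValueError(f"unknown apodization {apodization!r}")
        shape = [1, 1, 1]
        shape[ax] = prof.size
        w = w * prof.reshape(shape)
    return np.maximum(w, 1e-6)


def blend(
    panorama: Panorama | list[tuple[Volume, RigidPose6DOF]],
    apodization: str = "linear",
    ramp_mm: float | None = None,
) -> Volume:
    """Blend posed volumes onto the union grid with apodization weighting.

    Per voxel the output is the weight-normalized average of all covering
    volumes; weights come from the chosen window ramped across each
    volume's margin, so seams fade smoothly across overlaps.  With
    ``apodization='none'`` overlaps are plain unweighted averages.
    """
    if ramp_mm is not None and ramp_mm < 0:
        raise ValueError("ramp_mm must be non-negative")
    if isinstance(panorama, Panorama):
        entries = panorama.volumes
        grid = panorama.extent
    else:
        entries = list(panorama)
        grid = union_extent(entries)
        panorama = Panorama(volumes=entries, extent=grid)
    num = np.zeros(grid.shape)
    den = np.zeros(grid.shape)
    panorama.weights = []
    for vol, pose in entries:
        w_local = _apodization_weights(vol, apodization, ramp_mm)
        moved = apply_pose(vol, pose, grid)
        w_vol = vol.with_data(w_local)
        moved_w = apply_pose(w_vol, pose, grid)
        footprint_vol = vol.with_data(np.ones(vol.shape))
        footprint = apply_pose(footprint_vol, pose, grid).data > 0.5
        w = np.where(footprint, np.maximum(moved_w.data, 1e-6), 0.0)
        num += w * moved.data
        den += w
        panorama.weights.append(w)
    covered = den > 0
    blended = np.where(covered, num / np.where(covered, den, 1.0), 0.0)
    # store normalized weights (sum to 1 wherever covered)
    panorama.weights = [
        np.where(covered, w / np.where(covered, den, 1.0), 0.0)
        for w in panorama.weights
    ]
    ref = entries[0][0]
    out = Volume(
        data=blended,
        spacing_mm=grid.spacing_mm,
        origin_mm=grid.origin_mm,
        modality=ref.modality,
        wavelength_nm=ref.wavelength_nm,
        provenance=[f"blend(apodization={apodization}, n={len(entries)})"],
    )
    panorama.blended = out
    return out


def map_projection(volume: Volume, axis: int = 0) -> np.ndarray:
    """Maximum amplitude/intensity projection along an axis (default axial)."""
    return volume.data.max(axis=axis)


def depth_encode(volume: Volume, threshold: float = 0.0) -> np.ndarray:
    """Depth (mm) of the per-column axial maximum; NaN below threshold."""
    idx = np.argmax(volume.data, axis=0)
    peak = volume.data.max(axis=0)
    depth = volume.origin_mm[0] + volume.spacing_mm[0] * idx
    return np.where(peak > threshold, depth, np.nan)


def cumulative_map(frames, n_total: int | None = None):
    """Online cumulative MAP: yield the projection image after each frame.

    ``frames`` is an iterable of (z, x) cross-sections streamed in scan
    order.  The k-th yielded image is the (x, y) projection with columns
    0..k-1 filled by each frame's axial maximum and the rest still zero;
    the final image equals the full-stack MAP.
    """
    frames = list(frames)
    if not frames:
        return
    shape0 = frames[0].shape
    if any(f.shape != shape0 for f in frames):
        raise ValueError("all frames must share a shape")
    if n_total is None:
        n_total = len(frames)
    canvas = np.zeros((shape0[1], n_total))
    for k, frame in enumerate(frames):
        canvas[:, k] = frame.max(axis=0)
        yield canvas.copy()
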