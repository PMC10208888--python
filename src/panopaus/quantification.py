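"""Phantom-style performance metrics: peak SNR, FWHM resolution, depth slope.

Conventions: pSNR of a target is ``20 log10(peak signal / noise std)`` in
dB, with the signal and noise regions given as explicit boxes so any
convention can be audited.  ApSNR is the average of per-frame pSNRs over
all frames in all repeat volumes.  FWHM is measured by sub-sample linear
interpolation of the half-maximum crossings of a 1D profile through the
target peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Volume

__all__ = [
    "Box2D",
    "QuantReport",
    "TargetReport",
    "psnr",
    "apsnr_improvement",
    "fwhm",
    "depth_slope",
    "thread_report",
]


@dataclass(frozen=True)
class Box2D:
    """An axis-aligned rectangle in frame coordinates (mm)."""

    z_min_mm: float
    z_max_mm: float
    x_min_mm: float
    x_max_mm: float

    def __post_init__(self) -> None:
        if self.z_min_mm >= self.z_max_mm or self.x_min_mm >= self.x_max_mm:
            raise ValueError("box extents must be positive")

    def overlaps(self, other: "Box2D") -> bool:
        return not (
            self.z_max_mm <= other.z_min_mm
            or other.z_max_mm <= self.z_min_mm
            or self.x_max_mm <= other.x_min_mm
            or other.x_max_mm <= self.x_min_mm
        )

    def slices(
        self, spacing: tuple[float, float], origin: tuple[float, float],
        shape: tuple[int, int],
    ) -> tuple[slice, slice]:
        eps = 1e-9
        z0 = int(np.floor((self.z_min_mm - origin[0]) / spacing[0] + eps))
        z1 = int(np.ceil((self.z_max_mm - origin[0]) / spacing[0] - eps)) + 1
        x0 = int(np.floor((self.x_min_mm - origin[1]) / spacing[1] + eps))
        x1 = int(np.ceil((self.x_max_mm - origin[1]) / spacing[1] - eps)) + 1
        if z0 < 0 or x0 < 0 or z1 > shape[0] or x1 > shape[1]:
            raise ValueError("box falls outside the frame")
        return slice(z0, z1), slice(x0, x1)


def psnr(
    frame: np.ndarray,
    signal_box: Box2D,
    noise_box: Box2D,
    spacing_mm: tuple[float, float],
    origin_mm: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Peak SNR in dB: 20 log10(max over signal box / std over noise box)."""
    frame = np.asarray(frame, dtype=float)
    if signal_box.overlaps(noise_box):
        raise ValueError("signal and noise boxes must be disjoint")
    sz, sx = signal_box.slices(spacing_mm, origin_mm, frame.shape)
    nz, nx = noise_box.slices(spacing_mm, origin_mm, frame.shape)
    peak = frame[sz, sx].max()
    noise_std = frame[nz, nx].std()
    if noise_std <= 0:
        raise ValueError("noise box has zero standard deviation")
    return float(20.0 * np.log10(peak / noise_std))


def apsnr_improvement(apsnr_a, apsnr_b) -> float:
    """Mean elementwise ApSNR difference (a - b), in dB."""
    a = np.asarray(apsnr_a, dtype=float)
    b = np.asarray(apsnr_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("ApSNR lists must have equal length")
    return float(np.mean(a - b))


def fwhm(profile: np.ndarray, spacing: float = 1.0) -> float:
    """Full width at half maximum of a single-peaked 1D profile.

    Requires a unique connected region above half-maximum; the two
    half-maximum crossings are located with sub-sample linear
    interpolation.  Profiles whose above-half region is disconnected
    (multi-modal) are rejected.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or p.size < 3:
        raise ValueError("profile must be 1D with at least 3 samples")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    half = p.max() / 2.0
    above = p > half
    if not above.any():
        raise ValueError("profile has no samples above half maximum")
    runs = np.flatnonzero(np.diff(above.astype(int)) != 0)
    segments = (runs.size + (1 if above[0] else 0) + (1 if above[-1] else 0))
    if segments > 2:
        raise ValueError(
            "profile is multi-modal above half maximum; cannot assign a "
            "unique FWHM"
        )
    idx = np.flatnonzero(above)
    i0, i1 = idx[0], idx[-1]
    # left crossing between i0-1 and i0
    if i0 == 0:
        left = 0.0
    else:
        left = i0 - 1 + (half - p[i0 - 1]) / (p[i0] - p[i0 - 1])
    if i1 == p.size - 1:
        right = float(p.size - 1)
    else:
        right = i1 + (p[i1] - half) / (p[i1] - p[i1 + 1])
    return float((right - left) * spacing)


def depth_slope(depths_mm, apsnr_db) -> float:
    """Magnitude of the least-squares ApSNR-vs-depth slope, dB/mm."""
    d = np.asarray(depths_mm, dtype=float)
    a = np.asarray(apsnr_db, dtype=float)
    if d.size != a.size or d.size < 2:
        raise ValueError("need matching lists of at least 2 points")
    if np.ptp(d) == 0:
        raise ValueError("depths must not be constant")
    slope = np.polyfit(d, a, 1)[0]
    return float(abs(slope))


@dataclass
class TargetReport:
    depth_mm: float
    psnr_db_per_frame: list[float]
    apsnr_db: float
    fwhm_axial_um: float | None = None
    fwhm_lateral_um: float | None = None
    fwhm_elevation_um: float | None = None


@dataclass
class QuantReport:
    """Per-target metrics plus the fitted depth-attenuation slope."""

    per_target: list[TargetReport]
    slope_db_per_mm: float
    boxes: dict = field(default_factory=dict)

    @property
    def apsnr_db(self) -> list[float]:
        return [t.apsnr_db for t in self.per_target]


def _profile_through(data: np.ndarray, peak_idx, axis: int) -> np.ndarray:
    sl = list(peak_idx)
    sl[axis] = slice(None)
    return data[tuple(sl)]


def thread_report(
    volume: Volume,
    target_depths_mm,
    signal_halfwidth_mm: float = 2.0,
    noise_box: Box2D | None = None,
) -> QuantReport:
    """Quantify thread targets in an assembled phantom volume.

    For each expected target depth, the peak voxel within a +-half-width
    axial band is located; per-frame pSNRs are computed against a noise
    box (default: a region above the shallowest target), profiles through
    the peak give FWHM in the three axes, and the ApSNR-vs-depth slope is
    fitted by least squares.
    """
    dz, dx, dy = volume.spacing_mm
    nz, nx, ny = volume.shape
    z = volume.axis_coords(0)
    x = volume.axis_coords(1)
    depths = [float(d) for d in target_depths_mm]
    if noise_box is None:
        top = min(depths) - signal_halfwidth_mm
        noise_box = Box2D(max(top - 4.0, z[0]), max(top - 0.5, z[0] + dz),
                          x[0], x[-1])
    targets = []
    boxes = {"noise": noise_box, "signal": {}}
    for d in depths:
        band = (z >= d - signal_halfwidth_mm) & (z <= d + signal_halfwidth_mm)
        if not band.any():
            raise ValueError(
                f"target depth {d} mm lies outside the volume "
                f"(z covers {z[0]:.1f}-{z[-1]:.1f} mm)"
            )
        sub = volume.data[band]
        flat = int(np.argmax(sub))
        iz_b, ix, iy = np.unravel_index(flat, sub.shape)
        iz = int(np.flatnonzero(band)[iz_b])
        peak_idx = (iz, int(ix), int(iy))
        sig_box = Box2D(
            z[iz] - signal_halfwidth_mm, z[iz] + signal_halfwidth_mm,
            max(x[ix] - signal_halfwidth_mm, x[0]),
            min(x[ix] + signal_halfwidth_mm, x[-1]),
        )
        boxes["signal"][d] = sig_box
        frame_psnrs = []
        for k in range(ny):
            frame = volume.data[:, :, k]
            if frame.max() <= 0:
                continue
            try:
                frame_psnrs.append(
                    psnr(frame, sig_box, noise_box, (dz, dx),
                         (float(z[0]), float(x[0])))
                )
            except ValueError:
                continue
        widths = {}
        for axis, sp, key in (
            (0, dz, "axial"), (1, dx, "lateral"), (2, dy, "elevation")
        ):
            try:
                widths[key] = fwhm(
                    _profile_through(volume.data, peak_idx, axis), sp
                ) * 1000.0
            except ValueError:
                widths[key] = None
        targets.append(
            TargetReport(
                depth_mm=d,
                psnr_db_per_frame=frame_psnrs,
                apsnr_db=float(np.mean(frame_psnrs)) if frame_psnrs
                else float("nan"),
                fwhm_axial_um=widths["axial"],
                fwhm_lateral_um=widths["lateral"],
                fwhm_elevation_um=widths["elevation"],
            )
        )
    slope = depth_slope(depths, [t.apsnr_db for t in targets]) \
        if len(targets) >= 2 else float("nan")
    return QuantReport(per_target=targets, slope_db_per_mm=slope, boxes=boxes)
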