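"""Assemble beamformed frames into volumes: stack, resample, de-skin, flatten.

The scotch-yoke scan produces frames at sinusoidally varying elevational
positions, so the raw stack carries an explicit non-uniform y coordinate.
``resample_uniform`` interpolates it onto an arithmetic grid (default
0.059 mm).  Skin is then located on the co-registered US volume, the PA
volume is zeroed down to a fixed offset below the contour (default 40
axial pixels = 0.77 mm at the 19.25 um axial pitch), and depth-dependent
optical fluence is compensated by normalizing each frame's rows (indexed
relative to the skin) by their background level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.interpolate import interp1d

from .core import BeamformedFrame, Volume

__all__ = [
    "SkinContour",
    "stack_frames",
    "resample_uniform",
    "detect_skin",
    "remove_skin",
    "fluence_compensate",
]

DEFAULT_UNIFORM_STEP_MM = 0.059
DEFAULT_SKIN_OFFSET_PIXELS = 40


@dataclass
class SkinContour:
    """Per-(lateral, elevation) column first axial index of skin."""

    depth_index: np.ndarray  # (nx, ny) int
    threshold: float
    smooth_window: int

    def __post_init__(self) -> None:
        self.depth_index = np.asarray(self.depth_index, dtype=int)
        if self.depth_index.ndim != 2:
            raise ValueError("depth_index must be 2D (lateral x elevation)")
        if (self.depth_index < 0).any():
            raise ValueError("depth indices must be non-negative")


def stack_frames(
    frames: list[BeamformedFrame],
    positions_mm: np.ndarray,
    modality: str = "pa",
) -> Volume:
    """Stack 2D frames along elevation into a (z, x, y) volume.

    The (generally non-uniform) per-frame elevations are carried as the
    volume's explicit y coordinates until resampling.
    """
    if not frames:
        raise ValueError("at least one frame is required")
    positions = np.asarray(positions_mm, dtype=float)
    if positions.shape != (len(frames),):
        raise ValueError("one elevational position per frame is required")
    if len(positions) > 1 and not (np.diff(positions) > 0).all():
        raise ValueError("elevational positions must be strictly increasing")
    first = frames[0]
    for f in frames[1:]:
        if f.image.shape != first.image.shape:
            raise ValueError("all frames must share the same image shape")
        if f.wavelength_nm != first.wavelength_nm:
            raise ValueError("all frames must share the same wavelength")
        if (f.axial_spacing_mm, f.lateral_spacing_mm) != (
            first.axial_spacing_mm, first.lateral_spacing_mm
        ):
            raise ValueError("all frames must share the same pixel spacings")
    data = np.stack([f.image for f in frames], axis=2)
    mean_dy = float(np.mean(np.diff(positions))) if len(positions) > 1 else 1.0
    nx = first.image.shape[1]
    origin_x = -first.lateral_spacing_mm * (nx - 1) / 2.0
    vol = Volume(
        data=data,
        spacing_mm=(first.axial_spacing_mm, first.lateral_spacing_mm, mean_dy),
        origin_mm=(0.0, origin_x, float(positions[0])),
        modality=modality,
        wavelength_nm=first.wavelength_nm,
        y_coords_mm=positions - positions[0],
        provenance=[f"stack_frames(n={len(frames)})"],
    )
    return vol


def resample_uniform(
    volume: Volume, target_step_mm: float = DEFAULT_UNIFORM_STEP_MM
) -> Volume:
    """Linearly interpolate the elevation axis onto a uniform grid.

    The output grid runs from 0 to the scan range in steps of
    ``target_step_mm`` (floor(range/step)+1 planes), strictly inside the
    input coordinates so no extrapolation ever occurs.  x and z are
    untouched.
    """
    if target_step_mm <= 0:
        raise ValueError("target_step_mm must be positive")
    if volume.shape[2] < 2:
        raise ValueError("resampling requires at least 2 frames")
    y_old = (volume.y_coords_mm if volume.y_coords_mm is not None
             else volume.spacing_mm[2] * np.arange(volume.shape[2]))
    y_span = float(y_old[-1] - y_old[0])
    n_new = int(np.floor(y_span / target_step_mm + 1e-9)) + 1
    y_new = y_old[0] + target_step_mm * np.arange(n_new)
    f = interp1d(y_old, volume.data, axis=2, kind="linear",
                 assume_sorted=True, copy=False)
    data = f(y_new)
    out = volume.with_data(
        data,
        spacing_mm=(volume.spacing_mm[0], volume.spacing_mm[1], target_step_mm),
        y_coords_mm=None,
    )
    out.log(f"resample_uniform(step={target_step_mm} mm)")
    return out


def detect_skin(
    us_volume: Volume,
    threshold: float = 0.5,
    smooth_window: int = 11,
) -> SkinContour:
    """Locate the skin surface on a US volume by threshold crossing.

    Per (x, y) column, the first axial sample exceeding
    ``threshold x column max`` is taken; the resulting index map is
    median-smoothed over a ``smooth_window``-column square.  Columns with
    no crossing (all-zero columns) inherit the median of valid columns;
    an entirely empty volume is rejected.
    """
    if us_volume.modality != "us":
        raise ValueError("skin detection runs on the US volume")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    data = us_volume.data
    col_max = data.max(axis=0)
    valid = col_max > 0
    if not valid.any():
        raise ValueError("cannot detect skin on an all-zero US volume")
    above = data > (threshold * np.where(valid, col_max, np.inf))
    idx = np.argmax(above, axis=0)  # first True per column
    if (~valid).any():
        idx = idx.astype(float)
        idx[~valid] = np.median(idx[valid])
        idx = idx.astype(int)
    win = max(int(smooth_window), 1)
    smoothed = ndimage.median_filter(
        idx, size=(min(win, idx.shape[0]), min(win, idx.shape[1]))
    )
    return SkinContour(
        depth_index=smoothed, threshold=threshold, smooth_window=win
    )


def remove_skin(
    pa_volume: Volume,
    contour: SkinContour,
    offset_pixels: int = DEFAULT_SKIN_OFFSET_PIXELS,
) -> Volume:
    """Zero all voxels above skin + offset (default 40 pixels = 0.77 mm).

    Each cross-sectional PA image is segmented from a fixed depth below
    the skin contour, discarding the strong skin-surface PA signal.
    """
    if contour.depth_index.shape != pa_volume.shape[1:]:
        raise ValueError("contour grid does not match the PA volume")
    nz = pa_volume.shape[0]
    cut = contour.depth_index + int(offset_pixels)
    if (cut >= nz).all():
        warnings.warn(
            "skin offset pushes past the bottom of the volume; "
            "the result is all zero",
            stacklevel=2,
        )
    z_idx = np.arange(nz)[:, None, None]
    data = np.where(z_idx < cut[None, :, :], 0.0, pa_volume.data)
    out = pa_volume.with_data(data)
    out.log(f"remove_skin(offset_pixels={int(offset_pixels)})")
    return out


def _frame_background(
    frame: np.ndarray,
    skin_idx: np.ndarray,
    signal_threshold: float,
    smooth_rows: int = 0,
    quantile: float = 0.25,
) -> np.ndarray:
    """Per skin-relative-depth-row background level for one (z, x) frame.

    Rows are indexed relative to the skin contour.  The background level
    of a row is a low quantile (default the lower quartile) of its
    sub-threshold voxels pooled across the lateral direction.  The low
    quantile, rather than the median, keeps sidelobe clutter around
    strong absorbers — which inflates the upper part of the in-row
    amplitude distribution, and does so wavelength-dependently — from
    biasing the estimate; the clutter-free columns populate the lower
    quartile.  Rows without background voxels inherit the nearest valid
    row's level.
    """
    nz, nx = frame.shape
    fmax = frame.max()
    if fmax <= 0:
        return np.ones(nz)
    # align columns so row r means "r pixels below the skin"
    rows = np.arange(nz)[:, None] + skin_idx[None, :]  # source z per (r, x)
    valid_src = rows < nz
    rows_c = np.minimum(rows, nz - 1)
    aligned = frame[rows_c, np.arange(nx)[None, :]]
    background_ok = valid_src & (aligned < signal_threshold * fmax) \
        & (aligned > 0)
    if not background_ok.any():
        # frame is pure background (nothing below the relative threshold):
        # self-normalize on all positive voxels
        background_ok = valid_src & (aligned > 0)
    aligned_masked = np.where(background_ok, aligned, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        levels = np.nanquantile(aligned_masked, quantile, axis=1)
    good = np.isfinite(levels) & (levels > 0)
    if not good.any():
        return np.ones(nz)
    r = np.arange(nz)
    levels = np.interp(r, r[good], levels[good])
    if smooth_rows > 1:
        # optical fluence varies smoothly with depth; median-smoothing the
        # per-row levels rejects rows whose background estimate is inflated
        # by clutter around strong absorbers
        levels = ndimage.median_filter(
            levels, size=min(smooth_rows | 1, nz), mode="nearest"
        )
    return levels


def _fit_decay_profile(levels: np.ndarray) -> np.ndarray:
    """Robust exponential fit of background level vs skin-relative depth.

    Optical fluence in reasonably homogeneous soft tissue decays close to
    exponentially with depth, so the per-row background levels are
    summarized by a Theil-Sen fit of log(level) against row index.  The
    robust fit rides the clutter-free rows and bridges depth bands where
    strong absorbers contaminate the row-wise estimate.
    """
    nz = levels.size
    r = np.arange(nz)
    good = np.isfinite(levels) & (levels > 0)
    if good.sum() < 8:
        return levels
    rg, lg = r[good], levels[good]
    if rg.size > 300:  # decimate: Theil-Sen is O(n^2) in pairs
        step = rg.size // 300 + 1
        rg, lg = rg[::step], lg[::step]
    slope, intercept, *_ = stats.theilslopes(np.log(lg), rg)
    return np.exp(intercept + slope * r)


def fluence_compensate(
    pa_volume: Volume,
    contour: SkinContour,
    signal_threshold: float = 0.1,
    smooth_mm: float = 0.0,
    quantile: float = 0.25,
    profile: str = "rowwise",
) -> Volume:
    """Normalize each frame by its background PA level per depth row.

    Depth rows are indexed relative to the skin contour, matching the
    intent of compensating optical fluence decay beneath the skin.  Each
    wavelength's volume is normalized independently (this function sees
    one volume at a time).

    ``profile`` selects the depth model for the divisor: ``"rowwise"``
    (default) divides by the per-row background levels, following any
    measured background shape; ``"exponential"`` instead fits a robust
    exponential decay to the row levels, which suits quasi-homogeneous
    tissue but assumes clutter-contaminated depth bands are a small
    minority of the rows.  A positive ``smooth_mm`` additionally
    median-smooths the row levels across depth before use.  All-zero
    frames pass through unchanged.
    """
    if profile not in ("exponential", "rowwise"):
        raise ValueError("profile must be 'exponential' or 'rowwise'")
    if contour.depth_index.shape != pa_volume.shape[1:]:
        raise ValueError("contour grid does not match the PA volume")
    nz, nx, ny = pa_volume.shape
    smooth_rows = int(round(smooth_mm / pa_volume.spacing_mm[0]))
    data = pa_volume.data.copy()
    for k in range(ny):
        frame = data[:, :, k]
        if frame.max() <= 0:
            continue
        skin_idx = contour.depth_index[:, k]
        levels = _frame_background(
            frame, skin_idx, signal_threshold, smooth_rows, quantile
        )
        if profile == "exponential":
            levels = _fit_decay_profile(levels)
        # per-column divisor: level of the row's skin-relative depth
        rel = np.arange(nz)[:, None] - skin_idx[None, :]
        rel_c = np.clip(rel, 0, nz - 1)
        divisor = levels[rel_c]
        data[:, :, k] = frame / divisor
    out = pa_volume.with_data(data)
    out.log(f"fluence_compensate(signal_threshold={signal_threshold})")
    return out
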