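"""Scotch-yoke scan kinematics, timing, field-of-view, and laser safety.

The handheld scanner sweeps a 1D linear array through the elevation
direction using a scotch-yoke mechanism: a motor arm of length R rotates
from angle ``theta_start`` to ``theta_end`` and its horizontal projection
drives the probe.  The elevational position at motor angle theta is
``y = R (cos theta_start - cos theta)``, so uniform motor steps produce
sinusoidally varying imaging step sizes dy across the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import RigidPose6DOF

__all__ = [
    "ScannerSpec",
    "ScanPlan",
    "SamplingCheck",
    "TimingPlan",
    "DEFAULT_SPEC",
    "step_size",
    "scan_positions",
    "step_sizes",
    "check_elevation_sampling",
    "frame_period_from_prf",
    "plan_timing",
    "panorama_fov",
    "mpe_skin",
    "make_scan_plan",
]


@dataclass(frozen=True)
class ScannerSpec:
    """Immutable description of the transducer + scotch-yoke scanner.

    Defaults describe the handheld scanner this package models: a
    128-element, 38.4 mm aperture linear array (8.5 MHz centre frequency,
    >=62% fractional bandwidth, 40 MHz sampling) swept by a 15 mm motor
    arm between 32 and 145 degrees, acquiring 83 frames per scan at one
    frame per 0.2 s.
    """

    arm_length_mm: float = 15.0
    theta_start_deg: float = 32.0
    theta_end_deg: float = 145.0
    frames_per_scan: int = 83
    frame_period_s: float = 0.2
    n_elements: int = 128
    lateral_aperture_mm: float = 38.4
    center_freq_mhz: float = 8.5
    fractional_bandwidth: float = 0.62
    sampling_freq_mhz: float = 40.0
    sound_speed_m_s: float = 1540.0
    elevation_beamwidth_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.arm_length_mm <= 0:
            raise ValueError("arm_length_mm must be positive")
        if not (0.0 <= self.theta_start_deg < self.theta_end_deg <= 180.0):
            raise ValueError(
                "scan angles must satisfy 0 <= theta_start < theta_end <= 180"
            )
        if self.frames_per_scan < 2:
            raise ValueError("frames_per_scan must be at least 2")
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be positive")
        for name in (
            "n_elements",
            "lateral_aperture_mm",
            "center_freq_mhz",
            "fractional_bandwidth",
            "sampling_freq_mhz",
            "sound_speed_m_s",
            "elevation_beamwidth_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def pitch_mm(self) -> float:
        """Element pitch: lateral aperture / element count."""
        return self.lateral_aperture_mm / self.n_elements

    @property
    def axial_pixel_mm(self) -> float:
        """Axial pixel pitch on the US-grid convention, c / (2 fs)."""
        return self.sound_speed_m_s / (2.0 * self.sampling_freq_mhz * 1e6) * 1e3

    @property
    def scan_range_mm(self) -> float:
        """Full elevational scan range yScan."""
        return step_size(
            self.arm_length_mm, self.theta_start_deg, self.theta_end_deg
        )


DEFAULT_SPEC = ScannerSpec()


def step_size(R: float, theta_i: float, theta_f: float) -> float:
    """Elevational travel dy = R (cos theta_i - cos theta_f), in mm.

    ``theta_i`` and ``theta_f`` are motor angles in degrees at the previous
    and subsequent imaging positions; the full scan range follows from the
    same formula with the first and last scan angles.
    """
    if R <= 0:
        raise ValueError("motor arm length R must be positive")
    return float(
        R * (np.cos(np.deg2rad(theta_i)) - np.cos(np.deg2rad(theta_f)))
    )


def scan_positions(spec: ScannerSpec) -> np.ndarray:
    """Per-frame elevational positions y_k (mm) over one full scan.

    The motor angle advances in ``frames_per_scan - 1`` uniform increments
    spanning [theta_start, theta_end], so the first frame sits at y = 0 and
    the last exactly at the full scan range.
    """
    thetas = np.linspace(
        spec.theta_start_deg, spec.theta_end_deg, spec.frames_per_scan
    )
    return spec.arm_length_mm * (
        np.cos(np.deg2rad(spec.theta_start_deg)) - np.cos(np.deg2rad(thetas))
    )


def step_sizes(spec: ScannerSpec) -> np.ndarray:
    """The sinusoidally varying dy sequence (consecutive position diffs)."""
    return np.diff(scan_positions(spec))


@dataclass(frozen=True)
class SamplingCheck:
    """Result of the elevation-direction spatial sampling check."""

    passed: bool
    max_step_mm: float
    limit_mm: float

    @property
    def margin_mm(self) -> float:
        """Positive when sampling is fine: limit - max step."""
        return self.limit_mm - self.max_step_mm


def check_elevation_sampling(spec: ScannerSpec) -> SamplingCheck:
    """Check that every step stays below half the elevation beam-width.

    Sampling finer than half the -6 dB round-trip elevation beam-width
    avoids spatial aliasing along the scan direction.  The comparison is a
    strict inequality on the largest step.
    """
    if spec.elevation_beamwidth_mm <= 0:
        raise ValueError("elevation_beamwidth_mm must be positive")
    max_step = float(np.max(step_sizes(spec)))
    limit = spec.elevation_beamwidth_mm / 2.0
    return SamplingCheck(passed=max_step < limit, max_step_mm=max_step, limit_mm=limit)


def frame_period_from_prf(prf_hz: float, pulses_per_frame: int = 2) -> float:
    """Image acquisition period from laser PRF and pulses needed per frame.

    With a 64-channel acquisition system and a 128-element array, two laser
    pulses are needed per full-aperture PA frame, so a 10 Hz PRF gives a
    0.2 s frame period.
    """
    if prf_hz <= 0:
        raise ValueError("PRF must be positive")
    if pulses_per_frame < 1:
        raise ValueError("pulses_per_frame must be >= 1")
    return pulses_per_frame / prf_hz


@dataclass(frozen=True)
class TimingPlan:
    per_scan_s: float
    total_s: float


def plan_timing(
    frame_period_s: float,
    p: int,
    q: int,
    n: int,
    per_scan_override_s: float | None = None,
) -> TimingPlan:
    """Scan timing: per-scan time = frame period x p frames x q wavelengths.

    To keep the step size dy identical regardless of the number of
    wavelengths q, the motor turns q times slower, multiplying the scan
    time by q.  ``per_scan_override_s`` replaces the single-wavelength scan
    duration (still multiplied by q) when the realized per-scan time is
    known more precisely than ``frame_period_s * p``.
    """
    if frame_period_s <= 0:
        raise ValueError("frame_period_s must be positive")
    if per_scan_override_s is not None and per_scan_override_s <= 0:
        raise ValueError("per_scan_override_s must be positive")
    if min(p, q, n) < 1:
        raise ValueError("counts p, q, n must all be >= 1")
    if per_scan_override_s is not None:
        per_scan = per_scan_override_s * q
    else:
        per_scan = frame_period_s * p * q
    return TimingPlan(per_scan_s=per_scan, total_s=per_scan * n)


def panorama_fov(
    scan_range_mm: float,
    lateral_mm: float,
    n: int,
    overlap_mm: float = 0.0,
) -> tuple[float, float]:
    """(lateral, elevational) extent in mm of an n-position panoramic plan.

    Consecutive scan positions are advanced by ``scan_range - overlap``
    along elevation, so the elevational extent is
    ``n * scan_range - (n - 1) * overlap`` and the lateral extent is the
    aperture width, unchanged.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= overlap_mm < scan_range_mm):
        raise ValueError("overlap must satisfy 0 <= overlap < scan range")
    elevational = n * scan_range_mm - (n - 1) * overlap_mm
    return (lateral_mm, elevational)


def mpe_skin(wavelength_nm: float) -> float:
    """ANSI skin maximum permissible exposure for a pulsed laser, mJ/cm^2.

    Valid for 700-1050 nm where the limit is 20 x 10^(0.002 (lambda - 700))
    mJ/cm^2; wavelengths outside that band are rejected because the formula
    does not apply there.
    """
    if not (700.0 <= wavelength_nm <= 1050.0):
        raise ValueError(
            "MPE formula is only valid for 700-1050 nm, got "
            f"{wavelength_nm} nm"
        )
    return float(20.0 * 10.0 ** (0.002 * (wavelength_nm - 700.0)))


@dataclass
class ScanPlan:
    """A full panoramic acquisition plan: positions, steps, timing, FOV."""

    spec: ScannerSpec
    wavelengths_nm: tuple[float, ...]
    n_positions: int
    per_position_pose: list[RigidPose6DOF]
    positions_mm: np.ndarray
    step_sizes_mm: np.ndarray
    scan_range_mm: float
    per_scan_time_s: float
    total_time_s: float
    overlap_mm: float = 0.0
    fov_mm: tuple[float, float] = (0.0, 0.0)

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths_nm)

    @property
    def frames_per_scan(self) -> int:
        """Number of single-wavelength 2D frames per scan (alias s)."""
        return self.spec.frames_per_scan


def make_scan_plan(
    spec: ScannerSpec = DEFAULT_SPEC,
    wavelengths_nm=(797.0,),
    n_positions: int = 1,
    overlap_mm: float = 0.0,
    per_scan_override_s: float | None = None,
    poses: list[RigidPose6DOF] | None = None,
) -> ScanPlan:
    """Build a ScanPlan for an n-position, q-wavelength panoramic scan.

    Default poses are pure elevational translations advancing each scan by
    ``scan_range - overlap``; arbitrary 6-DOF poses may be supplied for
    curved anatomy (e.g. around a neck).
    """
    wavelengths = tuple(float(w) for w in wavelengths_nm)
    if not wavelengths:
        raise ValueError("at least one wavelength is required")
    positions = scan_positions(spec)
    dy = np.diff(positions)
    y_scan = float(positions[-1])
    timing = plan_timing(
        spec.frame_period_s,
        spec.frames_per_scan,
        len(wavelengths),
        n_positions,
        per_scan_override_s=per_scan_override_s,
    )
    fov = panorama_fov(
        y_scan, spec.lateral_aperture_mm, n_positions, overlap_mm
    )
    if poses is None:
        advance = y_scan - overlap_mm
        poses = [
            RigidPose6DOF(translation_mm=(0.0, k * advance, 0.0))
            for k in range(n_positions)
        ]
    if len(poses) != n_positions:
        raise ValueError("one pose per scan position is required")
    return ScanPlan(
        spec=spec,
        wavelengths_nm=wavelengths,
        n_positions=n_positions,
        per_position_pose=list(poses),
        positions_mm=positions,
        step_sizes_mm=dy,
        scan_range_mm=y_scan,
        per_scan_time_s=timing.per_scan_s,
        total_time_s=timing.total_s,
        overlap_mm=overlap_mm,
        fov_mm=fov,
    )
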