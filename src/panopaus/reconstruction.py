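"""Per-pulse energy calibration and 2D image formation from RF channel data.

Two beamformers are provided: delay-and-sum (DAS, the reference) and
delay-multiply-and-sum (DMAS, better sidelobe suppression).  PA data uses
one-way delays (optical excitation is effectively instantaneous across the
slice); pulse-echo US uses two-way delays.  Images are formed on a grid
with axial pixel pitch c/(2 fs) — the US-grid convention, which is also
the pixel bookkeeping used for skin removal — and lateral pitch equal to
the element pitch.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import hilbert

from .core import BeamformedFrame, RFFrame
from .scan_geometry import ScannerSpec

__all__ = [
    "calibrate_energy",
    "das_beamform",
    "dmas_beamform",
    "envelope",
]


def calibrate_energy(frame: RFFrame) -> RFFrame:
    """Divide RF channel data by the recorded laser pulse energy.

    Removes per-shot laser energy jitter before beamforming; the returned
    frame has pulse_energy reset to 1.
    """
    if frame.pulse_energy <= 0:
        raise ValueError("pulse_energy must be positive to calibrate")
    return RFFrame(
        channels=frame.channels / frame.pulse_energy,
        pulse_energy=1.0,
        wavelength_nm=frame.wavelength_nm,
        position_index=frame.position_index,
        elevation_mm=frame.elevation_mm,
    )


def envelope(signal: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal along the last axis."""
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] < 8:
        raise ValueError("envelope detection needs at least 8 samples")
    return np.abs(hilbert(signal, axis=-1))


def _image_grid(
    frame: RFFrame, spec: ScannerSpec, mode: str, n_axial: int | None
) -> tuple[np.ndarray, np.ndarray, float, float]:
    c = spec.sound_speed_m_s
    fs = spec.sampling_freq_mhz * 1e6
    dz = spec.axial_pixel_mm  # c / (2 fs), mm
    # maximum depth reachable by the recorded samples
    t_max = frame.n_samples / fs
    max_depth_mm = (c * t_max if mode == "one-way" else c * t_max / 2.0) * 1e3
    if n_axial is None:
        n_axial = int(math.floor(max_depth_mm / dz)) + 1
    z = np.arange(n_axial) * dz
    if z[-1] > max_depth_mm + 1e-9:
        raise ValueError(
            f"sampling too coarse for the requested depth: {z[-1]:.2f} mm "
            f"requested but RF data only reaches {max_depth_mm:.2f} mm"
        )
    ne = frame.n_elements
    x = (np.arange(ne) - (ne - 1) / 2.0) * spec.pitch_mm
    return z, x, dz, spec.pitch_mm


def _delayed_signal(
    rf: np.ndarray,
    e: int,
    z_mm: np.ndarray,
    x_mm: np.ndarray,
    elem_x_mm: np.ndarray,
    spec: ScannerSpec,
    mode: str,
    accept_tan: float,
) -> np.ndarray:
    """RF trace of element e sampled at each pixel's geometric delay."""
    c = spec.sound_speed_m_s
    fs = spec.sampling_freq_mhz * 1e6
    dxm = x_mm[None, :] - elem_x_mm[e]
    dist_mm = np.sqrt(dxm**2 + z_mm[:, None] ** 2)
    if mode == "one-way":
        delay_samp = dist_mm * 1e-3 / c * fs
    else:  # plane-wave transmit down + echo back to the element
        delay_samp = (z_mm[:, None] + dist_mm) * 1e-3 / c * fs
    vals = np.interp(
        delay_samp, np.arange(rf.shape[1]), rf[e], left=0.0, right=0.0
    )
    # aperture acceptance-angle cutoff
    accept = np.abs(dxm) <= z_mm[:, None] * accept_tan
    accept[0, :] = np.abs(dxm[0]) < 1e-9
    return np.where(accept, vals, 0.0)


def das_beamform(
    frame: RFFrame,
    spec: ScannerSpec,
    mode: str = "one-way",
    n_axial: int | None = None,
    accept_angle_deg: float = 30.0,
    detect_envelope: bool = True,
) -> BeamformedFrame:
    """Delay-and-sum beamforming of one RF frame.

    For each pixel, the RF sample of every element at the geometric delay
    (linearly interpolated between samples) is summed, subject to a
    +-``accept_angle_deg`` aperture acceptance cutoff, followed by envelope
    detection along the axial direction.  ``mode`` is "one-way" for PA and
    "two-way" for pulse-echo US.
    """
    if mode not in ("one-way", "two-way"):
        raise ValueError("mode must be 'one-way' or 'two-way'")
    z, x, dz, dx = _image_grid(frame, spec, mode, n_axial)
    accept_tan = math.tan(math.radians(accept_angle_deg))
    elem_x = (np.arange(frame.n_elements) - (frame.n_elements - 1) / 2.0) \
        * spec.pitch_mm
    acc = np.zeros((z.size, x.size))
    for e in range(frame.n_elements):
        acc += _delayed_signal(
            frame.channels, e, z, x, elem_x, spec, mode, accept_tan
        )
    image = envelope(acc.T).T if detect_envelope else acc
    return BeamformedFrame(
        image=image,
        axial_spacing_mm=dz,
        lateral_spacing_mm=dx,
        wavelength_nm=frame.wavelength_nm,
        elevation_mm=frame.elevation_mm,
        provenance={
            "beamformer": "das",
            "mode": mode,
            "accept_angle_deg": accept_angle_deg,
            "envelope": detect_envelope,
        },
    )


def dmas_beamform(
    frame: RFFrame,
    spec: ScannerSpec,
    mode: str = "one-way",
    n_axial: int | None = None,
    accept_angle_deg: float = 30.0,
    detect_envelope: bool = True,
) -> BeamformedFrame:
    """Delay-multiply-and-sum beamforming of one RF frame.

    Delayed signals are transformed as y_i = sign(s_i) sqrt(|s_i|) and the
    sum of pairwise products over distinct element pairs is accumulated
    via the identity sum_{i<j} y_i y_j = ((sum y)^2 - sum y^2) / 2, then
    envelope-detected.  Sharper mainlobe and lower sidelobes than DAS.
    """
    if mode not in ("one-way", "two-way"):
        raise ValueError("mode must be 'one-way' or 'two-way'")
    z, x, dz, dx = _image_grid(frame, spec, mode, n_axial)
    accept_tan = math.tan(math.radians(accept_angle_deg))
    elem_x = (np.arange(frame.n_elements) - (frame.n_elements - 1) / 2.0) \
        * spec.pitch_mm
    s1 = np.zeros((z.size, x.size))
    s2 = np.zeros((z.size, x.size))
    for e in range(frame.n_elements):
        d = _delayed_signal(
            frame.channels, e, z, x, elem_x, spec, mode, accept_tan
        )
        y = np.sign(d) * np.sqrt(np.abs(d))
        s1 += y
        s2 += y * y
    acc = 0.5 * (s1 * s1 - s2)
    image = envelope(acc.T).T if detect_envelope else acc
    return BeamformedFrame(
        image=image,
        axial_spacing_mm=dz,
        lateral_spacing_mm=dx,
        wavelength_nm=frame.wavelength_nm,
        elevation_mm=frame.elevation_mm,
        provenance={
            "beamformer": "dmas",
            "mode": mode,
            "accept_angle_deg": accept_angle_deg,
            "envelope": detect_envelope,
        },
    )
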