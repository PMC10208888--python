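"""Phantoms and forward simulation of per-frame RF channel data and US frames.

This module makes the whole pipeline testable without an acquisition
system.  The PA forward model is deliberately simple but physically
shaped: each absorber radiates a band-limited pulse received by every
element after a one-way time of flight, with amplitude attenuated by
depth-dependent optical fluence (exp(-mu_eff z)) and 1/r geometric
spreading, weighted by a Gaussian elevation sensitivity of the stated
beam-width, and scaled by the (jittered) per-shot laser pulse energy.
The US simulator is a phenomenological texture generator that provides a
detectable bright skin line and plausible speckle — the only things the
downstream skin-contour stage needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import RFFrame
from .scan_geometry import ScannerSpec
from .spectral_unmixing import DEFAULT_EXTINCTION, ExtinctionTable

__all__ = [
    "Absorber",
    "Phantom",
    "make_thread_phantom",
    "make_vessel_phantom",
    "simulate_rf",
    "simulate_us_frame",
    "simulate_scan",
]

# Default effective optical attenuation (per mm).  Combined with 1/r
# spreading and the depth-growing receive aperture, this yields a roughly
# linear pSNR decay of ~1.2 dB/mm over the 12-24 mm band that
# tissue-mimicking phantoms are probed at.
DEFAULT_MU_EFF_PER_MM = 0.18


@dataclass(frozen=True)
class Absorber:
    """A point, thread, or vessel absorber.

    Threads and vessels both run along the elevation (scan) axis y, so a
    cross-sectional (z, x) frame sees them as dots/disks; threads are
    thin (90 um) wavelength-independent lines, vessels are thicker
    cylinders carrying hemoglobin with an assigned sO2.

    ``center_mm`` is (x, y, z) with z the depth below the transducer face.
    ``so2`` is the oxygen saturation of the absorber's hemoglobin content;
    ``None`` means a wavelength-independent (black) absorber.
    """

    center_mm: tuple[float, float, float]
    strength: float = 1.0
    geometry: str = "point"  # point | thread | vessel
    radius_mm: float = 0.045
    length_mm: float = math.inf
    so2: float | None = None

    def __post_init__(self) -> None:
        if self.geometry not in ("point", "thread", "vessel"):
            raise ValueError(f"unknown absorber geometry {self.geometry!r}")
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        if self.so2 is not None and not (0.0 <= self.so2 <= 1.0):
            raise ValueError("so2 must be in [0, 1]")

    @property
    def hb_fraction(self) -> float | None:
        return None if self.so2 is None else 1.0 - self.so2

    @property
    def hbo2_fraction(self) -> float | None:
        return self.so2

    @property
    def depth_mm(self) -> float:
        return self.center_mm[2]


@dataclass
class Phantom:
    """A collection of absorbers in an optically attenuating background.

    ``background_scatterers``/``background_strength`` describe a sparse
    field of weak, wavelength-independent absorbers mimicking diffuse
    tissue background PA signal; zero (the default) gives a clear medium
    like a gelatin resolution phantom.  The scatterer field is frozen by
    ``background_seed`` so every frame and wavelength sees the same
    tissue.
    """

    absorbers: list[Absorber] = field(default_factory=list)
    background_mu_eff_per_mm: float = DEFAULT_MU_EFF_PER_MM
    skin_depth_mm: float = 2.0
    sound_speed_m_s: float = 1540.0
    background_scatterers: int = 0
    background_strength: float = 0.0
    background_seed: int = 0

    def __post_init__(self) -> None:
        if self.background_mu_eff_per_mm < 0:
            raise ValueError("mu_eff must be non-negative")
        if self.background_scatterers < 0 or self.background_strength < 0:
            raise ValueError("background parameters must be non-negative")
        for a in self.absorbers:
            if a.depth_mm <= self.skin_depth_mm:
                raise ValueError(
                    "all absorbers must lie below the skin layer "
                    f"(depth {a.depth_mm} mm <= skin {self.skin_depth_mm} mm)"
                )

    def background_points(
        self,
        x_half_mm: float,
        z_max_mm: float,
        y_range_mm: tuple[float, float] = (-5.0, 30.0),
    ) -> tuple[np.ndarray, np.ndarray]:
        """Frozen (x, y, z) background scatterer positions and strengths.

        The scatterer field is three-dimensional so the speckle it
        produces decorrelates along the scan direction, as tissue speckle
        does; the same frozen field is seen by every frame and
        wavelength.
        """
        if self.background_scatterers == 0 or self.background_strength == 0:
            return np.zeros((0, 3)), np.zeros(0)
        rng = np.random.default_rng(self.background_seed)
        n = self.background_scatterers
        x = rng.uniform(-x_half_mm, x_half_mm, n)
        y = rng.uniform(y_range_mm[0], y_range_mm[1], n)
        z = rng.uniform(self.skin_depth_mm + 0.5, z_max_mm, n)
        s = self.background_strength * rng.uniform(0.5, 1.5, n)
        return np.column_stack([x, y, z]), s


def make_thread_phantom(
    start_depth_mm: float = 12.0,
    spacing_mm: float = 6.0,
    n_threads: int = 3,
    diameter_um: float = 90.0,
    elevation_mm: float = 12.5,
    length_mm: float = 40.0,
    skin_depth_mm: float = 2.0,
    mu_eff_per_mm: float = DEFAULT_MU_EFF_PER_MM,
) -> Phantom:
    """Resolution/SNR phantom: black threads stepped in depth and lateral.

    Default: three 90-um threads running along the elevation (scan) axis
    at depths 12, 18, 24 mm, offset 6 mm apart laterally, below a 2 mm
    surface layer.  Each cross-sectional frame sees them as three dots.
    """
    absorbers = []
    x0 = -spacing_mm * (n_threads - 1) / 2.0
    for i in range(n_threads):
        absorbers.append(
            Absorber(
                center_mm=(x0 + i * spacing_mm, elevation_mm,
                           start_depth_mm + i * spacing_mm),
                strength=1.0,
                geometry="thread",
                radius_mm=diameter_um / 2000.0,
                length_mm=length_mm,
            )
        )
    return Phantom(
        absorbers=absorbers,
        skin_depth_mm=skin_depth_mm,
        background_mu_eff_per_mm=mu_eff_per_mm,
    )


def make_vessel_phantom(
    vessels,
    skin_depth_mm: float = 2.0,
    mu_eff_per_mm: float = DEFAULT_MU_EFF_PER_MM,
    vessel_strength: float = 25.0,
    background_scatterers: int = 50000,
    background_strength: float = 0.04,
) -> Phantom:
    """Vessel phantom: cylinders along elevation with assigned sO2.

    ``vessels`` is a list of ``(center_mm, radius_mm, so2)`` with
    ``center_mm = (x, y, z)``.  Overlapping vessels (in the x-z plane, the
    cylinders being parallel to y) are rejected.

    Defaults place the vessels in a weak diffuse tissue background
    (blood absorbs far more strongly than bulk tissue in the NIR, so the
    vessel-to-background signal ratio is ~25 dB, as for in vivo
    vasculature), which also gives the fluence-compensation stage a real
    background level to estimate.
    """
    absorbers = []
    for center, radius, so2 in vessels:
        absorbers.append(
            Absorber(
                center_mm=tuple(float(c) for c in center),
                strength=vessel_strength,
                geometry="vessel",
                radius_mm=float(radius),
                so2=float(so2),
            )
        )
    for i in range(len(absorbers)):
        for j in range(i + 1, len(absorbers)):
            a, b = absorbers[i], absorbers[j]
            d = math.hypot(a.center_mm[0] - b.center_mm[0],
                           a.center_mm[2] - b.center_mm[2])
            if d < a.radius_mm + b.radius_mm:
                raise ValueError(
                    f"vessels {i} and {j} overlap (centre distance {d:.3f} mm"
                    f" < radius sum {a.radius_mm + b.radius_mm:.3f} mm)"
                )
    return Phantom(
        absorbers=absorbers,
        skin_depth_mm=skin_depth_mm,
        background_mu_eff_per_mm=mu_eff_per_mm,
        background_scatterers=background_scatterers,
        background_strength=background_strength,
    )


def _elevation_weight(dy_mm: np.ndarray, beamwidth_mm: float) -> np.ndarray:
    """Gaussian elevation sensitivity with FWHM = elevation beam-width."""
    sigma = beamwidth_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-0.5 * (dy_mm / sigma) ** 2)


def _point_sources(
    phantom: Phantom,
    spec: ScannerSpec,
    elevation_mm: float,
    wavelength_nm: float,
    table: ExtinctionTable,
    z_max_mm: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Discretize absorbers near the imaging slice into weighted points.

    Returns (positions (n, 2) as (x, z) mm, amplitudes (n,)).
    """
    xs, zs, amps = [], [], []
    for a in phantom.absorbers:
        x0, y0, z0 = a.center_mm
        if a.so2 is None:
            chrom = 1.0
        else:
            # Normalize by the isosbestic-band mean so magnitudes stay O(1).
            hb, hbo2 = table.row(table.wavelengths_nm[len(table.wavelengths_nm) // 2])
            chrom = table.absorption(wavelength_nm, a.so2) / (0.5 * (hb + hbo2))
        if a.geometry == "point":
            w = float(_elevation_weight(
                np.array(elevation_mm - y0), spec.elevation_beamwidth_mm))
            if w < 1e-4:
                continue
            xs.append(x0)
            zs.append(z0)
            amps.append(a.strength * chrom * w)
        elif a.geometry == "thread":
            # thin line along the scan axis: a dot in the imaging plane
            off = max(abs(elevation_mm - y0) - a.length_mm / 2.0, 0.0)
            w = float(_elevation_weight(
                np.array(off), spec.elevation_beamwidth_mm))
            if w < 1e-4:
                continue
            xs.append(x0)
            zs.append(z0)
            amps.append(a.strength * chrom * w)
        else:  # vessel: cylinder along y
            if abs(elevation_mm - y0) > a.length_mm / 2.0:
                w = float(_elevation_weight(
                    np.array(abs(elevation_mm - y0) - a.length_mm / 2.0),
                    spec.elevation_beamwidth_mm))
                if w < 1e-4:
                    continue
            else:
                w = 1.0
            grid = max(a.radius_mm / 4.0, 0.02)
            g = np.arange(-a.radius_mm, a.radius_mm + grid / 2, grid)
            gx, gz = np.meshgrid(g, g)
            inside = gx**2 + gz**2 <= a.radius_mm**2
            px = (x0 + gx[inside]).tolist()
            pz = (z0 + gz[inside]).tolist()
            xs.extend(px)
            zs.extend(pz)
            amps.extend([a.strength * chrom * w * grid**2] * len(px))
    bg_pos, bg_amp = phantom.background_points(
        spec.lateral_aperture_mm / 2.0 + 2.0, z_max_mm
    )
    if not xs and bg_pos.shape[0] == 0:
        return np.zeros((0, 2)), np.zeros(0)
    pos = np.column_stack([np.asarray(xs), np.asarray(zs)]) \
        if xs else np.zeros((0, 2))
    amp = np.asarray(amps)
    if bg_pos.shape[0]:
        w_bg = _elevation_weight(
            bg_pos[:, 1] - elevation_mm, spec.elevation_beamwidth_mm
        )
        keep = w_bg > 1e-4
        pos = np.vstack([pos, bg_pos[keep][:, [0, 2]]])
        amp = np.concatenate([amp, bg_amp[keep] * w_bg[keep]])
    # depth-dependent optical fluence below the skin
    depth = np.maximum(pos[:, 1] - phantom.skin_depth_mm, 0.0)
    amp = amp * np.exp(-phantom.background_mu_eff_per_mm * depth)
    return pos, amp


def _pulse_sigma_s(spec: ScannerSpec) -> float:
    """Gaussian envelope sigma for the stated -6 dB fractional bandwidth."""
    bw_hz = spec.fractional_bandwidth * spec.center_freq_mhz * 1e6
    return math.sqrt(2.0 * math.log(2.0)) / (math.pi * bw_hz)


def simulate_rf(
    phantom: Phantom,
    spec: ScannerSpec,
    elevation_mm: float,
    wavelength_nm: float = 797.0,
    energy_jitter: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_samples: int = 1024,
    noise_std: float = 1e-3,
    position_index: int = 0,
    table: ExtinctionTable = DEFAULT_EXTINCTION,
) -> RFFrame:
    """Simulate one frame of PA RF channel data at an elevational position.

    Every absorber near the slice contributes, at each element, a
    band-limited pulse (Gaussian envelope at the array centre frequency) at
    the one-way delay distance/c, with amplitude proportional to
    strength x chromophore absorption x exp(-mu_eff depth) / distance.
    The per-shot pulse energy is drawn as ``1 + jitter N(0,1)`` and scales
    the recorded amplitudes; white noise is added on top.  Deterministic
    for a fixed seed.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    c = phantom.sound_speed_m_s
    fs = spec.sampling_freq_mhz * 1e6
    f0 = spec.center_freq_mhz * 1e6
    sigma = _pulse_sigma_s(spec)
    ne = spec.n_elements
    elem_x = (np.arange(ne) - (ne - 1) / 2.0) * spec.pitch_mm

    z_max_mm = c * n_samples / fs * 1e3
    channels = np.zeros((ne, n_samples))
    pos, amp = _point_sources(
        phantom, spec, elevation_mm, wavelength_nm, table, z_max_mm=z_max_mm
    )
    if pos.shape[0]:
        # one-way time of flight from each source to each element (seconds)
        dx = pos[:, 0][:, None] - elem_x[None, :]          # (np, ne) mm
        dist_mm = np.sqrt(dx**2 + pos[:, 1][:, None] ** 2)
        tau = dist_mm * 1e-3 / c                           # (np, ne)
        a = amp[:, None] / np.maximum(dist_mm, 0.1)        # 1/r spreading
        # evaluate the pulse only on a +-4 sigma window around each arrival
        half_w = max(int(math.ceil(4.0 * sigma * fs)), 4)
        offsets = np.arange(-half_w, half_w + 1)
        center_idx = np.rint(tau * fs).astype(int)         # (np, ne)
        idx = center_idx[:, :, None] + offsets[None, None, :]
        t_rel = idx / fs - tau[:, :, None]
        wave = a[:, :, None] * np.cos(2 * math.pi * f0 * t_rel) * np.exp(
            -0.5 * (t_rel / sigma) ** 2
        )
        valid = (idx >= 0) & (idx < n_samples)
        e_idx = np.broadcast_to(
            np.arange(ne)[None, :, None], idx.shape
        )
        np.add.at(
            channels,
            (e_idx[valid], idx[valid]),
            wave[valid],
        )
    energy = 1.0 + energy_jitter * rng.standard_normal() if energy_jitter else 1.0
    energy = max(energy, 0.05)
    channels *= energy
    if noise_std:
        channels += rng.normal(0.0, noise_std, size=channels.shape)
    return RFFrame(
        channels=channels,
        pulse_energy=energy,
        wavelength_nm=wavelength_nm,
        position_index=position_index,
        elevation_mm=elevation_mm,
    )


def simulate_us_frame(
    phantom: Phantom,
    spec: ScannerSpec,
    elevation_mm: float,
    n_axial: int = 1024,
    seed: int | np.random.Generator = 0,
    speckle_level: float = 0.05,
) -> np.ndarray:
    """Simulate a B-mode-like US frame (axial x lateral envelope image).

    A phenomenological generator: Rayleigh speckle background, a bright
    skin line at ``skin_depth_mm`` (Gaussian axial profile, peak amplitude
    1), and echogenic rings at absorber boundaries.  The axial pixel pitch
    follows the US-grid convention c/(2 fs).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    nx = spec.n_elements
    dz = spec.axial_pixel_mm
    z = np.arange(n_axial) * dz
    x = (np.arange(nx) - (nx - 1) / 2.0) * spec.pitch_mm
    img = speckle_level * np.abs(
        rng.standard_normal((n_axial, nx))
        + 1j * rng.standard_normal((n_axial, nx))
    ) / math.sqrt(2.0)
    # bright skin line
    skin_sigma_mm = 3.0 * dz
    img += np.exp(
        -0.5 * ((z - phantom.skin_depth_mm) / skin_sigma_mm) ** 2
    )[:, None]
    # echogenic absorber boundaries
    for a in phantom.absorbers:
        x0, y0, z0 = a.center_mm
        if a.geometry == "vessel":
            if abs(elevation_mm - y0) > a.length_mm / 2.0 + spec.elevation_beamwidth_mm:
                continue
            r = np.sqrt((x[None, :] - x0) ** 2 + (z[:, None] - z0) ** 2)
            ring_sigma = max(2.0 * dz, 0.05)
            img += 0.5 * np.exp(-0.5 * ((r - a.radius_mm) / ring_sigma) ** 2)
        else:
            off = (abs(elevation_mm - y0)
                   if a.geometry == "point"
                   else max(abs(elevation_mm - y0) - a.length_mm / 2.0, 0.0))
            w = float(_elevation_weight(
                np.array(off), spec.elevation_beamwidth_mm))
            if w < 1e-3:
                continue
            r2 = (x[None, :] - x0) ** 2 + (z[:, None] - z0) ** 2
            spot_sigma = max(2.0 * dz, a.radius_mm)
            img += 0.5 * w * np.exp(-0.5 * r2 / spot_sigma**2)
    return img


def simulate_scan(
    phantom: Phantom,
    spec: ScannerSpec,
    wavelengths_nm=(797.0,),
    energy_jitter: float = 0.02,
    seed: int = 0,
    n_samples: int = 1024,
    noise_std: float = 1e-3,
    us_axial_samples: int | None = None,
    table: ExtinctionTable = DEFAULT_EXTINCTION,
):
    """Simulate one full scotch-yoke scan: RF frames per wavelength + US.

    Returns ``(rf_frames, us_frames, positions_mm)`` where ``rf_frames``
    maps wavelength -> list of RFFrame (one per scan position) and
    ``us_frames`` is a list of 2D US images.
    """
    from .scan_geometry import scan_positions

    positions = scan_positions(spec)
    rng = np.random.default_rng(seed)
    rf_frames: dict[float, list[RFFrame]] = {
        float(w): [] for w in wavelengths_nm
    }
    us_frames = []
    if us_axial_samples is None:
        us_axial_samples = 2 * n_samples
    for k, y in enumerate(positions):
        for w in wavelengths_nm:
            rf_frames[float(w)].append(
                simulate_rf(
                    phantom, spec, y, wavelength_nm=float(w),
                    energy_jitter=energy_jitter, seed=rng,
                    n_samples=n_samples, noise_std=noise_std,
                    position_index=k, table=table,
                )
            )
        us_frames.append(
            simulate_us_frame(
                phantom, spec, y, n_axial=us_axial_samples, seed=rng
            )
        )
    return rf_frames, us_frames, positions
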