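"""Linear spectral unmixing of multi-wavelength PA volumes to Hb/HbO2 and sO2.

The per-voxel PA amplitude at wavelength lambda is modelled as
``P(lambda) = eps_Hb(lambda) C_Hb + eps_HbO2(lambda) C_HbO2`` after fluence
compensation.  With amplitudes at two or more wavelengths the two
concentrations are recovered by least squares; negative solutions (an
overfitting artifact) are truncated to zero, and oxygen saturation is
``sO2 = C_HbO2 / (C_Hb + C_HbO2)``.

The default three-wavelength protocol uses 756 nm (Hb-dominant), 797 nm
(near the Hb/HbO2 isosbestic point), and 866 nm (HbO2-dominant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as _sk_polygon

from .core import Volume

__all__ = [
    "ExtinctionTable",
    "DEFAULT_EXTINCTION",
    "ChromophoreMaps",
    "SO2Volume",
    "SO2Map",
    "ROIPolygon",
    "unmix",
    "compute_so2",
    "median_filter_mm",
    "median_filter_map",
    "so2_map",
    "roi_stats",
    "read_roi_polygons",
    "write_roi_polygons",
]


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients of Hb and HbO2 per wavelength.

    Units need only be mutually consistent (concentrations come out in the
    reciprocal relative unit).  The shipped default holds approximate
    literature molar extinction values (cm^-1 M^-1) at 756/797/866 nm and
    is replaceable via configuration.
    """

    wavelengths_nm: tuple[float, ...]
    eps_hb: tuple[float, ...]
    eps_hbo2: tuple[float, ...]

    def __post_init__(self) -> None:
        w = tuple(float(v) for v in self.wavelengths_nm)
        hb = tuple(float(v) for v in self.eps_hb)
        hbo2 = tuple(float(v) for v in self.eps_hbo2)
        if not (len(w) == len(hb) == len(hbo2)):
            raise ValueError("extinction table columns must have equal length")
        if len(w) < 2:
            raise ValueError("at least two wavelengths are required")
        if any(v <= 0 for v in hb + hbo2):
            raise ValueError("extinction coefficients must be positive")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "eps_hb", hb)
        object.__setattr__(self, "eps_hbo2", hbo2)

    def matrix(self, wavelengths_nm=None) -> np.ndarray:
        """(n_wavelengths, 2) matrix with columns (eps_Hb, eps_HbO2)."""
        if wavelengths_nm is None:
            wavelengths_nm = self.wavelengths_nm
        rows = [self.row(w) for w in wavelengths_nm]
        return np.array(rows, dtype=float)

    def row(self, wavelength_nm: float) -> tuple[float, float]:
        for w, hb, hbo2 in zip(self.wavelengths_nm, self.eps_hb, self.eps_hbo2):
            if abs(w - wavelength_nm) < 0.5:
                return (hb, hbo2)
        raise KeyError(f"no extinction entry for {wavelength_nm} nm")

    def absorption(self, wavelength_nm: float, so2: float) -> float:
        """Blood absorption at the given saturation, relative units."""
        hb, hbo2 = self.row(wavelength_nm)
        return (1.0 - so2) * hb + so2 * hbo2


# Approximate literature molar extinction coefficients (cm^-1 M^-1):
# 756 nm is Hb-dominant, 797 nm sits at the isosbestic point, 866 nm is
# HbO2-dominant.
DEFAULT_EXTINCTION = ExtinctionTable(
    wavelengths_nm=(756.0, 797.0, 866.0),
    eps_hb=(1601.0, 772.0, 712.0),
    eps_hbo2=(610.0, 763.0, 1100.0),
)


@dataclass
class ChromophoreMaps:
    """Per-voxel Hb and HbO2 concentration volumes (non-negative)."""

    c_hb: Volume
    c_hbo2: Volume

    def __post_init__(self) -> None:
        if self.c_hb.shape != self.c_hbo2.shape:
            raise ValueError("concentration volumes must share a shape")


@dataclass
class SO2Volume:
    """Per-voxel oxygen saturation; NaN marks undefined voxels.

    A voxel is undefined when both concentrations are zero (no hemoglobin
    signal); undefined voxels are excluded from all statistics.
    """

    so2: Volume

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.so2.data)


@dataclass
class SO2Map:
    """Projected sO2 image over (lateral, elevation), plus projecting depth."""

    so2: np.ndarray
    depth_index: np.ndarray
    spacing_mm: tuple[float, float]


def unmix(
    pa_volumes: dict[float, Volume],
    table: ExtinctionTable = DEFAULT_EXTINCTION,
) -> ChromophoreMaps:
    """Least-squares unmixing of per-wavelength PA volumes into Hb/HbO2.

    Negative concentrations from the unconstrained per-voxel solve are
    truncated to zero (coordinate-wise clamping), which projects the
    solution onto the non-negative orthant.
    """
    if len(pa_volumes) < 2:
        raise ValueError("unmixing requires at least two wavelengths")
    wavelengths = sorted(pa_volumes)
    vols = [pa_volumes[w] for w in wavelengths]
    shape = vols[0].shape
    if any(v.shape != shape for v in vols):
        raise ValueError("per-wavelength volumes must be co-registered "
                         "(same shape)")
    E = table.matrix(wavelengths)
    if np.linalg.matrix_rank(E) < 2:
        raise ValueError("extinction matrix is rank-deficient; the chosen "
                         "wavelengths cannot separate Hb from HbO2")
    P = np.stack([v.data.reshape(-1) for v in vols])  # (n_wl, n_vox)
    C = np.linalg.pinv(E) @ P  # unconstrained least squares
    C = np.maximum(C, 0.0)
    ref = vols[0]
    c_hb = ref.with_data(
        C[0].reshape(shape), modality="c_hb", wavelength_nm=None
    )
    c_hbo2 = ref.with_data(
        C[1].reshape(shape), modality="c_hbo2", wavelength_nm=None
    )
    for v in (c_hb, c_hbo2):
        v.log(f"unmix(wavelengths={wavelengths})")
    return ChromophoreMaps(c_hb=c_hb, c_hbo2=c_hbo2)


def compute_so2(maps: ChromophoreMaps) -> SO2Volume:
    """sO2 = C_HbO2 / (C_Hb + C_HbO2); NaN where the denominator is zero."""
    total = maps.c_hb.data + maps.c_hbo2.data
    with np.errstate(invalid="ignore", divide="ignore"):
        so2 = np.where(total > 0, maps.c_hbo2.data / np.where(total > 0, total, 1.0), np.nan)
    out = maps.c_hbo2.with_data(so2, modality="so2")
    out.log("compute_so2")
    return SO2Volume(so2=out)


def _odd_window(size_mm: float, spacing_mm: float) -> int:
    """Window length in voxels: round(size/spacing) forced to the nearest odd."""
    if size_mm <= 0:
        raise ValueError("filter size must be positive")
    c = size_mm / spacing_mm
    w = int(round(c))
    if w % 2 == 0:
        lower, upper = w - 1, w + 1
        w = lower if (c - lower) <= (upper - c) else upper
    return max(w, 1)


def median_filter_mm(
    volume: Volume, size_mm: tuple[float, float] = (4.0, 1.0)
) -> Volume:
    """Median filter in the elevation-lateral plane with a metric window.

    ``size_mm`` is (elevation, lateral); window sizes in voxels are
    round(size/spacing) forced odd.  The axial direction is untouched.
    """
    w_elev = _odd_window(size_mm[0], volume.spacing_mm[2])
    w_lat = _odd_window(size_mm[1], volume.spacing_mm[1])
    if w_elev > volume.shape[2] or w_lat > volume.shape[1]:
        raise ValueError(
            f"median window ({w_elev} x {w_lat} voxels) exceeds the volume "
            f"extent {volume.shape[2]} x {volume.shape[1]}"
        )
    data = ndimage.median_filter(volume.data, size=(1, w_lat, w_elev))
    out = volume.with_data(data)
    out.log(f"median_filter_mm(size_mm={tuple(size_mm)})")
    return out


def median_filter_map(
    so2_2d: np.ndarray,
    spacing_mm: tuple[float, float],
    size_mm: tuple[float, float] = (1.0, 4.0),
) -> np.ndarray:
    """Median-filter a projected (lateral, elevation) sO2 map.

    ``spacing_mm``/``size_mm`` are (lateral, elevation).  Undefined (NaN)
    pixels are filled with their nearest defined neighbour for the filter
    pass and restored to NaN afterwards, so undefined regions never leak
    values into statistics.
    """
    arr = np.asarray(so2_2d, dtype=float)
    w = (_odd_window(size_mm[0], spacing_mm[0]),
         _odd_window(size_mm[1], spacing_mm[1]))
    nan_mask = ~np.isfinite(arr)
    if nan_mask.all():
        return arr.copy()
    work = arr
    if nan_mask.any():
        idx = ndimage.distance_transform_edt(
            nan_mask, return_distances=False, return_indices=True
        )
        work = arr[tuple(idx)]
    out = ndimage.median_filter(work, size=w)
    out[nan_mask] = np.nan
    return out


def so2_map(so2_volume: SO2Volume, c_hbo2: Volume) -> SO2Map:
    """Project sO2 at the depth of maximum HbO2 concentration per column.

    For each (x, y) column, the axial index of the maximum C_HbO2 is found
    (ties resolved to the shallowest voxel) and the sO2 value at that voxel
    is placed in the map.  Columns whose chosen voxel is undefined map to
    NaN.
    """
    if so2_volume.so2.shape != c_hbo2.shape:
        raise ValueError("sO2 and C_HbO2 volumes must share a shape")
    depth_idx = np.argmax(c_hbo2.data, axis=0)  # first max => shallowest
    nx, ny = depth_idx.shape
    jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    so2_vals = so2_volume.so2.data[depth_idx, jj, kk]
    return SO2Map(
        so2=so2_vals,
        depth_index=depth_idx,
        spacing_mm=(c_hbo2.spacing_mm[1], c_hbo2.spacing_mm[2]),
    )


@dataclass(frozen=True)
class ROIPolygon:
    """A planar polygon drawn on one US frame (elevation index).

    Vertices are (lateral x, axial z) pairs in mm in the frame plane.
    """

    frame_index: int
    vertices_mm: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        v = tuple((float(a), float(b)) for a, b in self.vertices_mm)
        if len(v) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        object.__setattr__(self, "vertices_mm", v)


def _rasterize(poly: ROIPolygon, volume: Volume) -> np.ndarray:
    nz, nx, ny = volume.shape
    if not (0 <= poly.frame_index < ny):
        raise ValueError("polygon frame index outside the volume")
    xs = np.array([v[0] for v in poly.vertices_mm])
    zs = np.array([v[1] for v in poly.vertices_mm])
    cols = (xs - volume.origin_mm[1]) / volume.spacing_mm[1]
    rows = (zs - volume.origin_mm[0]) / volume.spacing_mm[0]
    if (rows < -0.5).any() or (rows > nz - 0.5).any() \
            or (cols < -0.5).any() or (cols > nx - 0.5).any():
        raise ValueError("polygon vertices fall outside the frame bounds")
    rr, cc = _sk_polygon(rows, cols, shape=(nz, nx))
    mask = np.zeros((nz, nx), dtype=bool)
    mask[rr, cc] = True
    return mask


def read_roi_polygons(path) -> list[ROIPolygon]:
    """Read ROI polygons from a plain-text polygon-per-line format.

    Each non-comment line is ``<frame_index> x1,z1 x2,z2 x3,z3 ...`` with
    vertices in mm in the (lateral, axial) frame plane.
    """
    polygons = []
    for lineno, line in enumerate(open(path), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            frame = int(parts[0])
            verts = tuple(
                tuple(float(v) for v in p.split(",")) for p in parts[1:]
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(
                f"{path}:{lineno}: cannot parse ROI polygon line"
            ) from exc
        polygons.append(ROIPolygon(frame, verts))
    return polygons


def write_roi_polygons(path, polygons: list[ROIPolygon]) -> None:
    """Write ROI polygons in the format read_roi_polygons reads."""
    with open(path, "w") as fh:
        fh.write("# frame_index  x_mm,z_mm ...\n")
        for p in polygons:
            verts = " ".join(f"{x:g},{z:g}" for x, z in p.vertices_mm)
            fh.write(f"{p.frame_index} {verts}\n")


def roi_stats(
    so2_volume: SO2Volume, roi_polygons: list[ROIPolygon]
) -> tuple[float, float, int]:
    """Mean, std, and voxel count of sO2 inside a stacked volumetric ROI.

    Each polygon is rasterized in its US frame; the per-frame masks stack
    into a volumetric ROI.  Undefined sO2 voxels are excluded.
    """
    if not roi_polygons:
        raise ValueError("empty ROI: at least one polygon is required")
    vol = so2_volume.so2
    mask = np.zeros(vol.shape, dtype=bool)
    for poly in roi_polygons:
        mask[:, :, poly.frame_index] |= _rasterize(poly, vol)
    values = vol.data[mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("ROI contains no defined sO2 voxels")
    return float(values.mean()), float(values.std()), int(values.size)
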