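"""Volume container I/O and standard-format exports.

Scans live in a single hierarchical HDF5 container per panorama position:

* ``/pa/<wavelength_nm>/data`` — PA volumes (one group per wavelength),
  with spacing/origin/pose attributes, an optional non-uniform
  ``y_coords_mm`` coordinate dataset, and an append-only provenance log.
* ``/us/data`` — the co-registered US volume.
* ``/rf/<wavelength_nm>/frame_NNNNN`` — raw RF frames with per-frame pulse
  energy and elevation.

Exports: 16-bit TIFF with a JSON scale sidecar (so values round-trip up
to quantization), and NIfTI volumes carrying the voxel spacings.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import tifffile

from .core import RFFrame, RigidPose6DOF, Volume

__all__ = [
    "write_container",
    "read_container",
    "append_volume",
    "export_tiff",
    "import_tiff",
    "export_nifti",
]

FORMAT_NAME = "panopaus-container"
FORMAT_VERSION = "1"


def _wavelength_key(w: float | None) -> str:
    return "none" if w is None else f"{float(w):g}"


def _write_volume_group(g: h5py.Group, volume: Volume) -> None:
    if "data" in g:
        del g["data"]
    g.create_dataset("data", data=volume.data)
    g.attrs["spacing_mm"] = volume.spacing_mm
    g.attrs["origin_mm"] = volume.origin_mm
    g.attrs["modality"] = volume.modality
    g.attrs["units"] = "mm"
    if volume.wavelength_nm is not None:
        g.attrs["wavelength_nm"] = float(volume.wavelength_nm)
    g.attrs["pose_translation_mm"] = volume.pose.translation_mm
    g.attrs["pose_rotation_deg"] = volume.pose.rotation_deg
    g.attrs["pose_convention"] = "intrinsic z-y-x Euler about volume centre"
    if "y_coords_mm" in g:
        del g["y_coords_mm"]
    if volume.y_coords_mm is not None:
        g.create_dataset("y_coords_mm", data=volume.y_coords_mm)
    g.attrs["provenance"] = [str(s) for s in volume.provenance]


def _read_volume_group(g: h5py.Group) -> Volume:
    pose = RigidPose6DOF(
        tuple(g.attrs.get("pose_translation_mm", (0.0, 0.0, 0.0))),
        tuple(g.attrs.get("pose_rotation_deg", (0.0, 0.0, 0.0))),
    )
    wl = g.attrs.get("wavelength_nm")
    return Volume(
        data=g["data"][()],
        spacing_mm=tuple(g.attrs["spacing_mm"]),
        origin_mm=tuple(g.attrs.get("origin_mm", (0.0, 0.0, 0.0))),
        modality=str(g.attrs.get("modality", "pa")),
        wavelength_nm=None if wl is None else float(wl),
        pose=pose,
        y_coords_mm=g["y_coords_mm"][()] if "y_coords_mm" in g else None,
        provenance=[str(s) for s in g.attrs.get("provenance", [])],
    )


def write_container(
    path,
    pa_volumes: dict[float, Volume] | None = None,
    us_volume: Volume | None = None,
    rf_frames: dict[float, list[RFFrame]] | None = None,
    mode: str = "a",
) -> Path:
    """Write volumes and/or RF frames to a container file.

    Mode "a" (default) appends to an existing container, leaving other
    groups untouched; "w" starts fresh.
    """
    path = Path(path)
    with h5py.File(path, mode) as f:
        if "format" in f.attrs:
            _check_format(f, path)
        f.attrs["format"] = FORMAT_NAME
        f.attrs["version"] = FORMAT_VERSION
        if pa_volumes:
            pa = f.require_group("pa")
            for w, vol in pa_volumes.items():
                _write_volume_group(
                    pa.require_group(_wavelength_key(w)), vol
                )
        if us_volume is not None:
            _write_volume_group(f.require_group("us"), us_volume)
        if rf_frames:
            rf = f.require_group("rf")
            for w, frames in rf_frames.items():
                wg = rf.require_group(_wavelength_key(w))
                for frame in frames:
                    name = f"frame_{frame.position_index:05d}"
                    if name in wg:
                        del wg[name]
                    d = wg.create_dataset(name, data=frame.channels)
                    d.attrs["pulse_energy"] = frame.pulse_energy
                    if frame.wavelength_nm is not None:
                        d.attrs["wavelength_nm"] = float(frame.wavelength_nm)
                    d.attrs["elevation_mm"] = frame.elevation_mm
                    d.attrs["position_index"] = frame.position_index
    return path


def _check_format(f: h5py.File, path: Path) -> None:
    fmt = f.attrs.get("format")
    if fmt != FORMAT_NAME:
        raise ValueError(f"{path} is not a {FORMAT_NAME} file (format={fmt!r})")
    version = str(f.attrs.get("version"))
    if version != FORMAT_VERSION:
        raise ValueError(
            f"{path} has container version {version}, expected "
            f"{FORMAT_VERSION}"
        )


def read_container(path):
    """Read a container: (pa_volumes, us_volume, rf_frames).

    ``pa_volumes`` maps wavelength (nm) to Volume; ``rf_frames`` maps
    wavelength to a position-ordered list of RFFrame.
    """
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(
            f"{path} is not a readable {FORMAT_NAME} file: {exc}"
        ) from exc
    with f:
        _check_format(f, path)
        pa_volumes: dict[float, Volume] = {}
        if "pa" in f:
            for key, g in f["pa"].items():
                vol = _read_volume_group(g)
                pa_volumes[float(key) if key != "none" else None] = vol
        us_volume = _read_volume_group(f["us"]) if "us" in f else None
        rf_frames: dict[float, list[RFFrame]] = {}
        if "rf" in f:
            for key, wg in f["rf"].items():
                frames = []
                for name in sorted(wg):
                    d = wg[name]
                    wl = d.attrs.get("wavelength_nm")
                    frames.append(
                        RFFrame(
                            channels=d[()],
                            pulse_energy=float(d.attrs["pulse_energy"]),
                            wavelength_nm=None if wl is None else float(wl),
                            position_index=int(d.attrs["position_index"]),
                            elevation_mm=float(d.attrs["elevation_mm"]),
                        )
                    )
                rf_frames[float(key) if key != "none" else None] = frames
    return pa_volumes, us_volume, rf_frames


def append_volume(path, volume: Volume, wavelength_nm: float | None = None):
    """Append one PA volume (or overwrite its wavelength group)."""
    w = volume.wavelength_nm if wavelength_nm is None else wavelength_nm
    return write_container(path, pa_volumes={w: volume})


def export_tiff(data, path, spacing_mm=None) -> Path:
    """Export a 2D image or 3D volume as 16-bit TIFF with a scale sidecar.

    Values are affinely mapped to the uint16 range; the offset/scale (and
    spacings, if given) go to ``<path>.scale.json`` so ``import_tiff``
    restores values up to 16-bit quantization.  3D (z, x, y) input becomes
    a multi-page TIFF with one page per elevation plane.  NaNs are stored
    as zero and flagged in the sidecar mask convention.
    """
    path = Path(path)
    if isinstance(data, Volume):
        arr = data.data
        spacing_mm = data.spacing_mm
    else:
        arr = np.asarray(data, dtype=float)
    if arr.ndim not in (2, 3):
        raise ValueError("TIFF export takes 2D images or 3D volumes")
    finite = np.isfinite(arr)
    vals = arr[finite]
    lo = float(vals.min()) if vals.size else 0.0
    hi = float(vals.max()) if vals.size else 1.0
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    quant = np.zeros(arr.shape, dtype=np.uint16)
    quant[finite] = np.round((arr[finite] - lo) / scale).astype(np.uint16)
    if arr.ndim == 3:
        pages = np.transpose(quant, (2, 0, 1))  # one page per y plane
        tifffile.imwrite(path, pages, photometric="minisblack")
    else:
        tifffile.imwrite(path, quant, photometric="minisblack")
    sidecar = {
        "offset": lo,
        "scale": scale,
        "nan_as_zero": bool((~finite).any()),
    }
    if spacing_mm is not None:
        sidecar["spacing_mm"] = list(spacing_mm)
    path.with_suffix(path.suffix + ".scale.json").write_text(
        json.dumps(sidecar, indent=1)
    )
    return path


def import_tiff(path) -> np.ndarray:
    """Read back a TIFF written by export_tiff, restoring the value scale."""
    path = Path(path)
    quant = tifffile.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".scale.json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        arr = quant.astype(float) * sidecar["scale"] + sidecar["offset"]
    else:
        arr = quant.astype(float)
    if arr.ndim == 3:
        arr = np.transpose(arr, (1, 2, 0))
    return arr


def export_nifti(volume: Volume, path) -> Path:
    """Export a volume as NIfTI with the voxel spacings in the header.

    Anisotropic spacings are preserved as-is, never resampled.
    """
    path = Path(path)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    affine[:3, 3] = volume.origin_mm
    img = nib.Nifti1Image(volume.data, affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))
    return path
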