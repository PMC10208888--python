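# panopaus

Panoramic volumetric handheld photoacoustic/ultrasound (PA/US) imaging,
as a tested Python library and CLI.

Handheld 3D PA/US scanners sweep a clinical 1D linear-array transducer
through the elevation direction with a scotch-yoke mechanism: a motor arm
of length *R* rotates from θ<sub>i</sub> to θ<sub>f</sub> and its
horizontal projection drives the probe, so per-frame steps vary
sinusoidally,

    dy    = R (cos θi − cos θf)
    yScan = R (cos θScan_i − cos θScan_f)
    TScan = TImage × p × q

with *p* frames per scan and *q* laser wavelengths.  Multiple scans are
mosaic-stitched in 6 degrees of freedom into a panoramic volume, and
multi-wavelength PA volumes are spectrally unmixed into oxy-/deoxy-
hemoglobin to map oxygen saturation, sO₂ = C<sub>HbO₂</sub> /
(C<sub>Hb</sub> + C<sub>HbO₂</sub>).

This package implements the complete processing chain for such a scanner
— everything downstream of the transducer — plus a physics-shaped
synthetic acquisition model so the chain is testable end to end without
hardware:

| module | role |
| --- | --- |
| `scan_geometry` | scotch-yoke kinematics, scan planning, timing, FOV, ANSI skin-MPE check |
| `synthetic_data` | thread/vessel phantoms, per-frame RF channel simulation, B-mode-like US frames |
| `reconstruction` | laser pulse-energy calibration, DAS and DMAS beamforming, envelope detection |
| `volume_assembly` | frame stacking, sinusoidal→uniform elevational resampling, skin detection/removal, fluence compensation |
| `spectral_unmixing` | linear Hb/HbO₂ unmixing, sO₂ volumes and MAPs, metric median filtering, ROI statistics |
| `stitching` | 6-DOF rigid poses, union-grid resampling, apodized blending, MAP/depth-encoded rendering |
| `quantification` | peak SNR, ApSNR comparison, FWHM resolution, depth-attenuation slope |
| `io` / `cli` | HDF5 scan containers, TIFF/NIfTI export, the `panopaus` command |

## Worked example

Plan the default scan and check it:

```sh
$ panopaus plan --wavelengths 756,797,866 --n-positions 18
yScan 25.0 mm over 83 frames
dy range 0.19-0.36 mm
elevation sampling: pass (max dy 0.36 mm, limit 0.50 mm)
per-scan 49.8 s, total 896.4 s for n=18
FOV 38.4 x 450.1 mm^2
MPE at 756 nm: 25.9 mJ/cm^2
MPE at 797 nm: 31.3 mJ/cm^2
MPE at 866 nm: 43.0 mJ/cm^2
```

The scan range is 25 mm (15 mm arm, 32°–145°), steps stay below half the
1 mm elevation beam-width, and the 756 nm exposure limit is the ANSI skin
value of 25.9 mJ/cm².

Run a synthetic micro-scan through the pipeline:

```sh
panopaus simulate --phantom threads --frames 8 --out raw.h5 --seed 1
panopaus beamform --in raw.h5 --out bf.h5 --mode das
panopaus assemble --in bf.h5 --out vol.h5 --step-mm 0.25
panopaus render   --in vol.h5 --out map.tif
panopaus quantify --in vol.h5 --depths 12,18,24 --out report.json
```

`report.json` then holds, per thread target, the per-frame peak SNRs,
their average (ApSNR), and FWHM widths, plus the fitted ApSNR-vs-depth
slope in dB/mm — the simulated threads sit at 12/18/24 mm depth and their
ApSNR decays roughly linearly at ≈1.2 dB/mm, mirroring optical
attenuation in tissue-mimicking phantoms.

The same stages are importable directly; see `tests/test_acceptance.py`
for a full three-wavelength vessel-phantom pipeline recovering assigned
sO₂ values (0.97 artery / 0.84 vein) within 0.03.

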