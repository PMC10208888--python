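"""Shared fixtures: scaled-down scanner specs and simulated mini-scans.

Tests run on reduced problem sizes (fewer frames, fewer elements, shorter
RF records) chosen so each stage still exercises its physics while the
whole suite stays fast on one CPU.
"""

import dataclasses

import numpy as np
import pytest

from panopaus.scan_geometry import ScannerSpec


@pytest.fixture(scope="session")
def default_spec():
    return ScannerSpec()


@pytest.fixture(scope="session")
def mini_spec():
    """Full 128-element array but only 9 frames per scan."""
    return ScannerSpec(frames_per_scan=9)


@pytest.fixture(scope="session")
def tiny_spec():
    """A 32-element array for brute-force-checkable beamforming."""
    return ScannerSpec(
        n_elements=32,
        lateral_aperture_mm=9.6,
        frames_per_scan=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def replace_spec(spec, **kw):
    return dataclasses.replace(spec, **kw)
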