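"""Shared fixtures: small optical configurations and simulated stacks.

Expensive PSF stacks are session-scoped; everything is generated at test
time from the package's own simulators.
"""

from __future__ import annotations

import numpy as np
import pytest

from focusism import (
    DepletionModel,
    DetectorGeometry,
    ISMDataset,
    OpticalConfig,
    Phantom,
    generate_phantom,
    scanned_psf_stack,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def config_2d() -> OpticalConfig:
    """Single-plane config on the standard 127x127 lateral grid."""
    return OpticalConfig(grid_shape=(1, 127, 127))


@pytest.fixture(scope="session")
def detector(config_2d) -> DetectorGeometry:
    return DetectorGeometry.from_config(config_2d)


@pytest.fixture(scope="session")
def stack_confocal(config_2d, detector):
    """In-focus analytic stack without depletion."""
    return scanned_psf_stack(config_2d, detector, DepletionModel(0.0),
                             method="analytic")


@pytest.fixture(scope="session")
def stack_sted300(config_2d, detector):
    """In-focus analytic stack at saturation factor 300."""
    return scanned_psf_stack(config_2d, detector, DepletionModel(300.0),
                             method="analytic")


@pytest.fixture(scope="session")
def config_3d() -> OpticalConfig:
    """Coarse 3D grid: 31 planes of 100 nm, 65x65 lateral at 20 nm."""
    return OpticalConfig(voxel_size=(100.0, 20.0, 20.0),
                         grid_shape=(31, 65, 65))


@pytest.fixture(scope="session")
def stack_3d_confocal(config_3d):
    det = DetectorGeometry.from_config(config_3d)
    return scanned_psf_stack(config_3d, det, DepletionModel(0.0),
                             method="analytic")


@pytest.fixture(scope="session")
def stack_3d_sted300(config_3d):
    det = DetectorGeometry.from_config(config_3d)
    return scanned_psf_stack(config_3d, det, DepletionModel(300.0),
                             method="analytic")


@pytest.fixture(scope="session")
def bead_dataset(config_2d, stack_confocal) -> ISMDataset:
    """Noisy acquisition of a sparse in-focus bead field."""
    phantom = generate_phantom(
        "beads", {"grid_shape": (1, 127, 127), "n": 6, "diameter_nm": 23,
                  "margin_nm": 250}, seed=3)
    return simulate_acquisition(phantom, stack_confocal, photon_budget=2000,
                                seed=1)


@pytest.fixture(scope="session")
def two_plane_scenario():
    """Two-plane filament scenario: in-focus and 500 nm defocused
    acquisitions through the same PSF stack, per saturation factor."""

    def build(saturation: float):
        cfg = OpticalConfig(grid_shape=(3, 127, 127),
                            voxel_size=(500.0, 10.0, 10.0))
        det = DetectorGeometry.from_config(cfg)
        stack = scanned_psf_stack(cfg, det, DepletionModel(saturation),
                                  method="analytic")
        plane_in = generate_phantom(
            "filaments3d", {"grid_shape": (1, 127, 127), "n": 6,
                            "n_steps": 300, "z_extent_nm": 0}, seed=21)
        plane_out = generate_phantom(
            "filaments3d", {"grid_shape": (1, 127, 127), "n": 6,
                            "n_steps": 300, "z_extent_nm": 0}, seed=22)
        vol_in = np.zeros((3, 127, 127))
        vol_in[1] = plane_in.volume[0]
        vol_out = np.zeros((3, 127, 127))
        vol_out[2] = plane_out.volume[0]
        d_in = simulate_acquisition(Phantom(vol_in, (500, 10, 10)), stack,
                                    photon_budget=500, noiseless=True)
        d_out = simulate_acquisition(Phantom(vol_out, (500, 10, 10)), stack,
                                     photon_budget=500, noiseless=True)
        return d_in, d_out

    return build
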