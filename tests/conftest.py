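"""Shared fixtures: bundled curve, toy crystals, and cached small datasets."""

import numpy as np
import pytest

from spread.scattering import AtomSite, CrystalModel, UnitCell, synthetic_mn_curve
from spread.simulator import Detector, MosaicModel, Spectrum, simulate_dataset


@pytest.fixture(scope="session")
def mn_curve():
    return synthetic_mn_curve()


@pytest.fixture(scope="session")
def toy_crystal(mn_curve):
    """Two-atom toy: one Mn-like anomalous site plus one oxygen."""
    return CrystalModel(
        cell=UnitCell(9.0, 10.0, 11.0),
        atoms=(
            AtomSite("Mn", (0.2, 0.3, 0.4), b_factor=1.5, anomalous_curve=mn_curve),
            AtomSite("O", (0.1, 0.8, 0.3), b_factor=2.0),
        ),
    )


@pytest.fixture(scope="session")
def degenerate_mosaic():
    """Single domain, zero spread: the inference kernel matches the
    simulation exactly."""
    return MosaicModel(n_domains=1, angular_spread_mrad=0.0)


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """40 shots, Poisson noise, +2 eV injected shift (default conditions)."""
    return simulate_dataset(n_shots=40, seed=42, edge_shift_ev=2.0)


@pytest.fixture(scope="session")
def exact_noisefree_dataset(degenerate_mosaic):
    """Noise-off dataset whose generating model the fit can represent
    exactly (degenerate mosaic, exact metadata)."""
    return simulate_dataset(
        n_shots=5,
        seed=7,
        edge_shift_ev=1.5,
        noise=False,
        mosaic=degenerate_mosaic,
        scale_est_sigma=0.0,
        orientation_est_mrad=0.0,
        cell_jitter=0.0,
    )
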