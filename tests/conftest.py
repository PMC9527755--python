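"""Shared fixtures: small instrument configurations and pre-fitted models.

Session-scoped fixtures cache the expensive global fits so several tests can
inspect the same converged result.
"""

from __future__ import annotations

import numpy as np
import pytest

from biqens import (
    GroundTruth,
    InstrumentConfig,
    fit_bidisperse_global,
    fit_monodisperse_global,
    incoherent_weights,
    make_d2o,
    make_mixture_spectra,
    make_resolution,
)
from biqens.pipeline import composition_for


@pytest.fixture(scope="session")
def instrument_full() -> InstrumentConfig:
    return InstrumentConfig()


@pytest.fixture(scope="session")
def instrument_small() -> InstrumentConfig:
    """Reduced grids for fast fit tests: 8 q points, 256 channels."""
    return InstrumentConfig(q_grid=np.linspace(0.3, 1.8, 8), channel_count=256)


@pytest.fixture(scope="session")
def calibration_small(instrument_small):
    """Exact resolution/solvent models plus their synthetic measurements."""
    vanadium, resolution = make_resolution(instrument_small, seed=11)
    d2o, solvent = make_d2o(instrument_small, resolution, seed=12)
    return {"vanadium": vanadium, "resolution": resolution,
            "d2o": d2o, "solvent": solvent}


@pytest.fixture(scope="session")
def bidisperse_sample_small(instrument_small, calibration_small):
    """One bidisperse mixture measurement at φ = 0.2, y = 0.5."""
    comp = composition_for(0.2, 0.5)
    truth = GroundTruth()          # D_BSA = 4.5, D_Ig = 1.5 Å²/ns
    spec = make_mixture_spectra(
        instrument_small, comp, truth, calibration_small["resolution"],
        calibration_small["solvent"], seed=13)
    return {"spectra": spec, "composition": comp, "truth": truth,
            "weights": incoherent_weights(comp),
            "solvent_scaled": calibration_small["solvent"].scaled(1 - 0.2)}


@pytest.fixture(scope="session")
def mono_fit_small(bidisperse_sample_small, calibration_small):
    return fit_monodisperse_global(
        bidisperse_sample_small["spectra"], calibration_small["resolution"],
        bidisperse_sample_small["solvent_scaled"], seed=1)


@pytest.fixture(scope="session")
def bi_fit_small(bidisperse_sample_small, calibration_small, mono_fit_small):
    return fit_bidisperse_global(
        bidisperse_sample_small["spectra"], calibration_small["resolution"],
        bidisperse_sample_small["solvent_scaled"],
        bidisperse_sample_small["weights"], seed=1, mono_init=mono_fit_small)
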