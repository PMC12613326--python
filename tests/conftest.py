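"""Shared fixtures: small analytic models and sampled ensembles."""

import numpy as np
import pytest

from pfmhop.models import DiabaticModel, NormalModeSpec, build_model

HARMONIC_MASS = 2000.0
HARMONIC_OMEGA = 0.01


def make_harmonic_model(mass=HARMONIC_MASS, omega=HARMONIC_OMEGA, offset=1.0):
    """Two uncoupled surfaces: a harmonic well and a flat upper state."""
    k = mass * omega * omega

    def V(r):
        x = np.asarray(r, dtype=float)[..., 0]
        out = np.zeros(x.shape + (2, 2))
        out[..., 0, 0] = 0.5 * k * x * x
        out[..., 1, 1] = offset
        return out

    def dV(r):
        x = np.asarray(r, dtype=float)[..., 0]
        out = np.zeros(x.shape + (2, 2, 1))
        out[..., 0, 0, 0] = k * x
        return out

    return DiabaticModel("harmonic", 2, 1, np.array([mass]), V, dV)


def make_flat_coupled_model(coupling=0.001, mass=2000.0):
    """Two flat surfaces with a constant coupling (Rabi test bed)."""

    def V(r):
        x = np.asarray(r, dtype=float)[..., 0]
        out = np.zeros(x.shape + (2, 2))
        out[..., 0, 1] = out[..., 1, 0] = coupling
        return out

    def dV(r):
        x = np.asarray(r, dtype=float)[..., 0]
        return np.zeros(x.shape + (2, 2, 1))

    return DiabaticModel("flat", 2, 1, np.array([mass]), V, dV)


def make_displaced_pair(mass=2000.0, omega=0.005, gap=0.05, displacement=0.0):
    """Two uncoupled harmonic surfaces with relative displacement and offset."""
    k = mass * omega * omega
    return build_model({
        "name": "pair",
        "masses": [mass],
        "states": [
            {"form": "harmonic", "k": k, "x0": 0.0, "e0": 0.0},
            {"form": "harmonic", "k": k, "x0": displacement, "e0": gap},
        ],
    })


@pytest.fixture(scope="session")
def harmonic_model():
    return make_harmonic_model()


@pytest.fixture(scope="session")
def preset_models():
    return {name: build_model(name) for name in
            ("avoided_crossing_2s", "ibr_surrogate_3s", "tully3_sloped", "lvc_nd")}


@pytest.fixture(scope="session")
def single_mode():
    return NormalModeSpec([HARMONIC_OMEGA], [[1.0]], [HARMONIC_MASS])
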