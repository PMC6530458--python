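"""Shared fixtures: standard geometry, laws and models used across tests."""

import warnings

import pytest

from starlingflow import (
    AirwayModel,
    ElasticMaterial,
    TubeGeometry,
    make_tube_law,
)

# the seven mechanical configurations of the default study grid
GRID_MECH = [
    (2e-3, 2e3), (4e-3, 2e3), (6e-3, 2e3), (8e-3, 2e3),
    (2e-3, 15e3), (2e-3, 24e3), (2e-3, 30e3),
]


@pytest.fixture
def geometry() -> TubeGeometry:
    """Standard collapsible-segment geometry: A0 = 1.18 cm², 20 mm long."""
    return TubeGeometry(A0=1.18e-4, h=2e-3, length=0.020)


@pytest.fixture
def soft_law(geometry):
    """Soft tissue-like law (E = 2 kPa, h = 2 mm)."""
    return make_tube_law(geometry, ElasticMaterial(E=2e3))


@pytest.fixture
def stiff_law(geometry):
    """Silicone-like law (E = 15 kPa, h = 2 mm)."""
    return make_tube_law(geometry, ElasticMaterial(E=15e3))


@pytest.fixture
def default_model(stiff_law) -> AirwayModel:
    """h = 2 mm, E = 15 kPa segment behind the open-nostril resistance."""
    return AirwayModel(law=stiff_law)


def grid_law(h: float, E: float):
    """Tube law for one grid configuration (thick-wall warning silenced)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_tube_law(
            TubeGeometry(A0=1.18e-4, h=h, length=0.020), ElasticMaterial(E=E)
        )


def grid_models(R_up: float = 0.07e6):
    """AirwayModels for the seven grid configurations."""
    return [AirwayModel(law=grid_law(h, E), R_up=R_up) for h, E in GRID_MECH]
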