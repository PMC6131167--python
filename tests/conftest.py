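"""Shared fixtures: one toy barrel + one design run reused across tests."""

from __future__ import annotations

import pytest

import poredesign as pdsg
from poredesign.design_engine import DesignSpec, dense_rotamer_library, place_water_wire
from poredesign.synthetic_fixtures import (
    BarrelParams,
    make_barrel,
    make_cylinder_cavity,
    make_water_wire,
)

#: design positions of the toy barrel's constriction ring (one inward
#: residue per strand, 14 strands, 10 residues per strand)
RING_POSITIONS = [("A", 5 + 10 * i) for i in range(14)]


@pytest.fixture(scope="session")
def barrel():
    return make_barrel(BarrelParams(constriction_bulge=2.0))


@pytest.fixture(scope="session")
def barrel_axis(barrel):
    return pdsg.compute_pore_axis(barrel)


@pytest.fixture(scope="session")
def barrel_profile(barrel, barrel_axis):
    return pdsg.compute_profile(barrel, axis=barrel_axis)


@pytest.fixture(scope="session")
def barrel_constriction(barrel_profile):
    return pdsg.find_constriction(barrel_profile)


@pytest.fixture(scope="session")
def placed_wire(barrel, barrel_axis, barrel_constriction):
    return place_water_wire(make_water_wire(9, 2.8), barrel, barrel_axis, barrel_constriction)


@pytest.fixture(scope="session")
def dense_library():
    return dense_rotamer_library()


@pytest.fixture(scope="session")
def design_run(barrel, barrel_axis, placed_wire, dense_library):
    """One seeded design run in an achievable window; reused by many tests."""
    spec = DesignSpec(
        positions=RING_POSITIONS,
        allowed_aas=("TRP", "PHE", "TYR", "ALA", "VAL", "LEU"),
        long_aas=("TRP", "PHE", "TYR"),
        min_long_fraction=0.5,
        restarts=8,
        seed=3,
        d_min=0.0,
        d_max=7.0,
        subsample=0.7,
    )
    designs = pdsg.generate_designs(
        barrel, spec, library=dense_library, wire=placed_wire, axis=barrel_axis
    )
    return spec, designs


@pytest.fixture(scope="session")
def cylinder5():
    return make_cylinder_cavity(5.0)
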