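"""Shared fixtures: meshes and synthetic measurement sets.

Everything is generated programmatically; the expensive optimal-control
solves are session-scoped so the patterns they produce can be checked by
several tests without re-solving.
"""

import numpy as np
import pytest
from hypothesis import settings

import vasocal as vc

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# ground-truth resistances for the four-outlet arch-like fixture
# (dominant descending-aorta-like branch plus three supra-aortic-like ones)
R_TRUE = np.array([7000.0, 21000.0, 16000.0, 1700.0])
Q_IN = 119.1


@pytest.fixture(scope="session")
def tube2d():
    return vc.make_tube_mesh(0.5, 5.0, 0.125, dim=2)


@pytest.fixture(scope="session")
def tube3d():
    return vc.make_tube_mesh(0.5, 2.0, 0.25, dim=3)


@pytest.fixture(scope="session")
def arch():
    """Four-outlet planar arch-like manifold."""
    return vc.make_branching_mesh([0.4, 0.25, 0.3, 0.8], trunk_radius=1.0,
                                  target_edge_length=0.1)


@pytest.fixture(scope="session")
def tube_meas(tube2d):
    return vc.make_synthetic_case(tube2d, vc.ResistanceSet([1000.0]), 10.0)


@pytest.fixture(scope="session")
def arch_meas(arch):
    """Mass-consistent synthetic measurements on the arch fixture."""
    return vc.make_synthetic_case(arch, vc.ResistanceSet(R_TRUE), Q_IN,
                                  violation_fraction=0.0)


@pytest.fixture(scope="session")
def arch_meas_13(arch):
    """Measurements with a 13% mass-conservation violation."""
    return vc.make_synthetic_case(arch, vc.ResistanceSet(R_TRUE), Q_IN,
                                  violation_fraction=0.13)


@pytest.fixture(scope="session")
def arch_fit(arch, arch_meas):
    return vc.solve_ocp(arch, arch_meas)


@pytest.fixture(scope="session")
def arch_fit_13(arch, arch_meas_13):
    return vc.solve_ocp(arch, arch_meas_13)


@pytest.fixture(scope="session")
def arch_fit_13_inlet(arch, arch_meas_13):
    return vc.solve_ocp(arch, arch_meas_13, control_inlet=True)


@pytest.fixture(scope="session")
def tube_fit(tube2d, tube_meas):
    return vc.solve_ocp(tube2d, tube_meas)
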