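"""Shared fixtures for the strutflow test suite.

The flow solutions are session-scoped because the steady solves are the
expensive part of the suite; every test that uses them treats them as
read-only.
"""

import numpy as np
import pytest

from strutflow.hemodynamics import (
    AxisymmetricDomain,
    FlowConditions,
    compute_wss,
    generate_mesh,
    scaffold_domain,
    solve_steady_flow,
)
from strutflow.synthetic import make_phantom, make_scaffold_design, simulate_pullback


@pytest.fixture(scope="session")
def absorb_design():
    return make_scaffold_design("absorb_like")


@pytest.fixture(scope="session")
def arterio_design():
    return make_scaffold_design("arteriosorb_like")


@pytest.fixture(scope="session")
def straight_phantom():
    return make_phantom(length_mm=20.0, radius_mm=1.5, curvature=0.0, seed=3)


@pytest.fixture(scope="session")
def absorb_pullback(straight_phantom, absorb_design):
    return simulate_pullback(straight_phantom, absorb_design,
                             protrusion_fraction=0.97, seed=3)


@pytest.fixture(scope="session")
def poiseuille_conditions():
    return FlowConditions(inlet_mean_velocity_m_s=0.15)


@pytest.fixture(scope="session")
def poiseuille_solution(poiseuille_conditions):
    """Strut-free cylinder, R = 1.5 mm, parabolic inlet at 0.15 m/s."""
    domain = AxisymmetricDomain(
        length_m=6.0e-3, wall_radius_m=1.5e-3, struts=[],
        scaffold_bounds_m=(2.0e-3, 4.0e-3),
    )
    mesh = generate_mesh(domain, strut_thickness_um=157.0, coarsening=2.0)
    sol = solve_steady_flow(mesh, poiseuille_conditions)
    compute_wss(sol)
    return sol


@pytest.fixture(scope="session")
def single_ring_solution():
    """One protruding strut ring in a short vessel (for recirculation and
    conservation checks near an obstacle)."""
    design = make_scaffold_design("absorb_like")
    domain = scaffold_domain(design, lumen_radius_mm=1.5,
                             protrusion_fraction=0.97, n_rings=1,
                             native_mm=2.0)
    mesh = generate_mesh(domain, design.strut_thickness_um, coarsening=2.0)
    sol = solve_steady_flow(mesh, FlowConditions())
    compute_wss(sol)
    return sol
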