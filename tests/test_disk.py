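"""Tests for the 1D osmo-poroelastic disk column."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinewell.disk import (DEFAULT_DISK_MATERIALS, ColumnStepper,
                            axial_tangent_stiffness, build_column,
                            intradiscal_pressure, permeability,
                            solve_consolidation)
from spinewell.errors import ConfigError

NP_PARAMS = DEFAULT_DISK_MATERIALS["NP"]


def uniform_column(n_nodes=11, area=100.0):
    """Single-tissue column (NP everywhere) for closed-form comparisons."""
    mats = {"NP": NP_PARAMS, "CEP": NP_PARAMS}
    return build_column(np_height=4.0, cep_height=2.0, area=area,
                        materials=mats, delta_pi=0.0, n_nodes=n_nodes)


# ----------------------------------------------------------------------
# permeability law
# ----------------------------------------------------------------------

def test_permeability_normalization_exact():
    for params in DEFAULT_DISK_MATERIALS.values():
        assert permeability(params.e0, params) == params.k0


def test_permeability_scalar_oracle():
    # e = 2 e0 for NP, evaluated independently from the law's definition
    e0, k0, M = 4.9, 0.0009, 8.5
    e = 2 * e0
    expected = k0 * ((e * (1 + e0)) / (e0 * (1 + e))) ** 2 \
        * math.exp(M * ((1 + e) / (1 + e0) - 1))
    assert permeability(e, NP_PARAMS) == pytest.approx(expected, rel=1e-14)
    assert expected == pytest.approx(1.2502118712375176, rel=1e-12)


@given(e=st.floats(0.1, 12.0), d=st.floats(1e-4, 1.0))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_permeability_strictly_increasing(e, d):
    assert permeability(e + d, NP_PARAMS) > permeability(e, NP_PARAMS)


def test_permeability_vanishes_at_zero_void_ratio():
    assert permeability(1e-9, NP_PARAMS) < 1e-12 * NP_PARAMS.k0
    with pytest.raises(ValueError):
        permeability(0.0, NP_PARAMS)


# ----------------------------------------------------------------------
# column construction
# ----------------------------------------------------------------------

def test_build_column_valid():
    col = build_column(8.0, 0.8, 1800.0, None, 0.15, 11)
    assert col.n_nodes == 31
    assert col.height == pytest.approx(9.6)
    assert col.pi[0] == 0.0 and col.pi[-1] == 0.0
    assert col.pi[col.np_center_node] == 0.15


def test_build_column_mirror_symmetric():
    col = build_column(8.0, 0.8, 1800.0, None, 0.15, 9)
    assert np.allclose(col.z + col.z[::-1], col.height)
    assert np.allclose(col.pi, col.pi[::-1])
    assert tuple(col.element_tissue) == tuple(col.element_tissue[::-1])


def test_build_column_errors():
    with pytest.raises(ConfigError):
        build_column(np_height=0.0)
    with pytest.raises(ConfigError):
        build_column(n_nodes=3)


# ----------------------------------------------------------------------
# consolidation solver
# ----------------------------------------------------------------------

def test_no_load_no_osmosis_is_inert():
    col = build_column(delta_pi=0.0, n_nodes=7)
    states = solve_consolidation(col, lambda t: 0.0, 100.0, dt=10.0)
    final = states[-1]
    assert np.max(np.abs(final.u)) < 1e-14
    assert np.max(np.abs(final.p)) < 1e-14


def test_terzaghi_consolidation_oracle():
    """Step load on a uniform constant-permeability column vs the classical
    consolidation series solution: < 1% space-time L2 error."""
    col = uniform_column()
    F = 5.0
    s0 = F / col.area
    H = col.height
    cv = NP_PARAMS.k0 * NP_PARAMS.aggregate_modulus

    def series(z, t):
        return sum(4 * s0 / (m * math.pi) * math.sin(m * math.pi * z / H)
                   * math.exp(-(m * math.pi / H) ** 2 * cv * t)
                   for m in range(1, 200, 2))

    states = solve_consolidation(col, lambda t: F, 4000.0, dt=10.0,
                                 strain_dependent_permeability=False)
    num = den = 0.0
    for s in states:
        if s.time < 100.0:
            continue
        exact = np.array([series(z, s.time) for z in col.z])
        num += np.sum((s.p - exact) ** 2)
        den += np.sum(exact ** 2)
    assert math.sqrt(num / den) < 0.01


def test_undrained_step_response():
    """An instantaneous load is carried entirely by the fluid: the filtered
    NP pressure equals F/A."""
    col = build_column(delta_pi=0.0, n_nodes=9)
    st_ = ColumnStepper(col)
    F = 276.0
    s = st_.trial_force(F, 2.0)
    assert intradiscal_pressure(s, col) == pytest.approx(F / col.area, rel=0.02)


def test_monotone_relaxation_under_constant_load():
    col = uniform_column()
    states = solve_consolidation(col, lambda t: 5.0, 3000.0, dt=20.0,
                                 strain_dependent_permeability=False)
    center = [intradiscal_pressure(s, col) for s in states[1:]]
    # 1e-6 absolute slack: equal-order element ripple on the undrained
    # plateau (max observed ~1e-7 per step, vs a 5e-2 signal)
    assert all(a >= b - 1e-6 for a, b in zip(center, center[1:]))


def test_overnight_swelling_pressure_rise():
    """Free swelling against drained boundaries drives the NP pressure to the
    osmotic plateau; the 8 h rise lands in the in-vivo overnight window."""
    col = build_column(8.0, 0.8, 1800.0, None, 0.15, 11)
    states = solve_consolidation(col, lambda t: 0.0, 8 * 3600.0, dt=1.0,
                                 dt_max=600.0)
    rise = intradiscal_pressure(states[-1], col) - intradiscal_pressure(states[0], col)
    assert 0.11 <= rise <= 0.15
    # cannot exceed the driving gradient under zero external load
    assert max(intradiscal_pressure(s, col) for s in states) <= 0.15 + 1e-9


def test_swelling_reciprocity_small_gradient():
    """Equilibrium pressure rise is linear in the osmotic gradient (small
    strains): doubling delta_pi doubles the rise within 5%."""
    rises = []
    for dpi in (0.01, 0.02):
        col = build_column(8.0, 0.8, 1800.0, None, dpi, 9)
        states = solve_consolidation(col, lambda t: 0.0, 8 * 3600.0, dt=1.0,
                                     dt_max=600.0)
        rises.append(intradiscal_pressure(states[-1], col))
    assert rises[1] / rises[0] == pytest.approx(2.0, rel=0.05)


def test_mesh_convergence_of_swelling():
    """Halving the node spacing changes the 8 h NP pressure by < 1%."""
    vals = []
    for n in (7, 13):
        col = build_column(8.0, 0.8, 1800.0, None, 0.15, n)
        states = solve_consolidation(col, lambda t: 0.0, 8 * 3600.0, dt=1.0,
                                     dt_max=600.0)
        vals.append(intradiscal_pressure(states[-1], col))
    assert abs(vals[1] - vals[0]) / vals[1] < 0.01


# ----------------------------------------------------------------------
# tangent stiffness
# ----------------------------------------------------------------------

def test_drained_tangent_stiffness_matches_closed_form():
    col = uniform_column()
    st_ = ColumnStepper(col, strain_dependent_permeability=False)
    K_drained = axial_tangent_stiffness(st_, dt=1e9)
    expected = NP_PARAMS.aggregate_modulus * col.area / col.height
    assert K_drained == pytest.approx(expected, rel=0.02)
    assert K_drained == pytest.approx(col.drained_axial_stiffness(), rel=0.02)


def test_undrained_stiffer_than_drained():
    col = uniform_column()
    st_ = ColumnStepper(col, strain_dependent_permeability=False)
    K_fast = axial_tangent_stiffness(st_, dt=1.0)
    K_slow = axial_tangent_stiffness(st_, dt=1e9)
    assert K_fast > K_slow > 0
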