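"""Unit and property tests for the active transversely isotropic muscle law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from conftest import random_kinematics, random_rotation
from spinewell.errors import InvalidKinematicsError, InvalidStrainError
from spinewell.muscle import (DEFAULT_MATERIALS, FiberKinematics,
                              active_fiber_factor,
                              active_parameter_from_sarcomere, cauchy_stress,
                              contractile_strain, fascicle_axial_force,
                              passive_fiber_factor, second_piola_kirchhoff,
                              strain_energy, strain_energy_from_cauchy_green)

MF = DEFAULT_MATERIALS["MF"]


def fd_second_pk(C, N, material, zeta, h=1e-6):
    """Independent oracle: S = 2 dU/dC by central differences on the energy
    (valid entrywise because the energy extends symmetrically in C)."""
    S = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Cp, Cm = C.copy(), C.copy()
            Cp[i, j] += h
            Cm[i, j] -= h
            S[i, j] = (strain_energy_from_cauchy_green(Cp, N, material, zeta)
                       - strain_energy_from_cauchy_green(Cm, N, material, zeta)) / (2 * h)
    return 2.0 * S


# ----------------------------------------------------------------------
# scalar fiber laws
# ----------------------------------------------------------------------

@pytest.mark.parametrize("lam, A, expected", [
    (1.0, 4.0, 0.0),            # threshold boundary
    (0.9, 4.0, 0.0),            # shortened fiber: passive branch off
    (1.1, 4.0, 0.04),           # 4 * 0.1^2
])
def test_passive_fiber_factor_values(lam, A, expected):
    assert passive_fiber_factor(lam, A) == pytest.approx(expected, abs=1e-14)


def test_passive_fiber_factor_rejects_nonpositive_stretch():
    with pytest.raises(InvalidKinematicsError):
        passive_fiber_factor(0.0, 4.0)


@pytest.mark.parametrize("lam, zeta, expected", [
    (1.0, 0.0, 0.0),                          # at threshold
    (0.99, -0.01, 0.0),                       # at shifted threshold
    (1.02, 0.0, 0.1 * (math.e ** 2 - 1.0)),   # 0.1*(e^2 - 1)
    (1.0, -0.01, 0.1 * (math.e - 1.0)),       # concentric: active at lam = 1
])
def test_active_fiber_factor_values(lam, zeta, expected):
    assert active_fiber_factor(lam, zeta) == pytest.approx(expected, rel=1e-12)


def test_active_fiber_factor_continuous_at_threshold():
    for zeta in (-0.02, 0.0, 0.01):
        thr = 1.0 + zeta
        below = active_fiber_factor(thr, zeta)
        above = active_fiber_factor(thr + 1e-12, zeta)
        assert below == 0.0
        assert above == pytest.approx(0.0, abs=1e-9)


@given(lam=st.floats(0.8, 1.3), d=st.floats(1e-6, 0.05))
@settings(max_examples=80, deadline=None, derandomize=True)
def test_fiber_factors_nondecreasing(lam, d):
    assert passive_fiber_factor(lam + d, 4.0) >= passive_fiber_factor(lam, 4.0)
    for zeta in (-0.02, 0.0, 0.01):
        assert active_fiber_factor(lam + d, zeta) >= active_fiber_factor(lam, zeta)


@pytest.mark.parametrize("eps, zeta, branch", [
    (0.0, 0.0, "inactive"),
    (0.015, 0.465 * 0.015, "eccentric"),      # C_CE2 branch
    (-0.02, 0.706 * -0.02, "concentric"),     # C_CE1 branch
])
def test_contractile_strain(eps, zeta, branch):
    act = contractile_strain(eps, MF)
    assert act.zeta == pytest.approx(zeta, rel=1e-12)
    assert act.branch == branch
    assert math.copysign(1, act.zeta) == math.copysign(1, eps) or eps == 0


@given(eps=st.floats(-0.9, 0.5))
@settings(max_examples=80, deadline=None, derandomize=True)
def test_contractile_strain_sign_and_branch(eps):
    act = contractile_strain(eps, MF)
    if eps < 0:
        assert act.branch == "concentric" and act.zeta < 0
    elif eps > 0:
        assert act.branch == "eccentric" and act.zeta > 0
    else:
        assert act.branch == "inactive" and act.zeta == 0.0


def test_contractile_strain_annihilation():
    with pytest.raises(InvalidStrainError):
        contractile_strain(-1.0, MF)


def test_active_parameter_from_sarcomere():
    assert active_parameter_from_sarcomere(2.8, 2.8) == pytest.approx(1.0)
    # invert the shipped PS and MF values, then forward-check
    assert active_parameter_from_sarcomere(1.111 * 2.8) == pytest.approx(1.111)
    assert active_parameter_from_sarcomere(0.811 * 2.8) == pytest.approx(0.811)
    with pytest.raises(ValueError):
        active_parameter_from_sarcomere(-1.0)


# ----------------------------------------------------------------------
# energy
# ----------------------------------------------------------------------

def test_energy_zero_at_reference():
    kin = FiberKinematics(np.eye(3), np.array([0.0, 0.0, 1.0]))
    assert strain_energy(kin, MF, 0.0) == 0.0


def test_energy_pure_dilatation_is_volumetric_only():
    J = 1.1
    kin = FiberKinematics(J ** (1 / 3) * np.eye(3), np.array([1.0, 0.0, 0.0]))
    expected = MF.K / 2.0 * math.log(J) ** 2
    assert strain_energy(kin, MF, 0.0) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("zeta", [0.0, 0.465 * 0.03, -0.005])
def test_energy_matches_quadrature_of_fiber_integrals(zeta):
    """Closed-form fiber integrals vs adaptive quadrature of the integrands."""
    lam = 1.05
    F = np.diag([lam ** -0.5, lam ** -0.5, lam])   # isochoric uniaxial
    kin = FiberKinematics(F, np.array([0.0, 0.0, 1.0]))
    U = strain_energy(kin, MF, zeta)
    fiber, _ = quad(lambda x: MF.sigma0 * (passive_fiber_factor(x, MF.A)
                                           + active_fiber_factor(x, zeta)),
                    1.0, lam, epsabs=1e-14, epsrel=1e-13, limit=200)
    matrix = MF.G / 2.0 * (kin.I1_bar - 3.0)
    assert U == pytest.approx(matrix + fiber, rel=1e-10)


def test_kinematics_deviatoric_stretch_identity(rng):
    for _ in range(20):
        F, N = random_kinematics(rng)
        kin = FiberKinematics(F, N)
        lam_bar_direct = math.sqrt(float(N @ kin.C_bar @ N))
        assert kin.lam_f_bar == pytest.approx(lam_bar_direct, abs=1e-12)
        assert kin.lam_f_bar == pytest.approx(kin.J ** (-1 / 3) * kin.lam,
                                              abs=1e-12)


def test_kinematics_validation():
    with pytest.raises(InvalidKinematicsError):
        FiberKinematics(np.diag([1.0, 1.0, -1.0]), np.array([0, 0, 1.0]))
    with pytest.raises(InvalidKinematicsError):
        FiberKinematics(np.eye(3), np.array([0, 0, 1.1]))


# ----------------------------------------------------------------------
# stress
# ----------------------------------------------------------------------

def test_stress_zero_at_reference():
    kin = FiberKinematics(np.eye(3), np.array([0.0, 0.0, 1.0]))
    res = cauchy_stress(kin, MF, 0.0)
    assert np.max(np.abs(res.S)) < 1e-12
    assert np.max(np.abs(res.sigma)) < 1e-12


@pytest.mark.parametrize("case", ["uniaxial", "shear"])
def test_second_pk_matches_finite_differences(case):
    N = np.array([0.0, 0.0, 1.0])
    if case == "uniaxial":
        lam = 1.03
        F = np.diag([lam ** -0.5, lam ** -0.5, lam])
    else:
        F = np.eye(3)
        F[0, 2] = 0.1  # simple shear, fiber in the shear plane
    kin = FiberKinematics(F, N)
    S = second_piola_kirchhoff(kin, MF, 0.0).S
    S_fd = fd_second_pk(kin.C, N, MF, 0.0)
    assert np.linalg.norm(S - S_fd) / np.linalg.norm(S_fd) < 1e-6


def test_cauchy_is_push_forward_and_fiber_direction(rng):
    for _ in range(10):
        F, N = random_kinematics(rng)
        kin = FiberKinematics(F, N)
        res = cauchy_stress(kin, MF, 0.002)
        push = F @ res.S @ F.T / kin.J
        assert np.max(np.abs(res.sigma - push)) < 1e-10
        assert np.linalg.norm(res.n - F @ N / np.linalg.norm(F @ N)) < 1e-12
        assert np.max(np.abs(res.sigma - res.sigma.T)) < 1e-10


def test_frame_indifference(rng):
    F, N = random_kinematics(rng)
    kin = FiberKinematics(F, N)
    sigma = cauchy_stress(kin, MF, 0.003).sigma
    for _ in range(10):
        Q = random_rotation(rng)
        sigma_rot = cauchy_stress(FiberKinematics(Q @ F, N), MF, 0.003).sigma
        assert np.max(np.abs(sigma_rot - Q @ sigma @ Q.T)) < 1e-9


# ----------------------------------------------------------------------
# uniaxial fascicle element
# ----------------------------------------------------------------------

def test_fascicle_force_zero_at_rest():
    act = contractile_strain(0.0, MF)
    total, passive, active, matrix = fascicle_axial_force(1.0, act, MF, 100.0)
    assert total == passive == active == matrix == 0.0


def test_fascicle_force_eccentric_example():
    """Stretch-activated MF element: independent scalar evaluation."""
    eps = 0.015
    act = contractile_strain(eps, MF)
    total, passive, active, matrix = fascicle_axial_force(1.0 + eps, act, MF, 100.0)
    zeta = 0.465 * eps
    expected_active = 0.46 * 0.1 * (math.exp(100 * (1.015 - 1 - zeta)) - 1) * 100 / 1.015
    assert active == pytest.approx(expected_active, rel=1e-12)
    assert active == pytest.approx(5.579422670512867, rel=1e-12)
    assert passive > 0 and matrix > 0
    assert total == pytest.approx(active + passive + matrix)


def test_fascicle_force_concentric_threshold_logic():
    """At lam = 0.98 with eps = -0.02 the activation threshold sits at
    1 + zeta = 0.98588 > lam, so only the matrix term (compressive) acts."""
    eps = -0.02
    act = contractile_strain(eps, MF)
    assert 1.0 + act.zeta > 1.0 + eps
    total, passive, active, matrix = fascicle_axial_force(1.0 + eps, act, MF, 100.0)
    assert passive == 0.0 and active == 0.0
    assert matrix < 0 and total == matrix


def test_fascicle_force_validation():
    act = contractile_strain(0.0, MF)
    with pytest.raises(InvalidKinematicsError):
        fascicle_axial_force(0.0, act, MF, 100.0)
    with pytest.raises(ValueError):
        fascicle_axial_force(1.0, act, MF, -1.0)


def test_material_invariants():
    for g, m in DEFAULT_MATERIALS.items():
        assert m.G > 0 and m.K > 0 and m.sigma0 > 0 and m.A >= 0
        assert m.C_CE1 > m.C_CE2 > 0
    assert DEFAULT_MATERIALS["MF"].K == pytest.approx(1000 * DEFAULT_MATERIALS["MF"].G)
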