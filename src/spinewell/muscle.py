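"""Active, transversely isotropic, hyperelastic muscle constitutive law.

The muscle tissue is a fiber-reinforced composite: an isotropic Neo-Hookean
matrix (deviatoric shear modulus ``G``, volumetric bulk modulus ``K``) with
embedded muscle fibers following a Hill-type rheology (parallel PE, series SE
and contractile CE elements).  The strain energy density decouples as

    U = G/2 (Ibar1 - 3) + K/2 (ln J)^2
        + sigma0 * int_1^lam_f_bar f_PE(lam) dlam
        + sigma0 * int_1^lam_f_bar f_SE(lam, zeta) dlam

where ``lam_f_bar = J^(-1/3) * lambda`` is the deviatoric fiber stretch
(``lambda = sqrt(N^T C N)``, ``N`` the unit fiber direction in the reference
configuration), ``sigma0`` the maximum tetanic stress and ``zeta`` the
contractile strain of the CE.  The passive branch is the quadratic
force-elongation law f_PE = A (lam - 1)^2 for lam > 1; the active branch is
the exponential contractile stress-stretch function
f_SE = 0.1 (exp[100 (lam - 1 - zeta)] - 1) for lam > 1 + zeta.

Activation needs no explicit neural input: ``zeta`` is slaved to the
engineering strain ``eps`` of the whole element through the active parameter
C_CE (optimal-to-resting sarcomere length ratio), with separate concentric
(eps < 0) and eccentric (eps > 0) values.  The stress tensors are obtained by
exact differentiation of the energy: S = 2 dU/dC (second Piola-Kirchhoff) and
sigma = J^-1 F S F^T (Cauchy).

Unit convention: N - mm - MPa - s.  Energies are MPa (= N*mm/mm^3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidKinematicsError, InvalidStrainError

__all__ = [
    "MuscleMaterial",
    "FiberKinematics",
    "ActivationState",
    "StressResult",
    "DEFAULT_MATERIALS",
    "OPTIMAL_SARCOMERE_LENGTH_UM",
    "passive_fiber_factor",
    "active_fiber_factor",
    "contractile_strain",
    "active_parameter_from_sarcomere",
    "strain_energy",
    "strain_energy_from_cauchy_green",
    "second_piola_kirchhoff",
    "cauchy_stress",
    "fascicle_axial_force",
]

MUSCLE_GROUPS = ("MF", "LTpL", "LTpTh", "ILpL", "PS")

#: Optimal sarcomere length (micrometres) used to normalize sarcomere-length
#: estimates into the dimensionless active parameter C_CE.
OPTIMAL_SARCOMERE_LENGTH_UM = 2.8


@dataclass(frozen=True)
class MuscleMaterial:
    """Parameter set of one muscle group.

    Parameters
    ----------
    G, K : float
        Matrix shear and bulk moduli (MPa).  The matrix is modeled as nearly
        incompressible; the shipped defaults use K = 1000 * G.
    sigma0 : float
        Maximum tetanic stress (MPa), the common stress scale of the passive
        and active fiber branches.
    A : float
        Dimensionless constant of the quadratic passive fiber law.
    C_CE1, C_CE2 : float
        Concentric (shortening) and eccentric (lengthening) active
        parameters; zeta = C_CE1*eps for eps < 0, C_CE2*eps for eps > 0.
    C_CE_literature : float, optional
        Sarcomere-length-derived active parameter (single-valued), kept for
        cross-checking the constant rescaling between the literature column
        and the working (C_CE1, C_CE2) pair.
    """

    G: float
    K: float
    sigma0: float
    A: float
    C_CE1: float
    C_CE2: float
    group_label: str
    C_CE_literature: float | None = None

    def __post_init__(self):
        if self.G <= 0 or self.K <= 0 or self.sigma0 <= 0:
            raise ValueError("G, K and sigma0 must be positive")
        if self.A < 0:
            raise ValueError("A must be non-negative")
        if self.C_CE1 <= 0 or self.C_CE2 <= 0:
            raise ValueError("active parameters must be positive")
        if self.group_label not in MUSCLE_GROUPS:
            raise ValueError(f"unknown muscle group {self.group_label!r}")


def _default_materials() -> dict[str, MuscleMaterial]:
    G = 16.42e-4  # MPa
    common = dict(G=G, K=1000.0 * G, sigma0=0.46, A=4.0)
    table = {
        # group: (C_CE1 concentric, C_CE2 eccentric, literature C_CE)
        "MF": (0.706, 0.465, 0.811),
        "LTpL": (0.718, 0.473, 0.825),
        "LTpTh": (0.718, 0.473, 0.825),
        "ILpL": (0.737, 0.485, 0.846),
        "PS": (0.967, 0.637, 1.111),
    }
    return {
        g: MuscleMaterial(group_label=g, C_CE1=c1, C_CE2=c2,
                          C_CE_literature=cl, **common)
        for g, (c1, c2, cl) in table.items()
    }


#: Shipped defaults, one entry per muscle group.
DEFAULT_MATERIALS: dict[str, MuscleMaterial] = _default_materials()


@dataclass(frozen=True)
class FiberKinematics:
    """Deformation gradient plus reference fiber direction, with the derived
    invariants used by the constitutive law."""

    F: np.ndarray
    N: np.ndarray

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        N = np.asarray(self.N, dtype=float)
        if F.shape != (3, 3) or N.shape != (3,):
            raise InvalidKinematicsError("F must be 3x3 and N a 3-vector")
        if abs(np.linalg.norm(N) - 1.0) > 1e-12:
            raise InvalidKinematicsError("fiber direction N must be a unit vector")
        if np.linalg.det(F) <= 0:
            raise InvalidKinematicsError("det F must be positive")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "N", N)

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def C(self) -> np.ndarray:
        return self.F.T @ self.F

    @property
    def C_bar(self) -> np.ndarray:
        return self.J ** (-2.0 / 3.0) * self.C

    @property
    def I1_bar(self) -> float:
        return float(np.trace(self.C_bar))

    @property
    def lam(self) -> float:
        """Fiber stretch ratio sqrt(N^T C N)."""
        return math.sqrt(float(self.N @ self.C @ self.N))

    @property
    def lam_f_bar(self) -> float:
        """Deviatoric fiber stretch J^(-1/3) * lam = sqrt(N^T Cbar N)."""
        return self.J ** (-1.0 / 3.0) * self.lam


@dataclass(frozen=True)
class ActivationState:
    """Contractile-element state: engineering strain, contractile strain and
    the branch of the active tension-length curve."""

    epsilon: float
    zeta: float
    branch: str  # "concentric" | "eccentric" | "inactive"


@dataclass
class StressResult:
    """Stress evaluation output; unused entries are None."""

    U: float | None = None
    S: np.ndarray | None = None
    sigma: np.ndarray | None = None
    sigma_PE: float | None = None
    sigma_SE: float | None = None
    n: np.ndarray | None = field(default=None)


# ----------------------------------------------------------------------
# scalar fiber laws
# ----------------------------------------------------------------------

def passive_fiber_factor(lam_f_bar: float, A: float) -> float:
    """Quadratic passive (PE) stress-stretch factor: A*(lam-1)^2 above rest
    length, zero otherwise.  Continuous and C1 at lam = 1."""
    if lam_f_bar <= 0:
        raise InvalidKinematicsError("fiber stretch must be positive")
    if lam_f_bar <= 1.0:
        return 0.0
    return A * (lam_f_bar - 1.0) ** 2


def active_fiber_factor(lam_f_bar: float, zeta: float) -> float:
    """Contractile (SE/CE) stress-stretch factor.

    Zero at and below the activation threshold lam = 1 + zeta, exponential
    above it.  At lam = 1 + zeta the contractile element shortens at its
    maximum velocity and transmits no force.
    """
    if lam_f_bar <= 0:
        raise InvalidKinematicsError("fiber stretch must be positive")
    if lam_f_bar <= 1.0 + zeta:
        return 0.0
    return 0.1 * math.expm1(100.0 * (lam_f_bar - 1.0 - zeta))


def contractile_strain(epsilon: float, material: MuscleMaterial) -> ActivationState:
    """Map the engineering strain of the element to the contractile strain
    zeta, choosing the concentric or eccentric active parameter."""
    if epsilon <= -1.0:
        raise InvalidStrainError(
            f"engineering strain {epsilon} <= -1: element annihilated")
    if epsilon < 0.0:
        return ActivationState(epsilon, material.C_CE1 * epsilon, "concentric")
    if epsilon > 0.0:
        return ActivationState(epsilon, material.C_CE2 * epsilon, "eccentric")
    return ActivationState(0.0, 0.0, "inactive")


def active_parameter_from_sarcomere(L_S: float,
                                    L0_S: float = OPTIMAL_SARCOMERE_LENGTH_UM) -> float:
    """Active parameter C_CE = L_S / L0_S from sarcomere lengths (um).

    Assumes normalized length ratios are preserved from the sarcomere to the
    fascicle level, so the optimal-to-resting fascicle length ratio equals
    the sarcomere one.
    """
    if L_S <= 0 or L0_S <= 0:
        raise ValueError("sarcomere lengths must be positive")
    return L_S / L0_S


# closed-form antiderivatives of the two fiber laws -------------------------

def _passive_integral(lam_f_bar: float, A: float) -> float:
    """int_1^lam f_PE dlam in closed form (zero below rest length)."""
    if lam_f_bar <= 1.0:
        return 0.0
    return A * (lam_f_bar - 1.0) ** 3 / 3.0


def _active_antiderivative(x: float, zeta: float) -> float:
    """Antiderivative of f_SE, chosen zero at the threshold x = 1 + zeta."""
    if x <= 1.0 + zeta:
        return 0.0
    y = x - 1.0 - zeta
    return 0.1 * (math.expm1(100.0 * y) / 100.0 - y)


def _active_integral(lam_f_bar: float, zeta: float) -> float:
    """int_1^lam f_SE dlam in closed form (handles thresholds on either side
    of 1, e.g. concentric states where zeta < 0 activate at lam <= 1)."""
    return _active_antiderivative(lam_f_bar, zeta) - _active_antiderivative(1.0, zeta)


# ----------------------------------------------------------------------
# energy and stress
# ----------------------------------------------------------------------

def strain_energy_from_cauchy_green(C: np.ndarray, N: np.ndarray,
                                    material: MuscleMaterial, zeta: float) -> float:
    """Strain energy density evaluated directly from the right Cauchy-Green
    tensor.  Used both by :func:`strain_energy` and by finite-difference
    oracles that perturb C."""
    C = np.asarray(C, dtype=float)
    detC = float(np.linalg.det(C))
    if detC <= 0:
        raise InvalidKinematicsError("det C must be positive")
    J = math.sqrt(detC)
    I1 = float(np.trace(C))
    I1_bar = J ** (-2.0 / 3.0) * I1
    lam2 = float(N @ C @ N)
    if lam2 <= 0:
        raise InvalidKinematicsError("non-positive fiber stretch")
    lam_f_bar = J ** (-1.0 / 3.0) * math.sqrt(lam2)
    U = material.G / 2.0 * (I1_bar - 3.0)
    U += material.K / 2.0 * math.log(J) ** 2
    U += material.sigma0 * _passive_integral(lam_f_bar, material.A)
    U += material.sigma0 * _active_integral(lam_f_bar, zeta)
    return U


def strain_energy(kin: FiberKinematics, material: MuscleMaterial,
                  zeta: float = 0.0) -> float:
    """Strain energy density U (MPa); zero in the reference state at zeta = 0."""
    return strain_energy_from_cauchy_green(kin.C, kin.N, material, zeta)


def second_piola_kirchhoff(kin: FiberKinematics, material: MuscleMaterial,
                           zeta: float = 0.0) -> StressResult:
    """Second Piola-Kirchhoff stress S = 2 dU/dC, by exact differentiation
    of the energy.

    The three contributions are

        S_iso = G J^(-2/3) (I - I1/3 C^-1)
        S_vol = K ln(J) C^-1
        S_fib = sigma0 (f_PE + f_SE) lam_f_bar (N(x)N / lam^2 - C^-1 / 3)
    """
    C = kin.C
    Cinv = np.linalg.inv(C)
    J = kin.J
    I1 = float(np.trace(C))
    lam = kin.lam
    lfb = kin.lam_f_bar
    N = kin.N

    S = material.G * J ** (-2.0 / 3.0) * (np.eye(3) - (I1 / 3.0) * Cinv)
    S += material.K * math.log(J) * Cinv

    f_pe = passive_fiber_factor(lfb, material.A)
    f_se = active_fiber_factor(lfb, zeta)
    UF_prime = material.sigma0 * (f_pe + f_se)
    if UF_prime != 0.0:
        S += UF_prime * lfb * (np.outer(N, N) / lam ** 2 - Cinv / 3.0)

    S = 0.5 * (S + S.T)  # enforce exact symmetry against round-off
    return StressResult(
        U=strain_energy(kin, material, zeta),
        S=S,
        sigma_PE=material.sigma0 * f_pe,
        sigma_SE=material.sigma0 * f_se,
    )


def cauchy_stress(kin: FiberKinematics, material: MuscleMaterial,
                  zeta: float = 0.0) -> StressResult:
    """Cauchy stress sigma = J^-1 F S F^T, with the deformed fiber direction
    n = F N / |F N| reported alongside."""
    res = second_piola_kirchhoff(kin, material, zeta)
    F = kin.F
    sigma = (F @ res.S @ F.T) / kin.J
    res.sigma = 0.5 * (sigma + sigma.T)
    fn = F @ kin.N
    res.n = fn / np.linalg.norm(fn)
    return res


def fascicle_axial_force(lam: float, activation: ActivationState,
                         material: MuscleMaterial, csa: float):
    """Axial force of a straight unidirectional fascicle element.

    Uniaxial, isochoric specialization (J = 1, hence lam_f_bar = lam) with a
    laterally traction-free matrix: the matrix contributes the incompressible
    Neo-Hookean uniaxial Cauchy stress G (lam^2 - 1/lam); the fiber branches
    contribute sigma0*f_PE and sigma0*f_SE along the fiber.  Forces are the
    Cauchy stresses times the current cross-section csa/lam; tension is
    positive.

    Returns
    -------
    (total, passive_fiber, active, matrix) : tuple of float, in newtons.
    """
    if lam <= 0:
        raise InvalidKinematicsError("stretch must be positive")
    if csa <= 0:
        raise ValueError("cross-sectional area must be positive")
    area = csa / lam
    matrix = material.G * (lam ** 2 - 1.0 / lam) * area
    passive = material.sigma0 * passive_fiber_factor(lam, material.A) * area
    active = material.sigma0 * active_fiber_factor(lam, activation.zeta) * area
    return (matrix + passive + active, passive, active, matrix)
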