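"""Gasser-Ogden-Holzapfel (GOH) hyperelasticity for incompressible membranes.

The strain-energy density of a matrix reinforced by N = 2 symmetric,
dispersed collagen-fiber families is

    U = C10 (I1 - 3) + k1/(2 k2) * sum_a { exp(k2 <E_a>^2) - 1 }

with the dispersed fiber strain of family a

    E_a = kappa (I1 - 3) + (1 - 3 kappa) (I4_a - 1),

where I1 = tr(C) and I4_a = a0_a . C a0_a are invariants of the right
Cauchy-Green tensor C = F^T F, a0_a are the unit mean fiber directions at
+/-gamma from the x axis in the membrane plane, <x> = max(x, 0) is the
Macauley bracket (fibers bear load only in extension), and kappa =
(1/4) int_0^pi rho(Theta) sin^3(Theta) dTheta measures fiber dispersion
(0 = perfectly aligned, 1/3 = 3-d isotropic).

The material is treated as exactly incompressible (the inverse bulk modulus
D is pinned to 0, J = 1): the thickness stretch is lambda_z =
1/(lambda_x lambda_y) and the reaction pressure is eliminated through the
membrane plane-stress condition sigma_zz = 0.

Units: stresses and C10, k1 in kPa; angles in degrees at the interface,
radians internally; stretches and k2, kappa dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .curves import StressStrainCurve, log_strain
from .errors import DomainError, FiberOverflowError

__all__ = [
    "MaterialParams",
    "PlanarDeformation",
    "FiberStrainState",
    "OrientationDensity",
    "kappa_from_density",
    "fiber_state",
    "strain_energy",
    "cauchy_stress",
    "biaxial_stress",
    "cauchy_stress_biaxial",
    "equibiaxial_curve",
    "simple_shear_stress",
    "small_strain_moduli",
]

#: isotropic value of the dispersion parameter (3-d uniform fiber density)
KAPPA_ISO = 1.0 / 3.0

#: default safety bound on the fiber exponent k2*<E>^2
EXP_BOUND = 50.0

_KAPPA_TOL = 1e-9


@dataclass(frozen=True)
class MaterialParams:
    """GOH parameter vector.

    Parameters
    ----------
    C10 : float
        Stress-like stiffness of the isotropic matrix, kPa. Must be > 0.
    k1 : float
        Stress-like fiber stiffness, kPa. k1 = 0 disables the fiber term and
        reduces the model to incompressible neo-Hooke with mu = 2*C10.
    k2 : float
        Dimensionless fiber exponent; > 0 whenever k1 > 0.
    gamma_deg : float
        Mean fiber angle from the x (alignment) axis, degrees, in [0, 90].
    kappa : float
        Fiber dispersion in [0, 1/3]; 1/3 is isotropic.
    D : float
        Inverse bulk modulus, kPa^-1. Fixed to 0 here (incompressible).
    n_families : int
        Number of fiber families; fixed to 2 (at +gamma and -gamma).
    """

    C10: float
    k1: float = 0.0
    k2: float = 1.0
    gamma_deg: float = 45.0
    kappa: float = KAPPA_ISO
    D: float = 0.0
    n_families: int = 2

    def __post_init__(self):
        if not (self.C10 > 0.0 and math.isfinite(self.C10)):
            raise DomainError(f"C10 must be finite and > 0, got {self.C10}")
        if self.k1 < 0.0:
            raise DomainError(f"k1 must be >= 0, got {self.k1}")
        if self.k1 > 0.0 and self.k2 <= 0.0:
            raise DomainError("k2 must be > 0 when k1 > 0")
        if not (0.0 <= self.gamma_deg <= 90.0):
            raise DomainError(f"gamma_deg must be in [0, 90], got {self.gamma_deg}")
        if not (-_KAPPA_TOL <= self.kappa <= KAPPA_ISO + _KAPPA_TOL):
            raise DomainError(f"kappa must be in [0, 1/3], got {self.kappa}")
        if self.D != 0.0:
            raise DomainError("only the incompressible limit D = 0 is supported")
        if self.n_families != 2:
            raise DomainError("exactly 2 symmetric fiber families are supported")

    @property
    def gamma_rad(self) -> float:
        return math.radians(self.gamma_deg)

    def fiber_directions(self) -> np.ndarray:
        """Unit mean directions of the two families, rows of a (2, 3) array."""
        g = self.gamma_rad
        return np.array(
            [[math.cos(g), math.sin(g), 0.0], [math.cos(g), -math.sin(g), 0.0]]
        )

    def replace(self, **kwargs) -> "MaterialParams":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass(frozen=True)
class PlanarDeformation:
    """Homogeneous in-plane deformation of an incompressible membrane.

    F = [[lambda_x, shear, 0], [0, lambda_y, 0], [0, 0, lambda_z]] with the
    thickness stretch lambda_z = 1/(lambda_x lambda_y) enforcing det F = 1.
    ``shear`` is the simple-shear amount (0 for biaxial states).
    """

    lambda_x: float
    lambda_y: float
    shear: float = 0.0

    def __post_init__(self):
        if not (self.lambda_x > 0.0 and self.lambda_y > 0.0):
            raise DomainError("in-plane stretches must be > 0")
        if not all(map(math.isfinite, (self.lambda_x, self.lambda_y, self.shear))):
            raise DomainError("deformation components must be finite")

    @property
    def lambda_z(self) -> float:
        return 1.0 / (self.lambda_x * self.lambda_y)

    @property
    def F(self) -> np.ndarray:
        return np.array(
            [
                [self.lambda_x, self.shear, 0.0],
                [0.0, self.lambda_y, 0.0],
                [0.0, 0.0, self.lambda_z],
            ]
        )

    @property
    def J(self) -> float:
        """Elastic volume ratio; identically 1 by construction."""
        return float(np.linalg.det(self.F))

    @classmethod
    def equibiaxial(cls, lam: float) -> "PlanarDeformation":
        return cls(lam, lam, 0.0)

    @classmethod
    def identity(cls) -> "PlanarDeformation":
        return cls(1.0, 1.0, 0.0)


@dataclass(frozen=True)
class FiberStrainState:
    """Invariants and dispersed fiber strains of a deformation state."""

    I1_bar: float
    I4_bar: np.ndarray      # per family
    E_bar: np.ndarray       # per family, kappa-weighted fiber strain
    active: np.ndarray      # per family, True where E_bar > 0


@dataclass(frozen=True)
class OrientationDensity:
    """Fiber orientation density rho(Theta) on [0, pi].

    Normalized so that (1/2) int_0^pi rho(Theta) sin(Theta) dTheta = 1;
    the uniform density rho = 1 satisfies this. ``quad_points`` optionally
    hints sharp features (e.g. a narrow peak) to the adaptive quadrature.
    """

    density: Callable[[float], float]
    quad_points: tuple = ()

    @classmethod
    def uniform(cls) -> "OrientationDensity":
        return cls(lambda theta: 1.0)


def kappa_from_density(rho: OrientationDensity, *, norm_tol: float = 1e-6) -> float:
    """Dispersion parameter kappa = (1/4) int_0^pi rho sin^3(Theta) dTheta.

    Validates that rho is non-negative and normalized before integrating.
    The result lies in [0, 1/2]: 0 for perfect alignment along the mean
    direction, 1/3 for a uniform (isotropic) density.
    """
    points = list(rho.quad_points) or None
    theta = np.linspace(0.0, math.pi, 721)
    vals = np.array([rho.density(t) for t in theta])
    if np.any(vals < -1e-12):
        raise DomainError("orientation density must be non-negative")
    norm, _ = quad(lambda t: 0.5 * rho.density(t) * math.sin(t), 0.0, math.pi,
                   limit=200, points=points)
    if abs(norm - 1.0) > norm_tol:
        raise DomainError(
            f"orientation density is not normalized: (1/2)∫ρ sinΘ dΘ = {norm:.6g}"
        )
    kappa, _ = quad(lambda t: 0.25 * rho.density(t) * math.sin(t) ** 3, 0.0, math.pi,
                    limit=200, points=points)
    return float(kappa)


def fiber_state(params: MaterialParams, deformation: PlanarDeformation) -> FiberStrainState:
    """Invariants I1, I4 per family and dispersed fiber strains E_a."""
    F = deformation.F
    C = F.T @ F
    I1 = float(np.trace(C))
    a0 = params.fiber_directions()
    I4 = np.einsum("ai,ij,aj->a", a0, C, a0)
    E = params.kappa * (I1 - 3.0) + (1.0 - 3.0 * params.kappa) * (I4 - 1.0)
    return FiberStrainState(I1_bar=I1, I4_bar=I4, E_bar=E, active=E > 0.0)


def _guarded_exponents(params: MaterialParams, E: np.ndarray, bound: float) -> np.ndarray:
    Epos = np.maximum(E, 0.0)
    args = params.k2 * Epos**2
    if params.k1 > 0.0:
        too_big = np.nonzero(args > bound)[0]
        if too_big.size:
            i = int(too_big[0])
            raise FiberOverflowError(i, float(args[i]), bound)
    return Epos


def strain_energy(params: MaterialParams, deformation: PlanarDeformation,
                  *, exp_bound: float = EXP_BOUND) -> float:
    """GOH strain-energy density U in kPa at an incompressible state.

    The volumetric term vanishes identically: D = 0 is treated as the exact
    constraint J = 1, which PlanarDeformation enforces by construction.
    """
    state = fiber_state(params, deformation)
    U = params.C10 * (state.I1_bar - 3.0)
    if params.k1 > 0.0:
        Epos = _guarded_exponents(params, state.E_bar, exp_bound)
        U += params.k1 / (2.0 * params.k2) * float(
            np.sum(np.expm1(params.k2 * Epos**2))
        )
    return float(U)


def cauchy_stress(params: MaterialParams, deformation: PlanarDeformation,
                  *, exp_bound: float = EXP_BOUND) -> np.ndarray:
    """Full Cauchy stress tensor (3x3, kPa) under the plane-stress condition.

    sigma = 2 F (dU/dC) F^T - p I with the reaction pressure p chosen so
    that sigma_zz = 0. Valid for arbitrary in-plane stretch + shear states.
    """
    F = deformation.F
    C = F.T @ F
    I1 = float(np.trace(C))
    a0 = params.fiber_directions()
    I4 = np.einsum("ai,ij,aj->a", a0, C, a0)
    E = params.kappa * (I1 - 3.0) + (1.0 - 3.0 * params.kappa) * (I4 - 1.0)

    dUdC = params.C10 * np.eye(3)
    if params.k1 > 0.0:
        Epos = _guarded_exponents(params, E, exp_bound)
        psi = params.k1 * Epos * np.exp(params.k2 * Epos**2)  # dU/dE per family
        for a in range(2):
            struct = params.kappa * np.eye(3) + (1.0 - 3.0 * params.kappa) * np.outer(
                a0[a], a0[a]
            )
            dUdC = dUdC + psi[a] * struct

    sigma = 2.0 * F @ dUdC @ F.T
    sigma = sigma - sigma[2, 2] * np.eye(3)  # plane stress: sigma_zz = 0
    return sigma


def biaxial_stress(params: MaterialParams, lambda_x, lambda_y,
                   *, exp_bound: float = EXP_BOUND):
    """Vectorized in-plane Cauchy stresses for shear-free biaxial stretch.

    For axis-aligned stretch the two families at +/-gamma see identical
    strain (cos^2 = cos^2, sin^2 = sin^2), and the shear stress vanishes by
    symmetry. Returns (sigma_xx, sigma_yy) in kPa, broadcasting over arrays.
    """
    lx = np.asarray(lambda_x, dtype=float)
    ly = np.asarray(lambda_y, dtype=float)
    if np.any(lx <= 0.0) or np.any(ly <= 0.0):
        raise DomainError("stretches must be > 0")
    lz = 1.0 / (lx * ly)
    lx2, ly2, lz2 = lx * lx, ly * ly, lz * lz
    I1 = lx2 + ly2 + lz2
    c2 = math.cos(params.gamma_rad) ** 2
    s2 = math.sin(params.gamma_rad) ** 2
    I4 = lx2 * c2 + ly2 * s2
    E = params.kappa * (I1 - 3.0) + (1.0 - 3.0 * params.kappa) * (I4 - 1.0)

    sxx = 2.0 * params.C10 * (lx2 - lz2)
    syy = 2.0 * params.C10 * (ly2 - lz2)
    if params.k1 > 0.0:
        Epos = np.maximum(E, 0.0)
        args = params.k2 * Epos**2
        if np.any(args > exp_bound):
            bad = float(np.max(args))
            raise FiberOverflowError(0, bad, exp_bound)
        psi = params.k1 * Epos * np.exp(args)
        # factor 4 = 2 (sigma = 2 F dU/dC F^T - p I) x 2 identical families
        # (under axis-aligned stretch both +/-gamma families see the same E)
        sxx = sxx + 4.0 * psi * (params.kappa * (lx2 - lz2) + (1.0 - 3.0 * params.kappa) * lx2 * c2)
        syy = syy + 4.0 * psi * (params.kappa * (ly2 - lz2) + (1.0 - 3.0 * params.kappa) * ly2 * s2)
    return sxx, syy


def cauchy_stress_biaxial(params: MaterialParams, lambda_x: float, lambda_y: float,
                          *, exp_bound: float = EXP_BOUND) -> tuple[float, float]:
    """Axial Cauchy stresses (sigma_xx, sigma_yy) in kPa for a biaxial state."""
    sxx, syy = biaxial_stress(params, lambda_x, lambda_y, exp_bound=exp_bound)
    return float(sxx), float(syy)


def equibiaxial_curve(params: MaterialParams, stretch_grid: Sequence[float],
                      *, exp_bound: float = EXP_BOUND) -> tuple[StressStrainCurve, StressStrainCurve]:
    """Forward equibiaxial-stretch sweep: one curve per loading axis.

    The grid must be strictly increasing and start at the unloaded state
    lambda = 1 (single-point grids [1.0] are allowed).
    """
    lam = np.asarray(stretch_grid, dtype=float)
    if lam.ndim != 1 or lam.size == 0:
        raise DomainError("stretch_grid must be a non-empty 1-d sequence")
    if abs(lam[0] - 1.0) > 1e-12:
        raise DomainError("stretch_grid must start at 1 (unloaded state)")
    if lam.size > 1 and np.any(np.diff(lam) <= 0.0):
        raise DomainError("stretch_grid must be strictly increasing")
    sxx, syy = biaxial_stress(params, lam, lam, exp_bound=exp_bound)
    eps = log_strain(lam)
    return (
        StressStrainCurve("x", eps, np.atleast_1d(sxx)),
        StressStrainCurve("y", eps, np.atleast_1d(syy)),
    )


def simple_shear_stress(params: MaterialParams, shear: float,
                        *, max_shear: float = 1.0, exp_bound: float = EXP_BOUND) -> float:
    """Cauchy shear stress tau (kPa) under in-plane simple shear F = I + s e1⊗e2."""
    if abs(shear) > max_shear:
        raise DomainError(f"|shear| = {abs(shear):.3g} exceeds the bound {max_shear}")
    sigma = cauchy_stress(params, PlanarDeformation(1.0, 1.0, shear), exp_bound=exp_bound)
    return float(sigma[0, 1])


def _uniaxial_stress(params: MaterialParams, lam: float) -> float:
    """sigma_xx under uniaxial loading: lateral in-plane stress solved to zero."""

    def lateral(ly: float) -> float:
        _, syy = cauchy_stress_biaxial(params, lam, ly)
        return syy

    guess = lam ** (-0.5)  # incompressible isotropic lateral contraction
    lo, hi = 0.95 * guess, 1.05 * guess
    while lateral(lo) > 0.0:
        lo *= 0.95
    while lateral(hi) < 0.0:
        hi *= 1.05
    ly = brentq(lateral, lo, hi, xtol=1e-14, rtol=8.9e-16)
    sxx, _ = cauchy_stress_biaxial(params, lam, ly)
    return sxx


def small_strain_moduli(params: MaterialParams, *, step: float = 1e-4) -> tuple[float, float]:
    """Small-strain Young's modulus E0 and shear modulus G0, kPa.

    E0 is the central-difference slope of the uniaxial Cauchy stress at
    lambda -> 1 with the lateral stresses relaxed to zero; G0 is the slope of
    the simple-shear stress at zero shear. For k1 = 0 (incompressible
    neo-Hooke, mu = 2 C10) the exact values are E0 = 6 C10, G0 = 2 C10 and
    the ratio is the ideal-elastic-network value 3.
    """
    E0 = (_uniaxial_stress(params, 1.0 + step) - _uniaxial_stress(params, 1.0 - step)) / (
        2.0 * step
    )
    G0 = (simple_shear_stress(params, step) - simple_shear_stress(params, -step)) / (
        2.0 * step
    )
    return float(E0), float(G0)
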