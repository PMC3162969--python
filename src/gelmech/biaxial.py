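"""Planar-biaxial test data reduction.

Turns raw acquisition records (four fiducial-marker positions, axial loads in
grams-force, specimen geometry) into Cauchy stress vs logarithmic strain
curves per axis, and differentiates those into tangent-modulus curves.

Conventions follow standard soft-tissue biaxial practice: in-plane stretches
come from the best-fit homogeneous deformation gradient over the marker quad,
true (Cauchy) stress divides the load by the current cross-section obtained
from incompressibility, and the preloaded state serves as the strain
reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .curves import StressStrainCurve, TangentModulusCurve, log_strain
from .errors import DomainError

__all__ = [
    "GF_TO_N",
    "SpecimenGeometry",
    "MarkerQuad",
    "BiaxialRecord",
    "stretches_from_markers",
    "deformation_gradient_from_markers",
    "cauchy_stress_from_load",
    "reduce_experiment",
    "tangent_modulus",
    "average_tangent_modulus",
]

#: grams-force to newtons (standard gravity)
GF_TO_N = 9.80665e-3


@dataclass(frozen=True)
class SpecimenGeometry:
    """Unloaded membrane geometry: edge lengths between loading bars and thickness.

    Defaults are the nominal square collagen-gel specimen: 15 mm x 15 mm
    between bars, 1 mm thick.
    """

    L0x_mm: float = 15.0
    L0y_mm: float = 15.0
    t0_mm: float = 1.0

    def __post_init__(self):
        if min(self.L0x_mm, self.L0y_mm, self.t0_mm) <= 0.0:
            raise DomainError("specimen dimensions must be > 0")


@dataclass(frozen=True)
class MarkerQuad:
    """Four fiducial markers (mm), ordered counterclockwise from lower-left.

    The nominal layout is a 5 mm x 5 mm square at the specimen center.
    """

    points: np.ndarray  # (4, 2)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (4, 2) or not np.all(np.isfinite(pts)):
            raise DomainError("marker quad must be a finite (4, 2) array")
        object.__setattr__(self, "points", pts)
        if self.area() <= 1e-12:
            raise DomainError("degenerate marker quad (non-positive area)")

    def area(self) -> float:
        """Signed shoelace area (positive for counterclockwise ordering)."""
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def centered(self) -> np.ndarray:
        return self.points - self.points.mean(axis=0)

    @classmethod
    def square(cls, side_mm: float = 5.0, center=(0.0, 0.0)) -> "MarkerQuad":
        h = side_mm / 2.0
        corners = np.array([[-h, -h], [h, -h], [h, h], [-h, h]]) + np.asarray(center)
        return cls(corners)


@dataclass(frozen=True)
class BiaxialRecord:
    """One acquisition frame: time, marker quad, axial loads (grams-force)."""

    time_s: float
    markers: MarkerQuad
    load_x_g: float
    load_y_g: float

    def __post_init__(self):
        if self.load_x_g < 0.0 or self.load_y_g < 0.0:
            raise DomainError("loads must be >= 0")


def deformation_gradient_from_markers(ref: MarkerQuad, cur: MarkerQuad) -> np.ndarray:
    """Best-fit homogeneous 2-d deformation gradient F mapping ref -> cur.

    Least squares over the four centered marker positions; translation drops
    out by centering, making the estimate frame-invariant. More robust to
    marker jitter than edge-length ratios.
    """
    X = ref.centered()
    x = cur.centered()
    # solve X @ F.T ~= x
    Ft, *_ = np.linalg.lstsq(X, x, rcond=None)
    return Ft.T


def stretches_from_markers(ref: MarkerQuad, cur: MarkerQuad) -> tuple[float, float]:
    """Axial stretches (lambda_x, lambda_y) from the best-fit F (diagonal part)."""
    F = deformation_gradient_from_markers(ref, cur)
    return float(F[0, 0]), float(F[1, 1])


def cauchy_stress_from_load(load_gf: float, axis: str, geom: SpecimenGeometry,
                            lambda_x: float, lambda_y: float) -> float:
    """Cauchy (true) stress in kPa from an axial load in grams-force.

    The current cross-section normal to axis x is (L0y * t0) / lambda_x by
    incompressibility (the transverse edge stretches by lambda_y while the
    thickness contracts by 1/(lambda_x lambda_y)), so

        sigma_xx = f_x * lambda_x / (L0y * t0)     (symmetric for y).
    """
    if lambda_x <= 0.0 or lambda_y <= 0.0:
        raise DomainError("stretches must be > 0")
    f_N = load_gf * GF_TO_N
    if axis == "x":
        area_mm2 = geom.L0y_mm * geom.t0_mm
        lam = lambda_x
    elif axis == "y":
        area_mm2 = geom.L0x_mm * geom.t0_mm
        lam = lambda_y
    else:
        raise DomainError(f"axis must be 'x' or 'y', got {axis!r}")
    # N / mm^2 = MPa; * 1e3 -> kPa
    return f_N * lam / area_mm2 * 1e3


def _reference_index(records: Sequence[BiaxialRecord], ref_policy: str,
                     preload_g: float, preload_tol_g: float) -> int:
    if ref_policy == "first_frame":
        return 0
    if ref_policy == "preload":
        loads = np.array([max(r.load_x_g, r.load_y_g) for r in records])
        idx = int(np.argmin(np.abs(loads - preload_g)))
        if abs(loads[idx] - preload_g) > preload_tol_g:
            raise DomainError(
                f"reference policy 'preload': no frame within {preload_tol_g} g "
                f"of the {preload_g} g preload (closest: {loads[idx]:.3g} g)"
            )
        return idx
    raise DomainError(f"unknown reference policy {ref_policy!r}")


def reduce_experiment(records: Sequence[BiaxialRecord],
                      geom: SpecimenGeometry = SpecimenGeometry(),
                      ref_policy: str = "preload",
                      *,
                      preload_g: float = 2.0,
                      preload_tol_g: float = 1.0,
                      loading_branch_only: bool = True,
                      branch_tol_frac: float = 0.005,
                      ) -> tuple[StressStrainCurve, StressStrainCurve]:
    """Reduce raw biaxial records to per-axis stress-strain curves.

    The reference marker quad is the frame selected by ``ref_policy``
    ("preload": load nearest ``preload_g``; "first_frame"). When
    ``loading_branch_only`` is set, only frames from the reference up to the
    load maximum on which both loads are non-decreasing (within
    ``branch_tol_frac`` of the maximum load) are retained.
    """
    if len(records) == 0:
        raise DomainError("no records to reduce")
    i0 = _reference_index(records, ref_policy, preload_g, preload_tol_g)
    ref = records[i0].markers

    frames = list(records[i0:])
    if loading_branch_only and len(frames) > 1:
        totals = np.array([r.load_x_g + r.load_y_g for r in frames])
        imax = int(np.argmax(totals))
        tol = branch_tol_frac * max(
            max(r.load_x_g for r in frames), max(r.load_y_g for r in frames)
        )
        kept = [frames[0]]
        for r in frames[1 : imax + 1]:
            if r.load_x_g >= kept[-1].load_x_g - tol and r.load_y_g >= kept[-1].load_y_g - tol:
                kept.append(r)
        frames = kept

    eps_x, eps_y, sig_x, sig_y = [], [], [], []
    for r in frames:
        lx, ly = stretches_from_markers(ref, r.markers)
        eps_x.append(log_strain(lx))
        eps_y.append(log_strain(ly))
        sig_x.append(cauchy_stress_from_load(r.load_x_g, "x", geom, lx, ly))
        sig_y.append(cauchy_stress_from_load(r.load_y_g, "y", geom, lx, ly))
    return (
        StressStrainCurve("x", np.array(eps_x), np.array(sig_x)),
        StressStrainCurve("y", np.array(eps_y), np.array(sig_y)),
    )


def _symmetric_moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average whose window shrinks symmetrically at the ends.

    Symmetric shrinking keeps the operator exact for linear data on any grid
    (the same operator is applied to both the strain and stress columns).
    """
    n = values.size
    half = max(window // 2, 0)
    out = np.empty_like(values)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = values[i - h : i + h + 1].mean()
    return out


def tangent_modulus(curve: StressStrainCurve, smoothing_window: int = 5,
                    *, slope_factor: float = 0.5) -> TangentModulusCurve:
    """Tangent modulus E_t = slope_factor * dsigma/deps of a stress-strain curve.

    The curve is smoothed with a centered moving average (both columns, so
    linear curves are differentiated exactly), then differentiated with
    second-order finite differences (central in the interior, one-sided at
    the ends). The conventional reporting factor 0.5 is applied by default;
    pass ``slope_factor=1.0`` for the raw derivative.
    """
    if len(curve) < 3:
        raise DomainError("tangent modulus needs at least 3 rows")
    if smoothing_window < 1:
        raise DomainError("smoothing_window must be >= 1")
    eps = _symmetric_moving_average(curve.strain, smoothing_window)
    sig = _symmetric_moving_average(curve.stress_kPa, smoothing_window)
    if np.any(np.diff(eps) <= 0.0):
        raise DomainError("strain must be strictly increasing to differentiate")
    Et = slope_factor * np.gradient(sig, eps, edge_order=2)
    return TangentModulusCurve(eps, Et, axis=curve.axis)


def average_tangent_modulus(curves: Sequence[TangentModulusCurve],
                            strain_grid: Sequence[float]) -> TangentModulusCurve:
    """Pointwise mean of tangent-modulus curves on a common strain grid.

    Each curve is linearly interpolated onto ``strain_grid``; the grid must
    lie within every curve's span. The pointwise standard deviation across
    curves is reported as ``spread_kPa``.
    """
    grid = np.asarray(strain_grid, dtype=float)
    if len(curves) == 0:
        raise DomainError("no curves to average")
    stack = []
    for k, c in enumerate(curves):
        lo, hi = c.strain.min(), c.strain.max()
        if grid.min() < lo - 1e-12 or grid.max() > hi + 1e-12:
            name = c.axis or f"#{k}"
            raise DomainError(
                f"strain grid [{grid.min():.4g}, {grid.max():.4g}] outside span "
                f"[{lo:.4g}, {hi:.4g}] of curve {name}"
            )
        stack.append(np.interp(grid, c.strain, c.Et_kPa))
    stack = np.asarray(stack)
    return TangentModulusCurve(
        grid, stack.mean(axis=0), axis="mean", spread_kPa=stack.std(axis=0)
    )
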