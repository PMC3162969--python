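"""Stress-strain and tangent-modulus curve containers.

These are the common currency between the forward constitutive model, the
planar-biaxial data reduction and the parameter fitting: paired logarithmic
strain (dimensionless) and Cauchy stress (kPa) per loading axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError


def log_strain(stretch):
    """Logarithmic (true) strain eps = ln(lambda) of a stretch ratio.

    Accepts scalars or arrays; stretches must be strictly positive.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0.0) or not np.all(np.isfinite(lam)):
        raise DomainError("stretch must be finite and > 0")
    out = np.log(lam)
    return float(out) if np.isscalar(stretch) or out.ndim == 0 else out


@dataclass
class StressStrainCurve:
    """One axis of a planar test: Cauchy stress (kPa) vs log strain."""

    axis: str
    strain: np.ndarray
    stress_kPa: np.ndarray

    def __post_init__(self):
        self.strain = np.atleast_1d(np.asarray(self.strain, dtype=float))
        self.stress_kPa = np.atleast_1d(np.asarray(self.stress_kPa, dtype=float))
        if self.strain.shape != self.stress_kPa.shape or self.strain.ndim != 1:
            raise DomainError("strain and stress must be 1-d arrays of equal length")
        if not (np.all(np.isfinite(self.strain)) and np.all(np.isfinite(self.stress_kPa))):
            raise DomainError("curve contains non-finite values")

    def __len__(self) -> int:
        return self.strain.size

    @property
    def stretch(self) -> np.ndarray:
        return np.exp(self.strain)


@dataclass
class TangentModulusCurve:
    """Tangent modulus E_t (kPa) vs log strain, with optional axis label."""

    strain: np.ndarray
    Et_kPa: np.ndarray
    axis: str = ""
    spread_kPa: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.strain = np.atleast_1d(np.asarray(self.strain, dtype=float))
        self.Et_kPa = np.atleast_1d(np.asarray(self.Et_kPa, dtype=float))
        if self.strain.shape != self.Et_kPa.shape or self.strain.ndim != 1:
            raise DomainError("strain and Et must be 1-d arrays of equal length")
        if self.spread_kPa is not None:
            self.spread_kPa = np.atleast_1d(np.asarray(self.spread_kPa, dtype=float))
            if self.spread_kPa.shape != self.strain.shape:
                raise DomainError("spread must match the strain grid")

    def __len__(self) -> int:
        return self.strain.size
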