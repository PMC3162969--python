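"""Oscillatory parallel-plate rheometry sweeps and tensile/shear comparison.

A sweep holds storage and loss moduli (G', G'', Pa) against either frequency
(Hz) or shear-strain amplitude (%). Summaries cover the loss tangent, the
elastic-dominance ratio G'/G'', and the comparison of the biaxial tangent
modulus against the storage modulus. For a purely elastic incompressible
isotropic solid the small-strain tensile-to-shear ratio is 3 (ideal elastic
network); hydrated collagen gels measured in tension vs torsion show far
larger ratios, attributed to interstitial-fluid (biphasic) effects that this
elastic model deliberately does not represent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .curves import TangentModulusCurve
from .errors import DomainError

__all__ = ["OscillatorySweep", "loss_tangent", "elastic_dominance", "tensile_shear_ratio"]

_MODES = ("frequency", "strain")


@dataclass(frozen=True)
class OscillatorySweep:
    """One rheometry sweep.

    mode : "frequency" (abscissa in Hz) or "strain" (abscissa in % amplitude).
    Moduli are in Pa and must be positive; the abscissa strictly increasing.
    """

    mode: str
    abscissa: np.ndarray
    G_storage_Pa: np.ndarray
    G_loss_Pa: np.ndarray
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in _MODES:
            raise DomainError(f"mode must be one of {_MODES}, got {self.mode!r}")
        for name in ("abscissa", "G_storage_Pa", "G_loss_Pa"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if not (self.abscissa.shape == self.G_storage_Pa.shape == self.G_loss_Pa.shape):
            raise DomainError("sweep columns must have equal length")
        if self.abscissa.size > 1 and np.any(np.diff(self.abscissa) <= 0.0):
            raise DomainError("abscissa must be strictly increasing")
        if np.any(self.G_storage_Pa <= 0.0) or np.any(self.G_loss_Pa <= 0.0):
            raise DomainError("moduli must be > 0")

    def __len__(self) -> int:
        return self.abscissa.size


def loss_tangent(sweep: OscillatorySweep) -> np.ndarray:
    """Loss tangent tan(delta) = G''/G' per row, paired with the abscissa.

    Returns an (n, 2) array of (abscissa, G''/G')."""
    ratio = sweep.G_loss_Pa / sweep.G_storage_Pa
    return np.column_stack([sweep.abscissa, ratio])


def elastic_dominance(sweep: OscillatorySweep) -> dict:
    """Summary of G'/G'' over the sweep.

    A gel is flagged predominantly elastic when the median storage-to-loss
    ratio strictly exceeds 1 (collagen gels typically show G' about ten times
    G'').
    """
    ratio = sweep.G_storage_Pa / sweep.G_loss_Pa
    med = float(np.median(ratio))
    return {
        "median_storage_to_loss": med,
        "min_storage_to_loss": float(ratio.min()),
        "max_storage_to_loss": float(ratio.max()),
        "predominantly_elastic": med > 1.0,
    }


def _interp(x: float, xs: np.ndarray, ys: np.ndarray, *, log_x: bool, what: str) -> float:
    if x < xs.min() - 1e-12 or x > xs.max() + 1e-12:
        raise DomainError(
            f"query {x:.4g} outside the {what} span [{xs.min():.4g}, {xs.max():.4g}]"
        )
    if log_x:
        return float(np.interp(np.log(x), np.log(xs), ys))
    return float(np.interp(x, xs, ys))


def tensile_shear_ratio(Et_curve: TangentModulusCurve, sweep: OscillatorySweep,
                        strain_for_Et: float, abscissa_for_G: float) -> float:
    """Dimensionless ratio of tensile tangent modulus to storage modulus.

    E_t (kPa) is linearly interpolated at ``strain_for_Et``; G' (Pa) at
    ``abscissa_for_G`` (on a log abscissa for frequency sweeps, linear for
    strain sweeps). Both are converted to Pa before dividing.
    """
    Et_kPa = _interp(strain_for_Et, Et_curve.strain, Et_curve.Et_kPa,
                     log_x=False, what="tangent-modulus strain")
    G_Pa = _interp(abscissa_for_G, sweep.abscissa, sweep.G_storage_Pa,
                   log_x=sweep.mode == "frequency", what=f"{sweep.mode} sweep")
    return Et_kPa * 1e3 / G_Pa
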