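"""Synthetic equibiaxial experiments and rheometry sweeps.

Emulates load-controlled equibiaxial stretching of an incompressible
15 mm x 15 mm x 1 mm collagen membrane: a 5 mm fiducial-marker square
deforming with the imposed stretches (plus optional jitter), axial loads
consistent with the GOH forward model (plus optional multiplicative stress
noise), a 2 g preload frame, and maximum loads of 70-100 g per axis. Also
generates oscillatory sweeps with the qualitative character of collagen-gel
rheometry (weak power-law G', loss tangent around 0.1).

A scenario library of published GOH parameter sets for genipin-crosslinked
collagen gels (nonaligned and magnetically aligned, at 0.03/0.1/0.25% GP)
ships with the package; scenarios are the ground truth for the
parameter-recovery harness.

Randomness contract: every generator draws from one ``numpy.random.default_rng``
seeded by the protocol/argument seed. Draw order is documented per function
so outputs are stable across versions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .biaxial import GF_TO_N, BiaxialRecord, MarkerQuad, SpecimenGeometry
from .curves import StressStrainCurve
from .errors import DomainError, FiberOverflowError
from .goh import MaterialParams, biaxial_stress
from .rheometry import OscillatorySweep

__all__ = [
    "ExperimentProtocol",
    "SyntheticExperiment",
    "scenario_names",
    "load_scenario",
    "generate_curves",
    "generate_raw_records",
    "generate_sweep",
]


@dataclass(frozen=True)
class ExperimentProtocol:
    """Load-controlled equibiaxial protocol and noise model.

    max_load_g : peak axial load (grams-force) the stiffer axis reaches.
    preload_g : reference preload; frame 0 sits at this load.
    stress_noise_rel_sd : multiplicative noise on stresses/loads (relative sd).
    marker_jitter_sd_mm : additive Gaussian jitter on marker coordinates.
    """

    max_load_g: float = 70.0
    n_frames: int = 30
    geometry: SpecimenGeometry = field(default_factory=SpecimenGeometry)
    preload_g: float = 2.0
    stress_noise_rel_sd: float = 0.0
    marker_jitter_sd_mm: float = 0.0
    seed: int = 0
    marker_square_mm: float = 5.0
    max_stretch_bound: float = 1.5
    half_cycle_s: float = 10.0

    def __post_init__(self):
        if not (self.max_load_g > self.preload_g >= 0.0):
            raise DomainError("need max_load_g > preload_g >= 0")
        if self.n_frames < 3:
            raise DomainError("n_frames must be >= 3")
        if self.stress_noise_rel_sd < 0.0 or self.marker_jitter_sd_mm < 0.0:
            raise DomainError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class SyntheticExperiment:
    """Raw records plus the ground truth needed for closure and recovery tests.

    ``truth_curves`` are expressed in the measured convention — strain
    referenced to the preload frame and stress formed from load and measured
    stretch — which is what a faithful reduction of ``records`` returns. With
    zero preload they coincide with the unloaded-reference forward model.
    """

    records: tuple[BiaxialRecord, ...]
    truth_curves: tuple[StressStrainCurve, StressStrainCurve]
    params: MaterialParams
    protocol: ExperimentProtocol
    stretch_grid: np.ndarray
    lambda_preload: float


def scenario_names() -> list[str]:
    return sorted(_scenarios().keys())


def _scenarios() -> dict:
    with resources.files("gelmech.data").joinpath("gel_scenarios.json").open() as fh:
        return json.load(fh)


def load_scenario(name: str) -> tuple[MaterialParams, ExperimentProtocol, dict]:
    """Material parameters, default protocol and metadata for a named scenario."""
    table = _scenarios()
    if name not in table:
        raise DomainError(f"unknown scenario {name!r}; available: {sorted(table)}")
    entry = table[name]
    p = entry["params"]
    params = MaterialParams(
        C10=p["C10_kPa"], k1=p["k1_kPa"], k2=p["k2"],
        gamma_deg=p["gamma_deg"], kappa=p["kappa"],
    )
    protocol = ExperimentProtocol(max_load_g=entry["max_load_g"])
    meta = {k: v for k, v in entry.items() if k != "params"}
    return params, protocol, meta


def _axial_loads_g(params: MaterialParams, lam: float, geom: SpecimenGeometry):
    """Per-axis loads (gf) producing the model stresses at equibiaxial stretch lam.

    Cauchy stress = f * lam / (L0_perp * t0), inverted: f = sigma * A0 / lam.
    """
    sxx, syy = biaxial_stress(params, lam, lam)
    fx_N = float(sxx) / 1e3 * (geom.L0y_mm * geom.t0_mm) / lam
    fy_N = float(syy) / 1e3 * (geom.L0x_mm * geom.t0_mm) / lam
    return fx_N / GF_TO_N, fy_N / GF_TO_N


def _stretch_at_load(params: MaterialParams, target_g: float,
                     protocol: ExperimentProtocol) -> float:
    """Invert the monotone load-stretch map: stretch where the larger axial
    load equals ``target_g`` (load-control emulation), by bisection."""
    if target_g <= 0.0:
        return 1.0
    geom = protocol.geometry

    def excess(lam: float) -> float:
        try:
            fx, fy = _axial_loads_g(params, lam, geom)
        except FiberOverflowError:
            # exponent blew past the guard: the load is certainly exceeded
            return 1e9
        return max(fx, fy) - target_g

    hi = protocol.max_stretch_bound
    if excess(hi) < 0.0:
        raise DomainError(
            f"load {target_g} g not reachable below stretch {hi} "
            "(increase max_stretch_bound or lower the load)"
        )
    return float(brentq(excess, 1.0, hi, xtol=1e-12, rtol=8.9e-16))


def generate_curves(params: MaterialParams,
                    protocol: ExperimentProtocol = ExperimentProtocol(),
                    *,
                    stretch_grid: Sequence[float] | None = None,
                    ) -> tuple[StressStrainCurve, StressStrainCurve]:
    """Forward equibiaxial stress-strain curves, optionally noisy.

    Without an explicit ``stretch_grid`` the grid is ``n_frames`` points from
    1 to the stretch where the stiffer axis reaches ``max_load_g``. Noise is
    multiplicative i.i.d. Gaussian on each stress value (draw order: all x
    stresses, then all y stresses). Zero noise reproduces the forward model
    exactly.
    """
    if stretch_grid is None:
        lam_max = _stretch_at_load(params, protocol.max_load_g, protocol)
        grid = np.linspace(1.0, lam_max, protocol.n_frames)
    else:
        grid = np.asarray(stretch_grid, dtype=float)
    sxx, syy = biaxial_stress(params, grid, grid)
    sxx, syy = np.atleast_1d(sxx).copy(), np.atleast_1d(syy).copy()
    if protocol.stress_noise_rel_sd > 0.0:
        rng = np.random.default_rng(protocol.seed)
        sxx *= 1.0 + protocol.stress_noise_rel_sd * rng.standard_normal(sxx.size)
        syy *= 1.0 + protocol.stress_noise_rel_sd * rng.standard_normal(syy.size)
    eps = np.log(grid)
    return StressStrainCurve("x", eps, sxx), StressStrainCurve("y", eps, syy)


def generate_raw_records(params: MaterialParams,
                         protocol: ExperimentProtocol = ExperimentProtocol(),
                         ) -> SyntheticExperiment:
    """Raw marker/load records of a load-controlled equibiaxial test.

    Frame 0 sits at the preload; the stretch grid runs from the preload
    stretch to the stretch where the stiffer axis reaches ``max_load_g``.
    Marker quads are the imposed homogeneous stretch applied to the unloaded
    5 mm fiducial square; loads are inverted from the model stresses
    (f = sigma * A0 / lambda). Draw order with noise: per frame, 8 marker
    jitter values (x1 y1 ... x4 y4), then the x-load factor, then the y-load
    factor.
    """
    geom = protocol.geometry
    lam_pre = _stretch_at_load(params, protocol.preload_g, protocol)
    lam_max = _stretch_at_load(params, protocol.max_load_g, protocol)
    grid = np.linspace(lam_pre, lam_max, protocol.n_frames)
    ref_square = MarkerQuad.square(protocol.marker_square_mm).points
    rng = np.random.default_rng(protocol.seed)

    records = []
    eps_t, sx_t, sy_t = [], [], []
    for i, lam in enumerate(grid):
        pts = ref_square * lam  # homogeneous equibiaxial stretch about the center
        fx, fy = _axial_loads_g(params, lam, geom)
        if protocol.marker_jitter_sd_mm > 0.0:
            pts = pts + protocol.marker_jitter_sd_mm * rng.standard_normal((4, 2))
        if protocol.stress_noise_rel_sd > 0.0:
            fx *= 1.0 + protocol.stress_noise_rel_sd * rng.standard_normal()
            fy *= 1.0 + protocol.stress_noise_rel_sd * rng.standard_normal()
        records.append(
            BiaxialRecord(
                time_s=i * protocol.half_cycle_s / max(protocol.n_frames - 1, 1),
                markers=MarkerQuad(pts),
                load_x_g=fx,
                load_y_g=fy,
            )
        )
        # measured convention: strain referenced to the preload frame; stress
        # from the (noise-free) load and the measured relative stretch
        lam_rel = lam / lam_pre
        fx0, fy0 = _axial_loads_g(params, lam, geom)
        eps_t.append(np.log(lam_rel))
        sx_t.append(fx0 * GF_TO_N * lam_rel / (geom.L0y_mm * geom.t0_mm) * 1e3)
        sy_t.append(fy0 * GF_TO_N * lam_rel / (geom.L0x_mm * geom.t0_mm) * 1e3)

    truth = (
        StressStrainCurve("x", np.array(eps_t), np.array(sx_t)),
        StressStrainCurve("y", np.array(eps_t), np.array(sy_t)),
    )
    return SyntheticExperiment(
        records=tuple(records),
        truth_curves=truth,
        params=params,
        protocol=protocol,
        stretch_grid=grid,
        lambda_preload=lam_pre,
    )


def generate_sweep(base_G_storage_Pa: float,
                   ratio_loss: float = 0.1,
                   *,
                   mode: str = "frequency",
                   trend_exponent: float = 0.05,
                   dip_amplitude: float = 0.0,
                   noise_rel_sd: float = 0.0,
                   n_points: int = 20,
                   seed: int = 0,
                   metadata: dict | None = None) -> OscillatorySweep:
    """Synthetic oscillatory sweep with collagen-gel-like trends.

    Frequency mode: abscissa 0.1-10 Hz (log-spaced); G' = base * f^trend (a
    weak power law, slightly increasing). Strain mode: abscissa 0.5-10 %
    amplitude; G' decreases mildly via a negative effective trend on the
    normalized amplitude. G'' = ratio_loss * G' exactly when
    ``dip_amplitude`` is 0 (the default); a positive amplitude superposes the
    dip-then-rise shape seen in frequency sweeps, G'' proportional to
    (1 + dip_amplitude * ((log10 f)^2 - 1/2)). Multiplicative noise draws:
    all G' factors, then all G'' factors.
    """
    if base_G_storage_Pa <= 0.0:
        raise DomainError("base_G_storage_Pa must be > 0")
    if not (0.0 < ratio_loss < 1.0):
        raise DomainError("ratio_loss must be in (0, 1)")
    if mode == "frequency":
        x = np.logspace(-1, 1, n_points)  # Hz
        Gp = base_G_storage_Pa * x**trend_exponent
        shape = 1.0 + dip_amplitude * (np.log10(x) ** 2 - 0.5)
    elif mode == "strain":
        x = np.linspace(0.5, 10.0, n_points)  # % amplitude
        Gp = base_G_storage_Pa * (x / x[0]) ** (-abs(trend_exponent))
        shape = 1.0 + dip_amplitude * (x - x[0]) / (x[-1] - x[0])
    else:
        raise DomainError(f"mode must be 'frequency' or 'strain', got {mode!r}")
    Gpp = ratio_loss * Gp * shape
    if noise_rel_sd > 0.0:
        rng = np.random.default_rng(seed)
        Gp = Gp * (1.0 + noise_rel_sd * rng.standard_normal(n_points))
        Gpp = Gpp * (1.0 + noise_rel_sd * rng.standard_normal(n_points))
    return OscillatorySweep(mode, x, Gp, Gpp, metadata=metadata or {})
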