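# Methods

## Constitutive model

`gelmech` implements the Gasser–Ogden–Holzapfel (GOH) strain-energy
function (Holzapfel, Gasser & Ogden 2000; Gasser, Ogden & Holzapfel 2006)
for a membrane of matrix material reinforced by N = 2 symmetric families of
dispersed collagen fibers:

U = C10(Ī₁ − 3) + k1/(2k2) Σ_α {exp[k2⟨Ē_α⟩²] − 1},  Ē_α = κ(Ī₁ − 3) + (1 − 3κ)(Ī₄^(αα) − 1).

Assumptions, in the form the package enforces:

* **Exact incompressibility.** The inverse bulk modulus D is pinned to 0
  and treated as the exact constraint J = 1 rather than as a penalty: the
  volumetric term vanishes identically, `PlanarDeformation` derives the
  thickness stretch λ_z = 1/(λ_x λ_y), and the reaction pressure is
  eliminated through the membrane plane-stress condition σ_zz = 0. At
  J ≡ 1 the isochoric (barred) and unbarred invariants coincide; the types
  carry the barred names.
* **Two in-plane families at ±γ.** The mean fiber directions lie in the
  membrane plane at ±γ from the x (alignment) axis. Under axis-aligned
  biaxial stretch both families see the same strain and the shear stress
  vanishes by symmetry; the general tensor route (`cauchy_stress`) also
  covers in-plane simple shear, where the families differ.
* **Tension-only fibers.** The Macauley bracket is applied to Ē_α exactly
  as defined: a family contributes iff Ē_α > 0. This differs from the
  alternative convention that activates fibers when Ī₄ > 1 — the two
  disagree whenever κ > 0 and Ī₁ ≠ 3 near the activation boundary — and the
  literal Ē_α > 0 rule is the one implemented.
* **Overflow guard.** The fiber exponent k2⟨Ē⟩² is capped (default 50);
  exceeding it raises an error naming the family. Fitted k2 values reach
  ~10³, which makes the exponential explosive just outside the few-percent
  strain range the parameters were identified on; the guard turns that
  silent blow-up into a diagnosable failure.

Stresses are analytic (σ = 2F(∂U/∂C)Fᵀ − pI). The test suite checks them
against an independent finite-difference derivative of the reduced energy
U(λ_x, λ_y) under the incompressibility constraint (relative step 1e-6,
agreement to 1e-6 relative over 200 random admissible states), and checks
that every operation collapses to the incompressible neo-Hookean closed
forms at k1 = 0 (μ = 2C10; equibiaxial σ = 2C10(λ² − λ⁻⁴); shear τ = 2C10·s;
E0/G0 = 3).

The dispersion parameter is also available as a quadrature,
κ = (1/4)∫₀^π ρ(Θ)sin³Θ dΘ, for validating candidate orientation densities
(uniform ρ ≡ 1 gives 1/3; a delta at Θ₀ gives sin²Θ₀/2). Because the
functional family of ρ is generally unknown for these gels, κ is fitted
phenomenologically; the quadrature is a validation tool, not part of the
fitting path.

## Biaxial reduction

Raw records are per-frame quads of four fiducial markers (nominally a 5 mm
square at the specimen center), axial loads in grams-force, and the
unloaded geometry (defaults 15 mm × 15 mm between loading bars, 1 mm
thick). Reduction choices:

* **Stretches** come from the best-fit homogeneous 2-d deformation
  gradient over the four centered markers (least squares). Centering makes
  the estimate translation-invariant, and using all four markers is more
  jitter-robust than edge ratios; off-diagonal components are available for
  shear QC.
* **Cauchy stress** divides the load (converted at 9.80665e-3 N/gf) by the
  current cross-section from incompressibility: σ_xx = f_x λ_x/(L0y t0).
  The nominal thickness is used by default; per-sample measured thickness
  can be passed through `SpecimenGeometry`.
* **Reference state.** The default policy takes the frame whose load is
  nearest the 2 g preload as the strain reference, matching standard
  practice (sutures must be straightened before strains are meaningful).
  A "first_frame" policy is provided; switching policies shifts ε by the
  constant ln λ_pre.
* **Loading branch.** Frames from the reference to the load maximum on
  which both loads are non-decreasing within 0.5% of the maximum load are
  retained; unloading half-cycles are dropped.
* **Tangent modulus.** E_t = 0.5·dσ/dε, the conventional reporting factor
  for these gels; `slope_factor=1.0` exposes the raw derivative. The curve
  is smoothed with a centered moving average whose window shrinks
  symmetrically at the ends (window 5 by default) applied to both columns —
  this keeps linear curves exact on any grid — then differentiated with
  second-order differences (central interior, one-sided ends). Averaging
  across samples interpolates linearly onto a common strain grid and
  reports the pointwise mean and standard deviation.

## Fitting protocol

Two stages, mirroring how nonaligned/aligned gel pairs are analyzed:

1. **Nonaligned (isotropic) fits** fix γ = 45° and κ = 0.333 and fit
   (C10, k1, k2).
2. **Aligned fits** pin C10 to the matching nonaligned value and fit
   (k1, k2, γ, κ) with κ bounded in [0, 1/3]. The result reports whether
   the fitted model reproduces the σ_xx > σ_yy ordering of the data, an
   anisotropy metric, and a flag when κ lands at the 1/3 boundary
   ("isotropic-indistinguishable").

The loss is the stacked sum of squared Cauchy-stress residuals over both
axes (both axes fitted simultaneously); each observed strain is mapped to
an equibiaxial stretch λ = exp(ε). The optimizer is bounded
trust-region-reflective least squares with k1 and k2 on a log10 scale
(their magnitudes span 10²–10⁴), restarted from 16 Latin-hypercube draws
(seed 1234 by default); ties in final loss are broken toward the smallest
k2 (flattest exponent), then lexicographic parameter order. Default bounds:
C10 ∈ [0.1, 200] kPa, k1 ∈ [10, 10⁶] kPa, k2 ∈ [1, 2000], γ ∈ [0°, 90°],
κ ∈ [0, 1/3]. The k2 ceiling of 2000 covers the published fits (≤ 1150)
while keeping the fiber exponent below the overflow guard everywhere on the
default fitting grid.

k1 and k2 trade off against each other (both scale the fiber stress over a
narrow strain window); the local Gauss-Newton correlation matrix at the
optimum is exposed on every `FitResult`, and the k1–k2 correlation is
strongly negative (≈ −0.94 on the packaged scenarios). Zero-noise recovery
tolerances used in the tests: 2% relative for C10, k1, k2; 0.5° absolute
for γ; 0.005 absolute for κ — the multistart fits on the packaged scenarios
actually recover all parameters to ~1e-12 relative.

`recovery_report` wraps generate → fit → tabulate (relative errors per
parameter, curve RMSE, the k1–k2 correlation) with per-replicate seeds
derived as protocol.seed + r, and serializes deterministically.

## Synthetic data

The generator emulates the load-controlled equibiaxial protocol: a 2 g
preload frame, equibiaxial stretch increasing until the stiffer axis
reaches the maximum load (70 g for the 0.03% GP scenarios, 100 g otherwise,
following the corresponding experiments), 30 frames, markers as the imposed
homogeneous stretch applied to the unloaded 5 mm square. Loads are inverted
from the model stresses (f = σ·A₀/λ); the load-stretch map is inverted by
bisection (brentq, xtol 1e-12) on its monotone branch. Noise is optional
and seeded: additive Gaussian marker jitter (mm) and multiplicative
Gaussian stress/load noise; draw order is documented per function so
outputs are stable. Fitting-grade curves default to λ ∈ [1.00, 1.06] with
30 points — a fixture convention matching the few-percent strains these
gels reach at 70–100 g, not a measured value.

What the generator does **not** emulate: preconditioning hysteresis,
suture/edge compliance, spatial inhomogeneity of the membrane, actual
marker-tracking image noise (jitter is i.i.d. Gaussian), and any
viscoelastic or poroelastic response. Passing tests therefore demonstrate
correctness of the reduction/fitting machinery and identifiability under
the stated protocol — not that the GOH model with these settings describes
any particular physical gel.

Ground truth for raw records is returned in the *measured* convention
(strains referenced to the preload frame, stress from load and measured
stretch), which is what a faithful reduction returns; with zero preload it
coincides with the unloaded-reference forward model. A consequence worth
knowing: reducing against the preload reference hides the toe region below
2 g, and parameters fitted to such curves are biased relative to the
generating set even at zero noise (C10 absorbs the hidden pre-stress). The
physical protocol shares this limitation; exact parameter recovery holds
when the unloaded state is the reference.

## Rheometry

Sweeps store (abscissa, G′, G″) with frequency in Hz or strain amplitude in
percent (converted internally when compared against model shear).
Frequency interpolation is on a log abscissa, strain linear. The synthetic
sweep uses a weak power law for G′ and a constant loss ratio by default
(G″ = ratio·G′), with an optional dip-then-rise shape for G″ in frequency
mode. For the purely elastic incompressible solid the small-strain
tensile-to-shear ratio is exactly 3 regardless of the fiber term at
κ = 1/3; the two-to-three orders of magnitude measured between biaxial
tangent moduli and rheometric storage moduli of hydrated gels is a
biphasic (interstitial fluid) effect that this model intentionally does not
reproduce — `tensile_shear_ratio` quantifies the measured contrast, and the
model-side baseline documents what an elastic network alone can do.

## Numerical choices

* Small-strain moduli by central differences (default step 1e-4); the
  uniaxial lateral stretch is solved to σ_yy = 0 with brentq from the
  isotropic guess λ_y = λ_x^(−1/2).
* Dispersion quadrature via adaptive `scipy.integrate.quad` with optional
  point hints for sharp densities; densities are validated for
  non-negativity and normalization ((1/2)∫ρ sinΘ dΘ = 1, tolerance 1e-6).
* Curve CSVs round-trip exactly: full-precision float repr on write,
  `float_precision="round_trip"` on read.
* Angles are degrees at every interface and radians internally.

## Known limitations

* Fiber dispersion is the standard 3-d transversely isotropic κ; no
  planar (2-d) dispersion variant.
* The homogeneous plane-stress point model replaces any finite-element
  treatment of the specimen; this is exact for a homogeneous equibiaxially
  loaded membrane away from attachments, but edge/suture effects are out of
  scope.
* No viscoelasticity or poroelasticity; rheometry is a data model plus
  summaries, not a constitutive fit.
* Aligned-fit identifiability degrades as data approach isotropy (γ → 45°
  or κ → 1/3 produce indistinguishable equibiaxial responses); the result
  flags this rather than resolving it.
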