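# Methods

`protoendo` models passive endocytosis in fatty-acid protocells: a giant
unilamellar vesicle (GUV) that simultaneously loses water under a
hyperosmotic shock and gains membrane area from added micelles raises its
surface-area-to-volume ratio, buckles inward, and buds an internal
compartment that slowly releases its cargo into the lumen by passive
permeation.  The package contains four quantitative pieces — the membrane
shape model, the permeation/release calculus, the stimulus-dosing
arithmetic, and the compartment-count statistics — plus seeded generators
that emulate the statistical structure of the corresponding bench data.

## Membrane shape model

### Physics

The membrane is a Helfrich sheet with energy

    E = (K_b / 2) ∮ (2H − c0)² dA,

where `H` is the mean curvature, `c0` the spontaneous curvature (negative
values favor bending toward the interior) and `K_b` the bending modulus in
units of k_B·T.  The shape is axisymmetric: a polyline of markers in the
(r, z) half-plane, pole to pole, revolved about the z axis.  Two slow
controls force the shape:

* **Area growth.** Micelle incorporation grows the membrane at relative
  rate γ: the area target is `A(t) = min(A0·e^{γt}, cap·A0)` with
  `cap = 2` by default (the observed area increase is at most twofold).
  A stiff quadratic penalty (default 2·10⁵ k_B·T on the squared relative
  mismatch) enforces the target; its gradient is the membrane tension.
* **Osmotic deflation.** The enclosed-volume target obeys
  `dV/dt = −P_f·v_w·A·Δc` with water permeability `P_f` (cm/s), water
  molar volume `v_w` (cm³/mol) and a constant osmolarity difference `Δc`
  (mM, outside minus inside).  A second quadratic penalty transmits this
  as a uniform normal (pressure) force.  The corresponding van't Hoff
  pressure `p = Δc·N_A·k_B·T` is exposed as a diagnostic.

Default parameters are the study conditions: initial diameter 1 μm,
`P_f = 14·10⁻³ cm/s`, `v_w = 20 cm³/mol`, μ = 0.01 dyn·s/cm²,
ρ = 1 g/cm³, γ ∈ [0, 2.5] s⁻¹, Δc ∈ [10, 100] mM, c0 ∈ [−1, −0.2] μm⁻¹,
K_b ∈ [2, 100] k_B·T, total time 1–3 s.

### Mobility: why hydrodynamic, not local drag

The contour follows an overdamped gradient flow, `v = M(−δE/δx)`,
projected on the local surface normal (tangential motion only
re-parameterizes the contour and is handled by periodic arclength
remeshing).  The mobility is the Stokes-flow response of a membrane: a
normal force density at arclength wavenumber `q` produces velocity
`f/(4μq)`.  This choice is load-bearing.  With a local (wavenumber-
independent) drag the flow funnels the deflating vesicle into the
energetically steep prolate-elongation/pearling branch — an outward
division pathway — because long-wavelength stretching costs no more drag
than local dimpling.  With the 1/(4μq) mobility, long-wavelength modes
are hydrodynamically slow and local dimpling fast, and the simulated
sequence becomes sphere → oblate → stomatocyte → deepening inward bud for
the experimental parameter sets, robustly across perturbation seeds.
This matches the observed transformation sequence and timescale
(seconds).

### Numerics

* Positions of interior markers are the degrees of freedom; the two pole
  markers are reconstructed every evaluation by even (r²) extrapolation,
  which removes stiff, nearly massless pole modes.
* Forces are exact gradients of the discretized energy computed by
  complex-step differentiation (step 10⁻³⁰; machine precision, no
  subtractive cancellation).  Curvatures use turning angles and
  `sin ψ / r`; area and volume use surface-of-revolution quadrature.
* The stiff bending flow (`∝ K_b q³` under the hydrodynamic mobility) and
  the second-order azimuthal/tension terms are stabilized by a
  semi-implicit (IMEX) solve that is diagonal in the sine transform over
  the arclength parameterization.  The two slow "breathing" modes coming
  from the rank-one penalty curvatures `k_A (∇A)(∇A)ᵀ` and
  `k_V (∇V)(∇V)ᵀ` are folded into the implicit solve with the Woodbury
  identity.  The step size is then set by the forcing, not the bending
  stiffness: steps adapt between 10⁻¹² and 2·10⁻³ s with an
  energy-decrease acceptance check (tolerance 10⁻³·|E| per step, against
  frozen targets).
* Markers are redistributed uniformly in arclength every 15 accepted
  steps (cubic spline, falling back to shape-preserving linear
  interpolation near tight necks), and immediately whenever a turning
  angle approaches the discretization limit.
* Degenerate inputs: fewer than 4 markers, off-axis poles, non-positive
  volume and self-intersecting contours are rejected at construction.

Topology is fixed: when the contour self-intersects, or an inner-cavity
neck (or outer waist) falls below `neck_fraction` (default 0.15) of the
volume-equivalent radius, the run terminates with status `pre_pinch` and
the last valid frame.  Pinch-off itself — and hence anything downstream
of a completed topological transformation — is outside the model.

Typical accuracy at the default resolution (64 markers): sphere bending
energy within 0.05% of 8πK_b and stationary to <0.01% over 2 s; sphere
volume under pure osmotic deflation within 1% of the analytic ODE over a
63% volume loss; relaxed bending energies change <1% when the marker
count doubles.  The worst transient area mismatch (~4%) occurs just
before buckling, while a still-nearly-spherical shape cannot yet store
excess area in deformation; the `area_tolerance` default (5%) reflects
this.

### Initial conditions and the number of invaginations

A perfect sphere cannot break symmetry in a deterministic axisymmetric
flow, so simulations start from a seeded low-order Legendre perturbation
(`gen_initial_shape("perturbed_sphere")`, default relative amplitude
0.02).  A deliberate consequence of determinism: the **number** of
simultaneous invaginations is controlled by the symmetry of that seed,
not by the stimulus.  Generic (asymmetric) seeds produce exactly one
deepening invagination for every studied parameter set; seeds with
near-even symmetry can produce two or more, but the count is sensitive to
resolution and amplitude.  In the laboratory, multi-compartment vesicles
plausibly arise from azimuthally separated buds and from sequential
pinch-off — non-axisymmetric and topological mechanisms that this reduced
model excludes by construction.  The corresponding reference behavior
(two distinct invaginations for the strongest shock at weak spontaneous
curvature) is therefore **not** reproduced by the default model, and the
test encoding it fails by design rather than being weakened; the cavity
counting and multi-invagination classification machinery is exercised by
analytic fixtures instead.

### Morphology classification and phase scan

`classify` applies deterministic rules: a cavity exists when some plane
normal to the axis cuts the full cross-section in ≥4 points (equivalently
the contour's z(s) is non-monotone); cavities are counted as interior
extrema of z(s) with prominence above `cavity_depth_fraction` (0.15) of
the equivalent radius.  Cavity-free shapes are `sphere` when the reduced
volume ν = 6√π·V·A^(−3/2) exceeds 0.98, else `prolate`/`oblate` by polar
versus equatorial extent.  One cavity is a `stomatocyte`, downgraded to
`invaginated` when its neck is below `neck_fraction`·R_eq; two or more
disjoint cavities are `multi_invaginated`.  All thresholds are
configurable; the defaults were chosen for robustness on analytic
fixtures (spheroids and cap-inverted spheres).

`phase_scan` runs simulate + classify over a (γ, Δc) grid (defaults: 6
log-spaced growth rates in 0–2.5 s⁻¹ × 4 shocks in 10–100 mM, 3 s each)
and reports the vesiculation threshold γ*(Δc), the smallest γ whose cell
reaches a vesiculated label.  At the study water permeability, osmotic
deflation alone vesiculates every cell within 3 s, so γ* = 0 across the
scanned range and its required monotone non-increase in Δc holds
degenerately; the γ dependence would re-emerge at lower permeability or
shorter times.

## Permeation and release calculus

Passive flux across a membrane is `J = P_s·ΔC`; over a vesicle of area
`A` this gives a crossing rate `dN/dt = J·A·N_A` and a mean
single-molecule crossing time `1/(dN/dt)`.  With the measured
trinucleotide permeability (0.21·10⁻¹² cm/s), a 4-μm GUV in a 1 mM pool
takes up ~0.06 molecules/s, i.e. ~16 s per molecule; the common-nutrient
permeability range 10⁻¹³–10⁻¹⁰ cm/s maps to 33–0.03 s.

Release from an endocytic compartment (radius r_c, concentration C_c)
into the lumen (C_l) which exchanges with an infinite bath (C_b) is the
linear system

    dC_c/dt = −k₁ (C_c − C_l),          k₁ = 3 P_s / r_c
    dC_l/dt = k₂ (C_c − C_l) − k₃ (C_l − C_b),

with k₂ = P_s·A_c/V_l and k₃ = P_s·A_l/V_l.  It is solved in closed form
by eigendecomposition about the fixed point C = C_b (also a fixed point
of the closed system, k₃ = 0, where total solute is conserved —
verified to 10⁻⁹ relative).  `time_to_fraction` inverts the solution by
bracketing and Brent root-finding; the single-membrane sink limit has
the closed form `t = −ln(1−f)·r/(3 P_s)`.  Release times quoted for
specific figure geometries in the source study involve model details
not fully specified at the level implemented here, so the package
exposes the general machinery without asserting those figure-level
numbers.

`fit_release_rate` estimates the first-order rate from intensity-ratio
decays either from two points, `k = ln(r₀/r_t)/(t−t₀)`, or by least
squares of −ln(ratio) on t; fluorescence ratios are assumed proportional
to concentration ratios.  The same fit is exposed object-style as
`ReleaseKineticsModel(...).fit() → ReleaseKineticsResults` with the rate,
its standard error, half-life and a summary table.

## Dosing arithmetic

Stock volumes realizing a stimulus (ΔC_V, ΔC_A) on a well of volume V₀
follow conservation of moles.  The buffer volume accounts for the
dilution by the added volume itself (ignoring the co-added micelle
volume): `v = ΔC_V·V₀/(C_stock − C₀ − ΔC_V)`, which reproduces the
protocol volumes 2.70 / 5.56 / 11.76 μL for shocks of 25 / 50 / 100 mM
from a 1 M stock.  Micelle volumes use the nominal convention
`v = ΔC_A·V₀/C_stock` (matching the protocol table); the exact
self-diluted form is also implemented and differs by up to ~6% at the
strongest dose.  `apply_stimulus` tracks every named species through
dilutions and sequential stimuli; nominal bookkeeping adds ΔC to running
concentrations and reproduces the sequential endpoint (250 mM buffer /
5.5 mM lipid after two (100, 2.5) events from (50, 0.5)).

## Compartment statistics

Count tables carry one row per vesicle: condition (ΔC_V, ΔC_A),
replicate, and the number of internal compartments.  `summarize` computes
replicate-level fractions first (any compartment; ≥2 compartments) and
reports their unweighted mean and sample SD across replicates — matching
how replicate error bars are reported; a vesicle-count-weighted mean is
available as an option.  A single replicate yields an undefined (NaN) SD
rather than zero.  Histograms pool vesicles with a configurable overflow
bin (default 3+).

## Synthetic data

* **Counts** follow a zero-inflated zero-truncated Poisson: a vesicle
  has ≥1 compartment with probability p₁ (rising with micelle dose
  ΔC_A), and conditionally a zero-truncated Poisson(λ) count (λ rising
  with shock ΔC_V).  The default 3×4 condition grid anchors p₁ at the
  reported corner fractions (≈7% at the weakest dose, ≈70–88% at the
  strongest) and λ at values implying the reported ~three-fold rise of
  the multi-compartment share with shock (λ ≈ 0.37 → 0.97).
* **Intensity-ratio series** decay as r₀·e^{−kt} with multiplicative
  log-normal noise (defaults k = 0.0388 h⁻¹, r₀ = 36.3, σ = 0.05, nine
  points over 24 h, mimicking the 24-h release measurements).
* **Initial contours** are spheres of diameter 1 μm with optional seeded
  Legendre perturbations (modes 2–5) or a deterministic even-dominant
  dimple seed.

All generators are bit-reproducible under a fixed seed.  What passing
recovery tests show is that the estimators are consistent for data whose
noise model matches the generator (log-normal multiplicative noise,
binomial sampling); they do not establish robustness to photobleaching,
segmentation error, vesicle-size-dependent detection, or replicate-level
batch effects present in real microscopy data.

## Known limitations

* Axisymmetric shapes only; azimuthal modes and side-by-side buds are
  unrepresentable, and the simultaneous multi-invagination count is
  IC-symmetry-limited (see above).
* No topological transitions: runs end at `pre_pinch`; compartment
  *formation* (neck scission) and anything after it are outside scope.
* Concentrations are held constant in time (no solute exchange feedback
  on osmosis); the mechanical (Laplace) contribution to the water flux
  is neglected relative to the osmotic term.
* The penalty formulation enforces area and volume only to ~1% (area
  transients to ~4%); Lagrange-multiplier exactness was traded for
  robustness.
* Fluorescence linearity and inert tracers are assumed throughout the
  release analysis.
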