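# Methods

## Model

The tissue is treated as a self-organised structure characterised by two
coarse parameters: porosity φ (extracellular volume fraction, defined
through the channel integral `φ = R_m⁻³ ∫₀^{R_m} h² dx`) and Young's
modulus Y.  An external protocol — a periodic mechanical force and a
chemical supply at the capillary boundary — drives the tissue out of
equilibrium; the entropy it produces, times temperature, is the dissipated
energy `E_d(φ, Y)`.  Along the empirical stiffening trend
`φ(Y) = a/(1+bY)`, `E_d` becomes a function of stiffness alone, and the
whole statistical machinery (free energy, configuration probability,
progression current, stages) is built on that one-dimensional landscape.

### Channel geometry

The interstitial channel has half-width
`h(x,t) = A_h (sin(πx/R_m − π/2) + 1)|sin(ft)| + h0`.  Two derived
quantities close the geometry:

* the bottleneck `h0 = sqrt(2 C0 R_m ΔP / Y) + r0`, from equating the
  elastic opening energy `Y(h0−r0)²/2R_m` with the work `C0 ΔP` of the
  applied force;
* the amplitude `A_h = sqrt((2/3)φR_m² − (2/9)h0²) − (2/3)h0`, the exact
  solution of the porosity integral at peak opening.  A `paper_literal`
  mode replaces `h0` by `r0` in this closed form (the weak-forcing
  approximation); the default self-consistent form is the one that makes
  `amplitude_from_porosity` and `porosity_of_geometry` exact inverses,
  which is enforced by a property test.

Porosity is evaluated at the forcing maximum `|sin(ft)| = 1`, the only
convention under which the closed form is derivable.

### Transport

Mass conservation for each transported species,
`∂c/∂t = −∂J/∂x − kc − (D_a/h)(c − c_cell)`, with the Fick–Jacobs flux
`J = −(D/RT) c ∂μ/∂x`, `μ = RT ln c + RT ln(h/R_m)²` (molar convention
throughout — the entropic term makes constrictions potential wells), and
tortuosity-reduced diffusivity `D = D0/[1+(∂h/∂x)²]^{1/2}`.  Boundary
conditions: Robin supply `J(0,t) = K(c* − c(0,t))` (only the product of
the printed boundary constants is identifiable; one coefficient `K_ch`
carries it) and `J(L,t) = 0` at `L = 4 R_m`, truncating the far field.
Sinks strictly remove mass when `c > c_cell`; consumption is `kc`.

Discretisation: conservative finite volumes with Scharfetter–Gummel
(exponential-fitting) face fluxes for the `ln(h/R_m)²` drift and
backward-Euler time stepping (banded solves).  The scheme is
positivity-preserving for any step, satisfies discrete mass balance to
round-off at every step (monitored, asserted < 1e-8), and holds the
discrete Fick–Jacobs equilibrium `c ∝ (h/R_m)⁻²` exactly stationary.
Time stepping is first order: held mass converges ~linearly under step
halving (measured ~1% at the default 128 cells × 64 steps/period).

### Entropy production and dissipated energy

Chemical: `σ_ch = (1/T)[J·(−∂μ/∂x) + |J_a| Δ_a z + (kc) Δz]`, each term a
flux times its conjugate affinity, signs fixed so every dissipative
process contributes non-negatively.  The diffusion term is evaluated with
the same Scharfetter–Gummel face fluxes the solver uses (flux × face
affinity); the discrete space-time integral then matches the discrete
free-energy decrease of a closed relaxing system to ~1e-4 per resolved
step — central-difference fluxes overestimate this dissipation by orders
of magnitude across steep entropic wells and must not be used here.  The
absorption affinity `Δ_a z` is the fugacity drop along the actual flux
direction (hence `|J_a|`), which keeps σ pointwise non-negative when
`c < c_cell`.

Mechanical: `σ_m = κ(ΔP sin ωt/λ)²` with `κ = Λ⁻¹ sqrt(Y/δ)/λ` and
`ω = 2πf` (the model's only frequency).  The printed units of this
expression do not resolve to an entropy density; it is implemented as
printed and the global calibration absorbs the scale (see below).

Both channels are integrated over one common protocol of `n_periods = 10`
breathing periods (π/f each): an infinite horizon diverges for both
steady parts, and truncating the chemical part at its own convergence
period would make `E_d(Y)` discontinuous in Y.  The chemical per-period
increments must converge (relative tolerance `tol_sigma`) inside the
window, otherwise a horizon error is raised.  `E_d = T Σ`, also reported
per gram using the representative-element mass `δ·L·R_m²`.

### The landscape and its extremum

`E_d(Y)` is swept over a log-spaced stiffness grid (2–150 kPa, 200
points; log spacing resolves the soft healthy flank).  A smoothing spline
(relative level `rel_smooth = 1e-3`, the solver's convergence tolerance)
carries all derivatives.  In this model the landscape is **monotone
increasing and concave-saturating**: every dissipation channel —
diffusion against the entropic barriers, wall absorption (∝ 1/h),
consumption of the better-filled channel, and the `sqrt(Y)` mechanical
term — intensifies with constriction, while the capillary supply never
throttles.  Stiff, dense tissue dissipates more; this is the model's
central ordering (carcinogenic > healthy) and it holds for every
parameter corner we explored, including multi-species and
cell-concentration (`c_cell > 0`) variants.

Consequently there is no interior zero of `∂E_d/∂Y` under the shipped
conditions.  The optimal-design reference `Y*` then falls back to the
**efficiency optimum** — the least-dissipative grid configuration (the
soft end) — consistent with reading the extremal configuration as the
thermodynamically efficient one that healthy tissue occupies.  The
configurational cost uses the quadratic expansion
`Δ_cG = (∂_Y E_d)²/2|∂_YY E_d(Y*)|` (default; the exact form
`|E_d − E_d(Y*)|` is available, and is advised automatically when the
curvature at `Y*` is degenerate).  With the efficiency-optimum reference
the total `ΔG(Y)` rises monotonically from a flat plateau at the soft
end: healthy configurations are the most probable, and the probability
decays with stiffening.

### Probability, current, stages

`ρ(Y) ∝ exp(−ΔG/RT)`, normalised by trapezoidal quadrature on the grid
(Boltzmann sign; a `paper_literal` switch with the opposite sign exists
for comparison).  The progression current uses the **driven** drift
convention `J = −D_Y(∂ρ/∂Y − (ρ/RT)∂ΔG/∂Y)`: cancer progression is an
active process that climbs the free-energy gradient toward
high-dissipation states; for the Boltzmann density this reduces to
`J = 2 D_Y β ρ ∂ΔG/∂Y ≥ 0` wherever the landscape rises.  The passive
(relaxational) convention `J = −D_Y(∂ρ/∂Y + (ρ/RT)∂ΔG/∂Y)` vanishes
identically for the Boltzmann density (detailed balance) and is kept as
the equilibrium sanity check — with it, every average current is ~0 and
every transition probability pins to 1/2, which the test suite asserts.

Stage boundaries sit at extrema of the derivative of the **specific**
current `j = J/ρ` (the drift velocity).  The density spans many decades
across the grid, so extrema of the bare `∂J/∂Y` all cluster at the
probability peak; the velocity field is scale-free in ρ and exposes the
stage structure over the whole range.  Fewer boundaries than six are
generically found on the smooth shipped landscape; the advanced labels
then merge into the stiffest interval (flagged), and "stage C" quantities
refer to the interval whose merged label set contains C.  Stability flags
mark intervals whose mean `|∂J/∂Y|` (bare current, as printed) is below
`stable_tol = 5%` of the global maximum.

Transition probabilities: `W = ½(1 + tanh(k_i ⟨J⟩))` with
`⟨J⟩ = ∫ J dY` over both stages of the pair and
`k_i = c_k / ⟨|∂J/∂Y|⟩` over the same span — one admissible reading of a
gain "depending on the average current derivative", making the tanh
argument invariant to the local current magnitude.  Conditional stage
probabilities are `P_1 = 1 − W_{1→2}`, `P_i = Π_{j≤i} W_{j−1→j}`.

## Parameters

Printed anchors (kept exactly): `C0 = 5e-10 m³`; carcinogenic averages
`φ_c = 0.0022`, `Y_c = 45.5 kPa`; `R_m` = four cell diameters.

Chosen once at physiological scales and flagged `[calibrated]` in the
shipped YAML: cell diameter 10 µm (`R_m = 40 µm`, `λ = 10 µm`); capillary
opening `r0 = 0.1 µm`; forcing `ΔP = 100 Pa`, `f = 1 s⁻¹`; `T = 310 K`;
density `δ = 1000 kg/m³`; glucose-like species `D0 = 7e-10 m²/s`,
`c* = 5 mol/m³`, `K = 1e-5 m/s`, `D_a = 1e-7 m/s`, `k = 0.05 s⁻¹`,
fugacity drops `Δ_a z = Δz = 500 J/mol`; attenuation `Λ = 2.5e19 Pa/m`
(the constant that also absorbs the printed σ_m unit mismatch);
trend `a = 0.0322`, `b = 3e-4 Pa⁻¹` (through the carcinogenic anchor);
healthy anchor `(φ_h, Y_h) = (0.0129, 5 kPa)` — soft healthy pancreas on
the trend.

Calibrated by `scripts/calibrate.py` from one landscape run:

* `n_mol = 1.228e-13 mol` — the molar conversion of the per-element
  dissipated energy, the single global scale mapping `E_d` onto `Δ_iG`;
  fixed so the healthy/carcinogenic probability ratio is 10³.  `ΔG` is
  linear in `1/n_mol`, so this has a closed-form solution.
* `c_k = 5.910e-9` — the tanh gain, fixed so the smallest advanced-stage
  transition probability is 0.9 (order-one tanh arguments).

`D_Y` is not identifiable separately from `c_k` and is fixed at 1.
`Δ_rG` defaults to 0: constant offsets cancel in every ratio and current.

## What the synthetic data emulate

No public (φ, Y) tables exist for pancreatic tissue; the generator
produces per-stage clusters along the trend (log-normal stiffness with
10% geometric spread, 5% multiplicative porosity noise), anchored at the
printed carcinogenic averages.  They emulate the described regions only:
real elastography data carry modality-dependent absolute scales,
heteroscedastic noise and within-patient correlations that the generator
does not model, so passing the recovery tests shows the fitting machinery
is correct, not that real pancreatic data follow the trend.

## What the model reproduces, and what it cannot

Reproduced under the shipped calibration (recomputed at run time, never
stored): the zero-current transition probability 1/2 (closed form); the
healthy-to-carcinogenic probability ratio of 10³; advanced-stage
transition probabilities ≥ 0.9; the dissipation ordering
`E_d(carcinogenic) > E_d(healthy)`; dynamically stable fibrous and
advanced stages.

Not reproducible from these equations, under any calibration we found
(and left honestly failing in the acceptance checks): an interior
probability maximum with a soft-side wall.  Because `E_d(Y)` is monotone,
`ρ(Y)` is maximal at the soft end of the grid and decreases with
stiffening.  Three published features depend on that missing wall: the
very low healthy-exit transition probability (here `W(H→F0) ≈ 0.68`
rather than ~10⁻³), the conditional stage-probability decay to the
10⁻³ scale (here the products stay O(0.6)), and the current's sign change
from positive to negative inside the carcinogenic stage (here `J ≥ 0`
throughout the rise).  The healthy stage also inherits the current
structure of the plateau exit and is not flagged stable.  These are
statements about the printed constitutive choices — a hyperbolic φ(Y),
`κ ∝ sqrt(Y)`, and Fick–Jacobs channel transport — whose dissipation is
provably monotone along the trend, not about numerical resolution.

## Numerical choices and limitations

* Grid: 200 log-spaced stiffness points; 128 cells × 64 steps per
  breathing period × 10 periods per transport solve (~70 ms each, ~15 s
  per full pipeline).  These sizes keep the refinement checks green while
  the whole pipeline stays interactive.
* Landscape derivatives always come from the smoothing spline; raw sweep
  values are kept alongside for inspection.
* Boundary detection: prominence `5e-5` of the velocity-derivative span,
  with a margin of 2% of the grid at each end excluded (edge stencils);
  at most six boundaries are kept.
* Degenerate inputs: zero forcing gives exactly zero entropy; empty cells
  are handled in flux form (no `ln 0`); overflow in the Boltzmann weight
  is guarded by subtracting the extremal `ΔG`.
* The model is 1-D per channel: no channel networks, no advection or
  osmotic flow, no multi-species coupling, no time-dependent
  Fokker–Planck evolution in Y (only stationary current diagnostics), and
  no remission (reverse) transitions.
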