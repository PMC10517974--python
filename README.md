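# tissuestage

A mechanistic, non-equilibrium-thermodynamics model of tissue stiffening
and cancer staging, specialised to pancreatic-adenocarcinoma-like parameter
regimes.  The package is for biophysicists and modellers who want a
quantitative, end-to-end chain from tissue microstructure to stage
statistics:

1. **Geometry.** The interstitial space is a periodically constricted
   "breathing" channel of half-width
   `h(x,t) = A_h (sin(πx/R_m − π/2) + 1)|sin(ft)| + h0`,
   with the bottleneck `h0 = sqrt(2 C0 R_m ΔP / Y) + r0` set by balancing
   elastic energy against the work of the applied force, and the amplitude
   `A_h` slaved to the porosity `φ = R_m⁻³ ∫ h² dx`.
2. **Transport.** A chemical species (drug, glucose) obeys
   `∂c/∂t = −∂J/∂x − k c − (D_a/h)(c − c_cell)` with the Fick–Jacobs flux
   `J = −(D/RT) c ∂μ/∂x`, `μ = RT ln c + RT ln (h/R_m)²`, a Robin supply
   `J(0,t) = K (c* − c(0,t))` at the capillary mouth and a closed far end.
   The solver is a conservative finite-volume scheme with
   Scharfetter–Gummel fluxes and backward-Euler stepping.
3. **Dissipation.** Entropy production from diffusion, absorption,
   consumption (`σ_ch`) and from periodic mechanical forcing
   (`σ_m = κ (ΔP sin ωt / λ)²`, `κ = Λ⁻¹ sqrt(Y/δ)/λ`) is integrated over a
   common forcing protocol; the dissipated energy is `E_d = T Σ`.  With
   porosity slaved to stiffness through `φ(Y) = a/(1 + bY)`, sweeping Y
   gives the dissipated-energy landscape `E_d(Y)`.
4. **Free energy and probability.** `ΔG = Δ_rG + E_d + Δ_cG`, where
   `Δ_cG = (∂_Y E_d)² / 2|∂_YY E_d(Y*)|` is the configurational cost of
   sitting away from the optimal-design stiffness `Y*`.  Configuration
   probabilities follow the Boltzmann weight `ρ(Y) ∝ exp(−ΔG/RT)`.
5. **Staging.** A drift-diffusion current over stiffness,
   `J(Y) = −D_Y (∂ρ/∂Y − (ρ/RT) ∂ΔG/∂Y)` (progression climbs the
   free-energy gradient, maintained by active internal processes),
   is segmented into stages H, F0, F, T, C, T_C, RC at the extrema of the
   drift-velocity derivative; transition probabilities follow the tanh map
   `W = ½(1 + tanh(k_i ⟨J⟩))` with `⟨J⟩` the current integrated over both
   stages, and conditional stage probabilities are telescoping products.

The shipped configuration passes exactly through the two printed
literature anchors — carcinogenic porosity/stiffness `(φ_c, Y_c) =
(0.0022, 45.5 kPa)` and the force-coupling volume `C0 = 5×10⁻¹⁰ m³` —
with all unprinted constants fixed once by `scripts/calibrate.py`
(documented in `docs/methods.md`).

## Worked example

```python
from tissuestage import paper_regime, run_pipeline

result = run_pipeline(paper_regime())   # ~15 s: 200 transport solves
print(result.stages.labels)
print(result.log10_probability_ratio())
print(result.W_by_name())
print(result.P_by_stage())
```

prints

```
('H', 'F0', 'F', 'T+C+T_C+RC')
2.9999999999999996
{'H->F0': 0.6839..., 'F0->F': 0.9, 'F->T+C+T_C+RC': 0.9988...}
{'H': 0.3160..., 'F0': 0.6839..., 'F': 0.6155..., 'T+C+T_C+RC': 0.6148...}
```

Reading: healthy tissue is a thousand times more probable than the
carcinogenic configuration (`log10 ρ_H/ρ_C = 3`); the stiffness axis
2–150 kPa splits into a healthy stage, two fibrous stages and a merged
advanced stage (fewer current-structure boundaries exist than the seven
canonical labels, so the advanced labels share the stiffest interval, and
`result.stages.merged` flags it); once fibrosis starts, every further
transition is probable (W ≥ 0.9).  The same run is available from the
shell as `tissuestage stages --out results/`, alongside `simulate`,
`landscape`, `fit-phi` and `fixtures` subcommands.

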