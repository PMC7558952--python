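# glassage

Physical-ageing analysis of amorphous glasses from differential scanning
calorimetry (DSC) data — built around the thermal behaviour of amorphous
pharmaceuticals such as indapamide (Tg ≈ 102 °C, ΔCp ≈ 0.47 J·g⁻¹·K⁻¹).

An amorphous drug stored below its glass transition temperature slowly
relaxes toward the equilibrium supercooled liquid ("physical ageing"),
losing enthalpy that is recovered on reheating as an endothermic overshoot
at the glass transition. How fast this happens, and how far the glass is
from equilibrium, controls the shelf-life advantage of the amorphous form.
`glassage` turns thermograms — measured, or simulated with a built-in
Tool–Narayanaswamy–Moynihan (TNM) glass model — into the standard
quantitative descriptors of ageing:

* **Enthalpy relaxation** from aged/unaged scan pairs,
  ΔH_r = (1/q)·∫(Φ_aged − Φ_unaged) dT = ∫(Cp_aged − Cp_unaged) dT,
  and its equilibrium ceiling ΔH_r^∞ = ∫_{Ta}^{Tg} ΔCp dT ≈ ΔCp·(Tg − Ta).
* **KWW kinetics**: weighted nonlinear fits of the stretched exponential
  ΔH_r(t) = ΔH_r^∞·[1 − exp(−(t/τ)^β)] and the recovery parameter
  φ(t) = exp(−(t/τ)^β) = 1 − ΔH_r/ΔH_r^∞.
* **Fictive temperature** T_f by the enthalpy-intersection construction
  (extended liquid enthalpy meets the glass enthalpy) and by the Moynihan
  equal-area balance, as mutually checking routes.
* **Kinetic fragility**: E_a = −R·d ln q / d(1/T) from rate sweeps and the
  Angell index m = E_a/(2.303·R·Tg), with strong / moderately fragile /
  fragile classification.

The TNM simulator evolves T_f under arbitrary thermal programs with
ln τ(T, T_f) = ln A + xΔh*/(RT) + (1−x)Δh*/(RT_f) and a stretched-exponential
memory kernel, producing rate-dependent glass transitions and
ageing overshoots so every analysis stage can be validated against known
ground truth.

## Worked example

Fit the ageing kinetics of a simulated relaxation series measured at
85 °C (noise 0.3 J·g⁻¹, the typical replicate scatter of DSC area
integration):

```python
import numpy as np
import glassage as ga

times = np.array([0.5, 1, 2, 4, 8, 16, 24, 32]) * 3600.0  # ageing times, s
series = ga.simulate_kww_series(
    Ta=358.15, times=times, tau=28 * 3600.0, beta=0.327,
    dHr_inf=7.92, noise_sd=0.3, seed=4,
)
fit = ga.fit_kww(series)
print(f"tau      = {fit.tau/3600:.1f} h")
print(f"beta     = {fit.beta:.3f}")
print(f"dHr_inf  = {fit.dHr_inf:.2f} J/g")
print(f"phi(32h) = {float(ga.recovery(32*3600.0, fit.tau, fit.beta)):.2f}")
```

prints

```
tau      = 26.9 h
beta     = 0.316
dHr_inf  = 7.72 J/g
phi(32h) = 0.35
```

τ ≈ 27 h means the glass needs roughly a day at 85 °C for substantial
relaxation; β ≈ 0.32 indicates a broad relaxation-time distribution; and
φ ≈ 0.35 after 32 h says two-thirds of the distance to equilibrium is
already gone at this ageing temperature. With three free parameters and
short-time data the fitted amplitude scatters between noise realisations;
fixing ΔH_r^∞ from the equilibrium estimate
(`ga.fit_kww(series, dHr_inf_fixed=...)`) stabilises τ considerably.

The full study design — ageing series at several temperatures plus
heating/cooling rate sweeps for fragility — runs from the command line:

```sh
glassage study --seed 1 --out results/
```

which writes `ageing_report.json`, `fragility_report.json` and CSV tables.
On the default TNM glass the fragility half reports
E_a ≈ 506/516 kJ·mol⁻¹ (heating/cooling), m ≈ 70/72 — a moderately
fragile glass, matching the input activation enthalpy Δh* = 500 kJ·mol⁻¹.

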