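# Methods

## Scope and data model

`glassage` analyses isothermal physical ageing and kinetic fragility of a
glass-forming material from DSC thermograms. A thermogram is a
`DSCCurve` — sampled time (s), temperature (K) and a per-gram signal that
is either heat flow (W·g⁻¹, endothermic up) or apparent specific heat
(J·g⁻¹·K⁻¹). Canonical internal units are kelvin, seconds, J·g⁻¹·K⁻¹ and
J·g⁻¹; °C, minutes and hours appear only at I/O boundaries (CSV columns,
YAML configs, display). Scan rates are kept in K·min⁻¹, the unit of every
instrument method, and converted where integrals need K·s⁻¹. The two
signal kinds interconvert exactly through Cp = Φ/|q|, so the two printed
forms of the relaxation integral agree to round-off by construction.

Thermal protocols are `ThermalProgram`s — sequences of ramps and
isothermal holds with continuous temperature — mirroring the study
design: melt-quench at 10 K·min⁻¹, age at Ta for t_a, cool to ambient,
reheat at 10 K·min⁻¹ through the transition.

## Baselines, Tg and fictive temperature

Solid and liquid Cp reference lines are ordinary least-squares fits
inside user-supplied windows. Defaults for the indapamide-like synthetic
system are solid 300–330 K and liquid 400–430 K. Both were placed by
inspecting simulated scans: the slowest cooling rate in the fragility
sweep (0.2 K·min⁻¹) leaves the glass structurally active down to
≈ 330 K, and the deepest ageing overshoots on reheating decay by
≈ 392 K, so windows at 310–350 / 390–420 K would clip the transition at
both ends and visibly tilt the liquid reference. Windows are
configuration, not auto-detected; real data need the same inspection.

The glass transition is reported by the half-step (midpoint) convention:
T_mid is where Cp crosses Cp_solid + ΔCp/2, with onset and end from the
tangent at the steepest slope. Midpoint is the common DSC convention; the
detector is exact for the TNM simulator in the sense that the Cp
half-step crossing coincides with the temperature where the simulated
dT_f/dT crosses 1/2 (this is the oracle the tests assert against).

Fictive temperature is computed two ways:

* **Enthalpy intersection.** Total enthalpy H(T) is the cumulative
  trapezoid of Cp anchored at a reference. The solid and liquid enthalpy
  references are the *integrals of the fitted Cp baseline lines*, each
  anchored to the measured H by its mean offset inside the corresponding
  window; T_f is where the extended liquid reference meets the glass
  reference. Fitting straight lines directly to H(T) and extrapolating
  is deliberately avoided in the pipeline: H of a phase with linearly
  varying Cp is quadratic in T, and a 30–50 K linear extrapolation
  injects a 1–4 K bias. A plain two-line intersection
  (`fictive_temperature`) is still provided for constructed geometries.
* **Equal-area (Moynihan).** T_f solves
  ∫_{T_f}^{T*} ΔCp dT = ∫_{T'}^{T*} (Cp − Cp_solid) dT with T′/T* at the
  inner window edges; the left side has a closed form for linear
  baselines and the root is bracketed and solved with Brent's method.

The two constructions are analytically equivalent; their residual
disagreement (≈ 0.1 K on simulated curves) measures numerical
implementation error, which is why the test suite uses one as the
cross-check of the other.

A note on conventions: for a stretched (β = 0.5) glass the heating-scan
midpoint sits 2–3 K above the limiting fictive temperature of the
preceding cooling — ordinary scan hysteresis. "T_f of the unaged glass
equals Tg" therefore holds against the material's nominal Tg (the
temperature where the equilibrium relaxation time is 100 s, 375.35 K for
the default glass, recovered within ≈ 1.5 K) and against the limiting
fictive temperature (recovered within ≈ 0.2 K), not against the heating
midpoint to sub-kelvin precision.

## Enthalpy relaxation and its equilibrium value

ΔH_r integrates the aged-minus-unaged Cp difference over [T1, T2] with
T1 < Tg < T2 (defaults Tg − 40 K and Tg + 25 K). Both curves are
linearly interpolated onto the union of their temperature samples inside
the limits — exact for piecewise-linear inputs and free of new extrema —
and integrated by the trapezoid rule. Heat-flow inputs are converted
through the common scan rate first; mismatched rates are an error.

ΔH_r^∞ is exposed in both printed forms: scalar ΔCp(Tg)·(Tg − Ta) and
the integral ∫_{Ta}^{Tg} ΔCp dT (closed form for linear baselines). The
two coincide for parallel baselines; neither is privileged because the
source values for the measured system are ambiguous between them.

Replicate scatter defaults to ±0.3 J·g⁻¹ per point when no standard
deviation is supplied, the typical reproducibility of DSC area
integration for such systems.

## KWW fitting

ΔH_r(t) = ΔH_r^∞·[1 − exp(−(t/τ)^β)] is fitted by weighted nonlinear
least squares (lmfit/least-squares, weights 1/sd²) in the parametrisation
(ln τ, β ∈ (0, 1], ln ΔH_r^∞), because τ spans hours to months across
ageing temperatures. Initialisation: ΔH_r^∞₀ = 1.2·max ΔH_r, β₀ = 0.5,
τ₀ from the log-interpolated half-amplitude crossing, plus a 5-point
log-spaced τ multi-start. Convergence tolerances are set to 1e-15 so
noiseless model-generated series are recovered to ≈ 1e-13 relative.

Two plausibility bounds are imposed on the free fit:
ΔH_r^∞ ∈ [0.5, 50]·max ΔH_r and τ within 10⁶× of the observed time
window. When every ageing time is far below τ, the data constrain only
the ratio ΔH_r^∞/τ^β and the unbounded problem can diverge along that
ridge (amplitudes of 10⁵ J·g⁻¹ for a 4 J·g⁻¹ data set); the bounds keep
such fits finite without touching well-identified ones. Fixing ΔH_r^∞
from the equilibrium estimate (either form) is supported and markedly
stabilises τ under noise — under ±0.3 J·g⁻¹ noise at the 85 °C settings
the median free-fit τ over replicates is within ≈ 15 % of truth, but
individual draws can hit the bounds.

The recovery parameter is computed both from fitted parameters
(φ = exp(−(t/τ)^β)) and from data (φ = 1 − ΔH_r/ΔH_r^∞); the two differ
by fit residuals and are reported side by side rather than forced to
agree. The linearised fictive-temperature track
T_f(t) = Tg − ΔH_r(t)/ΔCp complements the thermogram-based T_f.

## Fragility

ln q is regressed on 1/T_char (scipy linregress); E_a = −R·slope with
R = 8.314 J·mol⁻¹·K⁻¹, and m = E_a/(2.303·R·Tg_ref) with Tg_ref the
characteristic temperature of the 10 K·min⁻¹ scan. The printed form of
the activation-energy relation in common use omits R; the implemented
form is the dimensionally consistent one. Classification bands are
m < 40 strong, 40–100 moderately fragile, ≥ 100 fragile — amorphous
drugs typically fall at 60–120.

Cooling sweeps use the limiting fictive temperature (equal-area on the
cooling scan); heating sweeps use the midpoint Tg. Heating sweeps default
to **rate-matched cooling** (cool at q, reheat at q): this is the
proportional-rate condition under which d ln q/d(1/Tg) = −Δh*/R holds,
and the simulator confirms it (recovered E_a within ≈ 1 % of Δh* for
x ∈ [0.5, 1]). The fixed-cooling alternative (cool always at
20 K·min⁻¹) is available via `q_cool`, but for a nonlinear glass it
inflates the apparent E_a by 1.6–2×, because slow scans age the glass in
situ and compress the Tg shift; it should not feed the Angell index.

## The TNM synthetic generator

The simulator advances the fictive temperature by the discretised
superposition

T_f(t_n) = T₀ + Σ_j ΔT_j·[1 − exp(−(Z_n − Z_{j−1})^β)],
Z_n = Σ_k Δt_k/τ_k, ln τ_k = ln A + xΔh*/(R·T_k) + (1−x)Δh*/(R·T_f,k−1),

with ramps subdivided to ≤ 0.5 K per step (0.25 K in accuracy-sensitive
tests; results change by < 0.1 K between the two) and geometric time
grids on holds (200 steps by default, 300 for ≫ 100 h holds). When every
stored contribution has fully relaxed, the history is compacted to the
current temperature, which both bounds the cost and keeps reduced-time
differences within double precision across high-temperature excursions.
Apparent heat capacity on ramps is Cp_solid + ΔCp·dT_f/dT.

Default parameters (fixed in advance as a realistic indapamide-like set,
not fitted): Δh* = 500 kJ·mol⁻¹, x = 0.5, β = 0.5, ln A pinned so
τ(375.35 K, 375.35 K) = 100 s, parallel Cp baselines 0.0025·T + 0.30 and
0.0025·T + 0.77 (ΔCp = 0.47 J·g⁻¹·K⁻¹). These produce Tg ≈ 103–107 °C
depending on scan rate and m ≈ 70–72 (moderately fragile).

What the generator emulates: rate-dependent Tg and limiting T_f, ageing
overshoots that grow and shift upward with hold time, ΔH_r saturating
toward the equilibrium value, and T_f marching from Tg down to Ta. What
it does not emulate: instrument smearing and thermal lag, baseline
curvature and drift, the hemihydrate dehydration and melting endotherms
of the crystalline starting material, partial vitrification when Ta lies
inside the broad transition, and chemical degradation. Tests passing on
this generator therefore validate the analysis chain, not the
instrument-specific corrections real data may need. One measured
secondary effect worth knowing: the overshoot area recovered on
reheating underestimates the enthalpy lost during the hold by ≈ 5 %
(the unaged reference itself relaxes during its scan); the conservation
check is asserted at deep ageing where the effect is smallest.

The phenomenological pair generator (sigmoid step + Gaussian overshoot
of exact prescribed area) provides closed-form ground truth for the
relaxation integral; it requires the peak to sit ≥ 6σ inside the grid
and a few samples per peak width for 0.5 % trapezoid recovery. The KWW
series generator adds Gaussian noise via a seeded `default_rng`, clipped
at the −0.3 J·g⁻¹ plausibility floor used for measured records.

## Study sizes and reproducibility

The bundled study design uses ageing temperatures 65/75/85 °C, eight
ageing times from 0.5 to 32 h, heating rates 0.5–20 K·min⁻¹ and cooling
rates 0.2–10 K·min⁻¹ — a few dozen TNM simulations in total, which run
in seconds at the default step sizes. All stochastic stages take a
single integer seed; reports embed a config hash and contain no
timestamps, so a fixed seed reproduces byte-identical output.

## Known limitations

* The KWW τ at ageing temperatures where t_max ≪ τ (65 °C-like
  conditions) is identifiable from noiseless data but poorly conditioned
  under realistic noise with all three parameters free; fix ΔH_r^∞ when
  extrapolating such fits.
* The equal-area and intersection T_f both inherit the baseline windows;
  windows inside the transition tail bias T_f and, through it, the
  cooling-sweep fragility.
* The TNM recursion cost grows with stored history length (O(n) per step
  after compaction); pathological programs that never equilibrate keep
  the full history.
* Ta inside the transition region (e.g. 85 °C for a broad transition)
  mixes vitrification with ageing; the package quantifies but does not
  correct for this.
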