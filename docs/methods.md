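# Methods

## Scope and model overview

`glassprobe` treats the glass transition of a water-plasticized glucose
polymer as a multi-probe detection problem.  Each probe has a forward
model, a generator that synthesizes data from known ground truth, and an
analysis stage whose correctness is established by parameter recovery.
The package never claims to reproduce any particular measured dataset;
it reproduces the *analysis*, exercised at realistic study conditions.

## FID relaxation models

Model 1 is Abragam + exponential; model 2 adds a Gaussian solid
component:

    F2(t) = Sg e^{-(t/T2g*)^2} + Ss e^{-(t/T2s*)^2} sinc(bt) + L e^{-t/T2L*}

Conventions: the Gaussian exponent carries no factor ½ (`T2*` is defined
by `e^{-(t/T2*)^2}` exactly); `sinc` takes the value 1 at `bt = 0`.  The
second moment of the Abragam component is `M2 = 2/T2s*² + b²/3` (from
−F″(0)/F(0) of the unit-amplitude component), and of the Gaussian
`2/T2g*²`.

**Fitting.**  Bounded trust-region least squares (`scipy.optimize.
least_squares`).  The default initialization partitions the signal
coarsely (first points → total amplitude, tail median → mobile
amplitude) and grid-searches log-spaced `T2` values and a small set of
`b` values; non-convergence is flagged on the result rather than raised.
To keep component labels stable across a temperature series the Abragam
`b` is bounded below by 10⁻³ rad/µs, so the Abragam term can never
collapse onto the Gaussian and swap roles.  No leading points are masked
by default (no receiver dead time is simulated); a configurable leading
mask exists.

**Default ground truth** (amplitudes normalized to a unit total):
`Sg = 0.50`, `T2g* = 20 µs`, `Ss = 0.13`, `T2s* = 16 µs`, `b = 0.5
rad/µs`, `L = 0.37`, `T2L* = 400 µs`, sampled at 2048 points every
0.9 µs with additive Gaussian noise (default studies use 0.5 % of the
total amplitude).  The Abragam amplitude 0.13 is the documented
semi-crystalline share at 25 °C; the time constants are typical rigid-
lattice carbohydrate values chosen so that the two solid components are
*identifiable*: the Abragam beat is well resolved (`b·T2s* = 8`, first
node at ~6 µs) and clearly distinct from the slower amorphous Gaussian.
With strongly overlapping solid components (e.g. `b·T2s* ≲ 4` and
`T2g* ≈ T2s*`) the `Sg`/`Ss` split becomes genuinely ill-posed at this
noise level — the fit is then honest about a degeneracy the data cannot
resolve, and no choice of optimizer fixes it.  Recovery tests therefore
state what passing shows: unbiased recovery *for separable components*,
not for arbitrary parameter corners.

## χ² MCMC model selection

The likelihood is `exp(−χ²/2)` with `χ² = Σ((y−F)/σ)²` (unit σ when the
data carry no uncertainties) — the standard Gaussian-error assumption.
The sampler is plain Metropolis with independent Gaussian proposals,
acceptance probability `min(1, e^{−Δχ²/2})`, and outright rejection of
out-of-bounds proposals.  Default proposal SD is 2 % of each parameter's
bound range, rescaled every 100 steps *during burn-in only* toward ~30 %
acceptance (halved outright after a dead window); the post-burn-in
kernel is fixed, so detailed balance holds for the retained samples.
Defaults: 50 000 steps, 20 % burn-in.  Chains are byte-reproducible from
the seed.  Model selection compares minimal χ² (the χ² histogram mode is
reported alongside); exact ties go to the model with fewer parameters.
No information criterion and no marginal-likelihood integration are
attempted.

## Gordon–Taylor fit

`Tg = (Xs·Tgs + k·Xw·Tgw)/(Xs + k·Xw)` with `Xw` the *wet-basis* water
mass fraction and `Xs = 1 − Xw`.  `Tgw` is treated as a literature
constant (−135 °C), never fitted.  Laboratory moisture in g water per g
dry matter is converted via `w = dm/(1+dm)`.  The fit estimates
`(Tgs, k)` by least squares and reports `R² = 1 − SSE/SST`; a fit driven
to `k → 0` (constant-Tg data) is flagged as degenerate.  Note the
convention ambiguity: with the quoted parameters, wet-basis evaluation
at 0.1069 gives 57.2 °C while a fraction-of-dry convention gives
61.9 °C; the package defaults to wet-basis and exposes both conversions
rather than forcing agreement with any rounded published figure.

## Stoichiometry and AFGA cross-sections

Moisture maps to `ν` waters per anhydroglucose via
`ν = (g water/g d.m.) × 162.14/18.02`; element counts are `H = 10+2ν`,
`C = 6`, `O = 5+ν` (wet-basis 0.1069 → ν = 1.077 ≈ 1.1).  Proteins and
fat are neglected in the neutron stoichiometry.  Bound cross-sections
(H 82.02, C 5.551, O 4.232, Al 1.503 b) and nuclide-mass ratios are a
documented constants table; free cross-sections are
`σ_b·(A/(A+1))²`.

Each hydrogen-bearing group (CH₂, CH, OH, water OH) carries a three-mode
harmonic spectrum (defaults, meV: CH₂ {360, 175, 90}, CH {360, 160,
100}, OH and water {420, 200, 80}; one mode per momentum direction,
configurable).  Its cross-section is a Doppler-broadened free-gas curve

    σ(E) = σ_free [(1 + 1/(2x²)) erf(x) + e^{−x²}/(x√π)],  x² = A·E/(k_B·T*)

evaluated at the harmonic effective temperature
`T* = ⟨(ħω/2k_B) coth(ħω/2k_BT)⟩`.  Heavy atoms use a low-energy
lattice mode set.  This functional form is this package's own
construction: it preserves the properties the analysis actually uses —
additive group structure, the exact stoichiometric free-atom plateau at
epithermal energies (|σ/Σ_free − 1| < 0.5 % above 50 eV), a thermally
sensitive meV region, and a 1/v low-energy law.  One known qualitative
difference: in the 2.6–10 meV window this model's integral *rises*
gently with temperature (Doppler broadening of the free gas), whereas
measured curves of bound hydrogenous solids typically *fall*
(Debye–Waller suppression of the elastic line).  The discrepancy series
ΔI(T) = measured − model subtracts the model trend, so self-consistency
and injected-softening scenarios are unaffected; only the sign of the
raw trend differs, and tests assert smooth monotonicity rather than a
direction.

NMD widths are harmonic: `σ_y² = (1/3)Σ w_i (A·ħω_i/2(ħ²/m_n))
coth(ħω_i/2k_BT)` with `ħ²/m_n = 4.1434 meV·Å²`.  Over −20…80 °C the
hydrogen width varies by <1 % (zero-point dominated), the package's
quantitative statement of the "flat AFGA line".

## Densitometry

Scattering power is `s = −ln⟨T(E)⟩` over the epithermal window, default
[10, 100] eV (the plateau is quoted only as "above a few eV"; the window
is configurable).  Calibrated estimates are `ρ(T) = ρ_ref·s(T)/s(T_ref)`
with the reference pinned exactly.  The diffraction analogue integrates
the counts over a d-spacing window, default [2.5, 3.5] Å, that must
clear every allowed fcc aluminium reflection (a = 4.0495 Å; largest
d = a/√3 = 2.338 Å) by ≥3 peak widths — a violated window raises an
error naming the (hkl).  Error bars propagate counting noise only.

On noise-free synthetics the diffraction estimator recovers the schedule
exactly (linear construction); the transmission estimator differs by
≲3·10⁻⁵ g/cm³ because the free-gas plateau retains a tiny
effective-temperature dependence.  The two estimators therefore agree to
10⁻⁴ g/cm³, not to machine precision — a physical feature of a
temperature-dependent plateau, documented rather than suppressed.

**Transition bracketing.**  A drop between adjacent temperatures is
flagged when it exceeds 3× the median absolute inter-point change;
consecutive flagged intervals merge, and the largest-total-drop run is
reported as the two *measured* bracketing temperatures, never an
interpolated Tg.  Flat or uniformly sloped series return "none found".
The same rule, applied to |change|, flags discontinuities in the NMR
parameter series.

## Neutron Compton scattering

Inverse geometry: fixed final energy `E1 = 4897 meV`, flight paths
`L0 = 11 m`, `L1 = 0.7 m` (configurable defaults; instrument values are
not published with the study), neutron speed `v = 437.39·√E[meV] m/s`.
Recoil (y = 0) kinematics solve
`E0 − E1 = (1/A)(E0 + E1 − 2√(E0E1)cosθ)`; for A = 1 this is
`E0 = E1/cos²θ`, with no solution at θ ≥ 90° — the kinematic reason the
hydrogen peak appears only at forward detectors, enforced everywhere in
generation and fitting.  `y = (A·ω)/(ħ²/m_n · q) − q/2` per TOF bin.

TOF peaks map the y-space Gaussian (NMD width plus detector resolution
in quadrature) *pointwise* through the kinematic Jacobian |dy/dt|, so
the y-transform of a synthetic peak returns the generating Gaussian
exactly and the TOF integral equals the intensity by construction.  Full
convolution with measured resolution functions, multiple scattering and
gamma backgrounds are out of scope; the resolution is a single Gaussian
width per detector (default 0.5 Å⁻¹).

**Partitioned fit.**  For each trial width vector the intensities (and a
flat baseline) are the unique non-negative linear least-squares solution
(`scipy.optimize.nnls`); the outer search runs over log-widths only
(variable projection).  Intensities are physically non-negative, hence
the NNLS constraint.  Aggregation iterates detector-by-detector fits
with inverse-variance averaging of widths (tolerance 10⁻⁴ relative, max
10 iterations); per-mass *absolute* intensities are averaged over the
detectors where the mass is kinematically visible and then normalized
across masses, which keeps hydrogen (forward-only) comparable with the
all-detector masses.

## Synthetic-data realism

The generators emulate: the FID acquisition grid and additive noise; Tg
datasets with Gaussian temperature noise; transmission
`T(E) = e^{−n·d·σ(E,T)}` (default thickness 0.3 cm) with additive noise
clipped to (0, 1]; diffraction as a temperature-independent aluminium
Bragg template (Gaussian peaks, intensity ∝ d² as a crude structure
proxy) over a flat background ∝ ρ; and NCS spectra with
√counts-scaled Gaussian noise.  They do **not** emulate instrument
resolution functions beyond single Gaussian widths, beam spectrum or
efficiency shapes, multiple scattering, container subtraction errors, or
sorption-history effects.  Passing recovery tests therefore demonstrates
the correctness and conditioning of the estimators under the assumed
noise model, not robustness to every systematic in real beamline data.

The default density schedule is a logistic sigmoid, 1.3 → 1.1 g/cm³
with midpoint 50 °C and width 5 °C, sampled at −20, 0, 20, 40, 60,
80 °C — endpoints from the tabulated starch density used for calibration
and the simulated rubbery value, the midpoint centred in the observed
40–60 °C drop.  The NMR scenario steps the solid-matrix parameters at
42.5 °C (T2g* up, b down, Sg→Ss transfer), mirroring the discontinuity
pattern such systems show near the transition.

## Problem sizes

Default analyses run at desk scale: 2048-point FIDs, 400-point
log-energy transmission grids over 1 meV–1000 eV, 640-point diffraction
patterns, five detectors with ~840 TOF bins, 20 seeded repeats for
recovery statistics, and MCMC chains of a few thousand steps in the
pipeline (50 000 for posterior-convergence checks).

## Known limitations

* The AFGA group forms are a harmonic free-gas construction, not a fit
  to any measured vibrational density of states; only qualitative
  thermal trends and the exact plateau/width properties are asserted.
* Amplitude normalization of reported FID fractions is stated
  explicitly (fractions of the t = 0 total); raw amplitudes are also
  available since published conventions vary.
* Density estimates are relative to the calibration point; no absolute
  densitometry.
* The Metropolis sampler is single-chain; no tempering or evidence
  integration.
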