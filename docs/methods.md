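# Methods

## Scope and model

The package analyzes steady-state fluorescence quenching of a protein by a
small-molecule ligand under the *static* quenching model: the ligand forms
a non-fluorescent ground-state complex with the protein, so adding
quencher removes fluorophores from the emitting population without
altering the excited-state lifetime. All quantitative machinery follows
from two relations:

* the Stern–Volmer law `F0/F = 1 + K_SV [Q]`, linear in quencher
  concentration, with `K_q = K_SV / τ0` the bimolecular rate constant;
* the 1:n complex isotherm `(F0 − F)/F = K_b [Q]^n`, fitted in
  double-logarithmic form `log10((F0−F)/F) = log10 K_b + n log10 [Q]`.

Free-ligand concentration is approximated by total added ligand; no
ligand-depletion correction is applied (at the µM protein concentrations
of a typical titration, and with K_b of order 10⁴ L/mol, the bound
fraction of ligand is small but not zero — this is a recognized
approximation of the method, not of the implementation).

## Fitting choices

Both fits are ordinary least squares (`scipy.stats.linregress`), which is
the field's standard treatment of these linearized plots.

* The Stern–Volmer intercept is free by default and reported, because
  measured data rarely passes exactly through 1; an intercept-constrained
  fit (`fix_intercept=True`) is available and is the one under which the
  n = 1 isotherm and the linear quench law give identical constants. For
  the constrained fit the slope is `Σq(y−1)/Σq²` with standard error
  `sqrt(SSR/(N−1)/Σq²)`.
* `r_squared` is `1 − SSR/SST`, clipped to [0, 1]; flat data (no
  quenching) is treated as a perfect fit of the constant model.
* Double-log points with F ≥ F0 are undefined under the transform; they
  are excluded with a logged warning and counted in the result rather
  than raised, because noise near zero quenching is expected at the low
  end of a titration.
* Titration intensities above 1.05·F0 are flagged with a warning at
  construction (quenching can only lower the signal; 5% allows for
  noise), never silently repaired.

### Conditioning of the double-log intercept

`K_b = 10^intercept` is an extrapolation of the fitted line to
log10[Q] = 0, several decades below a typical 5–50 µM series
(mean log10[Q] ≈ −4.7). Intensity noise is therefore amplified twice:
first by the transform — a relative error δ in F perturbs
`(F0−F)/F` by δ·(F0/F)/((F0/F)−1), a ~40-fold amplification at a
weakly-quenched point — and then by the ~4.7-decade lever arm of the
extrapolation. With 1% multiplicative intensity noise the median relative
error of `K_b` is several tens of percent even though `n` (the slope) is
recovered to ~10%; at 0.1% noise, typical of a well-averaged instrument,
`K_b` recovery tightens to ~10% and the error scales roughly linearly
with the noise. The estimator is consistent but ill-conditioned; users
comparing K_b across conditions should rely on ratios fitted from the
same instrument and concentration series, which is exactly what the
displacement analysis does.

## Mechanism classification

The static/dynamic verdict combines two independent signatures across
temperatures: whether every `K_q` exceeds the diffusion-controlled
ceiling (default 7.4×10⁹ L mol⁻¹ s⁻¹ at 298 K, configurable — literature
values for this constant vary by an order of magnitude, so it is exposed
rather than hard-coded), and the sign of the least-squares slope of
`K_SV` versus temperature. When pointwise differences of `K_SV` change
sign the trend is reported as `non-monotone` and the verdict can only be
`ambiguous`: the classifier reports the trend it computes and never
coerces noisy evidence into a narrative. `static` requires both the
ceiling violation and a decreasing trend; `dynamic` requires all `K_q`
at or below the ceiling and an increasing trend.

## Structure probes

Synchronous scans are extracted from an EEM by reading the intensity at
(λ_ex, λ_ex + Δλ) with linear interpolation along the emission axis
(bilinear on the rectangle; excitation points are on-grid). Peak
positions everywhere are grid argmaxima, ties broken toward shorter
wavelength — instruments report integer-nm positions and sub-grid fitting
would add unverifiable precision. Percent intensity changes are computed
at full precision and rounded (default 1 decimal) only for table output.
The Rayleigh scatter peak (λ_ex = λ_em) is treated as an ordinary
rectangular region, by default [350, 370]×[350, 370] nm, not specially
modeled.

## Förster chain

The overlap integral uses the discrete form
`J = Σ F ε λ⁴ Δλ / Σ F Δλ` after resampling both spectra by linear
interpolation onto a uniform grid (default 0.5 nm) over the intersection
of their wavelength ranges; rectangle-rule summation mirrors the discrete
definition and converges to <0.1% of a 10⁻³-nm quadrature on smooth
bands. Units: ε in M⁻¹ cm⁻¹ and λ in nm give J in M⁻¹ cm⁻¹ nm⁴, the
convention under which `R0 = 0.211 (κ² n⁻⁴ Φ_D J)^{1/6}` evaluates in
ångströms (returned in nm). This is the only unit reading under which
the reference study's own numbers (J = 9.42×10¹² with R0 = 1.72 nm) are
mutually consistent, although that study prints the unit as cm³·L/mol.
Defaults κ² = 2/3 (isotropic dynamic averaging), n = 1.336 (aqueous
buffer), Φ_D = 0.15 (albumin tryptophan) are all overridable. Every
`ForsterResult` asserts `E = R0⁶/(R0⁶ + r⁶)` at construction, so an
inconsistent triple cannot be represented.

## Synthetic data

The generator emulates the study conditions of a ligand–albumin
titration: 10 quencher concentrations from 5 to 50 µM, F0 ≈ 1.2×10⁴
counts/s, a Gaussian tryptophan emission band at 322 nm (width 25 nm),
ground truth K_b = 3.83×10⁴ L/mol and n = 1.161 at 298 K, which quenches
~28% of the signal at the highest concentration. Noise is multiplicative
Gaussian on intensities — photon-count-like at high counts — with a
seeded `numpy.random.Generator` recorded in the titration label. Only the
static model is simulated (no collisional term, no sphere-of-action).
EEMs are sums of separable 2-D Gaussian peaks; the bound state applies
per-peak intensity multipliers and emission-center shifts, so peak-table
expectations are known by construction.

What the synthetic data does *not* emulate: inner-filter attenuation,
Raman scatter bands, detector saturation, baseline drift and
wavelength-dependent instrument response. Passing the closed-loop
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to these instrument artifacts.

## Problem sizes and numerics

Test and script workloads are sized for interactive runs: 200–1000
titration replicates for recovery statistics, 0.5-nm resampling for J
with a 10⁻³-nm brute-force oracle (~1.5×10⁵ points) as the quadrature
cross-check, and 10-nm EEM grids matching typical 3D-scan instrument
steps. All randomness flows through explicit integer seeds; rerunning any
command or test with the same seed reproduces its numbers exactly.

## Known limitations

* Single-temperature thermodynamics only: ΔG from K_b, no van't Hoff
  ΔH/ΔS decomposition and no multi-site global fitting.
* The double-log K_b is ill-conditioned under intensity noise (see
  above); reported standard errors are per-fit OLS errors in log10 space
  and do not capture between-replicate scatter.
* Mechanism classification is evidence-combining, not model selection; it
  will return `ambiguous` on data a practitioner might still interpret,
  by design.
* No inner-filter correction is applied to titration intensities; inputs
  are assumed to be already corrected or measured in its absence.
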