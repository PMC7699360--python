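# fluorbind

Quantitative analysis of steady-state fluorescence titrations of a
fluorescent protein (typically human serum albumin, whose Trp-214 residue
dominates the intrinsic emission) with a small-molecule ligand. Starting
from plain-CSV spectra and titration tables, the package covers the full
chain of analyses used to characterize ligand–protein binding by
fluorescence quenching:

* **Stern–Volmer quenching** — ordinary least squares of
  `F0/F = 1 + K_SV [Q]`, the bimolecular rate constant `K_q = K_SV / τ0`,
  and static-vs-dynamic mechanism classification from the temperature
  trend of `K_SV` and the diffusion-limit test on `K_q`;
* **binding isotherm** — the double-logarithmic fit
  `log10((F0−F)/F) = log10(K_b) + n·log10([Q])` giving the association
  constant `K_b` and stoichiometry `n`, and the Gibbs energy
  `ΔG = −RT ln K_b`;
* **site-marker displacement** — apparent-`K_b` comparison against
  titrations run with site-specific competitors (e.g. warfarin / Sudlow
  site I, flufenamic acid / site II, digitoxin / site III);
* **conformational probes** — synchronous fluorescence at fixed offsets
  Δλ = 15 nm (tyrosine) and 60 nm (tryptophan), excitation–emission-matrix
  peak tables (Rayleigh line and intrinsic-fluorophore peak), and UV-Vis
  λmax blue/red shifts;
* **FRET distance** — molar absorptivity via Beer–Lambert, the overlap
  integral `J = Σ F(λ)ε(λ)λ⁴Δλ / Σ F(λ)Δλ`, the Förster radius
  `R0 = 0.211·(κ² n⁻⁴ Φ_D J)^{1/6}` (Å, reported in nm), the transfer
  efficiency `E = (F0−F)/F0` and the donor–acceptor distance
  `r = R0·((1−E)/E)^{1/6}`.

A synthetic-data module generates titrations, Gaussian-band spectra and
EEMs from known ground truth, so every stage is testable without
instrument data.

## Worked example

Simulate a dataset and run the pipeline from the shell (the same steps are
available as library calls):

```sh
fluorbind simulate --out-dir demo --seed 7
fluorbind quench demo/titration_298K.csv demo/titration_310K.csv \
                 demo/titration_318K.csv --out-dir demo/out
fluorbind bind demo/titration_298K.csv --out-dir demo/out
fluorbind fret --donor demo/emission_donor.csv \
               --acceptor demo/absorbance_acceptor.csv \
               --f0 12000 --f 11280 --out-dir demo/out
```

which prints

```
T=298.0 K: K_SV=8115 L/mol, K_q=8.115e+11 /M/s, R^2=0.9943
T=310.0 K: K_SV=7554 L/mol, K_q=7.554e+11 /M/s, R^2=0.9949
T=318.0 K: K_SV=8213 L/mol, K_q=8.213e+11 /M/s, R^2=0.9826
mechanism: ambiguous (K_q above diffusion limit: True, K_SV trend: non-monotone)
T=298.0 K: K_b=4.208e+04 L/mol, n=1.169, dG=-26.38 kJ/mol
J=7.833e+12 M^-1 cm^-1 nm^4, R0=1.670 nm, E=0.0600, r=2.642 nm
```

Reading the output: every fitted `K_q` (~8×10¹¹ L mol⁻¹ s⁻¹) is two
orders of magnitude above the diffusion-controlled ceiling of
7.4×10⁹ L mol⁻¹ s⁻¹, which rules out purely collisional quenching; the
classifier still reports `ambiguous` because the 1%-noise simulation makes
the fitted `K_SV` sequence non-monotone in temperature, and the verdict
reports the trend it computes, not the one it expects. The 298 K binding
fit recovers the simulated ground truth (`K_b` = 3.83×10⁴ L/mol,
`n` = 1.161) within the noise, and the negative ΔG marks association as
spontaneous. The FRET block places the ligand ~2.6 nm from the donor
fluorophore, inside the 1–10 nm range where energy transfer is efficient.

Equivalent library calls:

```python
from fluorbind import GroundTruth, double_log_fit, generate_titration

fit = double_log_fit(generate_titration(GroundTruth()))  # noiseless
print(f"K_b={fit.K_b:.0f} L/mol, n={fit.n_sites:.3f}, dG={fit.delta_G:.2f} kJ/mol")
# K_b=38301 L/mol, n=1.161, dG=-26.15 kJ/mol
```

## File format

All I/O is plain CSV with `#`-prefixed `key=value` metadata lines and one
header row; see `fluorbind.spectra` for the exact dialect of each kind
(emission, absorbance, titration, EEM). `write_spectrum`/`read_spectrum`
round-trip every object at full floating-point precision.

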