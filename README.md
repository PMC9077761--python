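# specbind

Spectroscopic analysis of small-molecule binding to serum albumin (and
similar fluorescent proteins): from raw titration, time-resolved decay,
circular dichroism and site-marker displacement tables to the quenching
mechanism, binding constants, thermodynamic force typing, secondary-structure
content and Sudlow-site assignment. A synthetic-data generator with known
ground truth stands in for the instruments, so every estimator in the
pipeline can be validated end to end without lab data.

The package is aimed at people doing drug–protein interaction studies by
steady-state/time-resolved fluorescence and CD — the standard workup for a
new drug's plasma-protein binding — who want the arithmetic behind the
tables in such studies to be reproducible and testable.

## What it computes

**Quenching mechanism.** Observed intensities are inner-filter corrected,
F_corr = F_obs·10^((A_ex+A_em)/2), then fitted by the Stern–Volmer relation

    F0/F = 1 + K_SV[Q]

per temperature. The bimolecular constant K_q = K_SV/τ0 (τ0 the unliganded
lifetime) is compared against the diffusion limit 2×10¹⁰ M⁻¹s⁻¹; that
criterion plus the temperature trend of K_SV and the concentration
invariance of the average lifetime classify quenching as static (ground-state
complex) or dynamic (collisional).

**Binding constant and thermodynamics.** The double-logarithm ("modified
Stern–Volmer") plot log((F0−F)/F) = log K + n·log[Q] yields the binding
constant K and site number n at each temperature; the van't Hoff regression
ln K = −ΔH/(RT) + ΔS/R gives the enthalpy and entropy of binding, ΔG follows
by ΔH − TΔS (and, as a cross-check, −RT·ln K), and the signs of ΔH and ΔS
type the dominant forces (Ross–Subramanian rules: both negative → hydrogen
bonds/van der Waals).

**Lifetimes.** TCSPC histograms are tail-fitted with 1–3 exponentials by
Poisson-weighted least squares (variable projection over log-lifetimes,
amplitudes by non-negative least squares) and summarized by the
amplitude-weighted average lifetime ⟨τ⟩ = Σαᵢτᵢ.

**Conformation.** CD ellipticity at 208 nm → mean residue ellipticity
MRE = θ/(10·C_p·n·l) → α-helix % = ((−MRE₂₀₈ − 4000)/29000)·100; peak
finding with Rayleigh-scatter masking for synchronous and 3-D fluorescence;
competitive site-marker displacement (warfarin = site I probe,
dansylsarcosine = site II) with automatic site assignment.

## Worked example

Generate a noise-free synthetic study at the default ground truth, then run
the binding/thermodynamics pipeline on the generated files:

```
$ specbind simulate --noise 0 --outdir demo
$ specbind quench demo/titration_sv_*.csv
...
mechanism verdict: static
  kq_exceeds_diffusion_limit: static
  ksv_decreases_with_T: static
  lifetime_invariant: inconclusive

$ specbind thermo demo/titration_bind_*.csv
...
dH   -68.93 +/- 0.00 kJ/mol
dS   -138.95 +/- 0.00 J/mol/K
r    1.0000
dominant forces: hbond_vdw
dG(298 K)  -27.52 kJ/mol (dH - T dS); -27.52 kJ/mol (-RT ln K)
dG(304 K)  -26.69 kJ/mol (dH - T dS); -26.69 kJ/mol (-RT ln K)
dG(310 K)  -25.86 kJ/mol (dH - T dS); -25.86 kJ/mol (-RT ln K)
```

The quench verdict is static because every K_q (≈1.3×10¹³ M⁻¹s⁻¹) exceeds
the diffusion limit and K_SV falls with temperature; the thermo fit recovers
the generating ΔH = −68.93 kJ/mol and ΔS = −138.95 J/mol/K exactly (no
noise), and both ΔG routes agree because the generated K(T) lies exactly on
the van't Hoff line. Negative ΔH and ΔS classify the binding as hydrogen
bonding / van der Waals driven.

The same analyses are available as a library:

```python
from specbind import GroundTruth, make_titration, fit_stern_volmer

series = fit_stern_volmer(make_titration(GroundTruth(noise_sigma=0, seed=1), 298.0))
print(series.summary())   # K_SV = 6.702e+04 M^-1, K_q = 1.321e+13 M^-1 s^-1
```

`specbind reproduce` re-derives every published derived quantity that is
arithmetic on the study's tables (K_q values, average lifetimes, ΔH/ΔS/ΔG)
from the packaged fixture and reports pass/fail at print precision.

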