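# Methods

This note records the models specbind implements, the assumptions behind
them, the defaults and why they were chosen, and what the synthetic-data
round trips do and do not establish.

## Quenching analysis

The Stern–Volmer relation F0/F = 1 + K_SV[Q] is fitted by ordinary least
squares of F0/F on total added quencher concentration, with a **free
intercept**. Fixing the intercept at its theoretical value of 1 would hide
uncorrected inner-filter or dilution artifacts; instead the fit warns when
the intercept sits more than three standard errors from 1. F0 is the
measured intensity of the zero-concentration row, not an extrapolation —
the titration design includes a true blank. The reported correlation
coefficient is the Pearson r of the linearized variables.

Inner-filter correction multiplies each observed intensity by
10^((A_ex+A_em)/2); it is exact for a centered 1 cm-geometry cuvette
approximation and is the identity only at zero absorbance. Points where F
rises above F0 at nonzero [Q] (fluorescence enhancement) are kept in the
Stern–Volmer fit but flagged, since they carry diagnostic information;
the double-logarithm binding fit must exclude them (log of a negative
number) and does so with a warning.

Mechanism classification evaluates three criteria, each scored
static/dynamic/inconclusive:

1. K_q = K_SV/τ0 above the diffusion-controlled limit (2.0×10¹⁰ M⁻¹s⁻¹,
   configurable) at every temperature → static; below it everywhere →
   dynamic.
2. K_SV strictly decreasing over temperature → static; strictly increasing
   → dynamic. This is a trend test on point estimates, not a significance
   test — the underlying argument in this literature is made from the trend
   of a few values.
3. Maximum relative change of ⟨τ⟩ across quencher concentrations below 10%
   (configurable) → static; above → dynamic. The 10% default deliberately
   accepts the ~7% drift seen in real data of this kind, which is within
   instrument reproducibility for tail fits.

The verdict is static only if at least two criteria score static and none
scores dynamic (symmetrically for dynamic); everything else is ambiguous.
One τ0 (the 298 K value, default 5.073 ns) is applied at all temperatures
when computing K_q, mirroring common practice; per-temperature τ0 can be
passed instead.

## Binding constant and thermodynamics

The double-logarithm linearization log10((F0−F)/F) = log10 K + n·log10[Q]
is the form of the "modified Stern–Volmer" treatment that yields both the
binding constant (intercept) and the site number (slope); it is the only
linear form consistent with n ≈ 1 outputs. Total added ligand is used for
[Q] with no free-ligand depletion correction — the standard practice for
this method. The synthetic round trips quantify the consequence: the
noiseless forward model is recovered exactly, while at 1% multiplicative
intensity noise the log-intercept extrapolates over ~5 decades of
concentration and K scatters by severalfold between replicate titrations
(log10 K remains unbiased within Monte-Carlo error; see the acceptance
suite). Published K uncertainties in this field are regression standard
errors conditional on one titration and should be read accordingly.

van't Hoff: OLS of ln K on 1/T; ΔH = −R·slope, ΔS = R·intercept,
R = 8.314 J mol⁻¹ K⁻¹ exactly. ΔH is assumed temperature-independent over
the narrow (~12 K) span fitted; no heat-capacity term. Units are enforced
as kJ/mol for ΔH and ΔG and J/(mol·K) for ΔS to avoid silent kJ/J
mix-ups. Duplicate temperatures collapse to the geometric mean of K with a
warning. ΔG is reported by both routes — ΔH − TΔS (primary) and −RT·ln K —
together with their difference; the two agree to numerical precision
exactly when the K values lie on the fitted van't Hoff line, so the
difference is a lack-of-fit diagnostic.

Force typing uses the sign rules on (ΔH, ΔS): both negative → hydrogen
bonds/van der Waals; both positive → hydrophobic; ΔS positive with ΔH at
most mildly positive → electrostatic. The underlying rules are sign rules
only; the tolerance bands (4 kJ/mol, 10 J/(mol·K), configurable) prevent
typing from estimates statistically indistinguishable from zero, which are
reported as indeterminate.

## Lifetime fitting

Tail fitting (no instrument-response deconvolution): bins from the tail
start onward are fitted with I(t) = b + Σ Aᵢ·exp(−t/τᵢ), 1–3 components,
by weighted least squares with Poisson weights 1/max(counts, 1) (the floor
avoids division by zero in empty bins). The default tail window starts at
the histogram's stated tail start; if that is unset and the peak is not in
the first bin, it starts at the peak bin plus a 0.5 ns guard standing in
for the instrument-response width. Amplitudes are referenced at t = 0 and
reported normalized to sum 1, the convention of decay-analysis software,
which also makes noiseless generator round trips exact.

Numerically the fit uses variable projection: the nonlinear search runs
over log-lifetimes only, and at each trial the baseline and amplitudes are
solved by weighted non-negative least squares. Direct simultaneous
optimization of all 2n+1 parameters proved fragile here — on some Poisson
realizations Levenberg–Marquardt stalls in nearly flat regions far from
the optimum — while the projected 3-parameter problem converges reliably.
Multi-start initialization (lifetimes log-spaced over the tail span, then
seeded log-normal jitter; 5 restarts, default seed 20180126) guards
against the multi-modality of multi-exponential fitting; a start is
accepted early when its reduced χ² drops below 1.05, otherwise the best of
all starts wins. Reduced χ² is Σw(obs−model)²/(N−p) with p = 2n+1 (the
profiled linear parameters are genuine parameters and count toward p).
Degenerate inputs: flat histograms (no resolvable decay) and fits driven
to the lifetime bound raise a fitting error carrying the best candidate.

The average lifetime is the **amplitude-weighted** mean ⟨τ⟩ = Σαᵢτᵢ/Σαᵢ.
This choice is pinned by the test suite: it reproduces all three published
⟨τ⟩ values from their printed components to within 0.005 ns, while the
intensity-weighted form Σαᵢτᵢ²/Σαᵢτᵢ gives ≈5.93 ns for the ligand-free
row. The intensity-weighted variant is available behind a flag for
comparison with other conventions.

## CD and conformation probes

Mean residue ellipticity: MRE(λ) = θ_mdeg(λ)/(10·C_p·n·l) with C_p in
mol/L, n residues (585 for HSA), l in cm (0.1 default); θ at the requested
wavelength is linearly interpolated between bracketing points. α-helix
content is the affine map ((−MRE₂₀₈ − 4000)/(33000 − 4000))·100, the
canonical single-wavelength estimate for predominantly helical proteins;
the anchors (4000 = coil, 33000 = full helix) are configurable because
alternative constant sets exist in the literature. The raw percentage is
reported alongside a [0, 100]-clipped value; values escaping the range
indicate concentration or pathlength errors rather than structure.
Full basis-set CD deconvolution (CONTIN/SELCON-style) is out of scope.

Peak finding refines the argmax by three-point parabolic interpolation;
plateaus and edge maxima return the first grid position with a tie flag.
For excitation–emission matrices the Rayleigh ridge (|λ_em − λ_ex| < 20 nm)
and its second harmonic (|λ_em − 2λ_ex| < 20 nm) are masked before the
search, since the scatter ridge is brighter than either aromatic peak.
Peak shifts are signed (sample − reference) per axis; the no-shift verdict
uses a 2 nm default tolerance, bounded below by the instrument step sizes
(5 nm excitation increments, 1 nm emission sampling).

Site-marker displacement: I = 100·F2/F1 with F1 the zero-competitor
reading. A probe is counted as displaced when its percentage drops by at
least 20% (configurable) at the highest competitor concentration; warfarin
displaced alone assigns Sudlow site I, dansylsarcosine alone site II. The
threshold is an artifact default — the qualitative contrast it encodes is
"distinct decline" versus "minimally affected".

## Synthetic data

The generator's default ground truth is the study condition set: the
K_SV trio at 298/304/310 K, K = 6.826×10⁴ M⁻¹ with n = 1.049,
ΔH = −68.93 kJ/mol, ΔS = −138.95 J/(mol·K), the three-component
ligand-free decay, 53% helix, 0–9 μM titrations on 2 μM protein, 0–20 μM
displacement series on 4 μM protein/probe, TCSPC peak of 10⁴ counts over
512 × 0.1 ns bins. Intensity noise is multiplicative Gaussian (default
σ = 1%, F0 kept exact); counts are Poisson. Every output stream derives
its RNG from (seed, stream-id), so outputs are byte-reproducible and
mutually independent.

Forward models: Stern–Volmer titrations from F = F0/(1 + K_SV[Q]);
binding titrations from (F0−F)/F = K[Q]ⁿ, with K(T) placed exactly on the
van't Hoff line for multi-temperature sets; decays from the
scaled multi-exponential plus constant background; CD spectra as two
negative Gaussian lobes (208/222 nm) scaled so the 208 nm MRE inverts to
the target helix fraction; displacement series from the two-ligand
one-site competitive equilibrium, solved by bisection on free protein
(the mass-balance excess is strictly increasing in free protein, so
bisection on [0, P_tot] is unconditional); emission bands as a single
Gaussian (337 nm center, 60 nm FWHM); excitation–emission matrices as two
Gaussian peaks plus explicit Rayleigh ridges.

What the generator does **not** emulate — and what passing round trips
therefore do not establish about real data: instrument response
convolution and detector afterpulsing in decays; Raman bands and baseline
drift in spectra; ligand depletion and higher-order binding
stoichiometries; temperature dependence of τ0 and of ΔH; correlated
(non-white) intensity noise. Round-trip closure shows the estimators
invert their own forward models; the published-table checks show the
arithmetic matches the study; neither validates the forward models against
an instrument.

## Problem sizes

The test suite's Monte-Carlo ensembles use 100 seeded decays (peak 10⁴
counts) for the lifetime-recovery check and 200 seeded titrations at 1%
noise for the binding-bias check; these sizes give standard errors well
below the tolerances being asserted while keeping the default `pytest` run
in the seconds-to-minutes range on one CPU.

## Known limitations

- Sphere-of-action (combined static+dynamic) quenching models are not
  implemented; strongly curved Stern–Volmer plots will fit poorly and the
  free intercept warning is the only signal.
- The double-log binding fit inherits the method's extrapolation
  sensitivity; K from a single noisy titration is order-of-magnitude
  information unless the titration spans enough quenching.
- Tail fitting cannot resolve components much shorter than the tail start;
  the 0.5 ns guard trades IRF contamination against short-lifetime
  sensitivity.
- The JSON report schema validator implements the small subset of JSON
  Schema the shipped schema uses (types, required keys, item schemas), not
  the full standard.
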