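"""Synthetic instrument: generates every input the pipeline consumes with
known ground truth and controllable noise.

The default :class:`GroundTruth` mirrors the trametinib-HSA study
conditions: Stern-Volmer constants of 6.702/5.981/5.664e4 M^-1 at
298/304/310 K, binding constant 6.826e4 M^-1 with n = 1.049 at 298 K,
dH = -68.93 kJ/mol and dS = -138.95 J/mol/K, the three-component
free-protein decay (alpha = 0.362/0.062/0.576, tau = 3.102/0.604/6.796 ns),
about 53% alpha-helix, and 0-9 uM titration grids on a 2 uM protein.

Intensity noise is multiplicative Gaussian; photon counts are Poisson.
All stochastic output is driven by the mandatory seed, so identical truth
gives identical data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .conformation import MRE_COIL, MRE_HELIX
from .datatypes import CDSpectrum, DecayCurve, DisplacementSeries, TitrationSeries
from .exceptions import ValidationError

#: default 0-9 uM titration grid (mol/L), 1 uM steps
DEFAULT_CONC_GRID = tuple(np.arange(10) * 1e-6)

#: default 0-20 uM competitor grid (mol/L), 4 uM steps
DEFAULT_DISPLACEMENT_GRID = tuple(np.arange(6) * 4e-6)


@dataclass(eq=False)
class GroundTruth:
    """Known parameters behind every synthetic dataset.

    ``noise_sigma`` is the relative standard deviation of multiplicative
    Gaussian intensity noise; counts are always Poisson. The seed is
    mandatory for any stochastic output.
    """

    k_binding: float = 6.826e4
    n_sites: float = 1.049
    k_sv_by_T: dict = field(default_factory=lambda: {
        298.0: 6.702e4, 304.0: 5.981e4, 310.0: 5.664e4,
    })
    delta_h_kj: float = -68.93
    delta_s_j: float = -138.95
    lifetime_components: Tuple[Tuple[float, float], ...] = (
        (0.362, 3.102), (0.062, 0.604), (0.576, 6.796),
    )
    alpha_helix_pct: float = 53.0
    quench_mode: str = "static"
    f0: float = 1000.0
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_binding <= 0 or self.n_sites <= 0:
            raise ValidationError("k_binding and n_sites must be positive")
        if self.quench_mode not in ("static", "dynamic"):
            raise ValidationError(
                f"unknown quench_mode {self.quench_mode!r}: "
                "expected 'static' or 'dynamic'"
            )
        if any(a < 0 or t <= 0 for a, t in self.lifetime_components):
            raise ValidationError("lifetime components must be non-negative "
                                  "amplitudes with positive lifetimes")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent generator for one output stream of this truth."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def make_titration(
    truth: GroundTruth,
    temperature_K: float = 298.0,
    conc_grid: Sequence[float] = DEFAULT_CONC_GRID,
    model: str = "stern_volmer",
    with_absorbance: bool = False,
    absorbance_slope_per_M: float = 2.0e4,
) -> TitrationSeries:
    """Simulate a fluorescence titration at one temperature.

    ``model="stern_volmer"`` generates F = F0 / (1 + K_SV [Q]) with the
    truth's K_SV at this temperature; ``model="binding"`` generates from the
    double-log forward model (F0 - F)/F = K [Q]^n, so a power-law fit
    recovers the truth's K and n. Multiplicative Gaussian noise at
    ``truth.noise_sigma`` is applied to nonzero-concentration rows; with
    ``with_absorbance`` the returned intensities are attenuated by a linear
    inner-filter absorbance A = slope * [Q] at both wavelengths, so the
    correction step has real work to do.
    """
    q = np.asarray(conc_grid, dtype=float)
    if q[0] != 0:
        raise ValidationError("conc_grid must start at 0")
    if model == "stern_volmer":
        if temperature_K not in truth.k_sv_by_T:
            raise ValidationError(
                f"no K_SV stored for {temperature_K} K; "
                f"available: {sorted(truth.k_sv_by_T)}"
            )
        ksv = truth.k_sv_by_T[temperature_K]
        f = truth.f0 / (1.0 + ksv * q)
    elif model == "binding":
        with np.errstate(divide="ignore"):
            ratio = truth.k_binding * np.power(q, truth.n_sites)  # (F0-F)/F
        f = truth.f0 / (1.0 + ratio)
    else:
        raise ValidationError(f"unknown titration model {model!r}")

    if truth.noise_sigma > 0:
        stream = zlib.crc32(f"titration|{model}|{temperature_K:.6f}".encode())
        rng = truth.rng(stream=stream)
        factors = 1.0 + truth.noise_sigma * rng.standard_normal(q.size)
        factors[0] = 1.0  # keep F0 exact so the reference is well-defined
        f = f * np.clip(factors, 0.05, None)

    kwargs = {}
    if with_absorbance:
        a = absorbance_slope_per_M * q
        f = f * 10.0 ** (-(a + a) / 2.0)
        kwargs = {"absorbance_ex": a, "absorbance_em": a.copy()}

    return TitrationSeries(
        temperature_K=temperature_K,
        quencher_conc=q,
        intensity=f,
        corrected=not with_absorbance,
        label=f"synthetic {model} titration",
        **kwargs,
    )


def make_titrations_by_temperature(
    truth: GroundTruth,
    temperatures_K: Sequence[float] = (298.0, 304.0, 310.0),
    conc_grid: Sequence[float] = DEFAULT_CONC_GRID,
) -> list[TitrationSeries]:
    """One binding-model titration per temperature, with K(T) on the truth's
    van't Hoff line: ln K(T) = -dH/(R T) + dS/R (R = 8.314 J/mol/K).

    The site number is held at the truth's value across temperatures.
    """
    out = []
    for t in temperatures_K:
        k_t = float(np.exp(-truth.delta_h_kj * 1000.0 / (8.314 * t)
                           + truth.delta_s_j / 8.314))
        truth_t = replace(truth, k_binding=k_t)
        out.append(make_titration(truth_t, temperature_K=t,
                                  conc_grid=conc_grid, model="binding"))
    return out


def make_decay(
    truth: GroundTruth,
    peak_counts: int = 10_000,
    bin_width_ns: float = 0.1,
    n_bins: int = 512,
    baseline_counts: float = 2.0,
    noiseless: bool = False,
    stream: int = 1,
) -> DecayCurve:
    """Simulate a TCSPC histogram from the truth's decay components.

    Expected counts b + A * sum(alpha_i exp(-t/tau_i)) are scaled so the
    first bin's expectation equals ``peak_counts``, then Poisson-sampled
    (or returned exactly with ``noiseless=True``).
    """
    if peak_counts < 100:
        raise ValidationError("peak_counts must be >= 100")
    t = (np.arange(n_bins) + 0.5) * bin_width_ns
    alpha = np.array([a for a, _ in truth.lifetime_components])
    tau = np.array([x for _, x in truth.lifetime_components])
    alpha = alpha / alpha.sum()
    shape = np.sum(alpha[:, None] * np.exp(-t[None, :] / tau[:, None]), axis=0)
    amplitude = (peak_counts - baseline_counts) / shape[0]
    expected = baseline_counts + amplitude * shape
    if noiseless:
        counts = expected
    else:
        counts = truth.rng(stream=stream).poisson(expected).astype(float)
    return DecayCurve(time_ns=t, counts=counts, tail_start_ns=float(t[0]))


def make_cd(
    truth: GroundTruth,
    wavelengths_nm: Optional[Sequence[float]] = None,
    protein_conc_M: float = 2.0e-6,
    n_residues: int = 585,
    pathlength_cm: float = 0.1,
    noise_mdeg: float = 0.0,
    stream: int = 2,
) -> CDSpectrum:
    """Simulate a far-UV CD spectrum of a helical protein.

    Two negative Gaussian lobes at 208 and 222 nm sit on a small coil
    baseline; the whole curve is scaled so that the MRE at 208 nm maps back
    to ``truth.alpha_helix_pct`` through the standard affine formula.
    """
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(200.0, 250.5, 0.5)
    wl = np.asarray(wavelengths_nm, dtype=float)
    if not (wl.min() <= 208.0 <= wl.max()):
        raise ValidationError("wavelength grid must cover 208 nm")

    lobes = (np.exp(-((wl - 208.0) ** 2) / (2 * 6.0**2))
             + 0.95 * np.exp(-((wl - 222.0) ** 2) / (2 * 7.0**2)))
    lobe_208 = (np.exp(-0.0) + 0.95 * np.exp(-((208.0 - 222.0) ** 2)
                                             / (2 * 7.0**2)))
    target_mre_208 = -(MRE_COIL
                       + truth.alpha_helix_pct / 100.0 * (MRE_HELIX - MRE_COIL))
    mre = target_mre_208 * lobes / lobe_208
    theta = mre * 10.0 * protein_conc_M * n_residues * pathlength_cm
    if noise_mdeg > 0:
        theta = theta + truth.rng(stream=stream).normal(0.0, noise_mdeg, wl.size)
    return CDSpectrum(
        wavelength_nm=wl,
        ellipticity_mdeg=theta,
        protein_conc_M=protein_conc_M,
        n_residues=n_residues,
        pathlength_cm=pathlength_cm,
    )


def _competitive_bound_probe(
    protein_tot: float, probe_tot: float, comp_tot: float,
    k_probe: float, k_comp: float,
) -> float:
    """Probe-protein complex concentration for two ligands competing for one
    site, from the coupled mass balances solved by bisection on free protein.

    With free protein P, each ligand's free concentration is
    L = L_tot / (1 + K P), and P must satisfy
    P (1 + K_p L_p + K_c L_c) = P_tot; the left side is strictly increasing
    in P, so bisection on [0, P_tot] converges unconditionally.
    """

    def excess(p_free: float) -> float:
        probe_free = probe_tot / (1.0 + k_probe * p_free)
        comp_free = comp_tot / (1.0 + k_comp * p_free)
        return (p_free * (1.0 + k_probe * probe_free + k_comp * comp_free)
                - protein_tot)

    lo, hi = 0.0, protein_tot
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            hi = mid
        else:
            lo = mid
    p_free = 0.5 * (lo + hi)
    probe_free = probe_tot / (1.0 + k_probe * p_free)
    return k_probe * p_free * probe_free


def make_displacement(
    truth: GroundTruth,
    shared_site: bool = True,
    conc_grid: Sequence[float] = DEFAULT_DISPLACEMENT_GRID,
    protein_tot_M: float = 4.0e-6,
    probe_tot_M: float = 4.0e-6,
    k_probe: float = 3.0e5,
    f1: float = 500.0,
    probe_name: str = "warfarin",
    competitor_name: str = "ligand",
    stream: int = 3,
) -> DisplacementSeries:
    """Simulate a site-marker displacement series.

    With ``shared_site=True`` the competitor (binding constant
    ``truth.k_binding``) displaces the probe from their common site via the
    two-ligand competitive equilibrium; otherwise the probe signal stays
    constant apart from noise. Intensity is proportional to the bound-probe
    concentration, normalized so the zero-competitor reading equals ``f1``.
    """
    c = np.asarray(conc_grid, dtype=float)
    if c[0] != 0:
        raise ValidationError("conc_grid must start at 0")
    if shared_site:
        bound = np.array([
            _competitive_bound_probe(protein_tot_M, probe_tot_M, ct,
                                     k_probe, truth.k_binding)
            for ct in c
        ])
        intensity = f1 * bound / bound[0]
    else:
        intensity = np.full(c.size, f1)
    if truth.noise_sigma > 0:
        rng = truth.rng(stream=stream)
        factors = 1.0 + truth.noise_sigma * rng.standard_normal(c.size)
        factors[0] = 1.0
        intensity = intensity * np.clip(factors, 0.05, None)
    return DisplacementSeries(
        competitor_conc=c,
        intensity=intensity,
        probe_name=probe_name,
        competitor_name=competitor_name,
    )


def make_emission_spectrum(
    center_nm: float = 337.0,
    peak_intensity: float = 600.0,
    fwhm_nm: float = 60.0,
    wavelengths_nm: Optional[Sequence[float]] = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """A single Gaussian emission band sampled on a 1 nm grid (default
    290-450 nm); the building block for synchronous-scan fixtures."""
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(290.0, 450.5, 1.0)
    wl = np.asarray(wavelengths_nm, dtype=float)
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    y = peak_intensity * np.exp(-((wl - center_nm) ** 2) / (2 * sigma**2))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma * peak_intensity, wl.size)
    return wl, np.clip(y, 1e-9, None)


def make_eem(
    peaks: Sequence[Tuple[float, float, float]] = (
        (280.0, 338.0, 587.254), (225.0, 340.0, 728.174),
    ),
    ex_grid_nm: Optional[Sequence[float]] = None,
    em_grid_nm: Optional[Sequence[float]] = None,
    ex_width_nm: float = 12.0,
    em_width_nm: float = 25.0,
    scatter_intensity: float = 900.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate a 3-D (excitation-emission) fluorescence matrix.

    Each entry of ``peaks`` is (ex_center, em_center, intensity), by default
    the two aromatic-residue peaks of the free protein; a Rayleigh-scatter
    ridge along em = ex (and its second harmonic) is added so downstream
    masking is exercised. Excitation steps 5 nm, emission 1 nm, matching
    typical scan settings.
    """
    ex = (np.arange(200.0, 351.0, 5.0) if ex_grid_nm is None
          else np.asarray(ex_grid_nm, dtype=float))
    em = (np.arange(200.0, 500.5, 1.0) if em_grid_nm is None
          else np.asarray(em_grid_nm, dtype=float))
    exg, emg = np.meshgrid(ex, em, indexing="ij")
    z = np.zeros_like(exg)
    for ex_c, em_c, height in peaks:
        z += height * np.exp(-((exg - ex_c) ** 2) / (2 * ex_width_nm**2)
                             - ((emg - em_c) ** 2) / (2 * em_width_nm**2))
    z += scatter_intensity * np.exp(-((emg - exg) ** 2) / (2 * 5.0**2))
    z += 0.3 * scatter_intensity * np.exp(-((emg - 2 * exg) ** 2) / (2 * 8.0**2))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        z = z + rng.normal(0.0, noise_sigma * max(h for *_, h in peaks),
                           z.shape)
    return ex, em, z
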