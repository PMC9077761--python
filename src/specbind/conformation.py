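"""Protein conformation probes: CD secondary structure, fluorescence peak
shifts, and competitive site-marker displacement.

CD ellipticity at 208 nm is converted to mean residue ellipticity,

    MRE(lambda) = theta_mdeg(lambda) / (10 * C_p * n * l),

with protein concentration C_p (mol/L), residue count n and pathlength l
(cm), and mapped affinely to an alpha-helix percentage,

    helix% = ((-MRE_208 - 4000) / (33000 - 4000)) * 100.

Peak finding serves both synchronous scans (1-D) and excitation-emission
matrices (2-D, with Rayleigh-scatter ridges masked); peak shifts between a
reference and a sample spectrum report microenvironment changes of the
aromatic residues.

Site-marker displacement expresses probe-protein fluorescence as a
percentage of its zero-competitor value; a marked drop for the warfarin
probe but not the dansylsarcosine probe assigns the ligand to Sudlow
site I, and symmetrically for site II.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .datatypes import CDSpectrum, DisplacementSeries
from .exceptions import ValidationError

#: affine anchors mapping -MRE_208 to helix fraction: 0% and 100% intercepts
MRE_COIL = 4000.0
MRE_HELIX = 33000.0

#: half-width (nm) of the Rayleigh-scatter exclusion bands in EEM matrices
SCATTER_HALFWIDTH_NM = 20.0


def mean_residue_ellipticity(spectrum: CDSpectrum, wavelength_nm: float) -> float:
    """MRE at one wavelength, in deg cm^2 dmol^-1, by linear interpolation
    between the bracketing measured points."""
    wl = spectrum.wavelength_nm
    lo, hi = min(wl[0], wl[-1]), max(wl[0], wl[-1])
    if not lo <= wavelength_nm <= hi:
        raise ValidationError(
            f"wavelength {wavelength_nm} nm outside the measured range "
            f"[{lo}, {hi}] nm"
        )
    order = np.argsort(wl)
    theta = float(np.interp(wavelength_nm, wl[order],
                            spectrum.ellipticity_mdeg[order]))
    return theta / (10.0 * spectrum.protein_conc_M * spectrum.n_residues
                    * spectrum.pathlength_cm)


def alpha_helix_content(mre_208: float, mre_coil: float = MRE_COIL,
                        mre_helix: float = MRE_HELIX) -> float:
    """Alpha-helix percentage from MRE at 208 nm (raw, not clipped).

    Affine in MRE_208 with anchors MRE_208 = -mre_coil -> 0% and
    -mre_helix -> 100%. Values outside [0, 100] indicate data or
    normalization problems and are reported as-is; see
    :class:`MREResult` for the clipped companion.
    """
    if not np.isfinite(mre_208):
        raise ValidationError("mre_208 must be finite")
    return (-mre_208 - mre_coil) / (mre_helix - mre_coil) * 100.0


@dataclass(eq=False)
class MREResult:
    """MRE at 208 nm and the derived alpha-helix content (raw and clipped)."""

    mre_208: float
    alpha_helix_pct: float

    @property
    def alpha_helix_pct_clipped(self) -> float:
        return float(np.clip(self.alpha_helix_pct, 0.0, 100.0))

    def to_dict(self) -> dict:
        return {
            "mre_208_deg_cm2_dmol": self.mre_208,
            "alpha_helix_pct": self.alpha_helix_pct,
            "alpha_helix_pct_clipped": self.alpha_helix_pct_clipped,
        }

    def summary(self) -> str:
        return "\n".join([
            "CD secondary structure",
            "======================",
            f"MRE(208 nm)    {self.mre_208:.0f} deg cm^2 dmol^-1",
            f"alpha-helix    {self.alpha_helix_pct:.1f}% "
            f"(clipped: {self.alpha_helix_pct_clipped:.1f}%)",
        ])


def helix_from_spectrum(spectrum: CDSpectrum) -> MREResult:
    """Full CD route: MRE at 208 nm then the helix percentage."""
    mre = mean_residue_ellipticity(spectrum, 208.0)
    return MREResult(mre_208=mre, alpha_helix_pct=alpha_helix_content(mre))


# ---------------------------------------------------------------------------
# peak finding


@dataclass(eq=False)
class Peak:
    """A located spectral maximum: position (nm, or (ex, em) nm pair for
    matrices), its intensity, and whether the maximum was tied/at an edge."""

    position_nm: Union[float, Tuple[float, float]]
    intensity: float
    tie_flag: bool = False

    def to_dict(self) -> dict:
        pos = self.position_nm
        return {
            "position_nm": list(pos) if isinstance(pos, tuple) else pos,
            "intensity": self.intensity,
            "tie_flag": self.tie_flag,
        }


def _parabolic_refine(x: np.ndarray, y: np.ndarray, idx: int) -> Tuple[float, float]:
    """Refine an interior argmax by fitting a parabola to the three points
    around it; returns (position, height). Falls back to the grid point at
    edges or degenerate curvature."""
    if idx == 0 or idx == len(x) - 1:
        return float(x[idx]), float(y[idx])
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not concave at the maximum
        return float(x[idx]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    step = 0.5 * (x[idx + 1] - x[idx - 1])
    height = y1 - 0.25 * (y0 - y2) * delta
    return float(x[idx] + delta * step), float(height)


def find_peak(
    wavelength_nm: Sequence[float], intensity: Sequence[float]
) -> Peak:
    """Locate the dominant maximum of a 1-D spectrum.

    The argmax is refined by three-point parabolic interpolation. A plateau
    of equal maxima or a maximum on the scan edge is returned at its first
    grid position with ``tie_flag`` set.
    """
    x = np.asarray(wavelength_nm, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if x.size != y.size:
        raise ValidationError("wavelength and intensity lengths differ")
    if x.size < 5:
        raise ValidationError("need >= 5 points to locate a peak")
    idx = int(np.argmax(y))
    n_max = int(np.sum(y == y[idx]))
    tie = n_max > 1 or idx in (0, y.size - 1)
    pos, height = _parabolic_refine(x, y, idx)
    return Peak(position_nm=pos, intensity=height, tie_flag=tie)


def find_peak_eem(
    ex_nm: Sequence[float],
    em_nm: Sequence[float],
    intensity: np.ndarray,
    ex_window: Optional[Tuple[float, float]] = None,
    em_window: Optional[Tuple[float, float]] = None,
    mask_scatter: bool = True,
) -> Peak:
    """Locate the dominant peak of an excitation-emission matrix.

    ``intensity`` has shape (len(ex_nm), len(em_nm)). Rayleigh-scatter
    ridges (|em - ex| and |em - 2 ex| below 20 nm) are masked before the
    search; optional windows restrict the search to one spectral peak. The
    position is refined parabolically along both axes.
    """
    ex = np.asarray(ex_nm, dtype=float)
    em = np.asarray(em_nm, dtype=float)
    z = np.asarray(intensity, dtype=float)
    if z.shape != (ex.size, em.size):
        raise ValidationError("intensity shape must be (n_ex, n_em)")
    if ex.size < 5 or em.size < 5:
        raise ValidationError("need >= 5 points per axis")

    masked = z.copy()
    if mask_scatter:
        exg, emg = np.meshgrid(ex, em, indexing="ij")
        scatter = (np.abs(emg - exg) < SCATTER_HALFWIDTH_NM) | (
            np.abs(emg - 2 * exg) < SCATTER_HALFWIDTH_NM
        )
        masked[scatter] = -np.inf
    if ex_window is not None:
        masked[(ex < ex_window[0]) | (ex > ex_window[1]), :] = -np.inf
    if em_window is not None:
        masked[:, (em < em_window[0]) | (em > em_window[1])] = -np.inf
    if not np.any(np.isfinite(masked)):
        raise ValidationError("no unmasked points left to search")

    flat = int(np.argmax(masked))
    i, j = np.unravel_index(flat, masked.shape)
    peak_val = masked[i, j]
    tie = int(np.sum(masked == peak_val)) > 1

    # refine along each axis using the unmasked neighbours when finite
    def _axis_refine(x, profile, idx):
        ok = np.isfinite(profile)
        if idx == 0 or idx == x.size - 1 or not (ok[idx - 1] and ok[idx + 1]):
            return float(x[idx]), float(profile[idx]), True
        pos, height = _parabolic_refine(x, profile, idx)
        return pos, height, False

    ex_pos, _, ex_edge = _axis_refine(ex, masked[:, j], i)
    em_pos, em_height, em_edge = _axis_refine(em, masked[i, :], j)
    return Peak(
        position_nm=(ex_pos, em_pos),
        intensity=float(max(em_height, z[i, j])),
        tie_flag=tie or ex_edge or em_edge,
    )


@dataclass(eq=False)
class PeakShift:
    """Signed peak displacement between a reference and a sample spectrum.

    ``shift_nm`` is sample minus reference, per axis for matrix peaks. The
    verdict is "no_shift" when every component stays within the tolerance.
    """

    reference_peak_nm: Union[float, Tuple[float, float]]
    sample_peak_nm: Union[float, Tuple[float, float]]
    shift_nm: Union[float, Tuple[float, float]]
    intensity_ratio: float
    tolerance_nm: float = 2.0

    @property
    def no_shift(self) -> bool:
        shifts = self.shift_nm if isinstance(self.shift_nm, tuple) else (self.shift_nm,)
        return all(abs(s) <= self.tolerance_nm for s in shifts)

    @property
    def verdict(self) -> str:
        return "no_shift" if self.no_shift else "shifted"

    def to_dict(self) -> dict:
        def _aslist(v):
            return list(v) if isinstance(v, tuple) else v

        return {
            "reference_peak_nm": _aslist(self.reference_peak_nm),
            "sample_peak_nm": _aslist(self.sample_peak_nm),
            "shift_nm": _aslist(self.shift_nm),
            "intensity_ratio": self.intensity_ratio,
            "tolerance_nm": self.tolerance_nm,
            "verdict": self.verdict,
        }


def peak_shift(reference: Peak, sample: Peak,
               tolerance_nm: float = 2.0) -> PeakShift:
    """Shift and intensity ratio of a sample peak relative to a reference."""
    ref_pos, smp_pos = reference.position_nm, sample.position_nm
    if isinstance(ref_pos, tuple) != isinstance(smp_pos, tuple):
        raise ValidationError("reference and sample peaks have different shapes")
    if isinstance(ref_pos, tuple):
        shift: Union[float, Tuple[float, float]] = tuple(
            s - r for r, s in zip(ref_pos, smp_pos)
        )
    else:
        shift = smp_pos - ref_pos
    if reference.intensity == 0:
        raise ValidationError("reference peak intensity is zero")
    return PeakShift(
        reference_peak_nm=ref_pos,
        sample_peak_nm=smp_pos,
        shift_nm=shift,
        intensity_ratio=sample.intensity / reference.intensity,
        tolerance_nm=tolerance_nm,
    )


# ---------------------------------------------------------------------------
# site-marker displacement


@dataclass(eq=False)
class DisplacementResult:
    """Probe-protein fluorescence as a percentage of its baseline, aligned
    to the competitor concentrations; first entry is 100 by construction."""

    competitor_conc: np.ndarray
    percentages: np.ndarray
    probe_name: str = ""
    competitor_name: str = ""

    @property
    def final_drop_pct(self) -> float:
        """Drop from baseline at the highest competitor concentration."""
        return 100.0 - float(self.percentages[-1])

    def to_dict(self) -> dict:
        return {
            "competitor_conc_M": np.asarray(self.competitor_conc).tolist(),
            "percentages": np.asarray(self.percentages).tolist(),
            "probe_name": self.probe_name,
            "competitor_name": self.competitor_name,
            "final_drop_pct": self.final_drop_pct,
        }


def displacement_percentages(series: DisplacementSeries) -> DisplacementResult:
    """Express each intensity as a percentage of the zero-competitor reading:
    I_j = 100 * F2_j / F1."""
    f1 = series.f1
    if f1 <= 0:
        raise ValidationError("zero-competitor intensity must be positive")
    return DisplacementResult(
        competitor_conc=series.competitor_conc.copy(),
        percentages=100.0 * series.intensity / f1,
        probe_name=series.probe_name,
        competitor_name=series.competitor_name,
    )


def assign_site(
    warfarin_result: DisplacementResult,
    dansylsarcosine_result: DisplacementResult,
    drop_threshold_pct: float = 20.0,
) -> str:
    """Assign the competing ligand to a Sudlow site from the two probe series.

    A drop of at least ``drop_threshold_pct`` percent at the highest
    competitor concentration counts as displacement of that probe. Warfarin
    displaced alone -> "site_I"; dansylsarcosine alone -> "site_II"; both ->
    "both"; neither -> "neither".
    """
    war = warfarin_result.final_drop_pct >= drop_threshold_pct
    dan = dansylsarcosine_result.final_drop_pct >= drop_threshold_pct
    if war and not dan:
        return "site_I"
    if dan and not war:
        return "site_II"
    if war and dan:
        return "both"
    return "neither"
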