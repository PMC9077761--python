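"""Domain containers for the spectroscopic binding pipeline.

Each container validates its physical invariants on construction:
concentration grids start at zero and increase strictly, intensities are
positive, decay histograms have non-negative counts, CD metadata
(protein concentration, residue count, pathlength) is positive.
Internally everything is SI — concentrations in mol/L, lifetimes carried
in the units stated on the field name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import ValidationError


def _as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if arr.size == 0:
        raise ValidationError(f"{name} must not be empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def _check_conc_grid(conc: np.ndarray, name: str) -> None:
    if np.any(conc < 0):
        raise ValidationError(f"{name} must be non-negative")
    if np.any(np.diff(conc) <= 0):
        raise ValidationError(f"{name} must be strictly increasing")
    if conc[0] != 0.0:
        raise ValidationError(
            f"{name} must start at 0 (the zero row defines the reference intensity)"
        )


@dataclass(eq=False)
class AbsorbancePair:
    """Absorbance at the excitation and emission wavelengths (AU).

    Used for inner-filter correction: F_corr = F_obs * 10**((A_ex + A_em)/2).
    """

    a_ex: float
    a_em: float

    def __post_init__(self) -> None:
        if self.a_ex < 0 or self.a_em < 0:
            raise ValidationError("absorbances must be non-negative")


@dataclass(eq=False)
class TitrationSeries:
    """A fluorescence titration at one temperature.

    ``quencher_conc`` is in mol/L, starts at 0 (that row defines F0) and
    increases strictly; ``intensity`` holds positive fluorescence readings in
    arbitrary units. Optional per-row absorbances allow inner-filter
    correction of the whole series.
    """

    temperature_K: float
    quencher_conc: np.ndarray
    intensity: np.ndarray
    corrected: bool = False
    label: str = ""
    absorbance_ex: Optional[np.ndarray] = None
    absorbance_em: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValidationError("temperature_K must be positive")
        self.quencher_conc = _as_float_array(self.quencher_conc, "quencher_conc")
        self.intensity = _as_float_array(self.intensity, "intensity")
        if self.quencher_conc.size != self.intensity.size:
            raise ValidationError("quencher_conc and intensity lengths differ")
        _check_conc_grid(self.quencher_conc, "quencher_conc")
        if np.any(self.intensity <= 0):
            raise ValidationError("intensities must be strictly positive")
        for attr in ("absorbance_ex", "absorbance_em"):
            values = getattr(self, attr)
            if values is not None:
                arr = _as_float_array(values, attr)
                if arr.size != self.intensity.size:
                    raise ValidationError(f"{attr} length differs from intensity")
                if np.any(arr < 0):
                    raise ValidationError(f"{attr} must be non-negative")
                setattr(self, attr, arr)

    @property
    def f0(self) -> float:
        """Reference intensity: the reading at zero quencher."""
        return float(self.intensity[0])

    def __len__(self) -> int:
        return int(self.intensity.size)


@dataclass(eq=False)
class DecayCurve:
    """A TCSPC photon-arrival histogram.

    ``time_ns`` are bin centres, ``counts`` non-negative photon counts;
    ``tail_start_ns`` marks where the tail fit begins (past the instrument
    response, typically the peak bin plus a guard).
    """

    time_ns: np.ndarray
    counts: np.ndarray
    tail_start_ns: float = 0.0

    def __post_init__(self) -> None:
        self.time_ns = _as_float_array(self.time_ns, "time_ns")
        self.counts = _as_float_array(self.counts, "counts")
        if self.time_ns.size != self.counts.size:
            raise ValidationError("time_ns and counts lengths differ")
        if np.any(np.diff(self.time_ns) <= 0):
            raise ValidationError("time_ns must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if not (self.time_ns[0] <= self.tail_start_ns <= self.time_ns[-1]):
            raise ValidationError("tail_start_ns outside the time range")

    def tail(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (time, counts) restricted to t >= tail_start_ns."""
        mask = self.time_ns >= self.tail_start_ns
        return self.time_ns[mask], self.counts[mask]


@dataclass(eq=False)
class CDSpectrum:
    """A far-UV circular dichroism spectrum with the metadata needed for MRE.

    Ellipticity is in millidegrees; ``protein_conc_M`` (mol/L), ``n_residues``
    and ``pathlength_cm`` convert observed ellipticity to mean residue
    ellipticity (deg cm^2 dmol^-1).
    """

    wavelength_nm: np.ndarray
    ellipticity_mdeg: np.ndarray
    protein_conc_M: float
    n_residues: int
    pathlength_cm: float

    def __post_init__(self) -> None:
        self.wavelength_nm = _as_float_array(self.wavelength_nm, "wavelength_nm")
        self.ellipticity_mdeg = _as_float_array(
            self.ellipticity_mdeg, "ellipticity_mdeg"
        )
        if self.wavelength_nm.size != self.ellipticity_mdeg.size:
            raise ValidationError("wavelength and ellipticity lengths differ")
        diffs = np.diff(self.wavelength_nm)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValidationError("wavelength_nm must be strictly monotone")
        if self.protein_conc_M <= 0:
            raise ValidationError("protein_conc_M must be positive")
        if self.n_residues < 1:
            raise ValidationError("n_residues must be >= 1")
        if self.pathlength_cm <= 0:
            raise ValidationError("pathlength_cm must be positive")


@dataclass(eq=False)
class DisplacementSeries:
    """Probe-protein fluorescence versus competitor concentration.

    The zero-competitor row defines F1 (free probe-protein intensity);
    subsequent rows are F2 at each competitor concentration.
    """

    competitor_conc: np.ndarray
    intensity: np.ndarray
    probe_name: str = ""
    competitor_name: str = ""

    def __post_init__(self) -> None:
        self.competitor_conc = _as_float_array(
            self.competitor_conc, "competitor_conc"
        )
        self.intensity = _as_float_array(self.intensity, "intensity")
        if self.competitor_conc.size != self.intensity.size:
            raise ValidationError("competitor_conc and intensity lengths differ")
        _check_conc_grid(self.competitor_conc, "competitor_conc")
        if np.any(self.intensity <= 0):
            raise ValidationError("intensities must be strictly positive")

    @property
    def f1(self) -> float:
        return float(self.intensity[0])

    def __len__(self) -> int:
        return int(self.intensity.size)
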