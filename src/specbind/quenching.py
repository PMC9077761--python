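"""Fluorescence quenching analysis.

Covers inner-filter correction, the Stern-Volmer regression
F0/F = 1 + K_SV [Q], the bimolecular quenching constant K_q = K_SV / tau0,
and classification of the quenching mechanism as static or dynamic.

Static quenching (ground-state complex formation) is indicated by K_q above
the diffusion-controlled limit (~2e10 M^-1 s^-1), by K_SV decreasing as
temperature rises, and by a fluorescence lifetime that barely changes with
quencher concentration; dynamic (collisional) quenching shows the opposite
signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .datatypes import AbsorbancePair, TitrationSeries
from .exceptions import InsufficientDataError, ValidationError

#: diffusion-controlled limit for quenching of biopolymers, M^-1 s^-1
DIFFUSION_LIMIT = 2.0e10

#: lifetime of the ligand-free protein, s (measured at 298 K)
DEFAULT_TAU0_S = 5.073e-9


def correct_inner_filter(
    f_obs: Union[float, np.ndarray], absorbance: AbsorbancePair
) -> Union[float, np.ndarray]:
    """Correct an observed intensity for the inner filter effect.

    F_corr = F_obs * 10**((A_ex + A_em) / 2); the correction is the identity
    when both absorbances are zero and always increases the intensity
    otherwise.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    if np.any(f_obs <= 0):
        raise ValidationError("observed intensity must be positive")
    factor = 10.0 ** ((absorbance.a_ex + absorbance.a_em) / 2.0)
    out = f_obs * factor
    return float(out) if out.ndim == 0 else out


def correct_series(series: TitrationSeries) -> TitrationSeries:
    """Apply the inner-filter correction row-wise to a titration series.

    Requires per-row absorbances on the series; returns a new series with
    ``corrected=True``.
    """
    if series.absorbance_ex is None or series.absorbance_em is None:
        raise ValidationError("series carries no per-row absorbances")
    factor = 10.0 ** ((series.absorbance_ex + series.absorbance_em) / 2.0)
    return TitrationSeries(
        temperature_K=series.temperature_K,
        quencher_conc=series.quencher_conc.copy(),
        intensity=series.intensity * factor,
        corrected=True,
        label=series.label,
    )


@dataclass(eq=False)
class QuenchResult:
    """Stern-Volmer fit results at one temperature.

    ``k_sv`` is the slope of F0/F against [Q] (M^-1), ``k_q`` the derived
    bimolecular quenching constant K_SV / tau0 (M^-1 s^-1). ``r_corr`` is the
    Pearson correlation coefficient of the linearized variables.
    """

    temperature_K: float
    k_sv: float
    k_sv_se: float
    r_corr: float
    tau0_s: float
    intercept: float = 1.0
    intercept_se: float = 0.0
    n_obs: int = 0
    enhancement_flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tau0_s <= 0:
            raise ValidationError("tau0_s must be positive")
        if not np.isfinite(self.k_sv):
            raise ValidationError("k_sv must be finite")
        if abs(self.r_corr) > 1 + 1e-12:
            raise ValidationError("|r_corr| must be <= 1")

    @property
    def k_q(self) -> float:
        """Bimolecular quenching constant K_SV / tau0 (M^-1 s^-1)."""
        return self.k_sv / self.tau0_s

    @property
    def k_q_se(self) -> float:
        return self.k_sv_se / self.tau0_s

    def to_dict(self) -> dict:
        return {
            "temperature_K": self.temperature_K,
            "k_sv_per_M": self.k_sv,
            "k_sv_se_per_M": self.k_sv_se,
            "r_corr": self.r_corr,
            "k_q_per_M_s": self.k_q,
            "k_q_se_per_M_s": self.k_q_se,
            "tau0_s": self.tau0_s,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "n_obs": self.n_obs,
            "enhancement_flags": list(self.enhancement_flags),
        }

    def summary(self) -> str:
        lines = [
            "Stern-Volmer quenching fit",
            "==========================",
            f"temperature        {self.temperature_K:.1f} K",
            f"K_SV               {self.k_sv:.4g} +/- {self.k_sv_se:.2g} M^-1",
            f"intercept          {self.intercept:.4f} +/- {self.intercept_se:.2g}",
            f"Pearson r          {self.r_corr:.4f}",
            f"tau0               {self.tau0_s:.4g} s",
            f"K_q = K_SV/tau0    {self.k_q:.4g} M^-1 s^-1",
            f"n observations     {self.n_obs}",
        ]
        if self.enhancement_flags:
            lines.append(f"enhancement flags  {self.enhancement_flags}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic Stern-Volmer plot (F0/F vs [Q]) of the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        q = np.linspace(0, 1, 50)
        ax.plot(q, self.intercept + self.k_sv * q, "-", label="fit")
        ax.set_xlabel("[Q] (M)")
        ax.set_ylabel("F0/F")
        ax.legend()
        return ax


class SternVolmerModel:
    """OLS model of F0/F against quencher concentration.

    The intercept is left free; a fitted intercept further than three
    standard errors from 1 triggers a warning, since it usually signals
    uncorrected inner-filter or dilution artifacts.

    Parameters
    ----------
    series : TitrationSeries
        Titration including the zero-quencher row (defines F0).
    tau0_s : float
        Fluorophore lifetime without quencher, used for K_q.
    """

    def __init__(self, series: TitrationSeries, tau0_s: float = DEFAULT_TAU0_S):
        if tau0_s <= 0:
            raise ValidationError("tau0_s must be positive")
        if len(series) < 3:
            raise InsufficientDataError(
                f"Stern-Volmer fit needs >= 3 points, got {len(series)}"
            )
        self.series = series
        self.tau0_s = tau0_s

    def fit(self) -> QuenchResult:
        series = self.series
        q = series.quencher_conc
        ratio = series.f0 / series.intensity

        # fluorescence enhancement (F >= F0 at nonzero [Q]) is allowed but flagged
        flags = [
            f"intensity at [Q]={q[i]:.3g} M is >= F0 (enhancement, not quenching)"
            for i in range(1, len(series))
            if series.intensity[i] >= series.f0 * (1 + 1e-12)
        ]

        res = stats.linregress(q, ratio)
        if np.isfinite(res.intercept_stderr) and res.intercept_stderr > 0:
            if abs(res.intercept - 1.0) > 3 * res.intercept_stderr:
                warnings.warn(
                    f"Stern-Volmer intercept {res.intercept:.4f} deviates from 1 "
                    f"by more than 3 SE ({res.intercept_stderr:.2g}); check "
                    "inner-filter correction / dilution",
                    stacklevel=2,
                )
        return QuenchResult(
            temperature_K=series.temperature_K,
            k_sv=float(res.slope),
            k_sv_se=float(res.stderr),
            r_corr=float(res.rvalue),
            tau0_s=self.tau0_s,
            intercept=float(res.intercept),
            intercept_se=float(res.intercept_stderr),
            n_obs=len(series),
            enhancement_flags=flags,
        )


def fit_stern_volmer(series: TitrationSeries,
                     tau0_s: float = DEFAULT_TAU0_S) -> QuenchResult:
    """Fit the Stern-Volmer regression; convenience wrapper around
    :class:`SternVolmerModel`."""
    return SternVolmerModel(series, tau0_s=tau0_s).fit()


def compute_kq(k_sv: float, tau0_s: float) -> float:
    """Bimolecular quenching constant K_q = K_SV / tau0 (M^-1 s^-1)."""
    if tau0_s <= 0:
        raise ValidationError("tau0_s must be positive")
    if k_sv <= 0:
        raise ValidationError("k_sv must be positive")
    return k_sv / tau0_s


@dataclass(eq=False)
class MechanismVerdict:
    """Outcome of static-vs-dynamic classification with per-criterion evidence.

    ``evidence`` lists (criterion, outcome) pairs where outcome is "static",
    "dynamic" or "inconclusive". The verdict is static only when at least two
    criteria point static and none points dynamic (and symmetrically for
    dynamic); anything else is ambiguous.
    """

    verdict: str
    evidence: list

    def to_dict(self) -> dict:
        return {"verdict": self.verdict,
                "evidence": [list(pair) for pair in self.evidence]}


def classify_mechanism(
    results: Sequence[QuenchResult],
    lifetimes_ns: Optional[Sequence[float]] = None,
    diffusion_limit: float = DIFFUSION_LIMIT,
    lifetime_threshold: float = 0.10,
) -> MechanismVerdict:
    """Classify quenching as static, dynamic or ambiguous.

    Three criteria are evaluated:

    * ``kq_exceeds_diffusion_limit`` — static if K_q exceeds the diffusion
      limit at every temperature, dynamic if it stays below it everywhere;
    * ``ksv_decreases_with_T`` — static if K_SV strictly decreases with
      temperature (trend of point estimates), dynamic if it strictly
      increases; inconclusive for a single temperature or a mixed trend;
    * ``lifetime_invariant`` — static if the maximum relative change of the
      average lifetime across quencher concentrations stays below
      ``lifetime_threshold`` (default 10%), dynamic otherwise; inconclusive
      when no lifetimes are supplied.

    ``results`` must be sorted by temperature; the classifier sorts a copy
    itself, so input order never changes the verdict.
    """
    if not results:
        raise InsufficientDataError("no quenching results supplied")
    ordered = sorted(results, key=lambda r: r.temperature_K)

    evidence = []

    kq = np.array([r.k_q for r in ordered])
    if np.all(kq > diffusion_limit):
        evidence.append(("kq_exceeds_diffusion_limit", "static"))
    elif np.all(kq <= diffusion_limit):
        evidence.append(("kq_exceeds_diffusion_limit", "dynamic"))
    else:
        evidence.append(("kq_exceeds_diffusion_limit", "inconclusive"))

    ksv = np.array([r.k_sv for r in ordered])
    if len(ksv) < 2:
        evidence.append(("ksv_decreases_with_T", "inconclusive"))
    elif np.all(np.diff(ksv) < 0):
        evidence.append(("ksv_decreases_with_T", "static"))
    elif np.all(np.diff(ksv) > 0):
        evidence.append(("ksv_decreases_with_T", "dynamic"))
    else:
        evidence.append(("ksv_decreases_with_T", "inconclusive"))

    if lifetimes_ns is not None and len(lifetimes_ns) >= 2:
        tau = np.asarray(lifetimes_ns, dtype=float)
        rel_change = float(np.max(np.abs(tau - tau[0]) / tau[0]))
        outcome = "static" if rel_change < lifetime_threshold else "dynamic"
        evidence.append(("lifetime_invariant", outcome))
    else:
        evidence.append(("lifetime_invariant", "inconclusive"))

    n_static = sum(1 for _, o in evidence if o == "static")
    n_dynamic = sum(1 for _, o in evidence if o == "dynamic")
    if n_static >= 2 and n_dynamic == 0:
        verdict = "static"
    elif n_dynamic >= 2 and n_static == 0:
        verdict = "dynamic"
    else:
        verdict = "ambiguous"
    return MechanismVerdict(verdict=verdict, evidence=evidence)
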