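"""Binding constant, stoichiometry and thermodynamic force typing.

The double-logarithm ("modified Stern-Volmer") linearization

    log10((F0 - F)/F) = log10 K + n log10 [Q]

yields the binding constant K (intercept) and the number of binding sites n
(slope) from a single titration. Fitting ln K against 1/T (van't Hoff)
over temperatures gives the enthalpy change dH = -R * slope and entropy
change dS = R * intercept, assumed temperature-independent over the narrow
span fitted. The Gibbs energy follows either as dH - T dS or as -RT ln K;
both routes are reported.

Sign rules of Ross and Subramanian type the dominant interaction forces:
dH < 0 and dS < 0 point to hydrogen bonding / van der Waals contacts,
dH > 0 and dS > 0 to hydrophobic interactions, and dH <= 0 with dS > 0 to
electrostatic forces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .datatypes import TitrationSeries
from .exceptions import InsufficientDataError, ValidationError

#: gas constant, J mol^-1 K^-1
GAS_CONSTANT = 8.314


@dataclass(eq=False)
class BindingResult:
    """Double-log binding fit at one temperature: K (M^-1), n, Pearson r."""

    temperature_K: float
    k_binding: float
    k_binding_se: float
    n_sites: float
    n_sites_se: float
    r_corr: float
    n_obs: int = 0
    excluded_points: int = 0

    def __post_init__(self) -> None:
        if self.k_binding <= 0:
            raise ValidationError("k_binding must be positive")
        if self.n_sites <= 0:
            raise ValidationError("n_sites must be positive")

    def to_dict(self) -> dict:
        return {
            "temperature_K": self.temperature_K,
            "k_binding_per_M": self.k_binding,
            "k_binding_se_per_M": self.k_binding_se,
            "n_sites": self.n_sites,
            "n_sites_se": self.n_sites_se,
            "r_corr": self.r_corr,
            "n_obs": self.n_obs,
            "excluded_points": self.excluded_points,
        }

    def summary(self) -> str:
        return "\n".join([
            "Double-logarithm binding fit",
            "============================",
            f"temperature   {self.temperature_K:.1f} K",
            f"K             {self.k_binding:.4g} +/- {self.k_binding_se:.2g} M^-1",
            f"n sites       {self.n_sites:.3f} +/- {self.n_sites_se:.2g}",
            f"Pearson r     {self.r_corr:.4f}",
            f"points used   {self.n_obs} ({self.excluded_points} excluded)",
        ])


class DoubleLogBindingModel:
    """OLS of log10((F0-F)/F) on log10[Q] for one titration.

    Points with F >= F0 at nonzero concentration carry no quenching signal
    and are excluded with a warning; at least three usable points are
    required. Total added ligand is used for [Q] (no free-ligand depletion
    correction).
    """

    def __init__(self, series: TitrationSeries):
        self.series = series
        q = series.quencher_conc[1:]
        f = series.intensity[1:]
        f0 = series.f0
        usable = f < f0
        n_excluded = int(np.sum(~usable))
        if n_excluded:
            warnings.warn(
                f"excluding {n_excluded} point(s) with F >= F0 from the "
                "double-log fit (no quenching signal)",
                stacklevel=2,
            )
        if int(np.sum(usable)) < 3:
            raise InsufficientDataError(
                "double-log fit needs >= 3 nonzero-concentration points with F < F0"
            )
        self._logq = np.log10(q[usable])
        self._logy = np.log10((f0 - f[usable]) / f[usable])
        self._n_excluded = n_excluded

    def fit(self) -> BindingResult:
        res = stats.linregress(self._logq, self._logy)
        k = 10.0 ** res.intercept
        # delta method: se(K) = K ln10 se(log10 K)
        k_se = k * np.log(10.0) * res.intercept_stderr
        return BindingResult(
            temperature_K=self.series.temperature_K,
            k_binding=float(k),
            k_binding_se=float(k_se),
            n_sites=float(res.slope),
            n_sites_se=float(res.stderr),
            r_corr=float(res.rvalue),
            n_obs=int(self._logq.size),
            excluded_points=self._n_excluded,
        )


def fit_double_log(series: TitrationSeries) -> BindingResult:
    """Fit the double-logarithm binding model; wrapper around
    :class:`DoubleLogBindingModel`."""
    return DoubleLogBindingModel(series).fit()


@dataclass(eq=False)
class ThermoResult:
    """van't Hoff thermodynamics: dH (kJ/mol), dS (J/mol/K), dG per
    temperature (kJ/mol, dH - T dS route), and the force classification."""

    delta_h_kj: float
    delta_h_se_kj: float
    delta_s_j: float
    delta_s_se_j: float
    delta_g_kj: dict  # temperature_K -> dG via dH - T dS
    delta_g_from_k_kj: dict = field(default_factory=dict)  # via -RT ln K
    r_corr: float = float("nan")
    force_type: str = "indeterminate"
    gas_constant: float = GAS_CONSTANT

    def to_dict(self) -> dict:
        return {
            "delta_h_kj_per_mol": self.delta_h_kj,
            "delta_h_se_kj_per_mol": self.delta_h_se_kj,
            "delta_s_j_per_mol_K": self.delta_s_j,
            "delta_s_se_j_per_mol_K": self.delta_s_se_j,
            "delta_g_kj_per_mol": {str(t): g for t, g in self.delta_g_kj.items()},
            "delta_g_from_k_kj_per_mol": {
                str(t): g for t, g in self.delta_g_from_k_kj.items()
            },
            "delta_g_route_difference_kj_per_mol": {
                str(t): self.delta_g_kj[t] - self.delta_g_from_k_kj[t]
                for t in self.delta_g_from_k_kj
                if t in self.delta_g_kj
            },
            "r_corr": self.r_corr,
            "force_type": self.force_type,
            "gas_constant_j_per_mol_K": self.gas_constant,
        }

    def summary(self) -> str:
        lines = [
            "van't Hoff thermodynamics",
            "=========================",
            f"dH   {self.delta_h_kj:+.2f} +/- {self.delta_h_se_kj:.2f} kJ/mol",
            f"dS   {self.delta_s_j:+.2f} +/- {self.delta_s_se_j:.2f} J/mol/K",
            f"r    {self.r_corr:.4f}",
            f"dominant forces: {self.force_type}",
        ]
        for t in sorted(self.delta_g_kj):
            line = f"dG({t:g} K)  {self.delta_g_kj[t]:+.2f} kJ/mol (dH - T dS)"
            if t in self.delta_g_from_k_kj:
                line += f"; {self.delta_g_from_k_kj[t]:+.2f} kJ/mol (-RT ln K)"
            lines.append(line)
        return "\n".join(lines)


class VantHoffModel:
    """OLS of ln K against 1/T over binding results at several temperatures.

    Duplicate temperatures are collapsed to the geometric mean of their K
    values with a warning. dH is assumed temperature-independent over the
    fitted span.
    """

    def __init__(self, bindings: Sequence[BindingResult],
                 gas_constant: float = GAS_CONSTANT):
        if len({b.temperature_K for b in bindings}) < 2:
            raise InsufficientDataError(
                "van't Hoff regression needs >= 2 distinct temperatures"
            )
        for b in bindings:
            if b.k_binding <= 0:
                raise ValidationError("all binding constants must be positive")
        temps: dict[float, list[float]] = {}
        for b in bindings:
            temps.setdefault(float(b.temperature_K), []).append(float(b.k_binding))
        collapsed = {}
        for t, ks in temps.items():
            if len(ks) > 1:
                warnings.warn(
                    f"collapsing {len(ks)} duplicate results at {t} K by "
                    "geometric mean of K",
                    stacklevel=2,
                )
            collapsed[t] = float(np.exp(np.mean(np.log(ks))))
        self._temps = np.array(sorted(collapsed))
        self._ks = np.array([collapsed[t] for t in self._temps])
        self.gas_constant = gas_constant

    def fit(self) -> ThermoResult:
        res = stats.linregress(1.0 / self._temps, np.log(self._ks))
        R = self.gas_constant
        dh_kj = -R * res.slope / 1000.0
        ds_j = R * res.intercept
        dh_se = R * res.stderr / 1000.0 if np.isfinite(res.stderr) else 0.0
        ds_se = (R * res.intercept_stderr
                 if np.isfinite(res.intercept_stderr) else 0.0)
        dg = {t: compute_gibbs(dh_kj, ds_j, t) for t in self._temps}
        dg_k = {t: gibbs_from_k(k, t, gas_constant=R)
                for t, k in zip(self._temps, self._ks)}
        return ThermoResult(
            delta_h_kj=float(dh_kj),
            delta_h_se_kj=float(dh_se),
            delta_s_j=float(ds_j),
            delta_s_se_j=float(ds_se),
            delta_g_kj={float(t): float(g) for t, g in dg.items()},
            delta_g_from_k_kj={float(t): float(g) for t, g in dg_k.items()},
            r_corr=float(res.rvalue),
            force_type=classify_forces(dh_kj, ds_j),
            gas_constant=R,
        )


def fit_vant_hoff(bindings: Sequence[BindingResult],
                  gas_constant: float = GAS_CONSTANT) -> ThermoResult:
    """Fit the van't Hoff regression; wrapper around :class:`VantHoffModel`."""
    return VantHoffModel(bindings, gas_constant=gas_constant).fit()


def compute_gibbs(delta_h_kj: float, delta_s_j: float,
                  temperature_K: float) -> float:
    """Gibbs energy dG = dH - T dS, in kJ/mol (dH in kJ/mol, dS in J/mol/K)."""
    if temperature_K <= 0:
        raise ValidationError("temperature_K must be positive")
    return delta_h_kj - temperature_K * delta_s_j / 1000.0


def gibbs_from_k(k_binding: float, temperature_K: float,
                 gas_constant: float = GAS_CONSTANT) -> float:
    """Gibbs energy dG = -RT ln K, in kJ/mol."""
    if temperature_K <= 0:
        raise ValidationError("temperature_K must be positive")
    if k_binding <= 0:
        raise ValidationError("k_binding must be positive")
    return -gas_constant * temperature_K * np.log(k_binding) / 1000.0


def classify_forces(delta_h_kj: float, delta_s_j: float,
                    tol_h_kj: float = 4.0, tol_s_j: float = 10.0) -> str:
    """Type the dominant binding forces from the signs of dH and dS.

    Both clearly negative -> hydrogen bonds / van der Waals ("hbond_vdw");
    both clearly positive -> "hydrophobic"; dH near zero or negative with
    clearly positive dS -> "electrostatic"; anything within the tolerance
    bands -> "indeterminate". The tolerances (default 4 kJ/mol and
    10 J/mol/K) guard against over-interpreting near-zero estimates; the
    underlying rules are sign rules only.
    """
    if not (np.isfinite(delta_h_kj) and np.isfinite(delta_s_j)):
        raise ValidationError("dH and dS must be finite")
    if delta_h_kj < -tol_h_kj and delta_s_j < -tol_s_j:
        return "hbond_vdw"
    if delta_h_kj > tol_h_kj and delta_s_j > tol_s_j:
        return "hydrophobic"
    if delta_s_j > tol_s_j and delta_h_kj <= tol_h_kj:
        return "electrostatic"
    return "indeterminate"
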