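"""Readers and writers for every table the pipeline touches.

One canonical delimited-text dialect is used throughout: comma-separated,
"." decimal, a required header row, and "#"-prefixed comment lines.
Metadata that a column cannot carry (temperature, protein concentration,
probe names) is written as ``# key = value`` comment lines and parsed back
by the matching reader. Concentration columns default to micromolar in
files and are stored in mol/L in memory.

The JSON results report groups one block per pipeline stage; a versioned
schema ships with the package (``data/report_schema.json``) and
:func:`validate_report` checks a report against it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from .datatypes import CDSpectrum, DecayCurve, DisplacementSeries, TitrationSeries
from .exceptions import FormatError, ValidationError

REPORT_SCHEMA_VERSION = "specbind-report/1"

#: conversion factors to mol/L for the ``conc_unit`` dialect field
_CONC_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9}


@dataclass
class Dialect:
    """Delimited-text dialect for all CSV readers and writers."""

    sep: str = ","
    comment: str = "#"
    conc_unit: str = "uM"

    @property
    def conc_factor(self) -> float:
        try:
            return _CONC_FACTORS[self.conc_unit]
        except KeyError:
            raise ValidationError(
                f"unknown concentration unit {self.conc_unit!r}; "
                f"expected one of {sorted(_CONC_FACTORS)}"
            ) from None


DEFAULT_DIALECT = Dialect()


def _read_table(path, dialect: Dialect, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        frame = pd.read_csv(path, sep=dialect.sep, comment=dialect.comment)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty file: {path}") from None
    frame.columns = [str(c).strip() for c in frame.columns]
    for column in required:
        if column not in frame.columns:
            raise FormatError(f"missing column {column!r} in {path}")
    if len(frame) == 0:
        raise FormatError(f"no data rows in {path}")
    return frame


def _read_metadata(path, dialect: Dialect) -> dict[str, str]:
    """Parse ``# key = value`` comment lines preceding or inside the table."""
    meta: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if not stripped.startswith(dialect.comment):
            continue
        body = stripped.lstrip(dialect.comment).strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def _metadata_lines(meta: dict[str, Any], dialect: Dialect) -> str:
    return "".join(f"{dialect.comment} {k} = {v}\n" for k, v in meta.items())


# ---------------------------------------------------------------------------
# titration


def read_titration(
    path,
    dialect: Dialect = DEFAULT_DIALECT,
    temperature_K: Optional[float] = None,
) -> TitrationSeries:
    """Read a titration CSV (columns ``conc``, ``intensity``; optional
    ``a_ex``, ``a_em``) into a validated :class:`TitrationSeries`.

    ``temperature_K`` may come from a ``# temperature_K = ...`` comment line
    or the keyword argument (the argument wins).
    """
    frame = _read_table(path, dialect, ["conc", "intensity"])
    meta = _read_metadata(path, dialect)
    if temperature_K is None:
        if "temperature_K" not in meta:
            raise FormatError(
                f"temperature_K missing: pass it or add a comment line in {path}"
            )
        temperature_K = float(meta["temperature_K"])
    kwargs: dict[str, Any] = {}
    if "a_ex" in frame.columns and "a_em" in frame.columns:
        kwargs["absorbance_ex"] = frame["a_ex"].to_numpy(float)
        kwargs["absorbance_em"] = frame["a_em"].to_numpy(float)
    return TitrationSeries(
        temperature_K=float(temperature_K),
        quencher_conc=frame["conc"].to_numpy(float) * dialect.conc_factor,
        intensity=frame["intensity"].to_numpy(float),
        corrected=meta.get("corrected", "false").lower() == "true",
        label=meta.get("label", ""),
        **kwargs,
    )


def write_titration(series: TitrationSeries, path, dialect: Dialect = DEFAULT_DIALECT) -> None:
    meta = {
        "temperature_K": repr(series.temperature_K),
        "corrected": str(series.corrected).lower(),
        "label": series.label,
        "conc_unit": dialect.conc_unit,
    }
    data = {
        "conc": series.quencher_conc / dialect.conc_factor,
        "intensity": series.intensity,
    }
    if series.absorbance_ex is not None and series.absorbance_em is not None:
        data["a_ex"] = series.absorbance_ex
        data["a_em"] = series.absorbance_em
    _write_frame(path, data, meta, dialect)


# ---------------------------------------------------------------------------
# decay


def read_decay(path, dialect: Dialect = DEFAULT_DIALECT,
               tail_start_ns: Optional[float] = None) -> DecayCurve:
    """Read a TCSPC histogram CSV (columns ``time_ns``, ``counts``)."""
    frame = _read_table(path, dialect, ["time_ns", "counts"])
    meta = _read_metadata(path, dialect)
    if tail_start_ns is None:
        tail_start_ns = float(meta.get("tail_start_ns", frame["time_ns"].iloc[0]))
    return DecayCurve(
        time_ns=frame["time_ns"].to_numpy(float),
        counts=frame["counts"].to_numpy(float),
        tail_start_ns=tail_start_ns,
    )


def write_decay(curve: DecayCurve, path, dialect: Dialect = DEFAULT_DIALECT) -> None:
    meta = {"tail_start_ns": repr(curve.tail_start_ns)}
    _write_frame(path, {"time_ns": curve.time_ns, "counts": curve.counts},
                 meta, dialect)


# ---------------------------------------------------------------------------
# CD


def read_cd(path, dialect: Dialect = DEFAULT_DIALECT, **overrides) -> CDSpectrum:
    """Read a CD spectrum CSV (columns ``wavelength_nm``,
    ``ellipticity_mdeg``) with MRE metadata in comment lines or keyword
    overrides (``protein_conc_M``, ``n_residues``, ``pathlength_cm``)."""
    frame = _read_table(path, dialect, ["wavelength_nm", "ellipticity_mdeg"])
    meta = _read_metadata(path, dialect)

    def _need(key, cast):
        if key in overrides:
            return cast(overrides[key])
        if key in meta:
            return cast(meta[key])
        raise FormatError(f"{key} missing: pass it or add a comment line in {path}")

    return CDSpectrum(
        wavelength_nm=frame["wavelength_nm"].to_numpy(float),
        ellipticity_mdeg=frame["ellipticity_mdeg"].to_numpy(float),
        protein_conc_M=_need("protein_conc_M", float),
        n_residues=_need("n_residues", int),
        pathlength_cm=_need("pathlength_cm", float),
    )


def write_cd(spectrum: CDSpectrum, path, dialect: Dialect = DEFAULT_DIALECT) -> None:
    meta = {
        "protein_conc_M": repr(spectrum.protein_conc_M),
        "n_residues": spectrum.n_residues,
        "pathlength_cm": repr(spectrum.pathlength_cm),
    }
    _write_frame(
        path,
        {"wavelength_nm": spectrum.wavelength_nm,
         "ellipticity_mdeg": spectrum.ellipticity_mdeg},
        meta,
        dialect,
    )


# ---------------------------------------------------------------------------
# displacement


def read_displacement(path, dialect: Dialect = DEFAULT_DIALECT) -> DisplacementSeries:
    """Read a site-marker displacement CSV (columns ``conc``, ``intensity``)."""
    frame = _read_table(path, dialect, ["conc", "intensity"])
    meta = _read_metadata(path, dialect)
    return DisplacementSeries(
        competitor_conc=frame["conc"].to_numpy(float) * dialect.conc_factor,
        intensity=frame["intensity"].to_numpy(float),
        probe_name=meta.get("probe_name", ""),
        competitor_name=meta.get("competitor_name", ""),
    )


def write_displacement(series: DisplacementSeries, path,
                       dialect: Dialect = DEFAULT_DIALECT) -> None:
    meta = {
        "probe_name": series.probe_name,
        "competitor_name": series.competitor_name,
        "conc_unit": dialect.conc_unit,
    }
    _write_frame(
        path,
        {"conc": series.competitor_conc / dialect.conc_factor,
         "intensity": series.intensity},
        meta,
        dialect,
    )


def _write_frame(path, columns: dict[str, np.ndarray], meta: dict[str, Any],
                 dialect: Dialect) -> None:
    frame = pd.DataFrame(columns)
    path = Path(path)
    with open(path, "w") as handle:
        handle.write(_metadata_lines(meta, dialect))
        # float_format=None keeps full repr precision for lossless round-trips
        frame.to_csv(handle, sep=dialect.sep, index=False,
                     float_format=lambda x: repr(float(x)))


# ---------------------------------------------------------------------------
# JSON report


def _to_jsonable(obj: Any) -> Any:
    if hasattr(obj, "to_dict"):
        return _to_jsonable(obj.to_dict())
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def config_hash(config: Any) -> str:
    """Stable short hash of a configuration mapping, for report provenance."""
    if hasattr(config, "to_dict"):
        config = config.to_dict()
    payload = json.dumps(_to_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_report(results: dict[str, Any], path,
                 provenance: Optional[dict[str, Any]] = None) -> None:
    """Write the assembled pipeline results as a versioned JSON report.

    ``results`` maps block names ("quenching", "binding", "thermodynamics",
    "lifetime", "cd", "peaks", "displacement") to result objects (anything
    with ``to_dict``) or plain mappings; absent stages are simply absent
    blocks. Floats serialize at full repr precision, so a write/read
    round-trip preserves values exactly.
    """
    document = {
        "schema": REPORT_SCHEMA_VERSION,
        "provenance": _to_jsonable(provenance or {}),
        "results": _to_jsonable(results),
    }
    with open(path, "w") as handle:
        json.dump(document, handle, indent=2)
        handle.write("\n")


def read_report(path) -> dict[str, Any]:
    with open(path) as handle:
        document = json.load(handle)
    if document.get("schema") != REPORT_SCHEMA_VERSION:
        raise FormatError(
            f"unsupported report schema {document.get('schema')!r}"
        )
    return document


def load_report_schema() -> dict[str, Any]:
    with resources.files("specbind.data").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


_JSON_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
}


def _validate_node(instance: Any, schema: dict[str, Any], where: str,
                   errors: list[str]) -> None:
    expected = schema.get("type")
    if expected is not None:
        pytype = _JSON_TYPES[expected]
        if expected == "number" and isinstance(instance, bool):
            errors.append(f"{where}: expected number, got boolean")
            return
        if not isinstance(instance, pytype):
            errors.append(f"{where}: expected {expected}, got {type(instance).__name__}")
            return
    if expected == "object":
        for key in schema.get("required", []):
            if key not in instance:
                errors.append(f"{where}: missing required key {key!r}")
        for key, subschema in schema.get("properties", {}).items():
            if key in instance:
                _validate_node(instance[key], subschema, f"{where}.{key}", errors)
    elif expected == "array" and "items" in schema:
        for i, item in enumerate(instance):
            _validate_node(item, schema["items"], f"{where}[{i}]", errors)


def validate_report(document: dict[str, Any]) -> list[str]:
    """Check a report document against the shipped schema.

    Returns a list of human-readable problems; an empty list means the
    document is schema-valid.
    """
    schema = load_report_schema()
    errors: list[str] = []
    _validate_node(document, schema, "$", errors)
    blocks = schema.get("blockSchemas", {})
    results = document.get("results", {})
    if isinstance(results, dict):
        for name, block in results.items():
            if name in blocks:
                _validate_node(block, blocks[name], f"$.results.{name}", errors)
    return errors
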