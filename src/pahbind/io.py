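"""File readers/writers and run configuration.

All unit handling lives here: CSV headers may declare concentration units
(micromolar by default) and values are converted to mol/L on ingest; the
core modules never see anything but mol/L, kJ/mol, K and nm.  Readers
validate aggressively — invariant-violating inputs are rejected, never
silently coerced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass
from datetime import datetime, timezone
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import (
    R_KJ_PER_MOL_K,
    SITES_PER_TETRAMER_DEFAULT,
    T_CYCLE_DEFAULT,
    T_KD_DEFAULT,
    TETRAMER_MOLAR_MASS_DEFAULT,
    V0_NM3,
)
from .cycle import ErrorRule, LambdaWindow, TIProfile
from .exceptions import ParseError, ValidationError
from .polarity import EmissionSpectrum, UptakeTimeCourse
from .titration import TitrationSeries

__all__ = [
    "AnalysisConfig",
    "CONCENTRATION_UNITS",
    "packaged_fixture",
    "read_titration_csv",
    "read_timecourse_csv",
    "read_spectrum_csv",
    "read_xvg_dgdl",
    "read_ti_csv",
    "write_report",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1"

#: Concentration unit -> factor converting to mol/L.
CONCENTRATION_UNITS = {
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12,
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Package-wide defaults, emitted into every report for provenance."""

    temperature_kd: float = T_KD_DEFAULT
    temperature_cycle: float = T_CYCLE_DEFAULT
    gas_constant: float = R_KJ_PER_MOL_K
    v0: float = V0_NM3
    sites_per_tetramer: int = SITES_PER_TETRAMER_DEFAULT
    tetramer_molar_mass: float = TETRAMER_MOLAR_MASS_DEFAULT
    error_rule: ErrorRule = ErrorRule.rss_over_sqrt2
    blocks: int = 10

    def __post_init__(self):
        for name in ("temperature_kd", "temperature_cycle", "gas_constant",
                     "v0", "tetramer_molar_mass"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.sites_per_tetramer < 1 or self.blocks < 2:
            raise ValidationError("sites_per_tetramer >= 1 and blocks >= 2 required")


def packaged_fixture(name: str = "table1_naphthalene.csv") -> Path:
    """Path to a data file shipped inside the package."""
    return Path(str(resources.files("pahbind.data") / name))


def _parse_headers(path: Path) -> tuple[dict[str, str], list[tuple[int, str]]]:
    """Split a CSV into '# key: value' headers and (line_no, text) data rows."""
    meta: dict[str, str] = {}
    rows: list[tuple[int, str]] = []
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*([\w.]+)\s*:\s*(.+)$", line)
            if m:
                meta[m.group(1)] = m.group(2).strip()
            continue
        rows.append((i, line))
    return meta, rows


def _numeric_rows(rows: list[tuple[int, str]], n_cols: int, path) -> np.ndarray:
    out = []
    for line_no, text in rows:
        parts = [p.strip() for p in text.split(",")]
        if len(parts) != n_cols:
            raise ParseError(f"{path}:{line_no}: expected {n_cols} columns, got {len(parts)}")
        try:
            out.append([float(p) for p in parts])
        except ValueError as exc:
            raise ParseError(f"{path}:{line_no}: non-numeric value ({exc})") from None
    return np.asarray(out, dtype=float)


def _unit_factor(meta: dict[str, str]) -> float:
    unit = meta.get("unit", "uM")
    try:
        return CONCENTRATION_UNITS[unit]
    except KeyError:
        raise ParseError(f"unknown concentration unit {unit!r}; "
                         f"expected one of {sorted(CONCENTRATION_UNITS)}") from None


def read_titration_csv(path) -> TitrationSeries:
    """Read a `protein_conc,intensity` titration CSV into mol/L.

    Header comments carry the unit (default uM), the total ligand
    concentration in the same unit, and the assay temperature; validation
    (zero point, duplicates, length) happens on construction.
    """
    path = Path(path)
    meta, rows = _parse_headers(path)
    if rows and not rows[0][1][0].isdigit() and not rows[0][1].startswith(("-", ".")):
        rows = rows[1:]  # column-name header
    data = _numeric_rows(rows, 2, path)
    factor = _unit_factor(meta)
    if "ligand_total" not in meta:
        raise ParseError(f"{path}: missing '# ligand_total:' header")
    return TitrationSeries(
        ligand_name=meta.get("ligand", path.stem),
        ligand_total=float(meta["ligand_total"]) * factor,
        protein_total=data[:, 0] * factor,
        intensity=data[:, 1],
        emission_wavelength=float(meta.get("emission_nm", 350.0)),
        excitation_wavelength=float(meta.get("excitation_nm", 275.0)),
        temperature=float(meta.get("temperature_K", 293.15)),
    )


def read_timecourse_csv(path) -> UptakeTimeCourse:
    """Read a `time_hr,intensity` uptake time course."""
    path = Path(path)
    meta, rows = _parse_headers(path)
    if rows and rows[0][1].lower().startswith("time"):
        rows = rows[1:]
    data = _numeric_rows(rows, 2, path)
    factor = _unit_factor(meta)
    return UptakeTimeCourse(
        time=data[:, 0], intensity=data[:, 1],
        ligand_total=float(meta.get("ligand_total", 2.0)) * factor,
        protein_total=float(meta.get("protein_total", 70.0)) * factor,
        temperature=float(meta.get("temperature_K", 283.15)),
    )


def read_spectrum_csv(path) -> EmissionSpectrum:
    """Read a `wavelength,intensity` emission spectrum."""
    path = Path(path)
    meta, rows = _parse_headers(path)
    if rows and rows[0][1].lower().startswith("wavelength"):
        rows = rows[1:]
    data = _numeric_rows(rows, 2, path)
    return EmissionSpectrum(
        wavelength=data[:, 0], intensity=data[:, 1],
        excitation_wavelength=float(meta.get("excitation_nm", 334.0)),
    )


_LAMBDA_TOKEN = re.compile(r"lambda_([0-9]*\.?[0-9]+)")


def _lambda_from_name(path: Path) -> float:
    m = _LAMBDA_TOKEN.search(path.name)
    if not m:
        raise ParseError(f"{path}: cannot recover lambda; expected a "
                         f"'lambda_<value>' token in the filename or a manifest")
    return float(m.group(1))


def read_xvg_dgdl(paths, manifest: dict | None = None, n_blocks: int = 10) -> TIProfile:
    """Assemble a TI profile from per-window dG/dlambda XVG files.

    Each file is a two-column time/value series in the GROMACS dhdl
    dialect (``@`` and ``#`` header lines ignored).  The window's lambda
    is taken from ``manifest`` (a mapping of file name or path to lambda)
    or parsed from a ``lambda_<value>`` filename token.  Windows are block
    averaged, sorted, and endpoint-checked; input order does not matter.
    """
    windows = []
    seen: set[float] = set()
    for p in map(Path, paths):
        if manifest is not None:
            key = str(p) if str(p) in manifest else p.name
            if key not in manifest:
                raise ParseError(f"{p}: not listed in manifest")
            lam = float(manifest[key])
        else:
            lam = _lambda_from_name(p)
        if lam in seen:
            raise ParseError(f"duplicate lambda {lam} (file {p})")
        seen.add(lam)
        values = []
        for i, raw in enumerate(p.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith(("@", "#")):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{p}:{i}: expected two whitespace-separated columns")
            try:
                values.append(float(parts[1]))
            except ValueError:
                raise ParseError(f"{p}:{i}: non-numeric dG/dlambda value") from None
        windows.append(LambdaWindow.from_samples(lam, np.asarray(values), n_blocks=n_blocks))
    return TIProfile(windows=windows)


def read_ti_csv(path) -> TIProfile:
    """Read a consolidated `lambda,mean,sigma` TI summary CSV."""
    path = Path(path)
    _, rows = _parse_headers(path)
    if rows and rows[0][1].lower().startswith("lambda"):
        rows = rows[1:]
    data = _numeric_rows(rows, 3, path)
    windows = [LambdaWindow(lam=l, mean=m, sigma=s) for l, m, s in data]
    return TIProfile(windows=windows)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(results: dict, path, config: AnalysisConfig | None = None,
                 input_paths: list | None = None, seed: int | None = None,
                 timestamp: bool = True) -> dict:
    """Write a schema-versioned JSON report embedding config and provenance.

    ``results`` maps section names to result objects (dataclasses, arrays
    and plain values all serialize).  Input files are checksummed so a
    report can be traced back to its exact inputs.  With the same inputs,
    config and seed, two reports differ only in the timestamp field.
    Returns the document that was written.
    """
    config = config or AnalysisConfig()
    doc = {
        "schema_version": SCHEMA_VERSION,
        "package": "pahbind",
        "config": _jsonable(config),
        "seed": seed,
        "inputs": {str(p): _sha256(Path(p)) for p in (input_paths or [])},
        "results": _jsonable(results),
    }
    if timestamp:
        doc["timestamp"] = datetime.now(timezone.utc).isoformat()
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return doc
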