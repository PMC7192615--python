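"""File dialects, run configuration and report rendering.

All on-disk formats are plain text: Sparky-style ``.list`` peak lists and a
CSV peak-list dialect, an ITC CSV with a key/value comment header, CD
scan/melt CSVs with sample metadata in the header, YAML run configs, and a
thermodynamics report (CSV + JSON). Numeric CSVs use '.' decimals, UTF-8,
and carry a comment header with the package version and seed where one
applies.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import delta_g_from_kd, tds_from_dh_dg
from .cd import CDSpectrum, MeltingCurve
from .csp import CspFitResult, PeakAssignment
from .itc import InjectionSchedule, ItcFitResult

__all__ = [
    "read_peaklist",
    "write_peaklist",
    "read_itc_csv",
    "write_itc_csv",
    "read_itc_thermogram",
    "read_cd_spectrum",
    "write_cd_spectrum",
    "read_melting_curve",
    "write_melting_curve",
    "RunConfig",
    "load_run_config",
    "write_thermo_report",
]


class PeaklistError(ValueError):
    """Malformed peak-list file; carries the offending line number."""


def _parse_float(token: str, path: Path, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise PeaklistError(
            f"{path}:{lineno}: non-numeric {what}: {token!r}"
        ) from None


def read_peaklist(path, dialect: str = "sparky_list") -> list[PeakAssignment]:
    """Read assigned peaks from a Sparky-style .list or a CSV file.

    sparky_list: whitespace-separated columns (label, 15N ppm, 1H ppm),
    with an optional ``Assignment w1 w2`` header; labels are kept verbatim,
    including pseudo-assignments like ``G#2``. csv: header
    ``residue,h_ppm,n_ppm``. Duplicate labels are an error.
    """
    path = Path(path)
    peaks: list[PeakAssignment] = []
    seen: set[str] = set()
    if dialect == "sparky_list":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if lineno == 1 and parts[0].lower() == "assignment":
                continue
            if len(parts) < 3:
                raise PeaklistError(f"{path}:{lineno}: expected 3 columns")
            label = parts[0]
            n_ppm = _parse_float(parts[1], path, lineno, "15N shift")
            h_ppm = _parse_float(parts[2], path, lineno, "1H shift")
            if label in seen:
                raise PeaklistError(f"{path}:{lineno}: duplicate label {label!r}")
            seen.add(label)
            peaks.append(PeakAssignment(label, h_ppm, n_ppm))
    elif dialect == "csv":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if lineno == 1 and parts[0].lower() == "residue":
                continue
            if len(parts) < 3:
                raise PeaklistError(f"{path}:{lineno}: expected 3 columns")
            label = parts[0]
            h_ppm = _parse_float(parts[1], path, lineno, "1H shift")
            n_ppm = _parse_float(parts[2], path, lineno, "15N shift")
            if label in seen:
                raise PeaklistError(f"{path}:{lineno}: duplicate label {label!r}")
            seen.add(label)
            peaks.append(PeakAssignment(label, h_ppm, n_ppm))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return peaks


def write_peaklist(path, peaks: list[PeakAssignment],
                   dialect: str = "sparky_list") -> None:
    path = Path(path)
    if dialect == "sparky_list":
        lines = ["      Assignment         w1         w2"]
        lines += [
            f"{p.residue_label:>16s} {p.n_shift:10.3f} {p.h_shift:10.3f}"
            for p in peaks
        ]
    elif dialect == "csv":
        lines = ["residue,h_ppm,n_ppm"]
        lines += [
            f"{p.residue_label},{p.h_shift:.3f},{p.n_shift:.3f}" for p in peaks
        ]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# key/value comment headers shared by the ITC and CD dialects


def _read_header_and_table(path: Path) -> tuple[dict[str, float], pd.DataFrame]:
    meta: dict[str, float] = {}
    rows = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    meta[key.strip()] = val.strip()
        elif line.strip():
            rows.append(line)
    from io import StringIO

    table = pd.read_csv(StringIO("\n".join(rows)))
    return meta, table


def write_itc_csv(path, schedule: InjectionSchedule, heats: np.ndarray,
                  seed: int | None = None) -> None:
    """Write an ITC run: geometry in the comment header, one row per injection."""
    path = Path(path)
    lines = [
        f"# quadbind {__version__}",
        f"# cell_volume_ul: {schedule.cell_volume}",
        f"# cell_conc_uM: {schedule.cell_conc}",
        f"# syringe_conc_uM: {schedule.syringe_conc}",
        f"# temperature_C: {schedule.temperature - 273.15:.2f}",
        f"# spacing_s: {schedule.spacing}",
    ]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    lines.append("injection_ul,heat_ucal")
    for dv, q in zip(schedule.injections, heats):
        lines.append(f"{dv},{q:.6g}")
    path.write_text("\n".join(lines) + "\n")


def read_itc_csv(path) -> tuple[InjectionSchedule, np.ndarray]:
    """Read the ITC CSV dialect written by :func:`write_itc_csv`."""
    meta, table = _read_header_and_table(Path(path))
    required = {"cell_volume_ul", "cell_conc_uM", "syringe_conc_uM"}
    missing = required - meta.keys()
    if missing:
        raise ValueError(f"{path}: missing header keys: {sorted(missing)}")
    schedule = InjectionSchedule(
        cell_volume=float(meta["cell_volume_ul"]),
        cell_conc=float(meta["cell_conc_uM"]),
        syringe_conc=float(meta["syringe_conc_uM"]),
        injections=tuple(table["injection_ul"].astype(float)),
        temperature=float(meta.get("temperature_C", 25.0)) + 273.15,
        spacing=float(meta.get("spacing_s", 180.0)),
    )
    return schedule, table["heat_ucal"].to_numpy(dtype=float)


def read_itc_thermogram(data_path, injections_path) -> tuple[InjectionSchedule, np.ndarray]:
    """Read a raw-thermogram ITC run and integrate it to per-injection heats.

    ``data_path``: the usual geometry comment header plus rows
    ``time_s,power_ucal_per_s``. ``injections_path``: sidecar CSV with rows
    ``time_s,injection_ul`` marking each injection. Returns the schedule
    and baseline-corrected integrated heats (ucal).
    """
    from .itc import integrate_thermogram

    meta, trace = _read_header_and_table(Path(data_path))
    required = {"cell_volume_ul", "cell_conc_uM", "syringe_conc_uM"}
    missing = required - meta.keys()
    if missing:
        raise ValueError(f"{data_path}: missing header keys: {sorted(missing)}")
    _, marks = _read_header_and_table(Path(injections_path))
    schedule = InjectionSchedule(
        cell_volume=float(meta["cell_volume_ul"]),
        cell_conc=float(meta["cell_conc_uM"]),
        syringe_conc=float(meta["syringe_conc_uM"]),
        injections=tuple(marks["injection_ul"].astype(float)),
        temperature=float(meta.get("temperature_C", 25.0)) + 273.15,
        spacing=float(meta.get("spacing_s", 180.0)),
    )
    heats = integrate_thermogram(
        trace["time_s"].to_numpy(dtype=float),
        trace["power_ucal_per_s"].to_numpy(dtype=float),
        marks["time_s"].to_numpy(dtype=float),
    )
    return schedule, heats


def write_cd_spectrum(path, spec: CDSpectrum) -> None:
    """Write a CD scan: sample metadata header plus wavelength/ellipticity rows."""
    path = Path(path)
    lines = [
        f"# quadbind {__version__}",
        f"# conc_M: {spec.conc}",
        f"# path_cm: {spec.path}",
        f"# n_residues: {spec.n_residues}",
        f"# titrant_uM: {spec.titrant_conc}",
        "wavelength_nm,ellipticity_mdeg",
    ]
    for w, e in zip(spec.wavelengths, spec.ellipticity):
        lines.append(f"{w},{e:.6g}")
    path.write_text("\n".join(lines) + "\n")


def read_cd_spectrum(path) -> CDSpectrum:
    meta, table = _read_header_and_table(Path(path))
    required = {"conc_M", "n_residues"}
    missing = required - meta.keys()
    if missing:
        raise ValueError(f"{path}: missing header keys: {sorted(missing)}")
    return CDSpectrum(
        wavelengths=table["wavelength_nm"].to_numpy(dtype=float),
        ellipticity=table["ellipticity_mdeg"].to_numpy(dtype=float),
        conc=float(meta["conc_M"]),
        path=float(meta.get("path_cm", 1.0)),
        n_residues=int(meta["n_residues"]),
        titrant_conc=float(meta.get("titrant_uM", 0.0)),
    )


def write_melting_curve(path, curve: MeltingCurve) -> None:
    path = Path(path)
    lines = [
        f"# quadbind {__version__}",
        f"# wavelength_nm: {curve.wavelength}",
        "temperature_C,ellipticity_mdeg",
    ]
    for t, e in zip(curve.temperature, curve.ellipticity):
        lines.append(f"{t},{e:.6g}")
    path.write_text("\n".join(lines) + "\n")


def read_melting_curve(path) -> MeltingCurve:
    meta, table = _read_header_and_table(Path(path))
    return MeltingCurve(
        temperature=table["temperature_C"].to_numpy(dtype=float),
        ellipticity=table["ellipticity_mdeg"].to_numpy(dtype=float),
        wavelength=float(meta.get("wavelength_nm", 262.0)),
    )


# --------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass(frozen=True)
class TitrationStepConfig:
    protein_total_uM: float
    ligand_total_uM: float
    peaklist: str
    dialect: str = "sparky_list"


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated CSP-titration run configuration.

    YAML layout::

        modality: csp
        steps:
          - {protein_total_uM: 138, ligand_total_uM: 0, peaklist: step0.list}
          - ...
        n_scale: 5.0        # optional
        bootstrap: 0        # optional
        seed: 0             # optional
        temperature_K: 298.15

    Unknown keys are rejected.
    """

    modality: str
    steps: tuple[TitrationStepConfig, ...]
    n_scale: float = 5.0
    bootstrap: int = 0
    seed: int | None = None
    temperature_K: float = 298.15


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {"modality", "steps", "n_scale", "bootstrap", "seed", "temperature_K"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    if raw.get("modality") != "csp":
        raise ValueError(f"{path}: modality must be 'csp'")
    steps_raw = raw.get("steps")
    if not isinstance(steps_raw, list) or not steps_raw:
        raise ValueError(f"{path}: 'steps' must be a non-empty list")
    step_known = {"protein_total_uM", "ligand_total_uM", "peaklist", "dialect"}
    steps = []
    for i, s in enumerate(steps_raw):
        extra = set(s) - step_known
        if extra:
            raise ValueError(f"{path}: step {i}: unknown keys {sorted(extra)}")
        steps.append(TitrationStepConfig(**s))
    return RunConfig(
        modality="csp",
        steps=tuple(steps),
        n_scale=float(raw.get("n_scale", 5.0)),
        bootstrap=int(raw.get("bootstrap", 0)),
        seed=raw.get("seed"),
        temperature_K=float(raw.get("temperature_K", 298.15)),
    )


# --------------------------------------------------------------------------
# thermodynamics report


def write_thermo_report(
    fits: list[tuple[str, ItcFitResult | CspFitResult]],
    temperature: float = 298.15,
    csv_path=None,
    json_path=None,
) -> pd.DataFrame:
    """Render labelled fits into a thermodynamics table (CSV and/or JSON).

    dG and TdS are recomputed from the fitted Kd (and dH where the fit has
    one — CSP fits carry no enthalpy). Flagged fits keep their numbers but
    carry their markers in the ``flags`` column.
    """
    rows = []
    for label, fit in fits:
        kd = fit.kd
        dG = delta_g_from_kd(kd, temperature) if kd > 0 else float("nan")
        dH = getattr(fit, "dH", float("nan"))
        n = getattr(fit, "n", float("nan"))
        n_se = getattr(fit, "n_stderr", None)
        rows.append(
            {
                "experiment": label,
                "kd_uM": kd,
                "kd_se_uM": fit.kd_stderr,
                "dG_kcal": dG,
                "dH_kcal": dH,
                "dH_se_kcal": getattr(fit, "dH_stderr", None),
                "TdS_kcal": tds_from_dh_dg(dH, dG) if np.isfinite(dH) else float("nan"),
                "n": n,
                "n_se": n_se,
                "flags": ";".join(fit.flags) if fit.flags else "",
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "experiment", "kd_uM", "kd_se_uM", "dG_kcal", "dH_kcal",
            "dH_se_kcal", "TdS_kcal", "n", "n_se", "flags",
        ],
    )
    if csv_path is not None:
        with open(csv_path, "w", encoding="utf-8") as fh:
            fh.write(f"# quadbind {__version__}\n")
            report.to_csv(fh, index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(
                {"version": __version__, "temperature_K": temperature,
                 "rows": json.loads(report.to_json(orient="records"))},
                indent=2,
            )
        )
    return report
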