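"""Readers and writers for the package's delimited-text interfaces.

Spectra travel as wide CSV: first header cell ``time_h``, remaining header
cells wavelengths in nm, one row per acquisition; an optional sidecar JSON
(``<stem>.events.json``) lists the sampling-event times.  Off-line assay
series are three-column CSV ``time_h,F_molL,POH_molL`` with empty fields for
missing values.  Fitted parameters and calibrations are JSON records.
Floats are serialized at full precision (repr round-trip), so read-after-
write is the identity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import MonitoringCalibration, SpectraTimeSeries
from .kinetics import FitResult, KineticParams, OfflineSeries

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_offline",
    "write_offline",
    "write_fit_json",
    "read_params_json",
    "write_calibration_json",
]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number when known."""


def _events_sidecar(path: Path) -> Path:
    return path.with_suffix(".events.json")


def read_spectra(path: str | Path) -> SpectraTimeSeries:
    """Read a wide-CSV spectra file (and its sampling-events sidecar)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise ParseError(f"{path}: {e}") from e
    if df.columns[0] != "time_h":
        raise ParseError(
            f"{path}: first header cell must be 'time_h', got {df.columns[0]!r}"
        )
    try:
        wl = np.array([float(c) for c in df.columns[1:]])
    except ValueError as e:
        raise ParseError(f"{path}: non-numeric wavelength header: {e}") from e
    if np.any(np.diff(wl) <= 0):
        raise ParseError(f"{path}: wavelength header not strictly increasing")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2  # header is line 1
        raise ParseError(f"{path}: ragged or missing values near line {row}")

    events = None
    sidecar = _events_sidecar(path)
    if sidecar.exists():
        events = np.asarray(
            json.loads(sidecar.read_text())["sampling_events"], dtype=float
        )
    return SpectraTimeSeries(
        times=df["time_h"].to_numpy(dtype=float),
        wavelengths=wl,
        absorbance=df.iloc[:, 1:].to_numpy(dtype=float),
        sampling_events=events,
    )


def write_spectra(series: SpectraTimeSeries, path: str | Path) -> None:
    """Write a spectra series as wide CSV plus the events sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(
            "time_h," + ",".join(repr(float(w)) for w in series.wavelengths) + "\n"
        )
        for t, row in zip(series.times, series.absorbance):
            fh.write(
                repr(float(t)) + "," + ",".join(repr(float(v)) for v in row) + "\n"
            )
    if series.sampling_events is not None:
        _events_sidecar(path).write_text(
            json.dumps({"sampling_events": [float(e) for e in series.sampling_events]})
        )


def read_offline(path: str | Path) -> OfflineSeries:
    """Read an off-line assay CSV ``time_h,F_molL,POH_molL``."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    df = pd.read_csv(path)
    expected = ["time_h", "F_molL", "POH_molL"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: header must be {','.join(expected)}")
    if df["time_h"].isna().any():
        raise ParseError(f"{path}: missing time values")
    return OfflineSeries(
        times=df["time_h"].to_numpy(dtype=float),
        F=df["F_molL"].to_numpy(dtype=float),
        POH=df["POH_molL"].to_numpy(dtype=float),
    )


def write_offline(series: OfflineSeries, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("time_h,F_molL,POH_molL\n")
        for t, f, p in zip(series.times, series.F, series.POH):
            ff = "" if np.isnan(f) else repr(float(f))
            pp = "" if np.isnan(p) else repr(float(p))
            fh.write(f"{float(t)!r},{ff},{pp}\n")


def write_fit_json(fit: FitResult, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")


def read_params_json(path: str | Path) -> KineticParams:
    d = json.loads(Path(path).read_text())
    return KineticParams(
        k1=d["k1"],
        k2=d.get("k2", 0.0),
        f_nonreactive=d.get("f_nonreactive", 0.0),
        temperature_C=d.get("temperature_C"),
    )


def write_calibration_json(
    calibration: MonitoringCalibration, path: str | Path
) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(calibration.to_dict(), indent=2) + "\n")
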