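"""CSV readers/writers for spectra, thermograms and isothermal traces.

Instrument exports in this domain are plain ASCII tables, so the on-disk
dialect is CSV with metadata carried in leading comment lines of the form
``# key=value``.  Readers validate the metadata, build the corresponding
domain object (which enforces monotonicity etc.) and convert units to the
internal convention; writers emit files that round-trip exactly.

A ``decimal=","`` flag parses comma-decimal exports (common from
European-locale instrument software).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .bds import DielectricSpectrum
from .dsc import Thermogram
from .fractions import MixtureObservation
from .kinetics import CrystallizationTrace

__all__ = [
    "FormatError",
    "read_spectrum_csv", "write_spectrum_csv",
    "read_thermogram_csv", "write_thermogram_csv",
    "read_trace_csv", "write_trace_csv",
    "read_observations_csv", "write_observations_csv",
    "RunManifest",
]


class FormatError(ValueError):
    """A data file violates the documented CSV dialect."""


def _parse(path, required_meta: dict, columns: list[str], decimal: str = ".", sep: str = ","):
    """Split '# key=value' header lines from the table and validate both."""
    path = Path(path)
    meta_lines, body = {}, []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if "=" not in stripped:
                    raise FormatError(f"{path}:{lineno}: metadata line lacks 'key=value'")
                key, _, val = stripped.partition("=")
                meta_lines[key.strip()] = val.strip()
            else:
                body.append(line)
    missing = [k for k in required_meta if k not in meta_lines]
    if missing:
        raise FormatError(f"{path}: missing metadata header(s): {', '.join(missing)}")
    meta = {}
    for key, conv in required_meta.items():
        try:
            meta[key] = conv(meta_lines[key])
        except ValueError as exc:
            raise FormatError(f"{path}: bad metadata value for '{key}': {exc}") from exc
    df = pd.read_csv(_io.StringIO("".join(body)), decimal=decimal, sep=sep)
    missing_cols = [c for c in columns if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing_cols)}")
    if df[columns].isna().any().any():
        raise FormatError(f"{path}: table contains missing values")
    return meta, df


def _write(path, meta: dict, df: pd.DataFrame) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


# ------------------------------------------------------------------ spectra

def read_spectrum_csv(path, decimal: str = ".", sep: str = ",") -> DielectricSpectrum:
    """Columns frequency_Hz, eps_real, eps_imag; header ``# temperature_K=``."""
    meta, df = _parse(
        path, {"temperature_K": float},
        ["frequency_Hz", "eps_real", "eps_imag"], decimal, sep,
    )
    try:
        return DielectricSpectrum(
            frequency=df["frequency_Hz"].to_numpy(float),
            eps_real=df["eps_real"].to_numpy(float),
            eps_imag=df["eps_imag"].to_numpy(float),
            temperature=meta["temperature_K"],
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_spectrum_csv(path, spectrum: DielectricSpectrum) -> None:
    _write(
        path,
        {"temperature_K": repr(spectrum.temperature)},
        pd.DataFrame({
            "frequency_Hz": spectrum.frequency,
            "eps_real": spectrum.eps_real,
            "eps_imag": spectrum.eps_imag,
        }),
    )


# -------------------------------------------------------------- thermograms

def read_thermogram_csv(path, decimal: str = ".", sep: str = ",") -> Thermogram:
    """Columns temperature_C, signal; headers heating_rate_K_per_min, signal_kind."""
    meta, df = _parse(
        path,
        {"heating_rate_K_per_min": float, "signal_kind": str},
        ["temperature_C", "signal"], decimal, sep,
    )
    if meta["signal_kind"] not in ("cp", "heat_flow"):
        raise FormatError(f"{path}: signal_kind must be 'cp' or 'heat_flow'")
    try:
        return Thermogram(
            temperature=df["temperature_C"].to_numpy(float),
            signal=df["signal"].to_numpy(float),
            heating_rate=meta["heating_rate_K_per_min"],
            signal_kind=meta["signal_kind"],
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_thermogram_csv(path, tg: Thermogram) -> None:
    _write(
        path,
        {"heating_rate_K_per_min": repr(tg.heating_rate), "signal_kind": tg.signal_kind},
        pd.DataFrame({"temperature_C": tg.temperature, "signal": tg.signal}),
    )


# ------------------------------------------------------------------- traces

def read_trace_csv(path, decimal: str = ".", sep: str = ",") -> CrystallizationTrace:
    """Columns time_s, observable; headers kind (bds|dsc), temperature_K."""
    meta, df = _parse(
        path, {"kind": str, "temperature_K": float}, ["time_s", "observable"], decimal, sep,
    )
    if meta["kind"] not in ("bds", "dsc"):
        raise FormatError(f"{path}: kind must be 'bds' or 'dsc'")
    try:
        return CrystallizationTrace(
            time=df["time_s"].to_numpy(float),
            observable=df["observable"].to_numpy(float),
            kind=meta["kind"],
            temperature=meta["temperature_K"],
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_trace_csv(path, trace: CrystallizationTrace) -> None:
    _write(
        path,
        {"kind": trace.kind, "temperature_K": repr(trace.temperature)},
        pd.DataFrame({"time_s": trace.time, "observable": trace.observable}),
    )


# ------------------------------------------------------- mixture observations

def read_observations_csv(path, decimal: str = ".", sep: str = ",") -> list[MixtureObservation]:
    """Columns ms_mass_fraction, delta_cp_J_per_gK, cc_enthalpy_J_per_g."""
    _, df = _parse(
        path, {},
        ["ms_mass_fraction", "delta_cp_J_per_gK", "cc_enthalpy_J_per_g"], decimal, sep,
    )
    try:
        return [
            MixtureObservation(
                ms_mass_fraction=row.ms_mass_fraction,
                delta_cp_mixture=row.delta_cp_J_per_gK,
                cc_enthalpy_mixture=row.cc_enthalpy_J_per_g,
            )
            for row in df.itertuples()
        ]
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_observations_csv(path, observations) -> None:
    _write(
        path, {},
        pd.DataFrame({
            "ms_mass_fraction": [o.ms_mass_fraction for o in observations],
            "delta_cp_J_per_gK": [o.delta_cp_mixture for o in observations],
            "cc_enthalpy_J_per_g": [o.cc_enthalpy_mixture for o in observations],
        }),
    )


# ----------------------------------------------------------------- manifest

@dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted once per CLI run."""

    command: str
    config: Optional[str]
    inputs: dict          # path -> sha256
    seed: Optional[int]
    version: str
    timestamp: str
    status: str = "ok"

    @staticmethod
    def hash_file(path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 16), b""):
                h.update(chunk)
        return h.hexdigest()

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
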