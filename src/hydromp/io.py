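"""Delimited-text readers and writers for the four data modalities.

All files are UTF-8 comma-separated with a '.' decimal separator and a
required header line; scalar metadata travels in leading ``# key: value``
comment lines.  Floats are written with 17 significant digits so that a
write/read cycle is bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cd import CDSpectrum
from .dielectric import DielectricSpectrum, FrequencyGrid
from .dsc import Thermogram
from .ftir import IRSpectrum
from .hydration import SolutionComposition

__all__ = [
    "write_dielectric_spectrum", "read_dielectric_spectrum",
    "write_thermogram", "read_thermogram",
    "write_ir_spectrum", "read_ir_spectrum",
    "write_cd_spectrum", "read_cd_spectrum",
    "write_composition", "read_composition",
]

_FMT = "%.17g"


def _write_table(path, columns: dict[str, np.ndarray], meta: dict | None = None):
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write(",".join(columns) + "\n")
        arrays = list(columns.values())
        for row in zip(*arrays):
            fh.write(",".join(_FMT % x for x in row) + "\n")


def _read_table(path) -> tuple[pd.DataFrame, dict[str, str]]:
    path = Path(path)
    meta: dict[str, str] = {}
    skip = 0
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            skip += 1
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    return df, meta


# -- THz dielectric spectra --------------------------------------------------

def write_dielectric_spectrum(path, spec: DielectricSpectrum) -> None:
    cols = {"freq_THz": spec.grid.values,
            "eps_real": spec.eps_real, "eps_imag": spec.eps_imag}
    if spec.sigma is not None:
        cols["sigma"] = spec.sigma
    _write_table(path, cols)


def read_dielectric_spectrum(path) -> DielectricSpectrum:
    df, _ = _read_table(path)
    for col in ("freq_THz", "eps_real", "eps_imag"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    return DielectricSpectrum(
        FrequencyGrid(df["freq_THz"].to_numpy()),
        df["eps_real"].to_numpy(), df["eps_imag"].to_numpy(),
        df["sigma"].to_numpy() if "sigma" in df.columns else None,
    )


# -- DSC thermograms ---------------------------------------------------------

def write_thermogram(path, tg: Thermogram) -> None:
    rate_per_s = tg.ramp_rate / 60.0
    time_s = np.abs(tg.temperature - tg.temperature[0]) / rate_per_s
    meta = {"ramp_rate_C_per_min": _FMT % tg.ramp_rate,
            "direction": tg.direction, "cycle_label": tg.cycle_label}
    if tg.sample_mass is not None:
        meta["sample_mass_mg"] = _FMT % tg.sample_mass
    _write_table(path, {"time_s": time_s, "temperature_C": tg.temperature,
                        "heat_flow_mW": tg.heat_flow}, meta)


def read_thermogram(path) -> Thermogram:
    df, meta = _read_table(path)
    mass = meta.get("sample_mass_mg")
    return Thermogram(
        temperature=df["temperature_C"].to_numpy(),
        heat_flow=df["heat_flow_mW"].to_numpy(),
        ramp_rate=float(meta["ramp_rate_C_per_min"]),
        direction=meta["direction"],
        cycle_label=meta.get("cycle_label", ""),
        sample_mass=float(mass) if mass is not None else None,
    )


# -- FTIR spectra ------------------------------------------------------------

def write_ir_spectrum(path, spec: IRSpectrum) -> None:
    meta = {}
    if spec.temperature is not None:
        meta["temperature_C"] = _FMT % spec.temperature
    _write_table(path, {"wavenumber_cm1": spec.wavenumber,
                        "absorbance": spec.absorbance}, meta)


def read_ir_spectrum(path) -> IRSpectrum:
    df, meta = _read_table(path)
    t = meta.get("temperature_C")
    return IRSpectrum(df["wavenumber_cm1"].to_numpy(), df["absorbance"].to_numpy(),
                      temperature=float(t) if t is not None else None)


# -- CD spectra --------------------------------------------------------------

def write_cd_spectrum(path, spec: CDSpectrum) -> None:
    meta = {"path_length_cm": _FMT % spec.path_length,
            "molar_concentration_M": _FMT % spec.molar_concentration,
            "n_residues": str(spec.n_residues)}
    if spec.temperature is not None:
        meta["temperature_C"] = _FMT % spec.temperature
    _write_table(path, {"wavelength_nm": spec.wavelength,
                        "ellipticity_mdeg": spec.ellipticity}, meta)


def read_cd_spectrum(path) -> CDSpectrum:
    df, meta = _read_table(path)
    t = meta.get("temperature_C")
    return CDSpectrum(
        df["wavelength_nm"].to_numpy(), df["ellipticity_mdeg"].to_numpy(),
        path_length=float(meta["path_length_cm"]),
        molar_concentration=float(meta["molar_concentration_M"]),
        n_residues=int(meta["n_residues"]),
        temperature=float(t) if t is not None else None,
    )


# -- composition -------------------------------------------------------------

def write_composition(path, comp: SolutionComposition) -> None:
    obj = {
        "solute_wt_fraction": comp.solute_wt_fraction,
        "solute_molar_mass": comp.solute_molar_mass,
        "water_molar_mass": comp.water_molar_mass,
        "density_series": [list(p) for p in comp.density_series],
        "partial_specific_volume": comp.partial_specific_volume,
    }
    Path(path).write_text(json.dumps(obj, indent=2), encoding="utf-8")


def read_composition(path) -> SolutionComposition:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    return SolutionComposition(
        solute_wt_fraction=obj["solute_wt_fraction"],
        solute_molar_mass=obj["solute_molar_mass"],
        water_molar_mass=obj.get("water_molar_mass", 18.015),
        density_series=tuple(tuple(p) for p in obj.get("density_series", ())),
        partial_specific_volume=obj.get("partial_specific_volume", 0.735),
    )
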