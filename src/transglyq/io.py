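"""CSV/JSON readers and writers for the package's external interfaces.

All CSV dialects are comma-separated UTF-8 with a mandatory header row.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .hplc import Peak, PeakTable
from .spectro import ReferenceSet, Spectrum, TitrationSeries

__all__ = [
    "read_spectrum_csv",
    "read_references_csv",
    "write_references_csv",
    "read_titration_csv",
    "write_titration_csv",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_peak_table_csv",
    "write_peak_table_csv",
    "read_systems_csv",
    "load_table1",
    "write_json",
]

SYSTEMS_COLUMNS = ["label", "donor", "acceptor", "D0_mM", "B0_mM", "P0_mM"]
SYSTEMS_OPTIONAL = ["K_donor", "K_product", "observed_conversion_pct"]


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_spectrum_csv(path) -> Spectrum:
    """Read a spectrum CSV with columns (wavelength_nm, absorbance_au)."""
    df = pd.read_csv(path)
    _require_columns(df, ["wavelength_nm", "absorbance_au"], path)
    return Spectrum(df["wavelength_nm"].to_numpy(), df["absorbance_au"].to_numpy())


def read_references_csv(path) -> ReferenceSet:
    """Read a reference set CSV: wavelength_nm plus one column per reference."""
    df = pd.read_csv(path)
    _require_columns(df, ["wavelength_nm"], path)
    names = [c for c in df.columns if c != "wavelength_nm"]
    if len(names) < 2:
        raise ValueError(f"{path}: need at least two reference columns")
    return ReferenceSet(
        names=tuple(names),
        wavelengths=df["wavelength_nm"].to_numpy(),
        matrix=df[names].to_numpy(),
    )


def write_references_csv(refs: ReferenceSet, path) -> None:
    df = pd.DataFrame({"wavelength_nm": refs.wavelengths})
    for i, name in enumerate(refs.names):
        df[name] = refs.matrix[:, i]
    df.to_csv(path, index=False)


def read_titration_csv(path) -> TitrationSeries:
    """Read a long-format titration CSV (pH, wavelength_nm, absorbance_au)."""
    df = pd.read_csv(path)
    _require_columns(df, ["pH", "wavelength_nm", "absorbance_au"], path)
    ph_values, spectra = [], []
    for ph, group in df.groupby("pH", sort=True):
        group = group.sort_values("wavelength_nm")
        ph_values.append(float(ph))
        spectra.append(
            Spectrum(
                group["wavelength_nm"].to_numpy(),
                group["absorbance_au"].to_numpy(),
            )
        )
    return TitrationSeries(pH=np.array(ph_values), spectra=tuple(spectra))


def write_titration_csv(series: TitrationSeries, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "pH": ph,
                "wavelength_nm": spec.wavelengths,
                "absorbance_au": spec.absorbances,
            }
        )
        for ph, spec in zip(series.pH, series.spectra)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_timecourse_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a product time course CSV (time_min, product_mM)."""
    df = pd.read_csv(path)
    _require_columns(df, ["time_min", "product_mM"], path)
    df = df.sort_values("time_min")
    return df["time_min"].to_numpy(), df["product_mM"].to_numpy()


def write_timecourse_csv(times, product_mM, path) -> None:
    pd.DataFrame({"time_min": times, "product_mM": product_mM}).to_csv(
        path, index=False
    )


def read_peak_table_csv(path, quant_wavelength: float = 307.0) -> PeakTable:
    """Read an integrated peak table CSV (rt_min, wavelength_nm, area)."""
    df = pd.read_csv(path)
    _require_columns(df, ["rt_min", "wavelength_nm", "area"], path)
    peaks = tuple(
        Peak(
            retention_time=float(row.rt_min),
            wavelength=float(row.wavelength_nm),
            area=float(row.area),
        )
        for row in df.itertuples()
    )
    return PeakTable(peaks=peaks, quant_wavelength=quant_wavelength)


def write_peak_table_csv(table: PeakTable, path) -> None:
    pd.DataFrame(
        {
            "rt_min": [p.retention_time for p in table.peaks],
            "wavelength_nm": [p.wavelength for p in table.peaks],
            "area": [p.area for p in table.peaks],
            "compound": [p.compound or "" for p in table.peaks],
        }
    ).to_csv(path, index=False)


def read_systems_csv(path) -> pd.DataFrame:
    """Read a transglycosylation systems table.

    Required columns: label, donor, acceptor, D0_mM, B0_mM, P0_mM.
    Optional: K_donor, K_product, observed_conversion_pct.
    """
    df = pd.read_csv(path)
    _require_columns(df, SYSTEMS_COLUMNS, path)
    for col in SYSTEMS_OPTIONAL:
        if col not in df.columns:
            df[col] = np.nan
    return df


def load_table1() -> pd.DataFrame:
    """The packaged analytical transglycosylation table: fivefold sugar-donor
    excess conversions and product phosphorolysis constants for the four
    2-selenopyrimidine nucleosides."""
    with resources.files("transglyq.data").joinpath("table1.csv").open("rb") as fh:
        df = pd.read_csv(fh)
    for col in SYSTEMS_OPTIONAL:
        if col not in df.columns:
            df[col] = np.nan
    return df


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
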