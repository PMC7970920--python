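"""CSV dialects for titration series, peak tables, chromatograms and calibrations.

All formats are plain UTF-8 CSV.  Titration files carry their scalar metadata
(mode, fixed concentration, A0, A_inf, temperature) as leading ``# key = value``
comment lines ahead of the two data columns.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .complexation import TitrationSeries
from .fingerprint import Chromatogram, PeakRecord, PeakTable

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_peak_table_csv",
    "write_peak_table_csv",
    "read_chromatogram_csv",
    "write_chromatogram_csv",
    "read_calibration_csv",
    "write_similarity_matrix_csv",
]

_TITRATION_COLUMNS = ["varied_conc_mol_per_L", "absorbance"]


def write_titration_csv(series: TitrationSeries, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# mode = {series.mode}",
        f"# fixed_conc_mol_per_L = {float(series.fixed_conc)!r}",
        f"# temperature_K = {float(series.temperature)!r}",
    ]
    if series.A0 is not None:
        lines.append(f"# A0 = {float(series.A0)!r}")
    if series.A_inf is not None:
        lines.append(f"# A_inf = {float(series.A_inf)!r}")
    df = pd.DataFrame({
        _TITRATION_COLUMNS[0]: series.varied_concs,
        _TITRATION_COLUMNS[1]: series.absorbances,
    })
    path.write_text("\n".join(lines) + "\n" + df.to_csv(index=False))


def read_titration_csv(path: str | Path) -> TitrationSeries:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
    required = {"mode", "fixed_conc_mol_per_L", "temperature_K"}
    missing = required - meta.keys()
    if missing:
        raise ValueError(f"{path}: missing metadata rows: {sorted(missing)}")
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != _TITRATION_COLUMNS:
        raise ValueError(f"{path}: expected columns {_TITRATION_COLUMNS}, got {list(df.columns)}")
    return TitrationSeries(
        mode=meta["mode"],
        fixed_conc=float(meta["fixed_conc_mol_per_L"]),
        varied_concs=df[_TITRATION_COLUMNS[0]].to_numpy(),
        absorbances=df[_TITRATION_COLUMNS[1]].to_numpy(),
        A0=float(meta["A0"]) if "A0" in meta else None,
        A_inf=float(meta["A_inf"]) if "A_inf" in meta else None,
        temperature=float(meta["temperature_K"]),
    )


def write_peak_table_csv(table: PeakTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_peak_table_csv(path: str | Path, batch_id: str | None = None) -> PeakTable:
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["peak_id", "t_r_min", "area_mvs"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    peaks = [PeakRecord(int(r.peak_id), float(r.t_r_min), float(r.area_mvs))
             for r in df.itertuples()]
    return PeakTable(batch_id=batch_id or path.stem, peaks=peaks)


def write_chromatogram_csv(chrom: Chromatogram, path: str | Path) -> None:
    pd.DataFrame({"time_min": chrom.times, "intensity": chrom.intensities}).to_csv(
        path, index=False)


def read_chromatogram_csv(path: str | Path) -> Chromatogram:
    df = pd.read_csv(path)
    expected = ["time_min", "intensity"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return Chromatogram(times=df["time_min"].to_numpy(),
                        intensities=df["intensity"].to_numpy())


def read_calibration_csv(path: str | Path) -> pd.DataFrame:
    """Calibration points: columns analyte (optional), conc_ug_per_ml, area."""
    df = pd.read_csv(path)
    needed = {"conc_ug_per_ml", "area"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(needed)}, got {list(df.columns)}")
    if "analyte" not in df.columns:
        df = df.assign(analyte="analyte")
    return df


def write_similarity_matrix_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.round(3).to_csv(path, index_label="batch")
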