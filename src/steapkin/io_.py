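"""CSV readers/writers for all dataset dialects.

Dialects (all plain CSV, one ``# provenance: {json}`` comment line first):

* rapid scan — header ``time_s,<wavelength>,...``, one row per time point;
* time course — ``time_s,absorbance_AU``;
* titration — ``substrate_uM,k_obs_per_s``;
* BLI — long format ``phase,analyte_uM,time_s,response``;
* species library — ``wavelength_nm`` first column, one epsilon column per
  species;
* trajectory — ``time_s`` first column, one column per species.

Writers emit floats at full precision (%.17g) so write-then-read is the
identity to better than 1e-12; readers validate structure and report the
offending line/column on failure.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import ConcentrationTrajectory
from .spectral import SpeciesLibrary, SpeciesSpectrum
from .synth import BLISeries, RapidScanDataset, TimeCourse, TitrationTable

__all__ = [
    "write_rapid_scan", "read_rapid_scan",
    "write_timecourse", "read_timecourse",
    "write_titration", "read_titration",
    "write_bli", "read_bli",
    "write_species_library", "read_species_library",
    "write_trajectory",
]

_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FMT % x


class DatasetFormatError(ValueError):
    """Malformed dataset file; message carries line/column diagnostics."""


def _provenance_line(prov: dict) -> str:
    return "# provenance: " + json.dumps(prov, sort_keys=True, default=str)


def _read_provenance(path: Path) -> dict:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# provenance:"):
        try:
            return json.loads(first[len("# provenance:"):])
        except json.JSONDecodeError:
            return {}
    return {}


def _read_numeric_csv(path: Path) -> pd.DataFrame:
    """CSV -> numeric DataFrame; non-numeric cells reported by row/column."""
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    out = {}
    for col in df.columns:
        missing = df[col].isna()
        if missing.any():
            row = int(np.flatnonzero(missing)[0])
            raise DatasetFormatError(
                f"{path}: missing cell in column {col!r}, data row {row + 1}"
            )
        values = np.empty(len(df), dtype=float)
        # float() is correctly rounded; pandas' fast parser is not
        for i, cell in enumerate(df[col]):
            try:
                values[i] = float(cell)
            except ValueError:
                raise DatasetFormatError(
                    f"{path}: non-numeric cell {cell!r} in column {col!r},"
                    f" data row {i + 1}"
                ) from None
        out[col] = values
    return pd.DataFrame(out)


def _check_time(t: np.ndarray, path: Path) -> None:
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise DatasetFormatError(
            f"{path}: time not strictly increasing at data row {bad[0] + 2}"
        )


# --- rapid scan -------------------------------------------------------------

def write_rapid_scan(ds: RapidScanDataset, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_line(ds.provenance) + "\n")
        fh.write("time_s," + ",".join(_fmt(l) for l in ds.grid_nm) + "\n")
        for ti, row in zip(ds.time_s, ds.absorbance):
            fh.write(_fmt(ti) + "," + ",".join(_fmt(a) for a in row) + "\n")


def read_rapid_scan(path) -> RapidScanDataset:
    path = Path(path)
    prov = _read_provenance(path)
    df = _read_numeric_csv(path)
    if df.columns[0] != "time_s":
        raise DatasetFormatError(f"{path}: first column must be 'time_s',"
                                 f" got {df.columns[0]!r}")
    try:
        grid = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise DatasetFormatError(
            f"{path}: wavelength headers must be numeric ({exc})") from None
    t = df.iloc[:, 0].to_numpy()
    _check_time(t, path)
    return RapidScanDataset(t, grid, df.iloc[:, 1:].to_numpy(),
                            provenance=prov)


# --- time course ------------------------------------------------------------

def write_timecourse(tc: TimeCourse, path) -> None:
    path = Path(path)
    prov = dict(tc.provenance)
    prov.setdefault("wavelength_nm", tc.wavelength_nm)
    with open(path, "w") as fh:
        fh.write(_provenance_line(prov) + "\n")
        fh.write("time_s,absorbance_AU\n")
        for ti, ai in zip(tc.time_s, tc.absorbance):
            fh.write(f"{_fmt(ti)},{_fmt(ai)}\n")


def read_timecourse(path) -> TimeCourse:
    path = Path(path)
    prov = _read_provenance(path)
    df = _read_numeric_csv(path)
    if list(df.columns) != ["time_s", "absorbance_AU"]:
        raise DatasetFormatError(
            f"{path}: expected header 'time_s,absorbance_AU', got"
            f" {list(df.columns)}")
    t = df["time_s"].to_numpy()
    _check_time(t, path)
    return TimeCourse(float(prov.get("wavelength_nm", np.nan)), t,
                      df["absorbance_AU"].to_numpy(), provenance=prov)


# --- titration ---------------------------------------------------------------

def write_titration(table: TitrationTable, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_line(table.provenance) + "\n")
        fh.write("substrate_uM,k_obs_per_s\n")
        for s, k in zip(table.substrate_uM, table.k_obs):
            fh.write(f"{_fmt(s)},{_fmt(k)}\n")


def read_titration(path) -> TitrationTable:
    path = Path(path)
    prov = _read_provenance(path)
    df = _read_numeric_csv(path)
    if list(df.columns) != ["substrate_uM", "k_obs_per_s"]:
        raise DatasetFormatError(
            f"{path}: expected header 'substrate_uM,k_obs_per_s', got"
            f" {list(df.columns)}")
    return TitrationTable(df["substrate_uM"].to_numpy(),
                          df["k_obs_per_s"].to_numpy(), prov)


# --- BLI ---------------------------------------------------------------------

def write_bli(series: BLISeries, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_line(series.provenance) + "\n")
        fh.write("phase,analyte_uM,time_s,response\n")
        for phase, t, R in (("association", series.time_assoc_s,
                             series.association),
                            ("dissociation", series.time_dissoc_s,
                             series.dissociation)):
            for j, conc in enumerate(series.analyte_uM):
                for ti, ri in zip(t, R[:, j]):
                    fh.write(f"{phase},{_fmt(conc)},{_fmt(ti)},{_fmt(ri)}\n")


def read_bli(path) -> BLISeries:
    path = Path(path)
    prov = _read_provenance(path)
    df = pd.read_csv(path, comment="#", dtype=str)
    expected = ["phase", "analyte_uM", "time_s", "response"]
    if list(df.columns) != expected:
        raise DatasetFormatError(f"{path}: expected header {expected}, got"
                                 f" {list(df.columns)}")
    for col in expected[1:]:
        try:
            df[col] = np.array([float(v) for v in df[col]])
        except (TypeError, ValueError) as exc:
            raise DatasetFormatError(
                f"{path}: non-numeric cell in column {col!r} ({exc})"
            ) from None
    conc = np.sort(np.unique(df["analyte_uM"].to_numpy()))[::-1]

    def matrix(phase: str) -> tuple[np.ndarray, np.ndarray]:
        sub = df[df["phase"] == phase]
        t = np.unique(sub["time_s"].to_numpy())
        R = np.empty((t.size, conc.size))
        for j, c in enumerate(conc):
            block = sub[sub["analyte_uM"] == c].sort_values("time_s")
            if block.shape[0] != t.size:
                raise DatasetFormatError(
                    f"{path}: ragged {phase} block for analyte {c} uM")
            R[:, j] = block["response"].to_numpy()
        return t, R

    t_a, assoc = matrix("association")
    t_d, dissoc = matrix("dissociation")
    req = assoc[-1, :]
    return BLISeries(conc, t_a, assoc, t_d, dissoc, req, prov)


# --- species library & trajectories -----------------------------------------

def write_species_library(lib: SpeciesLibrary, path) -> None:
    path = Path(path)
    names = lib.names
    E = lib.epsilon_matrix(names)
    meta = {"redox_state": {n: lib[n].redox_state for n in names}}
    with open(path, "w") as fh:
        fh.write(_provenance_line(meta) + "\n")
        fh.write("wavelength_nm," + ",".join(names) + "\n")
        for lam, row in zip(lib.grid_nm, E):
            fh.write(_fmt(lam) + "," + ",".join(_fmt(e) for e in row) + "\n")


def read_species_library(path) -> SpeciesLibrary:
    path = Path(path)
    prov = _read_provenance(path)
    df = _read_numeric_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise DatasetFormatError(
            f"{path}: first column must be 'wavelength_nm'")
    grid = df["wavelength_nm"].to_numpy()
    states = prov.get("redox_state", {})
    lib = SpeciesLibrary()
    for name in df.columns[1:]:
        lib.add(SpeciesSpectrum(name=name,
                                redox_state=states.get(name, "other"),
                                grid_nm=grid,
                                epsilon=df[name].to_numpy()))
    return lib


def write_trajectory(traj: ConcentrationTrajectory, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_s," + ",".join(traj.species_names) + "\n")
        for ti, row in zip(traj.time_s, traj.concentrations):
            fh.write(_fmt(ti) + "," + ",".join(_fmt(c) for c in row) + "\n")
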