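"""Temperature-dependent bulge penalty tables (ΔΔG° in kcal/mol).

Three parameter classes cover every sliding bulge: 36 non-slide bulges
(``aTc``), 36 two-slide composites (``cTTc``) and the 4 interior triplet
states (``tTt``).  Measured values live on a dense Celsius grid
(canonically the 43 integer temperatures 25–67 °C); off-grid temperatures
are linearly interpolated inside the grid and extrapolated with a van't
Hoff line (ΔΔG°(T) = ΔΔH° − T·ΔΔS°, T in kelvin) outside it, with a
warning.  A seeded synthetic generator produces complete, reproducible
stand-in tables so the package builds and tests without any measured data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .motif_model import BASES, MotifError, parse_motif

KELVIN = 273.15

DEFAULT_GRID = tuple(float(t) for t in range(25, 68))

MOTIF_CLASSES = ("non_slide", "two_slide", "triplet")

#: Fixture ΔΔG°(37 °C) ranges (kcal/mol) per class.  Chosen to span the
#: qualitative behaviour of measured single-base bulge penalties: one to a
#: few kcal/mol for isolated bulges, with triplet states allowed a wider
#: spread (G triplets are distinctly stabilising-friendly, A triplets can
#: carry a much larger penalty at low temperature).
DEFAULT_ENERGY_RANGE = {
    "non_slide": (1.0, 3.5),
    "two_slide": (1.0, 3.5),
    "triplet": (1.0, 6.0),
}

#: Fixture ΔΔG° temperature slope range in kcal/mol per °C.  Mostly
#: negative: measured penalties, purine bulges especially, relax as
#: temperature rises.
DEFAULT_SLOPE_RANGE = (-0.04, 0.01)


class TableError(ValueError):
    """Raised for malformed, inconsistent or incomplete parameter input."""


class ExtrapolationWarning(UserWarning):
    """Emitted whenever a query temperature lies outside the measured grid."""


def class_keys(motif_class: str) -> list[str]:
    """All valid motif keys of a class, sorted: 36, 36 or 4 entries."""
    if motif_class == "non_slide":
        return sorted(
            f"{f5.lower()}{b}{f3.lower()}"
            for b in BASES
            for f5 in BASES
            if f5 != b
            for f3 in BASES
            if f3 != b
        )
    if motif_class == "two_slide":
        return sorted(
            f"{f5.lower()}{b}{b}{f3.lower()}"
            for b in BASES
            for f5 in BASES
            if f5 != b
            for f3 in BASES
            if f3 != b
        )
    if motif_class == "triplet":
        return [f"{b.lower()}{b}{b.lower()}" for b in BASES]
    raise TableError(f"unknown motif class {motif_class!r}")


def _validate_key(key: str, motif_class: str) -> str:
    if motif_class == "triplet":
        if key not in class_keys("triplet"):
            raise TableError(
                f"invalid triplet key {key!r}: expected one of aAa, cCc, gGg, tTt"
            )
        return key
    try:
        motif = parse_motif(key)
    except MotifError as exc:
        raise TableError(f"invalid motif key {key!r} for {motif_class}: {exc}") from exc
    want_n = 1 if motif_class == "non_slide" else 2
    if motif.n != want_n:
        raise TableError(
            f"key {key!r} has repeat count {motif.n}, but class {motif_class} "
            f"requires {want_n}"
        )
    return key


@dataclass(frozen=True)
class VantHoffFit:
    """Linear free-energy model ΔΔG°(T) = ddH − T·ddS (T in kelvin)."""

    ddH: float  # kcal/mol
    ddS: float  # kcal/(mol K)
    rmse: float  # kcal/mol

    def __call__(self, temperature_C: float | np.ndarray) -> float | np.ndarray:
        return self.ddH - (np.asarray(temperature_C, dtype=float) + KELVIN) * self.ddS


class EnergyTable:
    """ΔΔG°(motif, T) lookup for one motif class.

    Internally a motif-by-temperature matrix (NaN marks missing cells);
    temperatures are stored in °C and strictly increasing.
    """

    def __init__(self, motif_class: str, data: pd.DataFrame):
        if motif_class not in MOTIF_CLASSES:
            raise TableError(f"unknown motif class {motif_class!r}")
        grid = np.asarray(data.columns, dtype=float)
        if grid.size and np.any(np.diff(grid) <= 0):
            raise TableError("temperature grid must be strictly increasing")
        finite = data.to_numpy(dtype=float)
        if np.any(np.isinf(finite)):
            raise TableError("energies must be finite")
        self.motif_class = motif_class
        self.data = data.astype(float)
        self.data.columns = grid

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(
        cls, motif_class: str, records: "pd.DataFrame"
    ) -> "EnergyTable":
        """Build from long-form rows (motif, temperature_C, ddG_kcal_mol)."""
        required = {"motif", "temperature_C", "ddG_kcal_mol"}
        if not required.issubset(records.columns):
            raise TableError(
                f"missing columns {sorted(required - set(records.columns))}; "
                "expected header motif,temperature_C,ddG_kcal_mol"
            )
        for key in records["motif"].unique():
            _validate_key(str(key), motif_class)
        temps = pd.to_numeric(records["temperature_C"], errors="coerce")
        vals = pd.to_numeric(records["ddG_kcal_mol"], errors="coerce")
        if temps.isna().any():
            raise TableError("non-numeric temperature_C value")
        if vals.isna().any():
            raise TableError("non-numeric ddG_kcal_mol value")
        dup = records.duplicated(subset=["motif", "temperature_C"])
        if dup.any():
            row = records[dup].iloc[0]
            raise TableError(
                f"duplicate cell ({row['motif']}, {row['temperature_C']} degC)"
            )
        frame = pd.DataFrame(
            {"motif": records["motif"].astype(str), "T": temps, "g": vals}
        )
        wide = frame.pivot(index="motif", columns="T", values="g").sort_index()
        wide = wide.reindex(sorted(wide.columns), axis=1)
        return cls(motif_class, wide)

    # -- introspection ------------------------------------------------

    @property
    def grid(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=float)

    @property
    def motifs(self) -> list[str]:
        return list(self.data.index)

    def completeness(self) -> dict:
        """Report missing motifs and missing (motif, T) cells."""
        expected = class_keys(self.motif_class)
        missing_motifs = sorted(set(expected) - set(self.data.index))
        missing_cells = []
        for key in self.data.index:
            row = self.data.loc[key]
            for t in self.data.columns[row.isna()]:
                missing_cells.append((key, float(t)))
        n_present = int(self.data.notna().sum().sum())
        return {
            "motif_class": self.motif_class,
            "expected_motifs": len(expected),
            "present_motifs": len(self.data.index),
            "missing_motifs": missing_motifs,
            "missing_cells": missing_cells,
            "n_cells": n_present,
        }

    @property
    def is_complete(self) -> bool:
        rep = self.completeness()
        return not rep["missing_motifs"] and not rep["missing_cells"]

    def _series(self, motif_key: str) -> tuple[np.ndarray, np.ndarray]:
        if motif_key not in self.data.index:
            raise TableError(
                f"unknown motif {motif_key!r} in {self.motif_class} table"
            )
        row = self.data.loc[motif_key]
        mask = row.notna().to_numpy()
        return self.grid[mask], row.to_numpy(dtype=float)[mask]

    # -- evaluation ---------------------------------------------------

    def ddg_at(
        self, motif_key: str, temperature_C: float, extrapolate: bool = True
    ) -> float:
        """ΔΔG° at an arbitrary temperature.

        Exact at grid points, piecewise-linear between them; outside the
        covered range a van't Hoff line fitted to the motif's grid values
        is used and an :class:`ExtrapolationWarning` is issued.
        """
        temps, vals = self._series(motif_key)
        if temps.size == 0:
            raise TableError(f"no data for motif {motif_key!r}")
        t = float(temperature_C)
        if temps[0] <= t <= temps[-1]:
            return float(np.interp(t, temps, vals))
        if not extrapolate:
            raise TableError(
                f"temperature {t} degC outside grid "
                f"[{temps[0]}, {temps[-1]}] and extrapolation disabled"
            )
        fit = self.fit_vanthoff(motif_key)
        warnings.warn(
            f"{t} degC outside measured grid [{temps[0]}, {temps[-1]}] for "
            f"{motif_key}; using van't Hoff extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
        return float(fit(t))

    def fit_vanthoff(self, motif_key: str) -> VantHoffFit:
        """Least-squares ΔΔG° = ddH − T·ddS over the motif's grid values."""
        temps, vals = self._series(motif_key)
        if temps.size < 2:
            raise TableError(
                f"need >= 2 grid points to fit a van't Hoff line for {motif_key!r}"
            )
        t_k = temps + KELVIN
        slope, intercept = np.polyfit(t_k, vals, 1)
        resid = vals - (intercept + slope * t_k)
        rmse = float(np.sqrt(np.mean(resid**2)))
        return VantHoffFit(ddH=float(intercept), ddS=float(-slope), rmse=rmse)

    # -- serialization ------------------------------------------------

    def to_records(self) -> pd.DataFrame:
        long = (
            self.data.stack()
            .rename("ddG_kcal_mol")
            .reset_index()
            .rename(columns={"motif": "motif", "T": "temperature_C"})
        )
        long.columns = ["motif", "temperature_C", "ddG_kcal_mol"]
        return long

    def write_csv(self, path) -> None:
        self.to_records().to_csv(path, index=False, float_format="%.6f")

    def __eq__(self, other) -> bool:
        if not isinstance(other, EnergyTable):
            return NotImplemented
        return self.motif_class == other.motif_class and self.data.equals(other.data)


def load_table(path, motif_class: str) -> EnergyTable:
    """Read a parameter CSV (header ``motif,temperature_C,ddG_kcal_mol``)."""
    try:
        records = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TableError(f"malformed parameter CSV {path}: {exc}") from exc
    return EnergyTable.from_records(motif_class, records)


def write_table(table: EnergyTable, path) -> None:
    table.write_csv(path)


def ddg_at(table: EnergyTable, motif_key: str, temperature_C: float, **kw) -> float:
    return table.ddg_at(motif_key, temperature_C, **kw)


def fit_vanthoff(table: EnergyTable, motif_key: str) -> VantHoffFit:
    return table.fit_vanthoff(motif_key)


def synth_table(
    motif_class: str,
    seed: int,
    energy_range: tuple[float, float] | None = None,
    grid: tuple[float, ...] | None = None,
    slope_range: tuple[float, float] = DEFAULT_SLOPE_RANGE,
) -> EnergyTable:
    """Generate a complete synthetic table from seeded van't Hoff lines.

    Each motif receives ΔΔG°(37 °C) drawn uniformly from ``energy_range``
    and a temperature slope drawn uniformly from ``slope_range``; the cell
    values are the exact line evaluated on the grid.  Identical seeds give
    bit-identical tables.
    """
    if energy_range is None:
        energy_range = DEFAULT_ENERGY_RANGE[motif_class]
    lo, hi = energy_range
    if not (hi >= lo):
        raise TableError(f"empty energy range [{lo}, {hi}]")
    temps = np.asarray(grid if grid is not None else DEFAULT_GRID, dtype=float)
    if temps.size == 0:
        raise TableError("empty temperature grid")
    keys = class_keys(motif_class)
    rng = np.random.default_rng(seed)
    t_ref = 37.0 + KELVIN
    rows = {}
    for key in keys:  # sorted -> draw order is deterministic
        g37 = rng.uniform(lo, hi)
        slope = rng.uniform(*slope_range)  # d(ddG)/dT, per degree
        dds = -slope
        ddh = g37 + dds * t_ref
        rows[key] = ddh - dds * (temps + KELVIN)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=temps).sort_index()
    frame.index.name = "motif"
    return EnergyTable(motif_class, frame)


@dataclass
class ParameterSet:
    """The table trio needed to score any sliding bulge."""

    non_slide: EnergyTable
    two_slide: EnergyTable
    triplet: EnergyTable

    FILENAMES = {
        "non_slide": "non_slide.csv",
        "two_slide": "two_slide.csv",
        "triplet": "triplet.csv",
    }

    @classmethod
    def synthetic(cls, seed: int, grid=None) -> "ParameterSet":
        """Complete synthetic trio; sub-seeds derived from ``seed``."""
        return cls(
            non_slide=synth_table("non_slide", seed, grid=grid),
            two_slide=synth_table("two_slide", seed + 1, grid=grid),
            triplet=synth_table("triplet", seed + 2, grid=grid),
        )

    @classmethod
    def load_dir(cls, directory) -> "ParameterSet":
        d = Path(directory)
        tables = {}
        for cls_name, fname in cls.FILENAMES.items():
            path = d / fname
            if not path.exists():
                raise TableError(f"missing parameter file {path}")
            tables[cls_name] = load_table(path, cls_name)
        return cls(**tables)

    def save_dir(self, directory) -> list[Path]:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        written = []
        for cls_name, fname in self.FILENAMES.items():
            path = d / fname
            getattr(self, cls_name).write_csv(path)
            written.append(path)
        return written

    def table(self, motif_class: str) -> EnergyTable:
        if motif_class not in MOTIF_CLASSES:
            raise TableError(f"unknown motif class {motif_class!r}")
        return getattr(self, motif_class)
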