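"""Spectral data model and file I/O.

A :class:`SpectraSet` holds a wide-format spectral matrix: one row per
sample, one column per wavenumber (cm^-1) on a strictly increasing grid.
FT-NIR instruments typically export descending wavenumber order; files are
reordered to ascending at the boundary so that everything downstream can
assume one convention.

A :class:`ReferenceTable` holds the laboratory reference value of a single
trait (rind penetrometer resistance in N·mm^-2, or breaking force in N),
one scalar per sample. A :class:`WindowSet` is a list of closed wavenumber
intervals used for variable (wavelength-range) selection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DataError

REFLECTANCE = "reflectance"
ABSORBANCE = "absorbance"

TRAIT_UNITS = {"RPR": "N·mm⁻²", "breaking_force": "N"}


@dataclass
class SpectraSet:
    """Samples × wavenumbers intensity matrix on a strictly increasing grid."""

    sample_ids: list[str]
    grid: np.ndarray  # wavenumbers, cm^-1, strictly increasing
    values: np.ndarray  # shape (n_samples, n_wavenumbers)
    mode: str = REFLECTANCE

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.mode not in (REFLECTANCE, ABSORBANCE):
            raise DataError(f"unknown spectra mode {self.mode!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise DataError(f"duplicate sample ids: {dupes}")
        if self.n_samples < 1:
            raise DataError("SpectraSet requires at least one sample")
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise DataError("grid must be a 1-D array with >= 2 wavenumbers")
        if not np.all(np.diff(self.grid) > 0):
            raise DataError("wavenumber grid must be strictly increasing")
        if self.values.shape != (len(self.sample_ids), self.grid.size):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples × {self.grid.size} wavenumbers"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("spectra contain non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_wavenumbers(self) -> int:
        return int(self.grid.size)

    def subset(self, ids: list[str]) -> "SpectraSet":
        """Row-subset by sample id, in the order given."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise DataError(f"sample ids not present in SpectraSet: {missing[:5]}")
        rows = [index[s] for s in ids]
        return SpectraSet(list(ids), self.grid.copy(), self.values[rows], self.mode)


@dataclass
class ReferenceTable:
    """Per-sample laboratory reference values for one trait."""

    sample_ids: list[str]
    trait_name: str
    units: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids in ReferenceTable")
        if self.values.size != len(self.sample_ids):
            raise DataError("one reference value per sample id required")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise DataError("reference values must be finite and strictly positive")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, ids: list[str]) -> "ReferenceTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise DataError(f"sample ids not present in ReferenceTable: {missing[:5]}")
        rows = [index[s] for s in ids]
        return ReferenceTable(list(ids), self.trait_name, self.units, self.values[rows])


@dataclass
class WindowSet:
    """Closed wavenumber intervals [lo, hi] (cm^-1) for variable selection."""

    intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.intervals = [(float(lo), float(hi)) for lo, hi in self.intervals]
        if not self.intervals:
            raise DataError("WindowSet requires at least one interval")
        for lo, hi in self.intervals:
            if not lo < hi:
                raise DataError(f"interval bounds must satisfy lo < hi, got ({lo}, {hi})")
        ordered = sorted(self.intervals)
        for (_, hi_a), (lo_b, _) in zip(ordered, ordered[1:]):
            if lo_b <= hi_a:
                raise DataError("WindowSet intervals must be pairwise disjoint")

    def label(self) -> str:
        """Human-readable range label, e.g. '5669.7–9626.9, 10406.0–11200.6'."""
        return ", ".join(f"{lo:g}–{hi:g}" for lo, hi in sorted(self.intervals))

    def mask(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        m = np.zeros(grid.size, dtype=bool)
        for lo, hi in self.intervals:
            m |= (grid >= lo) & (grid <= hi)
        return m


def align(s: SpectraSet, ref: ReferenceTable) -> tuple[SpectraSet, ReferenceTable]:
    """Pair a spectra set with a reference table 1:1 on shared sample ids.

    Raises if either side holds ids the other lacks (the pairing must be
    exact, not an intersection, to avoid silent sample loss).
    """
    if set(s.sample_ids) != set(ref.sample_ids):
        only_s = sorted(set(s.sample_ids) - set(ref.sample_ids))
        only_r = sorted(set(ref.sample_ids) - set(s.sample_ids))
        raise DataError(
            f"spectra/reference id mismatch: {len(only_s)} only in spectra "
            f"{only_s[:3]}, {len(only_r)} only in reference {only_r[:3]}"
        )
    return s, ref.subset(s.sample_ids)


# ---------------------------------------------------------------------------
# File I/O (wide CSV for spectra; long CSV for references)
# ---------------------------------------------------------------------------

def read_spectra(path, mode: str = REFLECTANCE) -> SpectraSet:
    """Read a wide-format spectra CSV: first column sample id, header = wavenumbers.

    Descending instrument exports are reordered to an ascending grid.
    """
    # parse the header line directly: pandas mangles duplicate column names,
    # which would hide a malformed (repeated-wavenumber) grid
    with open(path, encoding="utf-8") as fh:
        header = next(csv.reader([fh.readline()]))
    if len(header) < 3:
        raise DataError(f"spectra CSV {path} needs a sample-id column and >= 2 wavenumbers")
    try:
        grid = np.array([float(c) for c in header[1:]])
    except ValueError as exc:
        raise DataError(f"non-numeric wavenumber in header of {path}: {exc}") from exc
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate sample ids in {path}: {dupes}")
    try:
        values = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise DataError(f"non-numeric intensity in {path}: {exc}") from exc
    if np.isnan(values).any():
        bad = df.index[np.isnan(values).any(axis=1)].tolist()
        raise DataError(f"non-numeric or missing intensities in {path} for samples {bad[:5]}")
    order = np.argsort(grid, kind="stable")
    grid, values = grid[order], values[:, order]
    if not np.all(np.diff(grid) > 0):
        raise DataError(f"malformed wavenumber grid in {path}: duplicates after sorting")
    return SpectraSet([str(i) for i in df.index], grid, values, mode)


def write_spectra(s: SpectraSet, path) -> None:
    df = pd.DataFrame(s.values, index=s.sample_ids, columns=[repr(float(v)) for v in s.grid])
    df.index.name = "sample_id"
    df.to_csv(path)


def read_reference(path, trait_name: str | None = None) -> ReferenceTable:
    """Read a reference CSV with columns sample_id,trait,value,units."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = {"sample_id", "trait", "value", "units"}
    if not required.issubset(df.columns):
        raise DataError(f"reference CSV needs columns {sorted(required)}, got {list(df.columns)}")
    if trait_name is not None:
        df = df[df["trait"] == trait_name]
        if df.empty:
            raise DataError(f"no rows for trait {trait_name!r} in {path}")
    traits = df["trait"].unique()
    if len(traits) != 1:
        raise DataError(f"reference CSV mixes traits {list(traits)}; pass trait_name")
    units = df["units"].unique()
    if len(units) != 1:
        raise DataError(f"inconsistent units for trait {traits[0]!r}: {list(units)}")
    return ReferenceTable(
        df["sample_id"].tolist(), str(traits[0]), str(units[0]), df["value"].to_numpy(float)
    )


def write_reference(ref: ReferenceTable, path) -> None:
    pd.DataFrame(
        {
            "sample_id": ref.sample_ids,
            "trait": ref.trait_name,
            "value": ref.values,
            "units": ref.units,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def to_absorbance(s: SpectraSet) -> SpectraSet:
    """Convert reflectance R to apparent absorbance log10(1/R)."""
    if s.mode != REFLECTANCE:
        raise DataError("to_absorbance expects a reflectance SpectraSet")
    if np.any(s.values <= 0):
        raise DataError("reflectance must be strictly positive to take log10(1/R)")
    return replace(s, values=np.log10(1.0 / s.values), mode=ABSORBANCE)


def to_reflectance(s: SpectraSet) -> SpectraSet:
    """Convert absorbance A to reflectance 10^-A (inverse of to_absorbance)."""
    if s.mode != ABSORBANCE:
        raise DataError("to_reflectance expects an absorbance SpectraSet")
    return replace(s, values=np.power(10.0, -s.values), mode=REFLECTANCE)


def apply_windows(s: SpectraSet, w: WindowSet) -> SpectraSet:
    """Keep exactly the grid points inside the closed intervals of ``w``.

    Column order is preserved; disjoint intervals yield concatenated blocks.
    """
    m = w.mask(s.grid)
    if not m.any():
        raise DataError(f"window selection {w.label()} matches no grid point")
    return replace(s, grid=s.grid[m], values=s.values[:, m])


def contiguous_blocks(grid: np.ndarray, rel_gap: float = 1.5) -> list[slice]:
    """Split a (possibly windowed) grid into contiguous runs.

    A gap larger than ``rel_gap`` × the median spacing starts a new block.
    Grid-dependent pretreatments (derivatives, detrending) operate per block.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        return [slice(0, grid.size)]
    d = np.diff(grid)
    cut = np.nonzero(d > rel_gap * np.median(d))[0]
    edges = [0, *(c + 1 for c in cut), grid.size]
    return [slice(a, b) for a, b in zip(edges, edges[1:])]
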