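"""Spectral pretreatment (scatter correction and derivatives).

The ten pretreatments offered before PLS calibration:

====== =====================================================================
NONE   identity
COE    constant offset elimination: subtract the per-spectrum minimum
SSL    straight-line subtraction: remove the least-squares line in wavenumber
SNV    standard normal variate: per-spectrum standardization (mean 0, SD 1)
MMN    min–max normalization to [0, 1]
MSC    multiplicative scatter correction against a reference spectrum
FD     Savitzky–Golay first derivative
SED    Savitzky–Golay second derivative
FD_SSL first derivative, then straight-line subtraction
FD_SNV first derivative, then SNV
FD_MSC first derivative, then MSC (reference on derivative spectra)
====== =====================================================================

Combination methods apply the derivative first and the scatter step on the
derivative spectra, matching the "FD + SNV" naming order. Only MSC carries
fitted state (the calibration-set mean spectrum, frozen so that prediction
never peeks at new-data statistics); everything else is stateless.

On multi-interval window selections, grid-dependent operators (FD/SED/SSL)
act per contiguous grid block — a derivative across a window gap would be
meaningless — while amplitude operators (COE/SNV/MMN/MSC) act on the whole
selected vector.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigError, DataError
from .spectra import SpectraSet, contiguous_blocks

METHODS = ("NONE", "COE", "SSL", "SNV", "MMN", "MSC", "FD", "SED", "FD_SSL", "FD_SNV", "FD_MSC")
_MSC_METHODS = ("MSC", "FD_MSC")
_DERIV_ORDER = {"FD": 1, "SED": 2, "FD_SSL": 1, "FD_SNV": 1, "FD_MSC": 1}


@dataclass
class PretreatmentSpec:
    """A pretreatment method plus its parameters and (for MSC) fitted state.

    Parameters
    ----------
    method : str
        One of :data:`METHODS`.
    sg_window : int
        Savitzky–Golay window length in points (odd, >= 5). Default 17.
    sg_polyorder : int
        Savitzky–Golay polynomial order (< sg_window). Default 2.
    msc_reference : ndarray or None
        Mean calibration spectrum (after the derivative step for FD_MSC);
        present only after :func:`fit_pretreatment`.
    """

    method: str = "NONE"
    sg_window: int = 17
    sg_polyorder: int = 2
    msc_reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"unknown pretreatment {self.method!r}; choose from {METHODS}")
        if self.sg_window % 2 == 0 or self.sg_window < 5:
            raise ConfigError(f"sg_window must be odd and >= 5, got {self.sg_window}")
        if self.sg_polyorder >= self.sg_window or self.sg_polyorder < 1:
            raise ConfigError("sg_polyorder must satisfy 1 <= polyorder < sg_window")
        if self.method == "SED" and self.sg_polyorder < 2:
            raise ConfigError("second derivative needs sg_polyorder >= 2")

    @property
    def needs_fit(self) -> bool:
        return self.method in _MSC_METHODS

    @property
    def is_fitted(self) -> bool:
        return (not self.needs_fit) or self.msc_reference is not None


# ---------------------------------------------------------------------------
# Per-spectrum operators
# ---------------------------------------------------------------------------

def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: (x - mean) / sample SD (n-1 denominator)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise DataError("SNV requires at least 3 points")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DataError("SNV undefined for a zero-variance spectrum")
    return (x - x.mean()) / sd


def msc(x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction: regress x ~ a + b·reference, return (x-a)/b."""
    x = np.asarray(x, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if x.shape != reference.shape:
        raise DataError("MSC spectrum and reference must have the same length")
    r = reference - reference.mean()
    denom = float(r @ r)
    if denom == 0:
        raise DataError("MSC reference spectrum has zero variance")
    b = float(r @ (x - x.mean())) / denom
    if abs(b) < 1e-12:
        raise DataError("degenerate MSC scatter fit (|slope| < 1e-12)")
    a = x.mean() - b * reference.mean()
    return (x - a) / b


def coe(x: np.ndarray) -> np.ndarray:
    """Constant offset elimination: subtract the minimum."""
    x = np.asarray(x, dtype=float)
    return x - x.min()


def ssl(x: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Straight-line subtraction: residual of the least-squares line in wavenumber."""
    x = np.asarray(x, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if x.shape != grid.shape:
        raise DataError("SSL spectrum and grid must have the same length")
    g = grid - grid.mean()
    slope = float(g @ (x - x.mean())) / float(g @ g)
    return x - x.mean() - slope * g


def mmn(x: np.ndarray) -> np.ndarray:
    """Min–max normalization to [0, 1]."""
    x = np.asarray(x, dtype=float)
    span = x.max() - x.min()
    if span == 0:
        raise DataError("min–max normalization undefined for a constant spectrum")
    return (x - x.min()) / span


def sg_derivative(
    x: np.ndarray, grid: np.ndarray, order: int, window: int = 17, polyorder: int = 2
) -> np.ndarray:
    """Savitzky–Golay derivative in units per cm^-1 on a uniform grid.

    Exact for polynomials of degree <= polyorder; edges are handled by a
    polynomial fit on the boundary window so grid length is preserved.
    """
    x = np.asarray(x, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if order not in (1, 2):
        raise ConfigError("derivative order must be 1 or 2")
    if polyorder < order:
        raise ConfigError("sg_polyorder must be >= derivative order")
    if window > x.shape[-1]:
        raise DataError(
            f"Savitzky–Golay window ({window}) exceeds spectrum length ({x.shape[-1]})"
        )
    d = np.diff(grid)
    if d.size == 0 or np.any(np.abs(d - d[0]) > 1e-6 * abs(d[0])):
        raise DataError("Savitzky–Golay derivative requires a uniform wavenumber grid")
    return savgol_filter(
        x, window_length=window, polyorder=polyorder, deriv=order, delta=d[0],
        axis=-1, mode="interp",
    )


# ---------------------------------------------------------------------------
# Fitting and batch application
# ---------------------------------------------------------------------------

def _derivative_step(values: np.ndarray, grid: np.ndarray, spec: PretreatmentSpec) -> np.ndarray:
    order = _DERIV_ORDER[spec.method]
    out = np.empty_like(values)
    for blk in contiguous_blocks(grid):
        out[:, blk] = sg_derivative(
            values[:, blk], grid[blk], order, spec.sg_window, spec.sg_polyorder
        )
    return out


def fit_pretreatment(s: SpectraSet, spec: PretreatmentSpec) -> PretreatmentSpec:
    """Freeze calibration statistics into the spec (MSC reference spectrum).

    For MSC-containing methods the reference is the column mean of the
    calibration spectra, taken after the derivative step for FD_MSC.
    Stateless methods are returned unchanged.
    """
    if not spec.needs_fit:
        return spec
    if s.n_samples < 2:
        raise DataError("MSC needs at least 2 calibration spectra to form a reference")
    values = s.values
    if spec.method == "FD_MSC":
        values = _derivative_step(values, s.grid, spec)
    return replace(spec, msc_reference=values.mean(axis=0))


def apply_pretreatment(s: SpectraSet, spec: PretreatmentSpec) -> SpectraSet:
    """Transform every spectrum per the spec; errors are annotated with sample id."""
    if not spec.is_fitted:
        raise DataError(f"{spec.method} must be fitted before application (MSC reference missing)")
    if spec.method == "NONE":
        return replace(s, values=s.values.copy())

    values = s.values
    if spec.method in _DERIV_ORDER:
        values = _derivative_step(values, s.grid, spec)
    scatter = {"FD_SSL": "SSL", "FD_SNV": "SNV", "FD_MSC": "MSC"}.get(spec.method, spec.method)

    if scatter in ("FD", "SED"):  # pure derivative, no scatter step
        return replace(s, values=values)

    out = np.empty_like(values)
    for i, sid in enumerate(s.sample_ids):
        try:
            if scatter == "SNV":
                out[i] = snv(values[i])
            elif scatter == "MSC":
                out[i] = msc(values[i], spec.msc_reference)
            elif scatter == "COE":
                out[i] = coe(values[i])
            elif scatter == "MMN":
                out[i] = mmn(values[i])
            elif scatter == "SSL":
                row = np.empty_like(values[i])
                for blk in contiguous_blocks(s.grid):
                    row[blk] = ssl(values[i, blk], s.grid[blk])
                out[i] = row
        except DataError as exc:
            raise DataError(f"pretreatment {spec.method} failed for sample {sid!r}: {exc}") from exc
    return replace(s, values=out)
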