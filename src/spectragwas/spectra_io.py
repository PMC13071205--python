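"""Reflectance calibration and spectra I/O on the canonical 1-nm grid.

Relative reflectance is computed from four radiance scans (white and black
references, leaf on white, optionally leaf on black) collected per sample:

    R(w) = panel(w) * (S_leaf(w) - S_black(w)) / (S_white(w) - S_black(w))

which removes both the background signal and additive instrument offsets.
When the leaf-on-black scan is supplied a dual-background variant subtracts
it from the leaf and white signals instead of the bare black reference.
Spectra tables are wide CSV: first column the sample id, remaining column
headers integer nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import WAVELENGTH_GRID

__all__ = [
    "RadianceScanSet",
    "CalibrationError",
    "CoverageError",
    "SpectraFormatError",
    "compute_reflectance",
    "clip_and_grid",
    "read_spectra",
    "write_spectra",
]


class CalibrationError(ValueError):
    """Raised when the reference scans cannot calibrate a band."""


class CoverageError(ValueError):
    """Raised when an input grid does not cover the requested range."""


class SpectraFormatError(ValueError):
    """Raised for malformed wide-format spectra tables."""


@dataclass
class RadianceScanSet:
    """Raw radiance scans for one sample, all on a shared wavelength grid."""

    wavelengths: np.ndarray
    white: np.ndarray
    black: np.ndarray
    leaf_on_white: np.ndarray
    leaf_on_black: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.wavelengths)
        for name in ("white", "black", "leaf_on_white"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"scan '{name}' length differs from wavelength grid")
        if self.leaf_on_black is not None and len(self.leaf_on_black) != n:
            raise ValueError("scan 'leaf_on_black' length differs from wavelength grid")


def compute_reflectance(
    scans: RadianceScanSet,
    panel_reflectance: np.ndarray | float = 1.0,
    dual_background: bool = False,
    clamp_negative: bool = False,
) -> pd.Series:
    """Relative reflectance from reference-corrected radiance scans.

    With ``dual_background`` (requires the leaf-on-black scan) the
    black-background leaf signal replaces the bare black reference in the
    numerator and denominator, correcting for light transmitted through the
    leaf and returned by the background.  Negative values are preserved for
    diagnostics unless ``clamp_negative`` is set.
    """
    wl = np.asarray(scans.wavelengths, dtype=float)
    white = np.asarray(scans.white, dtype=float)
    black = np.asarray(scans.black, dtype=float)
    leaf = np.asarray(scans.leaf_on_white, dtype=float)
    panel = np.broadcast_to(np.asarray(panel_reflectance, dtype=float), wl.shape)

    if dual_background:
        if scans.leaf_on_black is None:
            raise ValueError("dual_background requires the leaf_on_black scan")
        ref = np.asarray(scans.leaf_on_black, dtype=float)
    else:
        ref = black

    denom = white - ref
    bad = denom <= 0
    if np.any(bad):
        band = wl[np.argmax(bad)]
        raise CalibrationError(
            f"nonpositive white-minus-background signal at {band:g} nm"
        )
    r = panel * (leaf - ref) / denom
    if clamp_negative:
        r = np.clip(r, 0.0, None)
    return pd.Series(r, index=wl)


def clip_and_grid(
    spectrum: pd.Series,
    lo: int = 400,
    hi: int = 2500,
    step: int = 1,
) -> pd.Series:
    """Restrict to [lo, hi] nm and linearly interpolate onto the integer grid.

    Bands below ``lo`` (the low signal-to-noise 350-399 nm region) are
    dropped.  Idempotent on already-gridded input.
    """
    wl = np.asarray(spectrum.index, dtype=float)
    vals = np.asarray(spectrum.values, dtype=float)
    order = np.argsort(wl)
    wl, vals = wl[order], vals[order]
    if wl[0] > lo or wl[-1] < hi:
        raise CoverageError(
            f"input grid [{wl[0]:g}, {wl[-1]:g}] does not cover [{lo}, {hi}] nm"
        )
    grid = np.arange(lo, hi + 1, step)
    out = np.interp(grid, wl, vals)
    return pd.Series(out, index=grid)


def read_spectra(path) -> pd.DataFrame:
    """Read a wide spectra CSV into a samples x wavelengths DataFrame.

    Headers must be numeric nanometres, strictly increasing, with no gaps
    larger than implied by their own spacing being monotone; duplicate
    sample ids are rejected.
    """
    df = pd.read_csv(path, index_col=0)
    try:
        cols = [int(float(c)) for c in df.columns]
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavelength header in {path}") from exc
    if any(b <= a for a, b in zip(cols, cols[1:])):
        raise SpectraFormatError("wavelength headers must be strictly increasing")
    steps = set(b - a for a, b in zip(cols, cols[1:]))
    if len(steps) > 1:
        raise SpectraFormatError(
            f"wavelength grid not evenly spaced (missing bands?): steps {sorted(steps)}"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SpectraFormatError(f"duplicate sample id {dup!r}")
    df.columns = cols
    df.index.name = "sample"
    return df


def write_spectra(matrix: pd.DataFrame, path) -> None:
    """Write a samples x wavelengths DataFrame as wide CSV."""
    out = matrix.copy()
    out.index.name = "sample"
    out.to_csv(path)


def full_grid() -> np.ndarray:
    """The canonical 400-2500 nm analysis grid (2101 bands)."""
    return WAVELENGTH_GRID.copy()
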