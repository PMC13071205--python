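"""Spectral indices: band-ratio proxies for leaf pigments, water and dry matter.

Six indices are supported, each an exact evaluation at named integer
nanometre bands of a gridded reflectance spectrum:

======== ===========================================  ==========================
name     formula                                      feature
======== ===========================================  ==========================
NDWI     (R865 - R1614) / (R865 + R1614)              water content
CIre     R783 / R704 - 1                              chlorophyll (red edge)
CCI      (R560 - R664) / (R560 + R664)                chlorophyll/carotenoid
ARDSI_Cab (R750 - R730) / (R770 + R720)               chlorophyll a/b
ARDSI_Cw (R1360 - R1080) / (R1560 + R1240)            leaf water
ARDSI_Cm (R2200 - R1640) / (R2240 + R1720)            dry matter
======== ===========================================  ==========================

All are scale-invariant, and the normalized-difference forms (NDWI, CCI)
lie in [-1, 1] for nonnegative reflectance.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["INDEX_BANDS", "compute_index", "compute_indices"]

# (numerator pair, denominator pair); ratio-minus-one indices use a None marker
INDEX_BANDS: dict[str, dict] = {
    "NDWI": {"kind": "nd", "num": (865, 1614), "den": (865, 1614)},
    "CIre": {"kind": "ratio_minus_1", "num": (783, 704)},
    "CCI": {"kind": "nd", "num": (560, 664), "den": (560, 664)},
    "ARDSI_Cab": {"kind": "four_band", "num": (750, 730), "den": (770, 720)},
    "ARDSI_Cw": {"kind": "four_band", "num": (1360, 1080), "den": (1560, 1240)},
    "ARDSI_Cm": {"kind": "four_band", "num": (2200, 1640), "den": (2240, 1720)},
}


def _band(spectrum: pd.Series, nm: int) -> float:
    try:
        return float(spectrum.loc[nm])
    except KeyError as exc:
        raise ValueError(f"spectrum does not cover required band {nm} nm") from exc


def compute_index(spectrum: pd.Series, name: str) -> float:
    """Evaluate one named index on a 1-nm gridded reflectance spectrum.

    A zero denominator yields NaN (undefined value) rather than an error.
    """
    if name not in INDEX_BANDS:
        raise ValueError(f"unknown index {name!r}; choose from {list(INDEX_BANDS)}")
    spec = INDEX_BANDS[name]
    if spec["kind"] == "ratio_minus_1":
        a, b = spec["num"]
        denom = _band(spectrum, b)
        if denom == 0:
            return math.nan
        return _band(spectrum, a) / denom - 1.0
    a, b = spec["num"]
    c, d = spec["den"]
    num = _band(spectrum, a) - _band(spectrum, b)
    den = _band(spectrum, c) + _band(spectrum, d)
    if den == 0:
        return math.nan
    return num / den


def compute_indices(spectra: pd.DataFrame,
                    names: list[str] | None = None) -> pd.DataFrame:
    """Evaluate indices for every row of a samples x wavelengths matrix."""
    names = names or list(INDEX_BANDS)
    out = {}
    for name in names:
        out[name] = [compute_index(spectra.loc[s], name) for s in spectra.index]
    return pd.DataFrame(out, index=spectra.index)
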