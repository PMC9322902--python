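"""Peak detection on class-mean spectra and band-catalogue matching.

The band table mirrors the mid-IR assignments of the two flower-bud
classes: shared bands (saccharides, lipids, amide I, organic acids,
starch) plus the class-restricted bands — amide II at 1545, O-C-H 1400 and
saccharide skeletal 930 cm^-1 in class A; aromatic 1528 and saponin
781 cm^-1 in class B.  The report flags, per class-mean spectrum, whether
each catalogued band is detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import SpectraError, SpectrumSet

__all__ = ["BandTable", "default_band_table", "detect_peaks",
           "discriminating_report"]


@dataclass(frozen=True)
class BandTable:
    """Catalogue of (center, assignment, expected classes) band entries."""

    entries: tuple[tuple[float, str, tuple[str, ...]], ...]
    tolerance: float = 10.0   # matching window, cm^-1

    def __post_init__(self):
        if self.tolerance < 0:
            raise SpectraError("tolerance must be >= 0")
        for center, _, _ in self.entries:
            if center <= 0:
                raise SpectraError("band centers must be positive")


_DEFAULT_ENTRIES = (
    (3350.0, "O-H stretch (saccharides)", ("A", "B")),
    (2920.0, "CH2 asym stretch (lipids)", ("A", "B")),
    (2851.0, "CH2 sym stretch (lipids)", ("A", "B")),
    (1730.0, "C=O stretch (cutin/waxes)", ("A", "B")),
    (1630.0, "amide I", ("A", "B")),
    (1545.0, "amide II (proteins)", ("A",)),
    (1528.0, "aromatic ring (phenolics/flavonoids)", ("B",)),
    (1440.0, "organic acid O-H", ("A", "B")),
    (1400.0, "O-C-H bend (saccharides)", ("A",)),
    (1374.0, "organic acid O-H", ("A", "B")),
    (1320.0, "C-O stretch", ("A", "B")),
    (1260.0, "C-O stretch", ("A", "B")),
    (1150.0, "CO-O-C asym stretch", ("A", "B")),
    (1050.0, "C-O stretch (starch)", ("A", "B")),
    (930.0, "saccharide skeletal", ("A",)),
    (815.0, "C-H out-of-plane bend", ("A", "B")),
    (781.0, "COO- skeletal (saponins)", ("B",)),
)


def default_band_table(tolerance: float = 10.0) -> BandTable:
    return BandTable(entries=_DEFAULT_ENTRIES, tolerance=tolerance)


def detect_peaks(spectrum_row: np.ndarray, grid: np.ndarray,
                 min_prominence: float | None = None) -> np.ndarray:
    """Local maxima with prominence >= ``min_prominence``.

    Default prominence is 2% of the row's maximum value.  Returns the
    wavenumber positions (cm^-1) of the detected maxima.
    """
    y = np.asarray(spectrum_row, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if y.shape != grid.shape:
        raise SpectraError("spectrum and grid lengths differ")
    if min_prominence is None:
        top = y.max()
        if top <= 0:
            return np.array([])
        min_prominence = 0.02 * top
    if min_prominence < 0:
        raise SpectraError("min_prominence must be >= 0")
    idx, _ = find_peaks(y, prominence=min_prominence)
    return grid[idx]


def discriminating_report(s: SpectrumSet,
                          bands: BandTable | None = None) -> pd.DataFrame:
    """Match detected peaks of each class-mean spectrum to the catalogue.

    One row per (class, band): whether the band is expected in that class,
    whether a peak was detected within the tolerance window, and where.
    """
    bands = bands or default_band_table()
    if s.labels is None:
        raise SpectraError("labeled spectra required")
    classes = sorted(set(s.labels))
    if len(classes) != 2:
        raise SpectraError(f"exactly 2 classes required, got {classes}")
    lab = np.asarray(s.labels, dtype=object)
    rows = []
    for cls in classes:
        mean_row = s.values[lab == cls].mean(axis=0)
        peaks = detect_peaks(mean_row, s.wavenumbers)
        for center, assignment, expected in bands.entries:
            if peaks.size:
                d = np.abs(peaks - center)
                k = int(np.argmin(d))
                hit = d[k] <= bands.tolerance
                pos = float(peaks[k]) if hit else np.nan
            else:
                hit, pos = False, np.nan
            rows.append({
                "class": cls,
                "band_center": center,
                "assignment": assignment,
                "expected": cls in expected,
                "detected": bool(hit),
                "detected_position": pos,
            })
    return pd.DataFrame(rows)
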