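"""Spectral data model and I/O.

A :class:`SpectrumSet` holds a wide matrix of mid-infrared spectra — one row
per sample on a shared, uniformly spaced wavenumber grid (canonically
descending, 4000 -> 600 cm^-1).  Values are either percent transmittance
(%T) or absorbance (AU); every downstream stage (pretreatment, splitting,
modelling) consumes this container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TRANSMITTANCE = "transmittance_percent"
ABSORBANCE = "absorbance"
_MODES = (TRANSMITTANCE, ABSORBANCE)

#: Default acquisition grid: 4000 down to 600 cm^-1 in 4 cm^-1 steps (851 points).
DEFAULT_GRID = np.arange(4000.0, 599.0, -4.0)


class SpectraError(ValueError):
    """Raised on malformed spectral data or invalid operations on it."""


@dataclass
class SpectrumSet:
    """Labeled set of spectra on a common wavenumber grid.

    Parameters
    ----------
    wavenumbers : array, shape (n_points,)
        Strictly monotonic, uniformly spaced grid in cm^-1.  Ascending input
        is flipped (together with ``values``) so the stored grid is always
        descending, the spectroscopy convention.
    values : array, shape (n_samples, n_points)
        Intensity matrix; all entries finite.  In transmittance mode every
        entry must be > 0.
    mode : {"transmittance_percent", "absorbance"}
    sample_ids : sequence of unique str
    labels : sequence of str, optional
        Per-sample class tags (e.g. "A"/"B"); ``None`` for unknowns.
    """

    wavenumbers: np.ndarray
    values: np.ndarray
    mode: str
    sample_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.labels is not None:
            self.labels = [str(x) for x in self.labels]
        self._validate_and_canonicalize()

    # -- validation -------------------------------------------------------
    def _validate_and_canonicalize(self) -> None:
        w = self.wavenumbers
        if w.ndim != 1 or w.size < 2:
            raise SpectraError("wavenumber grid must be 1-D with >= 2 points")
        d = np.diff(w)
        if np.all(d > 0):  # ascending -> canonical descending
            self.wavenumbers = w[::-1].copy()
            self.values = self.values[:, ::-1].copy()
            d = -d[::-1]
        elif not np.all(d < 0):
            raise SpectraError("wavenumber grid must be strictly monotonic")
        # note: spacing is uniform on acquisition grids but may carry gaps
        # after interior region exclusion (e.g. CO2 window removal)
        if self.values.shape[1] != self.wavenumbers.size:
            raise SpectraError(
                f"values has {self.values.shape[1]} columns but the grid has "
                f"{self.wavenumbers.size} points"
            )
        if self.values.shape[0] != len(self.sample_ids):
            raise SpectraError("one sample_id required per row of values")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise SpectraError(f"duplicate sample ids: {dupes}")
        if self.labels is not None and len(self.labels) != len(self.sample_ids):
            raise SpectraError("labels must have one entry per sample")
        if not np.all(np.isfinite(self.values)):
            raise SpectraError("values must all be finite")
        if self.mode not in _MODES:
            raise SpectraError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mode == TRANSMITTANCE and np.any(self.values <= 0):
            bad = [self.sample_ids[i] for i in np.unique(np.where(self.values <= 0)[0])]
            raise SpectraError(f"transmittance values must be > 0 (samples {bad})")

    # -- conveniences ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, mode: str | None = None) -> "SpectrumSet":
        """Copy of this set with a new intensity matrix (same grid/samples)."""
        return SpectrumSet(
            wavenumbers=self.wavenumbers.copy(),
            values=np.asarray(values, dtype=float),
            mode=self.mode if mode is None else mode,
            sample_ids=list(self.sample_ids),
            labels=None if self.labels is None else list(self.labels),
        )

    def take(self, idx: Sequence[int]) -> "SpectrumSet":
        """Row subset (sample selection) by integer indices."""
        idx = np.asarray(idx, dtype=int)
        return SpectrumSet(
            wavenumbers=self.wavenumbers.copy(),
            values=self.values[idx],
            mode=self.mode,
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
        )

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise SpectraError("this SpectrumSet carries no class labels")
        return np.asarray(self.labels, dtype=object)


@dataclass
class RegionSet:
    """Closed wavenumber intervals, used to keep or exclude grid regions.

    A grid point lying exactly on an interval boundary belongs to the
    interval.  Intervals are normalized to a sorted, disjoint list (touching
    or overlapping intervals are merged).
    """

    intervals: list[tuple[float, float]]
    mode: str = "keep"  # or "exclude"

    def __post_init__(self) -> None:
        if self.mode not in ("keep", "exclude"):
            raise SpectraError("RegionSet mode must be 'keep' or 'exclude'")
        norm: list[tuple[float, float]] = []
        for lo, hi in sorted((float(lo), float(hi)) for lo, hi in self.intervals):
            if not lo < hi:
                raise SpectraError(f"interval must satisfy lo < hi, got [{lo}, {hi}]")
            if norm and lo <= norm[-1][1]:
                norm[-1] = (norm[-1][0], max(norm[-1][1], hi))
            else:
                norm.append((lo, hi))
        self.intervals = norm

    def member_mask(self, grid: np.ndarray) -> np.ndarray:
        """Boolean mask over ``grid``: True where the point is retained."""
        inside = np.zeros(grid.shape, dtype=bool)
        for lo, hi in self.intervals:
            hit = (grid >= lo) & (grid <= hi)
            if not hit.any():
                warnings.warn(
                    f"interval [{lo}, {hi}] cm^-1 contains no grid point", stacklevel=3
                )
            inside |= hit
        return inside if self.mode == "keep" else ~inside


# ---------------------------------------------------------------------------
# unit conversion and region arithmetic
# ---------------------------------------------------------------------------

#: Smallest %T admitted when the opt-in floor is enabled (A = 6 AU ceiling).
T_FLOOR = 1e-4


def to_absorbance(s: SpectrumSet, floor: bool = False) -> SpectrumSet:
    """Convert percent transmittance to absorbance, A = 2 - log10(%T).

    Already-absorbance input is returned unchanged with a warning.  %T <= 0
    is rejected unless ``floor=True``, which clips to ``T_FLOOR`` %T first.
    """
    if s.mode == ABSORBANCE:
        warnings.warn("spectra already in absorbance; to_absorbance is a no-op")
        return s.with_values(s.values.copy())
    v = s.values
    if floor:
        v = np.maximum(v, T_FLOOR)
    elif np.any(v <= 0):
        bad = [s.sample_ids[i] for i in np.unique(np.where(v <= 0)[0])]
        raise SpectraError(f"%T <= 0 in samples {bad}; enable floor=True to clip")
    return s.with_values(2.0 - np.log10(v), mode=ABSORBANCE)


def to_transmittance(s: SpectrumSet) -> SpectrumSet:
    """Inverse conversion, %T = 10^(2 - A)."""
    if s.mode == TRANSMITTANCE:
        warnings.warn("spectra already in transmittance; no-op")
        return s.with_values(s.values.copy())
    return s.with_values(np.power(10.0, 2.0 - s.values), mode=TRANSMITTANCE)


def subset_region(s: SpectrumSet, region: RegionSet) -> SpectrumSet:
    """Column subset of the spectra retaining grid points selected by ``region``."""
    mask = region.member_mask(s.wavenumbers)
    if not mask.any():
        raise SpectraError("region selection leaves no grid points")
    return SpectrumSet(
        wavenumbers=s.wavenumbers[mask],
        values=s.values[:, mask],
        mode=s.mode,
        sample_ids=list(s.sample_ids),
        labels=None if s.labels is None else list(s.labels),
    )


def resample(s: SpectrumSet, grid: np.ndarray) -> SpectrumSet:
    """Linear interpolation of every spectrum onto ``grid``.

    Only interpolation is allowed: the target grid must lie within the
    source range.  Used to map external spectra onto a model's training grid.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.wavenumbers.min(), s.wavenumbers.max()
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise SpectraError(
            f"target grid [{grid.min()}, {grid.max()}] extends beyond the "
            f"source range [{lo}, {hi}]; extrapolation is not supported"
        )
    asc = s.wavenumbers[::-1]
    out = np.empty((s.n_samples, grid.size))
    order = np.argsort(grid)
    for i in range(s.n_samples):
        yi = np.interp(grid[order], asc, s.values[i, ::-1])
        out[i, order] = yi
    return SpectrumSet(grid, out, s.mode, list(s.sample_ids),
                       None if s.labels is None else list(s.labels))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------
# Dialect: optional leading comment "# mode=<mode>", then a header row
# "sample_id[,label],<wn1>,<wn2>,..." and one row per sample.


def read_csv(path, orientation: str = "samples_as_rows",
             mode: str | None = None) -> SpectrumSet:
    """Read a wide spectra CSV.

    ``orientation='samples_as_columns'`` accepts the transposed layout
    (wavenumbers down the first column, one column per sample; no labels).
    ``mode`` overrides the file's ``# mode=...`` metadata line; default
    transmittance when neither is present.
    """
    path = Path(path)
    file_mode = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first.lstrip("#").strip().split():
            if tok.startswith("mode="):
                file_mode = tok.split("=", 1)[1]
        skiprows = 1
    else:
        skiprows = 0
    eff_mode = mode or file_mode or TRANSMITTANCE

    try:
        df = pd.read_csv(path, skiprows=skiprows, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SpectraError(f"malformed CSV {path}: {exc}") from exc

    if orientation == "samples_as_columns":
        wn = _parse_numeric(df.iloc[:, 0], path, df.columns[0])
        vals = np.column_stack(
            [_parse_numeric(df[c], path, c) for c in df.columns[1:]]
        ).T
        return SpectrumSet(wn, vals, eff_mode, list(df.columns[1:]))
    if orientation != "samples_as_rows":
        raise SpectraError(f"unknown orientation {orientation!r}")

    cols = list(df.columns)
    has_label = len(cols) > 1 and cols[1].strip().lower() == "label"
    data_cols = cols[2:] if has_label else cols[1:]
    try:
        wn = np.array([float(c) for c in data_cols])
    except ValueError as exc:
        raise SpectraError(f"non-numeric wavenumber header in {path}: {exc}") from exc
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    labels = df.iloc[:, 1].astype(str).tolist() if has_label else None
    vals = np.column_stack([_parse_numeric(df[c], path, c) for c in data_cols])
    return SpectrumSet(wn, vals, eff_mode, sample_ids, labels)


def _parse_numeric(col: pd.Series, path, name) -> np.ndarray:
    try:
        return pd.to_numeric(col, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise SpectraError(
            f"non-numeric cell in {path}, column {name!r}: {exc}"
        ) from exc


def write_csv(s: SpectrumSet, path) -> None:
    """Write the standard wide CSV (round-trips with :func:`read_csv`)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# mode={s.mode}\n")
        header = ["sample_id"]
        if s.labels is not None:
            header.append("label")
        header += [_fmt(w) for w in s.wavenumbers]
        fh.write(",".join(header) + "\n")
        for i, sid in enumerate(s.sample_ids):
            row = [sid]
            if s.labels is not None:
                row.append(s.labels[i])
            row += [_fmt(v) for v in s.values[i]]
            fh.write(",".join(row) + "\n")


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


# ---------------------------------------------------------------------------
# JCAMP-DX (read-only, single-spectrum XYDATA files)
# ---------------------------------------------------------------------------

def read_jcamp(paths: Iterable, mode: str | None = None) -> SpectrumSet:
    """Assemble single-spectrum JCAMP-DX files into a SpectrumSet.

    Supports the AFFN ``##XYDATA=(X++(Y..Y))`` form with XFACTOR/YFACTOR
    scaling.  All files must share the same grid.  YUNITS of TRANSMITTANCE
    are interpreted as %T; ABSORBANCE as AU; ``mode`` overrides.
    """
    sets = []
    ids = []
    for p in paths:
        wn, y, yunits, title = _read_jcamp_one(Path(p))
        sets.append((wn, y, yunits))
        ids.append(title or Path(p).stem)
    wn0 = sets[0][0]
    for wn, _, _ in sets[1:]:
        if wn.shape != wn0.shape or not np.allclose(wn, wn0):
            raise SpectraError("JCAMP files do not share a common grid")
    eff = mode
    if eff is None:
        yu = (sets[0][2] or "").upper()
        eff = ABSORBANCE if "ABSORB" in yu else TRANSMITTANCE
    vals = np.vstack([y for _, y, _ in sets])
    return SpectrumSet(wn0, vals, eff, ids)


def _read_jcamp_one(path: Path):
    fields: dict[str, str] = {}
    data: list[tuple[float, list[float]]] = []
    in_data = False
    for raw in path.read_text().splitlines():
        line = raw.split("$$")[0].strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                in_data = False
            fields[key] = val
            continue
        if in_data:
            nums = [float(t) for t in line.replace(",", " ").split()]
            if len(nums) >= 2:
                data.append((nums[0], nums[1:]))
    if not data:
        raise SpectraError(f"no XYDATA block found in {path}")
    xfac = float(fields.get("XFACTOR", 1.0))
    yfac = float(fields.get("YFACTOR", 1.0))
    xs: list[float] = []
    ys: list[float] = []
    npts = int(float(fields["NPOINTS"])) if "NPOINTS" in fields else None
    firstx = float(fields["FIRSTX"]) if "FIRSTX" in fields else None
    lastx = float(fields["LASTX"]) if "LASTX" in fields else None
    for xstart, yvals in data:
        ys.extend(yvals)
        xs.append(xstart * xfac)
    n = len(ys)
    if npts is not None and npts != n:
        raise SpectraError(f"{path}: NPOINTS={npts} but {n} Y values found")
    if firstx is not None and lastx is not None and n > 1:
        wn = np.linspace(firstx, lastx, n)
    else:
        # reconstruct from per-line start X values and counts
        wn = np.empty(n)
        pos = 0
        for (xstart, yvals), nxt in zip(data, data[1:] + [None]):
            m = len(yvals)
            if nxt is not None and m > 1:
                step = (nxt[0] * xfac - xstart * xfac) / m
            elif pos > 0:
                step = wn[pos - 1] - wn[pos - 2]
            else:
                step = 1.0
            wn[pos:pos + m] = xstart * xfac + step * np.arange(m)
            pos += m
    title = fields.get("TITLE", "")
    return wn, np.array(ys) * yfac, fields.get("YUNITS", ""), title
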