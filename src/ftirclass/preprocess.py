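"""Spectral pretreatment: filter transformations, normalizations, baseline
correction, and composable named recipes.

Transforms operate row-wise on a :class:`~ftirclass.core.SpectrumSet` and
return a new set.  A :class:`PreprocessRecipe` chains transforms left to
right; fitting a recipe on a calibration set freezes any data-derived
statistics (currently the MSC reference spectrum) so validation and
external spectra are treated with calibration-set statistics only.

Preset registry (one per pretreatment compared in the study):

====================  =====================================================
``none``              absorbance conversion only ("no methods" raw data)
``vector_first``      absorbance -> Savitzky-Golay 1st derivative (window 9,
                      order 2) -> Euclidean vector normalization
``vector_second``     as above with the 2nd derivative
``minmax``            absorbance -> ATR penetration-depth correction ->
                      min-max normalization (divide by max - min)
``area``              absorbance -> ATR correction -> area normalization
``ewma``              absorbance -> exponentially weighted moving average
``msc``               absorbance -> multiplicative scatter correction
``rc``                absorbance -> row centering
``sg``                absorbance -> Savitzky-Golay smoothing (deriv 0)
``snv``               absorbance -> standard normal variate
``airpls``            absorbance -> airPLS baseline removal
====================  =====================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import solveh_banded
from scipy.signal import lfilter, savgol_filter

from .core import ABSORBANCE, SpectraError, SpectrumSet, to_absorbance

__all__ = [
    "snv", "msc", "savitzky_golay", "vector_normalize", "area_normalize",
    "minmax_normalize", "row_center", "ewma_smooth", "airpls", "atr_correct",
    "AirPLSParams", "PreprocessRecipe", "FittedRecipe", "apply_recipe",
    "PRESETS", "preset_recipe",
]


# ---------------------------------------------------------------------------
# row-wise transforms
# ---------------------------------------------------------------------------

def snv(s: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: per-row centering and scaling by the sample
    standard deviation (n-1 denominator)."""
    x = s.values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.where(sd.ravel() == 0)[0]
    if bad.size:
        names = [s.sample_ids[i] for i in bad]
        raise SpectraError(f"SNV undefined for constant spectra: {names}")
    return s.with_values((x - mu) / sd)


def msc(s: SpectrumSet, reference: np.ndarray | None = None) -> SpectrumSet:
    """Multiplicative scatter correction.

    Each spectrum x is regressed on the reference (OLS, x ~ a*ref + b) and
    corrected to (x - b) / a.  The reference defaults to the mean spectrum
    of ``s``; pass a calibration-set mean to correct new data without
    leakage (see :class:`PreprocessRecipe`).
    """
    x = s.values
    ref = x.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.shape != (s.n_points,):
        raise SpectraError("MSC reference length does not match the grid")
    rc = ref - ref.mean()
    denom = float(rc @ rc)
    if denom == 0:
        raise SpectraError("MSC reference is constant")
    a = (x - x.mean(axis=1, keepdims=True)) @ rc / denom  # per-row slope
    if np.any(a == 0):
        bad = [s.sample_ids[i] for i in np.where(a == 0)[0]]
        raise SpectraError(f"MSC slope is zero for samples {bad}")
    b = x.mean(axis=1) - a * ref.mean()
    return s.with_values((x - b[:, None]) / a[:, None])


def savitzky_golay(s: SpectrumSet, window: int = 9, polyorder: int = 2,
                   deriv: int = 0) -> SpectrumSet:
    """Savitzky-Golay smoothing / derivative along the grid.

    The derivative is taken with respect to the point index (unit step);
    boundary windows are handled by polynomial fits (scipy 'interp' mode).
    """
    if window % 2 == 0:
        raise SpectraError("Savitzky-Golay window must be odd")
    if window > s.n_points:
        raise SpectraError("Savitzky-Golay window exceeds the number of points")
    if polyorder >= window:
        raise SpectraError("polyorder must be < window")
    if deriv not in (0, 1, 2):
        raise SpectraError("deriv must be 0, 1, or 2")
    out = savgol_filter(s.values, window_length=window, polyorder=polyorder,
                        deriv=deriv, delta=1.0, axis=1, mode="interp")
    return s.with_values(out)


def vector_normalize(s: SpectrumSet) -> SpectrumSet:
    """Scale each row to unit Euclidean norm."""
    nrm = np.linalg.norm(s.values, axis=1, keepdims=True)
    bad = np.where(nrm.ravel() == 0)[0]
    if bad.size:
        raise SpectraError(
            f"zero-norm spectra cannot be vector-normalized: "
            f"{[s.sample_ids[i] for i in bad]}")
    return s.with_values(s.values / nrm)


def area_normalize(s: SpectrumSet) -> SpectrumSet:
    """Divide each row by its integrated (trapezoidal) area over wavenumber.

    On the canonical descending grid the signed integral is negative; the
    absolute value is used, so positive spectra keep their sign.
    """
    area = np.abs(np.trapezoid(s.values, x=s.wavenumbers, axis=1))
    bad = np.where(area <= 0)[0]
    if bad.size:
        raise SpectraError(
            f"non-positive spectral area for samples "
            f"{[s.sample_ids[i] for i in bad]}")
    return s.with_values(s.values / area[:, None])


def minmax_normalize(s: SpectrumSet, conventional: bool = False) -> SpectrumSet:
    """Min-max normalization.

    Default divides each row by its range (max - min), the operation as the
    study describes it; ``conventional=True`` uses (x - min) / (max - min).
    """
    x = s.values
    rng = x.max(axis=1) - x.min(axis=1)
    bad = np.where(rng == 0)[0]
    if bad.size:
        raise SpectraError(
            f"zero-range spectra: {[s.sample_ids[i] for i in bad]}")
    if conventional:
        return s.with_values((x - x.min(axis=1, keepdims=True)) / rng[:, None])
    return s.with_values(x / rng[:, None])


def row_center(s: SpectrumSet) -> SpectrumSet:
    """Subtract each row's mean."""
    return s.with_values(s.values - s.values.mean(axis=1, keepdims=True))


def ewma_smooth(s: SpectrumSet, lam: float = 0.2) -> SpectrumSet:
    """Exponentially weighted moving average along the grid.

    z_1 = x_1;  z_t = lam * x_t + (1 - lam) * z_{t-1}.  One forward pass.
    """
    if not 0 < lam <= 1:
        raise SpectraError("EWMA lam must be in (0, 1]")
    x = s.values
    # IIR filter z_t = lam x_t + (1-lam) z_{t-1}; zi chosen so z_1 = x_1
    zi = (1 - lam) * x[:, :1]
    out, _ = lfilter([lam], [1.0, -(1.0 - lam)], x, axis=1, zi=zi)
    return s.with_values(out)


def atr_correct(s: SpectrumSet, ref_wavenumber: float = 1000.0) -> SpectrumSet:
    """Penetration-depth compensation for ATR spectra.

    The ATR effective path length scales like 1/wavenumber, attenuating
    high-wavenumber absorbance; this applies the simple proportional model
    A'(v) = A(v) * v / v_ref.  It approximates (not reproduces) instrument-
    vendor ATR correction.
    """
    if s.mode != ABSORBANCE:
        raise SpectraError("ATR correction expects absorbance spectra")
    return s.with_values(s.values * (s.wavenumbers / float(ref_wavenumber)))


# ---------------------------------------------------------------------------
# airPLS baseline correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AirPLSParams:
    """Adaptive iteratively reweighted penalized least squares settings.

    ``lam`` is the Whittaker-smoother roughness penalty (larger -> stiffer
    baseline), ``diff_order`` the difference order of the penalty,
    ``tol`` the termination ratio |d-| < tol * |x|.
    """

    lam: float = 1e5
    diff_order: int = 2
    max_iter: int = 15
    tol: float = 1e-3

    def __post_init__(self):
        if self.lam <= 0:
            raise SpectraError("airPLS lam must be > 0")
        if self.diff_order not in (1, 2):
            raise SpectraError("airPLS diff_order must be 1 or 2")
        if self.max_iter < 1:
            raise SpectraError("airPLS max_iter must be >= 1")
        if not 0 < self.tol < 1:
            raise SpectraError("airPLS tol must be in (0, 1)")


def _penalty_bands(n: int, lam: float, order: int) -> np.ndarray:
    """Upper banded form of lam * D'D for solveh_banded."""
    D = sparse.eye(n, format="csc")
    for _ in range(order):
        D = D[1:] - D[:-1]
    P = (lam * (D.T @ D)).todia()
    ab = np.zeros((order + 1, n))
    for off in range(order + 1):
        diag = P.diagonal(off)
        ab[order - off, off:] = diag
    return ab


def _whittaker(y: np.ndarray, w: np.ndarray, pen_ab: np.ndarray,
               order: int) -> np.ndarray:
    ab = pen_ab.copy()
    ab[order] = ab[order] + w
    return solveh_banded(ab, w * y, lower=False)


def _airpls_row(y: np.ndarray, p: AirPLSParams, pen_ab: np.ndarray) -> np.ndarray:
    n = y.size
    w = np.ones(n)
    z = y.copy()
    norm_y = np.abs(y).sum()
    for it in range(1, p.max_iter + 1):
        z = _whittaker(y, w, pen_ab, p.diff_order)
        d = y - z
        neg = d < 0
        s_neg = float(np.abs(d[neg]).sum())
        if s_neg < p.tol * norm_y:
            return z
        w[~neg] = 0.0
        w[neg] = np.exp(it * np.abs(d[neg]) / s_neg)
        # anchor the endpoints (reference airPLS convention)
        peak_w = np.exp(it * (np.abs(d[neg]).max() / s_neg)) if neg.any() else 1.0
        w[0] = peak_w
        w[-1] = peak_w
    warnings.warn("airPLS did not converge within max_iter; returning last iterate")
    return z


def airpls(s: SpectrumSet, params: AirPLSParams | None = None
           ) -> tuple[SpectrumSet, SpectrumSet]:
    """Estimate and remove each row's baseline with the airPLS algorithm.

    Iteratively reweighted Whittaker smoothing: points above the current
    baseline iterate get weight 0 (treated as peak), points below get
    exponentially growing weights, so the smoother relaxes onto the lower
    envelope.  Returns ``(baseline, corrected)`` with
    ``corrected + baseline == input`` exactly.
    """
    p = params or AirPLSParams()
    if s.n_points <= p.diff_order + 1:
        raise SpectraError("too few points for the requested difference order")
    pen_ab = _penalty_bands(s.n_points, p.lam, p.diff_order)
    base = np.vstack([_airpls_row(row, p, pen_ab) for row in s.values])
    return s.with_values(base), s.with_values(s.values - base)


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

# registry: name -> (apply(s, state, **params), fit(s, **params) -> state)
def _fit_none(s, **kw):
    return None


_REGISTRY = {
    "to_absorbance": (lambda s, st, **kw: to_absorbance(s, **kw), _fit_none),
    "snv": (lambda s, st, **kw: snv(s), _fit_none),
    "msc": (lambda s, st, **kw: msc(s, reference=st),
            lambda s, **kw: s.values.mean(axis=0)),
    "savitzky_golay": (lambda s, st, **kw: savitzky_golay(s, **kw), _fit_none),
    "vector_normalize": (lambda s, st, **kw: vector_normalize(s), _fit_none),
    "area_normalize": (lambda s, st, **kw: area_normalize(s), _fit_none),
    "minmax_normalize": (lambda s, st, **kw: minmax_normalize(s, **kw), _fit_none),
    "row_center": (lambda s, st, **kw: row_center(s), _fit_none),
    "ewma_smooth": (lambda s, st, **kw: ewma_smooth(s, **kw), _fit_none),
    "airpls": (lambda s, st, **kw: airpls(s, kw.get("params"))[1], _fit_none),
    "atr_correct": (lambda s, st, **kw: atr_correct(s, **kw), _fit_none),
}

_SG = {"window": 9, "polyorder": 2}

PRESETS: dict[str, list[tuple[str, dict]]] = {
    "none": [("to_absorbance", {})],
    "vector_first": [("to_absorbance", {}),
                     ("savitzky_golay", dict(_SG, deriv=1)),
                     ("vector_normalize", {})],
    "vector_second": [("to_absorbance", {}),
                      ("savitzky_golay", dict(_SG, deriv=2)),
                      ("vector_normalize", {})],
    "minmax": [("to_absorbance", {}), ("atr_correct", {}),
               ("minmax_normalize", {})],
    "area": [("to_absorbance", {}), ("atr_correct", {}),
             ("area_normalize", {})],
    "ewma": [("to_absorbance", {}), ("ewma_smooth", {"lam": 0.2})],
    "msc": [("to_absorbance", {}), ("msc", {})],
    "rc": [("to_absorbance", {}), ("row_center", {})],
    "sg": [("to_absorbance", {}), ("savitzky_golay", dict(_SG, deriv=0))],
    "snv": [("to_absorbance", {}), ("snv", {})],
    "airpls": [("to_absorbance", {}), ("airpls", {})],
}


@dataclass
class PreprocessRecipe:
    """Ordered, parameterized transform chain."""

    steps: list[tuple[str, dict]]
    name: str | None = None

    def __post_init__(self):
        for tname, params in self.steps:
            if tname not in _REGISTRY:
                raise SpectraError(f"unknown transform {tname!r} in recipe")
            if not isinstance(params, dict):
                raise SpectraError("step params must be a dict")

    def fit(self, s: SpectrumSet) -> "FittedRecipe":
        """Fit data-derived statistics step by step on ``s`` (the
        calibration set), returning a frozen, reusable chain."""
        states = []
        cur = s
        for tname, params in self.steps:
            apply_fn, fit_fn = _REGISTRY[tname]
            st = fit_fn(cur, **params)
            states.append(st)
            try:
                cur = apply_fn(cur, st, **params)
            except Exception as exc:
                raise SpectraError(
                    f"recipe {self.name or '<anonymous>'} step {tname!r}: {exc}"
                ) from exc
        return FittedRecipe(recipe=self, states=states, n_fit_rows_=s.n_samples)


@dataclass
class FittedRecipe:
    """A recipe with frozen per-step statistics (e.g. MSC reference).

    ``n_fit_rows_`` records how many samples the statistics were learned
    from — pipeline tests use it to verify there is no calibration /
    validation leakage.
    """

    recipe: PreprocessRecipe
    states: list
    n_fit_rows_: int

    def transform(self, s: SpectrumSet) -> SpectrumSet:
        cur = s
        for (tname, params), st in zip(self.recipe.steps, self.states):
            apply_fn, _ = _REGISTRY[tname]
            try:
                cur = apply_fn(cur, st, **params)
            except Exception as exc:
                raise SpectraError(
                    f"recipe {self.recipe.name or '<anonymous>'} step "
                    f"{tname!r}: {exc}") from exc
        return cur


def preset_recipe(name: str) -> PreprocessRecipe:
    """Look up one of the named pretreatment presets."""
    if name not in PRESETS:
        raise SpectraError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")
    return PreprocessRecipe(steps=[(t, dict(p)) for t, p in PRESETS[name]],
                            name=name)


def apply_recipe(recipe: PreprocessRecipe | str, s: SpectrumSet) -> SpectrumSet:
    """Fit-and-apply convenience: statistics learned from ``s`` itself."""
    if isinstance(recipe, str):
        recipe = preset_recipe(recipe)
    return recipe.fit(s).transform(s)
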