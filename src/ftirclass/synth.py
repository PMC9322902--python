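"""Synthetic two-class ATR-FTIR spectrum generator.

Emulates the statistical structure of dried-flower-bud mid-IR fingerprints:
two classes ("A", "B") share a catalogue of absorption bands (saccharide O-H
near 3350, lipid C-H near 2920/2851, amide I near 1630, starch C-O near
1050 cm^-1, ...), while a handful of bands discriminate: class A carries
amide-II 1545, O-C-H 1400 and saccharide-skeleton 930 cm^-1; class B
carries aromatic 1528 and saponin 781 cm^-1.  On top of the clean band sum
the generator adds smooth baseline drift, per-sample multiplicative scatter
and offset (the particle-size/thickness artifacts scatter-correction
pretreatments exist to remove), and additive white noise, then emits
percent transmittance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import DEFAULT_GRID, TRANSMITTANCE, SpectrumSet

__all__ = [
    "BandSpec", "BaselineConfig", "SyntheticConfig",
    "default_bands", "generate", "make_fixture", "FIXTURES",
]


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``amplitude_cv`` is the fractional inter-sample variability of the band
    amplitude (log-normal jitter); ``classes`` lists the classes in which
    the band appears.
    """

    center: float            # cm^-1
    width: float             # Gaussian sigma, cm^-1
    amplitude_mean: float    # AU
    amplitude_cv: float = 0.1
    classes: tuple[str, ...] = ("A", "B")

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.amplitude_mean < 0 or self.amplitude_cv < 0:
            raise ValueError("band amplitude mean and cv must be >= 0")
        if not self.classes:
            raise ValueError("band must appear in at least one class")


# Shared band catalogue (center, sigma, amplitude).  Amplitudes are scaled so
# the discriminating bands sit at 10-30% of the strongest shared band
# (starch C-O, 1050 cm^-1, 0.60 AU).
_SHARED = [
    (3350.0, 80.0, 0.45),   # O-H stretch, saccharides / water
    (2920.0, 15.0, 0.25),   # CH2 asym stretch, lipids
    (2851.0, 12.0, 0.18),   # CH2 sym stretch, lipids
    (1730.0, 12.0, 0.20),   # C=O stretch, cutin/waxes
    (1630.0, 20.0, 0.50),   # amide I
    (1440.0, 14.0, 0.28),   # organic acid O-H
    (1374.0, 9.0, 0.22),    # organic acid O-H
    (1320.0, 12.0, 0.18),   # C-O stretch
    (1260.0, 14.0, 0.20),   # C-O stretch
    (1150.0, 14.0, 0.30),   # CO-O-C asym stretch
    (1050.0, 20.0, 0.60),   # C-O stretch, starch (strongest)
    (815.0, 10.0, 0.10),    # C-H oop bend
]
_A_ONLY = [(1545.0, 12.0, 0.12), (1400.0, 8.0, 0.14), (930.0, 10.0, 0.08)]
_B_ONLY = [(1528.0, 12.0, 0.12), (781.0, 9.0, 0.09)]

#: Centers of the five class-restricted (discriminating) bands.
DISCRIMINATING_CENTERS = (1545.0, 1400.0, 930.0, 1528.0, 781.0)


def default_bands(amplitude_cv: float = 0.1,
                  class_amplitude_scale: float = 1.0) -> list[BandSpec]:
    """Default band catalogue; ``class_amplitude_scale`` shrinks only the
    class-restricted bands (used to build harder fixtures)."""
    bands = [BandSpec(c, w, a, amplitude_cv, ("A", "B")) for c, w, a in _SHARED]
    bands += [BandSpec(c, w, a * class_amplitude_scale, amplitude_cv, ("A",))
              for c, w, a in _A_ONLY]
    bands += [BandSpec(c, w, a * class_amplitude_scale, amplitude_cv, ("B",))
              for c, w, a in _B_ONLY]
    return bands


@dataclass(frozen=True)
class BaselineConfig:
    """Smooth additive baseline: low-order polynomial drift plus one broad
    Gaussian hump with a random center in the 2500-3600 cm^-1 region."""

    degree: int = 2
    coef_scale: float = 0.05       # SD of polynomial coefficients (AU)
    offset_range: tuple[float, float] = (0.05, 0.2)   # uniform constant term
    hump_amplitude: float = 0.08   # AU


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration; identical config + seed => identical output."""

    n_per_class: int = 100
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    bands: tuple[BandSpec, ...] = field(
        default_factory=lambda: tuple(default_bands()))
    baseline: BaselineConfig | None = field(default_factory=BaselineConfig)
    scatter_slope_sd: float = 0.08   # sigma of log-normal multiplicative factor
    scatter_offset_sd: float = 0.01  # SD of additive offset (AU)
    noise_sd: float = 0.002          # additive white noise (AU)
    seed: int = 20220720

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.noise_sd < 0 or self.scatter_slope_sd < 0 or self.scatter_offset_sd < 0:
            raise ValueError("noise/scatter scales must be >= 0")


def _gaussian(grid: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / sigma) ** 2)


def generate(cfg: SyntheticConfig) -> SpectrumSet:
    """Generate ``2 * n_per_class`` labeled spectra in percent transmittance.

    Per sample: sum of class-appropriate Gaussian bands with log-normal
    amplitude jitter; + baseline; then ``y <- a*y + b`` scatter distortion;
    + white noise; absorbance clipped to [0, 4]; %T = 10^(2 - A).
    """
    rng = np.random.default_rng(cfg.seed)
    grid = np.asarray(cfg.grid, dtype=float)
    n = cfg.n_per_class
    profiles = {b: _gaussian(grid, b.center, b.width) for b in cfg.bands}

    rows = []
    ids = []
    labels = []
    u = (grid - grid.mean()) / (0.5 * (grid.max() - grid.min()))  # ~[-1, 1]
    for cls in ("A", "B"):
        for i in range(n):
            a_spec = np.zeros_like(grid)
            for b in cfg.bands:
                if cls not in b.classes:
                    continue
                if b.amplitude_cv > 0:
                    s = np.sqrt(np.log1p(b.amplitude_cv ** 2))
                    amp = b.amplitude_mean * rng.lognormal(-0.5 * s * s, s)
                else:
                    amp = b.amplitude_mean
                a_spec += amp * profiles[b]
            if cfg.baseline is not None:
                bl = cfg.baseline
                base = rng.uniform(*bl.offset_range) * np.ones_like(grid)
                for k in range(1, bl.degree + 1):
                    base += rng.normal(0.0, bl.coef_scale) * u ** k
                hump_c = rng.uniform(2500.0, 3600.0)
                hump_s = rng.uniform(400.0, 700.0)
                base += abs(rng.normal(0.0, bl.hump_amplitude)) * _gaussian(
                    grid, hump_c, hump_s)
                a_spec = a_spec + base
            slope = rng.lognormal(0.0, cfg.scatter_slope_sd) if cfg.scatter_slope_sd else 1.0
            offset = rng.normal(0.0, cfg.scatter_offset_sd) if cfg.scatter_offset_sd else 0.0
            a_spec = slope * a_spec + offset
            if cfg.noise_sd:
                a_spec = a_spec + rng.normal(0.0, cfg.noise_sd, grid.size)
            a_spec = np.clip(a_spec, 0.0, 4.0)
            rows.append(np.power(10.0, 2.0 - a_spec))
            ids.append(f"{cls}_{i + 1:03d}")
            labels.append(cls)
    return SpectrumSet(grid, np.vstack(rows), TRANSMITTANCE, ids, labels)


# ---------------------------------------------------------------------------
# fixture registry
# ---------------------------------------------------------------------------

def _easy_cfg(seed: int, n: int = 100) -> SyntheticConfig:
    return SyntheticConfig(n_per_class=n, seed=seed)


def _hard_cfg(seed: int, n: int = 100) -> SyntheticConfig:
    return SyntheticConfig(
        n_per_class=n,
        bands=tuple(default_bands(amplitude_cv=0.6, class_amplitude_scale=0.25)),
        scatter_slope_sd=0.25,
        scatter_offset_sd=0.03,
        noise_sd=0.03,
        seed=seed,
    )


def _noise_free_cfg(seed: int, n: int = 100) -> SyntheticConfig:
    return SyntheticConfig(
        n_per_class=n,
        bands=tuple(default_bands(amplitude_cv=0.0)),
        baseline=None,
        scatter_slope_sd=0.0,
        scatter_offset_sd=0.0,
        noise_sd=0.0,
        seed=seed,
    )


# Extra bands shared by both classes in "prescription" external spectra,
# emulating compound formulations: the same herb signature diluted among
# excipient/by-herb absorptions.
_EXCIPIENT = [
    BandSpec(1680.0, 18.0, 0.15, 0.1, ("A", "B")),
    BandSpec(1580.0, 14.0, 0.10, 0.1, ("A", "B")),
    BandSpec(1210.0, 14.0, 0.12, 0.1, ("A", "B")),
    BandSpec(870.0, 12.0, 0.08, 0.1, ("A", "B")),
]


def _prescription_cfg(seed: int, n: int = 20) -> SyntheticConfig:
    return SyntheticConfig(
        n_per_class=n,
        bands=tuple(default_bands()) + tuple(_EXCIPIENT),
        seed=seed,
    )


FIXTURES = ("easy", "hard", "noise_free", "prescription")


def make_fixture(name: str, seed: int = 20220720,
                 n_per_class: int = 100) -> tuple[SpectrumSet, SpectrumSet]:
    """Return a (training, external-prediction) SpectrumSet pair.

    ``easy``: default low-noise conditions, 100/class training + 20/class
    external drawn from the same process.  ``hard``: overlapping class
    amplitude distributions plus stronger noise/scatter.  ``noise_free``:
    all stochastic artifacts off (separability sanity floor).
    ``prescription``: easy training set, external set with extra shared
    excipient bands (compound formulations), labels retained for scoring.
    """
    seed = int(seed)
    if name == "easy":
        return generate(_easy_cfg(seed, n_per_class)), generate(_easy_cfg(seed + 1, 20))
    if name == "hard":
        return generate(_hard_cfg(seed, n_per_class)), generate(_hard_cfg(seed + 1, 20))
    if name == "noise_free":
        # external drawn with jitter-free bands too, but distinct seed is
        # irrelevant (process is deterministic); use fewer samples
        return (generate(_noise_free_cfg(seed, n_per_class)),
                generate(_noise_free_cfg(seed + 1, 20)))
    if name == "prescription":
        return generate(_easy_cfg(seed, n_per_class)), generate(_prescription_cfg(seed + 1, 20))
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURES}")
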