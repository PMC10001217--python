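"""Synthetic NIR hyperspectral scenes and spectrum tables with known truth.

The generator emulates a push-broom measurement of a strawberry lying on a
resin tray: an elliptical fruit (flesh with achene speckles and a sepal patch
at the apex) over a dark background, on a nominal uniform 200-band grid from
913 to 2166 nm.  Endmember reflectances are smooth continua minus Gaussian
absorption features; flesh carries the water/sugar bands at 970, 1165, 1420,
1780 and 1900 nm, achene additionally a C-H2 feature near 1710 nm and a much
weaker 1420 nm water band.  Sugar content modulates the depths of the 1420,
1780 and 1900 nm features linearly (a Beer-Lambert proxy), so wavelength-
selection methods have a known right answer.

Per-pixel nuisances mirror what SNV is meant to remove: a multiplicative
scatter factor and an additive offset, plus white Gaussian noise.  A few
pixels are clipped to a saturation plateau to emulate specular Fresnel
reflections.  Everything the generators randomise is recorded in the returned
truth object, and all randomness flows through one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypercube import Hypercube, WavelengthAxis, nearest_band
from .preprocess import SpectrumTable, snv_rows
from scipy.signal import savgol_filter

__all__ = [
    "CLASS_LABELS",
    "EndmemberLibrary",
    "SceneTruth",
    "nominal_axis",
    "make_library",
    "generate_scene",
    "generate_dataset",
    "generate_grid_tables",
]

CLASS_LABELS = {"background": 0, "tray": 1, "sepal": 2, "flesh": 3, "achene": 4}

N_BANDS = 200
LO_NM, HI_NM = 913.0, 2166.0

# Brix-dependent absorption features: (center nm, width nm, depth per Brix%)
BRIX_FEATURES = ((1420.0, 30.0, 0.010), (1780.0, 25.0, 0.008),
                 (1900.0, 35.0, 0.012))

# Scene defaults: the study conditions the fixtures emulate
DEFAULT_ACHENE_FRACTION = 0.087      # mean achene share of fruit pixels
DEFAULT_NOISE_SD = 0.02              # reflectance units, ~2% of signal
DEFAULT_SCATTER = (0.2, 0.05)        # mult U(1±0.2), add U(±0.05)
SATURATION_PLATEAU = 2.5


def nominal_axis(n_bands: int = N_BANDS) -> WavelengthAxis:
    """Uniform nominal wavelength grid from 913 to 2166 nm."""
    return WavelengthAxis(np.linspace(LO_NM, HI_NM, n_bands))


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


@dataclass(frozen=True)
class EndmemberLibrary:
    """Pure-class reflectance spectra plus the peak table that built them."""

    axis: WavelengthAxis
    spectra: dict[str, np.ndarray]
    peaks: dict[str, tuple[tuple[float, float, float], ...]]

    def spectrum(self, name: str) -> np.ndarray:
        return self.spectra[name]


def _build_endmember(wl: np.ndarray, base: float, slope: float,
                     peaks: tuple[tuple[float, float, float], ...]) -> np.ndarray:
    s = base + slope * (wl - wl[0]) / (wl[-1] - wl[0])
    for center, width, depth in peaks:
        s = s - depth * _gauss(wl, center, width)
    return s


# Peak tables: (center nm, width nm, depth).  Flesh carries the O-H bands at
# 970/1420/1900 nm and C-H bands at 1165/1780 nm; achene has far less water
# (weak 1420/1900) plus the lipid C-H2 feature near 1710 nm; sepal's deep
# 1940 nm water feature is what the SNV gate keys on.
_PEAKS = {
    "flesh": ((970.0, 25.0, 0.12), (1165.0, 30.0, 0.10), (1420.0, 45.0, 0.65),
              (1780.0, 35.0, 0.15), (1900.0, 50.0, 0.22)),
    "achene": ((970.0, 25.0, 0.05), (1165.0, 30.0, 0.20), (1420.0, 45.0, 0.14),
               (1710.0, 20.0, 0.18), (1780.0, 35.0, 0.22), (1900.0, 50.0, 0.08)),
    "sepal": ((970.0, 25.0, 0.08), (1190.0, 40.0, 0.10), (1450.0, 60.0, 0.55),
              (1940.0, 55.0, 1.05)),
    "tray": ((1730.0, 60.0, 0.06),),
    "background": (),
}

_CONTINUUM = {           # (base reflectance, linear tilt over the range)
    "flesh": (1.70, -0.20),
    "achene": (1.68, -0.18),
    "sepal": (1.95, -0.30),
    "tray": (0.80, -0.10),
    "background": (0.22, 0.0),
}

T1077 = 1.205
T1940_SNV = -1.325
SCATTER_MULT_MAX = 1.0 + DEFAULT_SCATTER[0]
SCATTER_MULT_MIN = 1.0 - DEFAULT_SCATTER[0]
SCATTER_ADD = DEFAULT_SCATTER[1]


def make_library(seed: int = 0, n_bands: int = N_BANDS) -> EndmemberLibrary:
    """Build the five-class endmember library and self-check its separations.

    The construction is deterministic; ``seed`` is accepted for interface
    symmetry with the other generators.  Raises if the built spectra would
    not honour the thresholding contract (tray/background below the 1077 nm
    gate and sepal below the 1940 nm SNV gate under the worst-case scatter),
    so a broken library can never silently reach a test.
    """
    axis = nominal_axis(n_bands)
    wl = axis.centers
    spectra = {name: _build_endmember(wl, *_CONTINUUM[name], _PEAKS[name])
               for name in _PEAKS}

    b1077 = nearest_band(axis, 1077.0)
    b1940 = nearest_band(axis, 1940.0)
    b1420 = nearest_band(axis, 1420.0)
    # stage-1 gate must hold under worst-case multiplicative/additive scatter
    for name in ("background", "tray"):
        worst = spectra[name][b1077] * SCATTER_MULT_MAX + SCATTER_ADD
        if worst >= T1077:
            raise AssertionError(f"{name} can cross the 1077 nm gate ({worst:.3f})")
    for name in ("sepal", "flesh", "achene"):
        worst = spectra[name][b1077] * SCATTER_MULT_MIN - SCATTER_ADD
        if worst <= T1077:
            raise AssertionError(f"{name} can fall below the 1077 nm gate ({worst:.3f})")
    # stage-2 gate: SNV is scatter-invariant, so check the clean spectra
    sm = savgol_filter(np.vstack([spectra[n] for n in ("sepal", "flesh", "achene")]),
                       7, 2, axis=1, mode="mirror")
    vals = snv_rows(sm)[:, b1940]
    if not vals[0] < T1940_SNV:
        raise AssertionError(f"sepal SNV(1940) = {vals[0]:.3f} not below the gate")
    if not (vals[1] > T1940_SNV and vals[2] > T1940_SNV):
        raise AssertionError("flesh/achene SNV(1940) not above the gate")
    diff = np.abs(spectra["flesh"] - spectra["achene"])
    if abs(wl[np.argmax(diff)] - 1420.0) > 60:
        raise AssertionError("flesh-achene contrast not dominated by the 1420 nm water band")
    return EndmemberLibrary(axis=axis, spectra=spectra,
                            peaks={k: tuple(v) for k, v in _PEAKS.items()})


@dataclass
class SceneTruth:
    """Everything the scene generator randomised, for oracle tests."""

    labels: np.ndarray                  # 2-D class map (CLASS_LABELS codes)
    brix_field: np.ndarray              # 2-D Brix%, NaN off flesh+achene
    mixing: np.ndarray                  # 2-D achene fraction (0 flesh, 1 achene)
    saturated: np.ndarray               # (k, 2) injected saturated pixel coords
    seed: int
    achene_fraction: float              # realised achene share of fruit pixels


def generate_scene(shape: tuple[int, int] = (128, 128),
                   brix_gradient: tuple[float, float] = (5.0, 5.0),
                   achene_fraction: float = DEFAULT_ACHENE_FRACTION,
                   noise_sd: float = DEFAULT_NOISE_SD,
                   scatter: tuple[float, float] | None = DEFAULT_SCATTER,
                   n_saturated: int = 5,
                   seed: int = 0,
                   library: EndmemberLibrary | None = None) -> tuple[Hypercube, SceneTruth]:
    """Render one labelled strawberry scene with a per-pixel Brix field.

    ``brix_gradient`` = (Brix at the base, apex-minus-base difference); the
    field varies linearly along the fruit's long axis (sugar accumulates
    toward the apex).  ``scatter`` = (m, a) draws a per-pixel multiplicative
    factor U(1-m, 1+m) and additive offset U(-a, a); None disables both.
    """
    rows, cols = shape
    if rows < 32 or cols < 32:
        raise ValueError("scene must be at least 32x32 pixels")
    lib = library or make_library()
    wl = lib.axis.centers
    rng = np.random.default_rng(seed)

    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = rows / 2.0, cols / 2.0
    a_ax, b_ax = rows * 0.34, cols * 0.26       # fruit long axis along rows
    d2 = ((rr - cy) / a_ax) ** 2 + ((cc - cx) / b_ax) ** 2
    fruit = d2 <= 1.0
    tray = (d2 <= 1.45) & ~fruit
    # sepal patch at the apex (low row indices), overlapping the fruit rim
    sep_cy = cy - a_ax
    sepal = (((rr - sep_cy) / (rows * 0.08)) ** 2
             + ((cc - cx) / (cols * 0.12)) ** 2) <= 1.0
    labels = np.full(shape, CLASS_LABELS["background"], dtype=int)
    labels[tray] = CLASS_LABELS["tray"]
    labels[fruit] = CLASS_LABELS["flesh"]
    labels[sepal] = CLASS_LABELS["sepal"]

    fruit_px = np.argwhere(labels == CLASS_LABELS["flesh"])
    n_fruit = len(fruit_px)
    n_achene = int(round(achene_fraction * n_fruit))
    if n_achene > n_fruit:
        raise ValueError("achene fraction exceeds the fruit area")
    pick = rng.choice(n_fruit, size=n_achene, replace=False)
    for r, c in fruit_px[pick]:
        labels[r, c] = CLASS_LABELS["achene"]

    # Brix field: linear along the long (row) axis, apex = low row index
    base, delta = brix_gradient
    frac = (cy + a_ax - rr) / (2 * a_ax)        # 0 at fruit base, 1 at apex
    brix = np.full(shape, np.nan)
    on_fruit = (labels == CLASS_LABELS["flesh"]) | (labels == CLASS_LABELS["achene"])
    brix[on_fruit] = base + delta * frac[on_fruit]

    data = np.empty((rows, cols, wl.size))
    for name, code in CLASS_LABELS.items():
        sel = labels == code
        if np.any(sel):
            data[sel] = lib.spectra[name]
    # Brix-proportional absorption on flesh and achene
    feat = np.zeros(wl.size)
    for center, width, depth in BRIX_FEATURES:
        feat += depth * _gauss(wl, center, width)
    data[on_fruit] -= brix[on_fruit, None] * feat

    if scatter is not None:
        m, a = scatter
        mult = rng.uniform(1.0 - m, 1.0 + m, size=shape)
        add = rng.uniform(-a, a, size=shape)
        data = data * mult[:, :, None] + add[:, :, None]
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)

    sat_coords = np.empty((0, 2), dtype=int)
    if n_saturated > 0:
        pick = rng.choice(n_fruit, size=min(n_saturated, n_fruit), replace=False)
        sat_coords = fruit_px[pick]
        data[sat_coords[:, 0], sat_coords[:, 1], :] = SATURATION_PLATEAU

    mixing = (labels == CLASS_LABELS["achene"]).astype(float)
    mixing[labels < CLASS_LABELS["flesh"]] = np.nan
    truth = SceneTruth(labels=labels, brix_field=brix, mixing=mixing,
                       saturated=sat_coords, seed=seed,
                       achene_fraction=n_achene / n_fruit)
    return Hypercube(data, lib.axis), truth


def generate_dataset(n_samples: int = 400,
                     brix_range: tuple[float, float] = (5.0, 11.0),
                     informative_bands: np.ndarray | None = None,
                     noise_sd: float = 0.2,
                     seed: int = 0,
                     spectral_noise_sd: float = 0.003,
                     scatter: tuple[float, float] | None = (0.05, 0.02),
                     feature_depth: float = 0.01,
                     n_bands: int = N_BANDS) -> SpectrumTable:
    """Flat spectra-vs-Brix table for chemometrics tests.

    Each row is the flesh endmember plus Brix-weighted narrow Gaussian
    features (index-space SD 0.5 bands, so the named band carries almost all
    of the signal) centred at ``informative_bands`` (default: the bands
    nearest 970, 1165, 1420, 1780 and 1900 nm).  ``noise_sd`` is the SD of
    Gaussian measurement noise on the recorded Brix value, in Brix%;
    ``spectral_noise_sd`` is white reflectance noise; ``scatter`` adds a mild
    per-sample affine nuisance.
    """
    if n_samples < 20:
        raise ValueError("dataset needs at least 20 samples")
    lib = make_library(n_bands=n_bands)
    axis = lib.axis
    if informative_bands is None:
        informative_bands = np.array(
            [nearest_band(axis, w) for w in (970, 1165, 1420, 1780, 1900)])
    informative_bands = np.asarray(informative_bands, dtype=int)
    rng = np.random.default_rng(seed)
    brix_true = rng.uniform(*brix_range, size=n_samples)
    idx = np.arange(n_bands, dtype=float)
    feat = np.zeros(n_bands)
    for j in informative_bands:
        feat += np.exp(-0.5 * ((idx - j) / 0.5) ** 2)
    X = lib.spectra["flesh"][None, :] - feature_depth * brix_true[:, None] * feat[None, :]
    if scatter is not None:
        m, a = scatter
        X = X * rng.uniform(1 - m, 1 + m, n_samples)[:, None] \
            + rng.uniform(-a, a, n_samples)[:, None]
    if spectral_noise_sd > 0:
        X = X + rng.normal(0, spectral_noise_sd, X.shape)
    y = brix_true + (rng.normal(0, noise_sd, n_samples) if noise_sd > 0 else 0.0)
    return SpectrumTable(X, axis, y)


def generate_grid_tables(n_fruits: int = 60, seed: int = 0,
                         brix_range: tuple[float, float] = (5.0, 11.0),
                         noise_sd: float = 0.2,
                         achene_fraction: float = DEFAULT_ACHENE_FRACTION,
                         n_bands: int = N_BANDS) -> dict[str, SpectrumTable]:
    """Sample-aligned {fruit, flesh, achene} mean-spectrum tables.

    Emulates the measurement bookkeeping: every fruit is measured on two
    sides, each side split into a top and a bottom half, so each fruit
    contributes four records per ROI.  The fruit spectrum is the
    achene-fraction-weighted mixture of flesh and achene.  ``meta`` carries
    fruit/side/half columns for the paired train/test splitter.
    """
    lib = make_library(n_bands=n_bands)
    wl = lib.axis.centers
    rng = np.random.default_rng(seed)
    feat = np.zeros(wl.size)
    for center, width, depth in BRIX_FEATURES:
        feat += depth * _gauss(wl, center, width)
    records = {"fruit": [], "flesh": [], "achene": []}
    ys, fruits, sides, halves = [], [], [], []
    for f in range(n_fruits):
        fruit_brix = rng.uniform(*brix_range)
        for side in ("A", "B"):
            side_shift = rng.normal(0, 0.3)
            for half, half_shift in (("bottom", -0.4), ("top", +0.4)):
                b = fruit_brix + side_shift + half_shift + rng.normal(0, 0.15)
                flesh = lib.spectra["flesh"] - b * feat
                achene = lib.spectra["achene"] - 0.3 * b * feat
                mix = (1 - achene_fraction) * flesh + achene_fraction * achene
                for roi, spec in (("fruit", mix), ("flesh", flesh),
                                  ("achene", achene)):
                    m = rng.uniform(0.97, 1.03)
                    add = rng.uniform(-0.01, 0.01)
                    noise = rng.normal(0, 0.003, wl.size)
                    records[roi].append(spec * m + add + noise)
                ys.append(b + rng.normal(0, noise_sd))
                fruits.append(f)
                sides.append(side)
                halves.append(half)
    import pandas as pd
    meta = pd.DataFrame({"fruit": fruits, "side": sides, "half": halves})
    y = np.asarray(ys)
    return {roi: SpectrumTable(np.vstack(records[roi]), lib.axis, y, meta.copy())
            for roi in records}
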