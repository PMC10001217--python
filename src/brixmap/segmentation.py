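"""Automatic ROI extraction on a measured fruit surface.

The pipeline builds six named masks — {fruit, flesh, achene} x {bottom, top} —
without any training data:

1. wavelength thresholding removes background and resin tray
   (reflectance at 1077 nm, default threshold 1.205) and sepals
   (SNV value at 1940 nm after Savitzky-Golay smoothing, default -1.325);
2. saturated pixels (specular Fresnel reflections) are discarded;
3. the surviving fruit pixels are smoothed, SNV-treated, autoscaled and
   decomposed by PCA fitted on that surface alone; the PC1 score image is
   binarised with Otsu's method, and the smaller class is labelled achene;
4. the fruit bounding box is split at the midpoint of its longer axis into
   bottom and top halves.

Mean ROI spectra are taken from the *raw* reflectance cube; model
pretreatments are applied downstream to the averaged spectrum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .hypercube import Hypercube, nearest_band
from .preprocess import snv_rows
from scipy.signal import savgol_filter

__all__ = [
    "PixelMask",
    "ROISet",
    "threshold_mask",
    "fruit_mask",
    "remove_saturated",
    "pc1_score_image",
    "otsu_threshold",
    "flesh_achene_masks",
    "split_top_bottom",
    "extract_mean_spectrum",
    "build_roi_set",
    "write_mask_png",
]

PixelMask = np.ndarray  # 2-D boolean array, same spatial shape as the cube

ROI_NAMES = ("fruit_bottom", "fruit_top", "flesh_bottom", "flesh_top",
             "achene_bottom", "achene_top")


@dataclass
class ROISet:
    """The six named masks with their mean spectra and pixel counts."""

    masks: dict[str, PixelMask]
    mean_spectra: dict[str, np.ndarray]
    pixel_counts: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(ROI_NAMES) - set(self.masks)
        if missing:
            raise ValueError(f"ROISet missing masks: {sorted(missing)}")
        for name, mask in self.masks.items():
            if self.pixel_counts[name] != int(mask.sum()):
                raise ValueError(f"pixel count for {name} disagrees with its mask")
        flesh = self.masks["flesh_bottom"] | self.masks["flesh_top"]
        achene = self.masks["achene_bottom"] | self.masks["achene_top"]
        fruit = self.masks["fruit_bottom"] | self.masks["fruit_top"]
        if np.any(flesh & achene):
            raise ValueError("flesh and achene masks overlap")
        if np.any((flesh | achene) & ~fruit):
            raise ValueError("flesh/achene must be subsets of fruit")


def threshold_mask(cube: Hypercube, wavelength: float, threshold: float,
                   keep: str = "above") -> PixelMask:
    """Strict-inequality threshold at the band nearest ``wavelength``."""
    band = cube.data[:, :, nearest_band(cube.axis, wavelength)]
    if keep == "above":
        return band > threshold
    if keep == "below":
        return band < threshold
    raise ValueError("keep must be 'above' or 'below'")


def _smooth_snv(spectra: np.ndarray, smooth: bool = True, window: int = 7,
                polyorder: int = 2) -> np.ndarray:
    if smooth:
        spectra = savgol_filter(spectra, window, polyorder, axis=1, mode="mirror")
    return snv_rows(spectra)


def fruit_mask(cube: Hypercube, t1077: float = 1.205, t1940_snv: float = -1.325,
               smooth_first: bool = True) -> PixelMask:
    """Two-stage fruit ROI: reflectance gate at 1077 nm, SNV gate at 1940 nm.

    Stage 1 keeps pixels with R(1077) > ``t1077`` (drops background and resin
    tray).  Stage 2 smooths + SNV-transforms the survivors only and keeps
    those whose SNV value at 1940 nm exceeds ``t1940_snv`` (drops sepals,
    whose deep water absorption pushes the SNV value far negative).
    """
    stage1 = threshold_mask(cube, 1077.0, t1077, keep="above")
    if not stage1.any():
        raise ValueError("no pixels exceed the 1077 nm threshold: no fruit found")
    spectra = cube.data[stage1]
    pre = _smooth_snv(spectra, smooth=smooth_first)
    b1940 = nearest_band(cube.axis, 1940.0)
    keep = pre[:, b1940] > t1940_snv
    mask = np.zeros_like(stage1)
    mask[stage1] = keep
    return mask


def remove_saturated(cube: Hypercube, mask: PixelMask,
                     sat_level: float = 2.2) -> PixelMask:
    """Drop pixels whose reflectance reaches ``sat_level`` at any band.

    Specular (Fresnel) highlights clip at the detector; the default 2.2 sits
    above any diffuse flesh reflectance yet well below the clipping plateau.
    """
    if sat_level <= 0:
        raise ValueError("sat_level must be positive")
    saturated = np.any(cube.data >= sat_level, axis=2)
    return mask & ~saturated


def pc1_score_image(cube: Hypercube, mask: PixelMask,
                    smooth_window: int = 7) -> tuple[np.ndarray, np.ndarray]:
    """PC1 score image over the masked pixels, plus the unit-norm loading.

    The surface's masked spectra are smoothed, SNV-transformed and autoscaled,
    then decomposed by PCA fitted on this surface alone.  Scores are NaN off
    the mask.  The loading's sign is fixed so its largest-magnitude element is
    positive (PCA sign is otherwise arbitrary).
    """
    n_pix = int(mask.sum())
    if n_pix < len(cube.axis):
        raise ValueError(
            f"mask has {n_pix} pixels but PCA needs at least {len(cube.axis)}"
        )
    spectra = _smooth_snv(cube.data[mask], window=smooth_window)
    mu = spectra.mean(axis=0)
    sd = spectra.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance band among masked pixels; PCA degenerate")
    Z = (spectra - mu) / sd
    # PC1 via SVD of the centered, autoscaled matrix
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    if s[0] == 0:
        raise ValueError("masked spectra have no variance; PCA degenerate")
    loading = vt[0]
    if loading[np.argmax(np.abs(loading))] < 0:
        loading = -loading
    scores = Z @ loading
    image = np.full(mask.shape, np.nan)
    image[mask] = scores
    return image, loading


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold over an ``nbins``-bin histogram of the values.

    Classes are {v <= t} and {v > t}; the returned threshold is the histogram
    edge whose split maximises the between-class variance.  When several
    splits tie exactly (empty bins between two well-separated classes), the
    tied edges are averaged, which keeps the threshold centred in the gap and
    makes the partition invariant under negation of the values.
    """
    values = np.asarray(values, dtype=float).ravel()
    if np.unique(values).size < 2:
        raise ValueError("Otsu needs at least two distinct values")
    counts, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(counts)[:-1].astype(float)
    w1 = counts.sum() - w0
    csum = np.cumsum(counts * centers)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum[:-1] / w0
        mu1 = (csum[-1] - csum[:-1]) / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
    var[~np.isfinite(var)] = -np.inf
    # exact ties form a contiguous run of empty boundary bins around the
    # maximiser; average only that run (far-away rounding coincidences must
    # not drag the threshold out of the class gap)
    best = int(np.argmax(var))
    lo = best
    while lo > 0 and var[lo - 1] == var[best]:
        lo -= 1
    hi = best
    while hi < var.size - 1 and var[hi + 1] == var[best]:
        hi += 1
    return float(np.mean(edges[lo + 1:hi + 2]))


def flesh_achene_masks(score_image: np.ndarray, fruit: PixelMask,
                       nbins: int = 256) -> tuple[PixelMask, PixelMask]:
    """Split the fruit mask into flesh and achene via Otsu on PC1 scores.

    PCA sign is arbitrary, so the classes cannot be labelled by sign; the
    smaller class is called achene (achenes cover a small fraction of the
    fruit surface).  The two masks partition the fruit mask.
    """
    scores = score_image[fruit]
    t = otsu_threshold(scores, nbins=nbins)
    low = np.zeros_like(fruit)
    low[fruit] = scores <= t
    high = fruit & ~low
    if low.sum() <= high.sum():
        achene, flesh = low, high
    else:
        achene, flesh = high, low
    return flesh, achene


def split_top_bottom(mask: PixelMask, orientation: str = "axis-auto",
                     top_side: str = "low-index") -> tuple[PixelMask, PixelMask]:
    """Split a mask into (bottom, top) halves at its bounding-box midpoint.

    The cut is perpendicular to the longer bounding-box axis (or forced with
    ``orientation`` = 'rows' / 'cols').  Which half is "top" depends on how
    the fruit was laid on the slider, hence the ``top_side`` flag.  Pixels
    exactly on the midpoint line go to the bottom half.
    """
    if not mask.any():
        raise ValueError("cannot split an empty mask")
    rr, cc = np.nonzero(mask)
    if orientation == "axis-auto":
        extent_r = rr.max() - rr.min()
        extent_c = cc.max() - cc.min()
        orientation = "rows" if extent_r >= extent_c else "cols"
    if orientation == "rows":
        coord, lo, hi = rr, rr.min(), rr.max()
        grid = np.arange(mask.shape[0])[:, None]
    elif orientation == "cols":
        coord, lo, hi = cc, cc.min(), cc.max()
        grid = np.arange(mask.shape[1])[None, :]
    else:
        raise ValueError("orientation must be 'axis-auto', 'rows' or 'cols'")
    mid = (lo + hi) / 2.0
    if top_side == "low-index":
        top = mask & (grid < mid)
    elif top_side == "high-index":
        top = mask & (grid > mid)
    else:
        raise ValueError("top_side must be 'low-index' or 'high-index'")
    bottom = mask & ~top
    return bottom, top


def extract_mean_spectrum(cube: Hypercube, mask: PixelMask) -> np.ndarray:
    """Arithmetic mean of raw reflectance over the masked pixels, per band."""
    if not mask.any():
        raise ValueError("cannot average over an empty mask")
    return cube.data[mask].mean(axis=0)


def build_roi_set(cube: Hypercube, t1077: float = 1.205,
                  t1940_snv: float = -1.325, sat_level: float = 2.2,
                  top_side: str = "low-index", nbins: int = 256) -> ROISet:
    """Run the full segmentation pipeline and assemble the six-ROI set."""
    fruit = fruit_mask(cube, t1077=t1077, t1940_snv=t1940_snv)
    fruit = remove_saturated(cube, fruit, sat_level=sat_level)
    score_img, _ = pc1_score_image(cube, fruit)
    flesh, achene = flesh_achene_masks(score_img, fruit, nbins=nbins)
    bottom, top = split_top_bottom(fruit, top_side=top_side)
    masks = {
        "fruit_bottom": fruit & bottom, "fruit_top": fruit & top,
        "flesh_bottom": flesh & bottom, "flesh_top": flesh & top,
        "achene_bottom": achene & bottom, "achene_top": achene & top,
    }
    spectra = {}
    counts = {}
    for name, m in masks.items():
        counts[name] = int(m.sum())
        spectra[name] = (extract_mean_spectrum(cube, m) if m.any()
                         else np.full(len(cube.axis), np.nan))
    return ROISet(masks, spectra, counts)


def write_mask_png(mask: PixelMask, path: str | Path,
                   sidecar: bool = True) -> None:
    """Write a mask as an 8-bit 0/255 PNG with a JSON pixel-count sidecar."""
    path = Path(path)
    iio.imwrite(path, (mask.astype(np.uint8) * 255))
    if sidecar:
        meta = {"pixels": int(mask.sum()), "shape": list(mask.shape)}
        path.with_suffix(".json").write_text(json.dumps(meta))
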