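"""Per-pixel Brix prediction maps and their distribution summaries.

A trained calibration is applied to every flesh pixel of a cube (the model's
pretreatment chain and training-set autoscaling are reused per pixel), the
map is denoised with a mask-aware Gaussian filter, and the Brix distribution
of the whole flesh and of its bottom/top halves is summarised the way a
violin plot draws it: kernel density estimate, median, interquartile range
and mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import gaussian_kde

from .chemometrics import PLSRModel
from .hypercube import Hypercube
from .preprocess import SpectrumTable
from .segmentation import PixelMask

__all__ = ["BrixMap", "ViolinSummary", "predict_map", "smooth_map",
           "violin_summary", "render", "summary_to_csv"]


@dataclass
class BrixMap:
    """2-D Brix% map defined on a flesh mask; NaN off the mask."""

    values: np.ndarray
    mask: PixelMask
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("map and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite Brix values on the mask")


@dataclass
class RegionStats:
    mean: float
    median: float
    q1: float
    q3: float
    n_pixels: int
    kde_grid: np.ndarray
    kde_density: np.ndarray
    low_support: bool


@dataclass
class ViolinSummary:
    """Per-region (whole / bottom / top) distribution statistics."""

    regions: dict[str, RegionStats]


def predict_map(cube: Hypercube, flesh_mask: PixelMask,
                model: PLSRModel) -> BrixMap:
    """Apply the calibration to every masked pixel's spectrum."""
    if not flesh_mask.any():
        raise ValueError("flesh mask is empty")
    table = SpectrumTable(cube.data[flesh_mask], cube.axis)
    pre = model.pretreatment.apply(table)
    preds = model.predict_matrix(pre.X)
    values = np.full(flesh_mask.shape, np.nan)
    values[flesh_mask] = preds
    return BrixMap(values=values, mask=flesh_mask.copy(), sigma=0.0)


def smooth_map(bmap: BrixMap, sigma: float = 1.0) -> BrixMap:
    """Mask-aware Gaussian smoothing: kernel weights renormalised inside the
    mask so background never bleeds in.  ``sigma`` = 0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return BrixMap(bmap.values.copy(), bmap.mask.copy(), 0.0)
    filled = np.where(bmap.mask, bmap.values, 0.0)
    num = gaussian_filter(filled, sigma=sigma, mode="constant")
    den = gaussian_filter(bmap.mask.astype(float), sigma=sigma, mode="constant")
    out = np.full(bmap.values.shape, np.nan)
    out[bmap.mask] = num[bmap.mask] / den[bmap.mask]
    return BrixMap(out, bmap.mask.copy(), sigma)


def _region_stats(values: np.ndarray, min_support: int = 5) -> RegionStats:
    if values.size == 0:
        raise ValueError("empty region")
    mean = float(values.mean())
    q1, med, q3 = (float(v) for v in
                   np.percentile(values, [25, 50, 75]))  # linear interpolation
    low = values.size < min_support
    spread = values.std(ddof=1) if values.size > 1 else 0.0
    if spread > 0 and not low:
        kde = gaussian_kde(values, bw_method="silverman")
        grid = np.linspace(values.min() - 3 * kde.factor * spread,
                           values.max() + 3 * kde.factor * spread, 256)
        density = kde(grid)
    else:
        # degenerate distribution: a narrow triangle of unit area at the mean
        half = max(abs(mean), 1.0) * 1e-6
        grid = np.array([mean - half, mean, mean + half])
        density = np.array([0.0, 1.0 / half, 0.0])
    area = np.trapezoid(density, grid)
    density = density / area
    return RegionStats(mean=mean, median=med, q1=q1, q3=q3,
                       n_pixels=int(values.size), kde_grid=grid,
                       kde_density=density, low_support=low)


def violin_summary(bmap: BrixMap, bottom: PixelMask, top: PixelMask) -> ViolinSummary:
    """Distribution statistics for the whole flesh and its two halves."""
    if np.any(bottom & top):
        raise ValueError("bottom and top masks overlap")
    if not np.array_equal(bottom | top, bmap.mask):
        raise ValueError("bottom and top must partition the map's mask")
    regions = {}
    for name, m in (("whole", bmap.mask), ("bottom", bottom), ("top", top)):
        vals = bmap.values[m]
        if vals.size == 0:
            raise ValueError(f"region '{name}' is empty")
        regions[name] = _region_stats(vals)
    return ViolinSummary(regions=regions)


def summary_to_csv(summary: ViolinSummary, path: str | Path) -> None:
    rows = [{"region": name, "mean": s.mean, "median": s.median,
             "q1": s.q1, "q3": s.q3, "n_pixels": s.n_pixels,
             "low_support": s.low_support}
            for name, s in summary.regions.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def render(bmap: BrixMap, summary: ViolinSummary, out_dir: str | Path,
           vmin: float | None = None, vmax: float | None = None,
           prefix: str = "brix") -> tuple[Path, Path]:
    """Write the heatmap and violin-plot PNGs; outputs carry no timestamps so
    re-rendering the same inputs is byte-identical."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    heat_path = out_dir / f"{prefix}_heatmap.png"
    violin_path = out_dir / f"{prefix}_violin.png"

    on = bmap.values[bmap.mask]
    vmin = float(on.min()) if vmin is None else vmin
    vmax = float(on.max()) if vmax is None else vmax
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(np.where(bmap.mask, bmap.values, np.nan),
                   vmin=vmin, vmax=vmax, cmap="turbo")
    fig.colorbar(im, ax=ax, label="Brix (%)")
    ax.set_axis_off()
    fig.savefig(heat_path, dpi=120, metadata={"Software": "brixmap"})
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    order = ("whole", "bottom", "top")
    for i, name in enumerate(order):
        s = summary.regions[name]
        width = s.kde_density / max(s.kde_density.max(), 1e-12) * 0.38
        ax.fill_betweenx(s.kde_grid, i - width, i + width, alpha=0.6)
        ax.vlines(i, s.q1, s.q3, color="black", lw=4)      # IQR bar
        ax.plot(i, s.median, "o", color="red", ms=5)       # median dot
        ax.hlines(s.mean, i - 0.42, i + 0.42, color="C3", lw=1.2)  # mean line
    ax.set_xticks(range(len(order)), order)
    ax.set_ylabel("Brix (%)")
    fig.tight_layout()
    fig.savefig(violin_path, dpi=120, metadata={"Software": "brixmap"})
    plt.close(fig)
    return heat_path, violin_path
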