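"""Spectral pretreatments: Savitzky-Golay smoothing, SNV, second derivative,
autoscaling, and the SpectrumTable container they operate on.

All pretreatments act row-wise (one spectrum per row).  SNV removes per-
spectrum additive offsets and multiplicative scatter by centering each row and
dividing by its sample standard deviation (n-1 denominator).  Autoscaling is
the column-wise analogue fitted on training data only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .hypercube import WavelengthAxis

__all__ = [
    "SpectrumTable",
    "ScalingParams",
    "Pretreatment",
    "savgol_smooth",
    "snv",
    "snv_rows",
    "second_derivative",
    "autoscale_fit",
    "autoscale_apply",
    "read_table_csv",
    "write_table_csv",
]


@dataclass
class SpectrumTable:
    """Samples x bands matrix with a wavelength axis and optional Brix values.

    ``meta`` (optional) carries per-row sample bookkeeping such as fruit id,
    measured side and top/bottom half, used by the train/test splitter.
    """

    X: np.ndarray
    axis: WavelengthAxis
    y: np.ndarray | None = None
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[1] != len(self.axis):
            raise ValueError(
                f"{self.X.shape[1]} columns vs axis length {len(self.axis)}"
            )
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (self.X.shape[0],):
                raise ValueError("y length must equal the number of rows")
        if self.meta is not None and len(self.meta) != self.X.shape[0]:
            raise ValueError("meta length must equal the number of rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def replace(self, X: np.ndarray, axis: WavelengthAxis | None = None) -> "SpectrumTable":
        return SpectrumTable(X, axis or self.axis, self.y, self.meta)

    def subset_rows(self, idx) -> "SpectrumTable":
        meta = self.meta.iloc[idx].reset_index(drop=True) if self.meta is not None else None
        y = self.y[idx] if self.y is not None else None
        return SpectrumTable(self.X[idx], self.axis, y, meta)


@dataclass(frozen=True)
class ScalingParams:
    """Per-band autoscaling parameters fitted on a training set."""

    means: np.ndarray
    stds: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "stds", np.asarray(self.stds, dtype=float))
        if self.means.shape != self.stds.shape or self.means.ndim != 1:
            raise ValueError("means and stds must be matching 1-D vectors")
        if np.any(self.stds <= 0):
            raise ValueError("autoscaling stds must be strictly positive")


def savgol_smooth(table: SpectrumTable, window: int = 7, polyorder: int = 2) -> SpectrumTable:
    """Savitzky-Golay smoothing per row; shape preserved via reflect padding."""
    _check_sg(window, polyorder, table.n_bands)
    sm = savgol_filter(table.X, window, polyorder, axis=1, mode="mirror")
    return table.replace(sm)


def snv_rows(X: np.ndarray) -> np.ndarray:
    """SNV on a bare 2-D array: row-center, divide by row sample SD (n-1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least two bands per row")
    sd = X.std(axis=1, ddof=1)
    zero = sd == 0
    if np.any(zero):
        raise ValueError(f"zero-variance row(s) {np.flatnonzero(zero).tolist()}: SNV undefined")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def snv(table: SpectrumTable) -> SpectrumTable:
    """Standard normal variate transform of every spectrum in the table."""
    return table.replace(snv_rows(table.X))


def second_derivative(table: SpectrumTable, window: int = 7, polyorder: int = 2,
                      trim: int | tuple[int, int] | None = None) -> SpectrumTable:
    """Savitzky-Golay second derivative per row, with edge bands trimmed.

    The filter's least-squares fit is unreliable within half a window of each
    edge, so those bands are dropped and the axis shortened.  ``trim`` is
    bands-per-edge; a ``(left, right)`` pair allows asymmetric removal (the
    band counts some instruments report after derivative pretreatment imply an
    odd total trim, which a symmetric rule cannot produce).  Default:
    (window-1)/2 per side.

    The derivative is with respect to band index; for a uniform grid divide by
    the squared grid step to get per-nm^2 units.
    """
    _check_sg(window, polyorder, table.n_bands)
    if polyorder < 2:
        raise ValueError("second derivative needs polyorder >= 2")
    if trim is None:
        trim = (window - 1) // 2
    left, right = (trim, trim) if np.isscalar(trim) else trim
    if left < 0 or right < 0:
        raise ValueError("trim must be non-negative")
    if table.n_bands - left - right < 1:
        raise ValueError("trim removes every band")
    d2 = savgol_filter(table.X, window, polyorder, deriv=2, axis=1, mode="mirror")
    stop = table.n_bands - right
    return table.replace(d2[:, left:stop],
                         WavelengthAxis(table.axis.centers[left:stop]))


def autoscale_fit(table: SpectrumTable) -> ScalingParams:
    """Fit per-band mean/SD (n-1) on a training table."""
    if table.n_samples < 2:
        raise ValueError("autoscaling needs at least two rows")
    means = table.X.mean(axis=0)
    stds = table.X.std(axis=0, ddof=1)
    zero = stds == 0
    if np.any(zero):
        raise ValueError(
            f"zero-variance band(s) at column {np.flatnonzero(zero).tolist()}"
        )
    return ScalingParams(means, stds)


def autoscale_apply(table: SpectrumTable, params: ScalingParams) -> SpectrumTable:
    """Apply stored autoscaling; never refits on the data it is given."""
    if table.n_bands != params.means.size:
        raise ValueError("band count does not match scaling parameters")
    return table.replace((table.X - params.means) / params.stds)


@dataclass(frozen=True)
class Pretreatment:
    """Ordered pretreatment chain applied to mean spectra before modelling.

    Order is fixed: smoothing, then SNV (optional), then the SG second
    derivative (optional).  Autoscaling happens downstream, as part of model
    fitting, because its parameters belong to the training set.
    """

    snv: bool = False
    deriv2: bool = False
    smooth_window: int = 0          # 0 disables smoothing
    smooth_polyorder: int = 2
    deriv_window: int = 7
    deriv_polyorder: int = 2
    deriv_trim: tuple[int, int] | int | None = None

    def apply(self, table: SpectrumTable) -> SpectrumTable:
        out = table
        if self.smooth_window:
            out = savgol_smooth(out, self.smooth_window, self.smooth_polyorder)
        if self.snv:
            out = snv(out)
        if self.deriv2:
            out = second_derivative(out, self.deriv_window, self.deriv_polyorder,
                                    self.deriv_trim)
        return out

    @property
    def label(self) -> str:
        parts = []
        if self.snv:
            parts.append("SNV")
        if self.deriv2:
            parts.append("2nd derivative")
        return " + ".join(parts) if parts else "Raw"

    def to_dict(self) -> dict:
        trim = self.deriv_trim
        if trim is not None and not np.isscalar(trim):
            trim = list(trim)
        return {"snv": self.snv, "deriv2": self.deriv2,
                "smooth_window": self.smooth_window,
                "smooth_polyorder": self.smooth_polyorder,
                "deriv_window": self.deriv_window,
                "deriv_polyorder": self.deriv_polyorder,
                "deriv_trim": trim}

    @classmethod
    def from_dict(cls, d: dict) -> "Pretreatment":
        trim = d.get("deriv_trim")
        if isinstance(trim, list):
            trim = tuple(trim)
        return cls(snv=d["snv"], deriv2=d["deriv2"],
                   smooth_window=d["smooth_window"],
                   smooth_polyorder=d["smooth_polyorder"],
                   deriv_window=d["deriv_window"],
                   deriv_polyorder=d["deriv_polyorder"],
                   deriv_trim=trim)


def _check_sg(window: int, polyorder: int, n_bands: int) -> None:
    if window % 2 == 0:
        raise ValueError("Savitzky-Golay window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > n_bands:
        raise ValueError("window exceeds the number of bands")


# ---------------------------------------------------------------------------
# CSV round-trip: header row = wavelengths, optional 'brix' column, optional
# meta columns (prefixed 'meta_') for sample bookkeeping.

def write_table_csv(table: SpectrumTable, path: str | Path) -> None:
    df = pd.DataFrame(table.X, columns=[f"{w:.4f}" for w in table.axis.centers])
    if table.y is not None:
        df.insert(0, "brix", table.y)
    if table.meta is not None:
        for col in reversed(table.meta.columns):
            df.insert(0, f"meta_{col}", table.meta[col].to_numpy())
    df.to_csv(path, index=False)


def read_table_csv(path: str | Path) -> SpectrumTable:
    df = pd.read_csv(path)
    meta_cols = [c for c in df.columns if c.startswith("meta_")]
    meta = None
    if meta_cols:
        meta = df[meta_cols].rename(columns=lambda c: c[len("meta_"):])
    y = df["brix"].to_numpy() if "brix" in df.columns else None
    band_cols = [c for c in df.columns if c not in meta_cols and c != "brix"]
    axis = WavelengthAxis(np.array([float(c) for c in band_cols]))
    return SpectrumTable(df[band_cols].to_numpy(float), axis, y, meta)
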