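"""Hyperspectral cube containers, I/O and reflectance calibration.

A hypercube is a ``rows x cols x bands`` array of relative reflectance with a
wavelength axis along the trailing dimension.  Raw camera counts are converted
to relative reflectance with white/dark reference images,

    R = (S - D) / (W - D),

evaluated elementwise per wavelength and pixel.  Values above 1 are legal
(specular/Fresnel geometry); saturated pixels are dealt with downstream.

Two on-disk formats are supported: a plain ENVI header + raw binary pair
(BSQ or BIL interleave) and a portable ``.npz`` container holding the array
plus JSON metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthAxis",
    "Hypercube",
    "ReferenceCubes",
    "read_cube",
    "write_cube",
    "calibrate_reflectance",
    "select_band_range",
    "nearest_band",
]


@dataclass(frozen=True)
class WavelengthAxis:
    """Band-center wavelengths in nm, strictly increasing."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", c)
        if c.ndim != 1 or c.size < 2:
            raise ValueError("wavelength axis needs at least two 1-D centers")
        if not np.all(np.isfinite(c)) or np.any(c <= 0):
            raise ValueError("wavelength centers must be finite and positive")
        if np.any(np.diff(c) <= 0):
            raise ValueError("wavelength centers must be strictly increasing")

    def __len__(self) -> int:
        return int(self.centers.size)


@dataclass
class Hypercube:
    """Reflectance cube (rows x cols x bands) with its wavelength axis."""

    data: np.ndarray
    axis: WavelengthAxis

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows x cols x bands)")
        if self.data.shape[2] != len(self.axis):
            raise ValueError(
                f"band dimension {self.data.shape[2]} does not match "
                f"axis length {len(self.axis)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ReferenceCubes:
    """White and dark reference images.

    Either full cubes matching the sample shape, or 2-D ``(cols, bands)``
    arrays for a push-broom system whose references are constant along the
    scan direction.  ``white_scale`` compensates an exposure / frame-rate
    difference between white-reference and sample acquisition (a white plate
    is often recorded at a different frame rate); 1.0 assumes the vendor has
    already normalised counts.
    """

    white: np.ndarray
    dark: np.ndarray
    white_scale: float = 1.0

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark references must share a shape")
        if self.white_scale <= 0:
            raise ValueError("white_scale must be positive")


def calibrate_reflectance(sample: np.ndarray, refs: ReferenceCubes,
                          axis: WavelengthAxis) -> Hypercube:
    """Convert raw counts to relative reflectance R = (S - D)/(W - D)."""
    s = np.asarray(sample, dtype=float)
    w = refs.white * refs.white_scale
    d = refs.dark
    if w.ndim == 2:  # per-(col, band) references broadcast over scan lines
        w = w[np.newaxis, :, :]
        d = d[np.newaxis, :, :]
    denom = w - d
    bad = denom <= 0
    if np.any(bad):
        idx = np.argwhere(bad)[0]
        raise ValueError(
            "white - dark is non-positive at (row, col, band) = "
            f"{tuple(int(i) for i in idx)}; calibration undefined there"
        )
    return Hypercube((s - d) / denom, axis)


def select_band_range(cube: Hypercube, lo: float, hi: float) -> Hypercube:
    """Restrict the cube to bands with lo <= wavelength <= hi."""
    if lo >= hi:
        raise ValueError("lo must be strictly below hi")
    keep = (cube.axis.centers >= lo) & (cube.axis.centers <= hi)
    if not np.any(keep):
        raise ValueError(f"no bands in [{lo}, {hi}] nm")
    return Hypercube(cube.data[:, :, keep], WavelengthAxis(cube.axis.centers[keep]))


def nearest_band(axis: WavelengthAxis, target: float) -> int:
    """Index of the band center closest to ``target``; ties go to the lower index."""
    return int(np.argmin(np.abs(axis.centers - target)))


# ---------------------------------------------------------------------------
# I/O

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float64): 5, np.dtype(np.float32): 4}


def _parse_envi_header(text: str) -> dict:
    """Parse the ``key = value`` lines of an ENVI header, honouring {...} lists."""
    meta: dict = {}
    body = text
    if body.lstrip().upper().startswith("ENVI"):
        body = body.lstrip()[4:]
    i = 0
    while i < len(body):
        eq = body.find("=", i)
        if eq == -1:
            break
        key = body[i:eq].strip().lower()
        rest = body[eq + 1:].lstrip()
        offset = eq + 1 + (len(body[eq + 1:]) - len(rest))
        if rest.startswith("{"):
            close = body.find("}", offset)
            if close == -1:
                raise ValueError(f"unterminated {{...}} for ENVI key '{key}'")
            meta[key] = body[offset + 1:close]
            i = close + 1
        else:
            nl = body.find("\n", offset)
            nl = len(body) if nl == -1 else nl
            meta[key] = body[offset:nl].strip()
            i = nl + 1
    return meta


def _read_envi(path: Path) -> Hypercube:
    hdr = path.with_suffix(".hdr")
    if not hdr.exists():
        raise FileNotFoundError(f"ENVI header {hdr} not found")
    meta = _parse_envi_header(hdr.read_text())
    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in meta:
            raise ValueError(f"ENVI header missing required field '{key}'")
    if "wavelength" not in meta:
        raise ValueError("ENVI header carries no wavelength list")
    cols = int(meta["samples"])
    rows = int(meta["lines"])
    bands = int(meta["bands"])
    dtype = np.dtype(_ENVI_DTYPES[int(meta["data type"])])
    interleave = meta["interleave"].strip().lower()
    wl = np.array([float(v) for v in meta["wavelength"].split(",")])
    if wl.size != bands:
        raise ValueError(f"{wl.size} wavelengths for {bands} bands")
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != rows * cols * bands:
        raise ValueError(
            f"binary holds {raw.size} values, header declares "
            f"{rows}x{cols}x{bands} = {rows * cols * bands}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:
        raise ValueError(f"unsupported interleave '{interleave}'")
    return Hypercube(np.ascontiguousarray(data, dtype=float), WavelengthAxis(wl))


def _write_envi(cube: Hypercube, path: Path, interleave: str = "bsq") -> None:
    interleave = interleave.lower()
    rows, cols, bands = cube.shape
    data = cube.data.astype(np.float64)
    if interleave == "bsq":
        flat = data.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = data.transpose(0, 2, 1)
    else:
        raise ValueError(f"unsupported interleave '{interleave}'")
    flat.tofile(path)
    wl = ", ".join(f"{v:.17g}" for v in cube.axis.centers)
    hdr = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "data type = 5\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(".hdr").write_text(hdr)


def _read_npz(path: Path) -> Hypercube:
    with np.load(path, allow_pickle=False) as z:
        if "wavelengths" not in z:
            raise ValueError(f"{path} carries no wavelength metadata")
        data = z["data"]
        wl = z["wavelengths"]
    if data.ndim != 3 or data.shape[2] != wl.size:
        raise ValueError(
            f"container shape {data.shape} inconsistent with "
            f"{wl.size} wavelengths"
        )
    return Hypercube(data, WavelengthAxis(wl))


def _write_npz(cube: Hypercube, path: Path) -> None:
    meta = json.dumps({"format": "brixmap-cube", "version": 1,
                       "units": "relative reflectance"})
    np.savez_compressed(path, data=cube.data, wavelengths=cube.axis.centers,
                        meta=np.array(meta))


def read_cube(path: str | Path, format: str | None = None) -> Hypercube:
    """Read a hypercube from an ENVI pair or an ``.npz`` container.

    The format is inferred from the suffix unless given explicitly
    (``"envi"`` or ``"npz"``).
    """
    path = Path(path)
    if format is None:
        format = "npz" if path.suffix == ".npz" else "envi"
    if format == "npz":
        return _read_npz(path)
    if format == "envi":
        return _read_envi(path)
    raise ValueError(f"unknown cube format '{format}'")


def write_cube(cube: Hypercube, path: str | Path, format: str | None = None,
               interleave: str = "bsq") -> None:
    """Write a hypercube as ENVI (.dat + .hdr) or an ``.npz`` container."""
    path = Path(path)
    if format is None:
        format = "npz" if path.suffix == ".npz" else "envi"
    if format == "npz":
        _write_npz(cube, path)
    elif format == "envi":
        _write_envi(cube, path, interleave=interleave)
    else:
        raise ValueError(f"unknown cube format '{format}'")
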