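"""File formats: ENVI-style cubes, band TIFFs, PNG masks, CSV tables.

The cube format is the classic ENVI layout — an ASCII ``.hdr`` with the band
wavelength list next to a flat binary ``.img`` (band-sequential, BSQ). Only
the small subset of header fields this package writes is parsed back.
"""

from __future__ import annotations

import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .grid import WavelengthGrid
from .simulate import Campaign, HyperCube

__all__ = [
    "write_envi",
    "read_envi",
    "write_band_tiffs",
    "write_mask_png",
    "read_mask_png",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_ground_truth_csv",
]

_DTYPE_CODES = {4: np.float32, 5: np.float64, 12: np.uint16, 2: np.int16}
_CODE_FOR = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}


def write_envi(cube: HyperCube, path_base: str | Path) -> tuple[Path, Path]:
    """Write ``<base>.hdr`` + ``<base>.img`` (BSQ interleave)."""
    base = Path(path_base)
    hdr, img = base.with_suffix(".hdr"), base.with_suffix(".img")
    rows, cols, bands = cube.values.shape
    data = np.ascontiguousarray(
        np.moveaxis(cube.values, 2, 0))  # BSQ: band, line, sample
    dtype = data.dtype if data.dtype in _CODE_FOR else np.dtype(np.float32)
    data = data.astype(dtype, copy=False)
    wl = ", ".join(f"{c:.4f}" for c in cube.grid.centers)
    hdr.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_CODE_FOR[dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"units = {cube.units}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n")
    data.tofile(img)
    return hdr, img


def _header_fields(text: str) -> dict[str, str]:
    # joins the brace-delimited wavelength block into one logical line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields = {}
    for line in text.splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(path_base: str | Path) -> HyperCube:
    """Read a cube written by :func:`write_envi` (BSQ or BIL interleave)."""
    base = Path(path_base)
    hdr = base if base.suffix == ".hdr" else base.with_suffix(".hdr")
    img = hdr.with_suffix(".img")
    f = _header_fields(hdr.read_text())
    rows, cols = int(f["lines"]), int(f["samples"])
    bands = int(f["bands"])
    dtype = _DTYPE_CODES[int(f["data type"])]
    interleave = f.get("interleave", "bsq").lower()
    wl = np.array([float(x) for x in
                   re.findall(r"[-\d.eE+]+", f["wavelength"].strip("{} "))])
    data = np.fromfile(img, dtype=dtype)
    if interleave == "bsq":
        values = np.moveaxis(data.reshape(bands, rows, cols), 0, 2)
    elif interleave == "bil":
        values = np.moveaxis(data.reshape(rows, bands, cols), 1, 2)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    return HyperCube(values=np.ascontiguousarray(values, dtype=float),
                     grid=WavelengthGrid(wl),
                     units=f.get("units", "dn"),
                     panel_region=None, background_region=None)


def write_band_tiffs(cube: HyperCube, outdir: str | Path,
                     prefix: str = "band") -> list[Path]:
    """One 16-bit TIFF per band, scaled to the cube's global maximum."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vmax = float(cube.values.max()) or 1.0
    paths = []
    for b, nm in enumerate(cube.grid.centers):
        img = np.round(cube.values[:, :, b] / vmax * 65535).astype(np.uint16)
        p = outdir / f"{prefix}_{nm:.1f}nm.tif"
        tifffile.imwrite(p, img)
        paths.append(p)
    return paths


def write_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    iio.imwrite(path, (mask.astype(np.uint8) * 255))
    return path


def read_mask_png(path: str | Path) -> np.ndarray:
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img >= 128


def write_spectrum_csv(spectrum: np.ndarray, grid: WavelengthGrid,
                       path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"wavelength_nm": grid.centers,
                  "reflectance": np.asarray(spectrum)}).to_csv(path,
                                                               index=False)
    return path


def read_spectrum_csv(path: str | Path) -> tuple[np.ndarray, WavelengthGrid]:
    df = pd.read_csv(path)
    return (df["reflectance"].to_numpy(),
            WavelengthGrid(df["wavelength_nm"].to_numpy()))


def write_ground_truth_csv(campaign: Campaign, path: str | Path) -> Path:
    path = Path(path)
    rows = [{"sample_id": s.sample_id, "stage": s.stage,
             "k_percent": s.k_percent, "seed": s.seed} for s in campaign]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
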