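"""DN-to-reflectance calibration, leaf segmentation and spectrum extraction.

The acquisition produces raw digital numbers (DN); dividing by the mean DN of
the gray reference panel band-by-band and multiplying by the panel's known
reflectance converts the cube to reflectance. The leaf is segmented by a
single-band threshold at the band nearest 800 nm (reflectance below 0.25 is
the background plate), and the whole-leaf mean spectrum over the retained
400-950 nm window is the sample's original spectrum R. Reference leaf
potassium content comes from a flame-photometer assay:

    K(%) = rho * V * t_s * 1e-4 / m

with rho the K mass concentration from the standard curve (ug/mL), V the
measuring liquid volume (mL), t_s the separation multiple and m the dry
sample mass (g).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import measure

from .grid import WavelengthGrid
from .simulate import HyperCube

__all__ = [
    "LeafSample",
    "LabAssay",
    "CalibrationError",
    "SegmentationError",
    "calibrate_reflectance",
    "segment_leaf",
    "mean_spectrum",
    "trim_bands",
    "lab_k_percent",
]

SEGMENTATION_BAND_NM = 800.0
SEGMENTATION_THRESHOLD = 0.25
TRIM_LO_NM = 400.0
TRIM_HI_NM = 950.0


class CalibrationError(RuntimeError):
    pass


class SegmentationError(RuntimeError):
    pass


@dataclass
class LeafSample:
    """One processed leaf: mask, whole-leaf mean spectrum and reference K."""

    sample_id: str
    stage: str
    mask: np.ndarray
    mean_spectrum: np.ndarray
    grid: WavelengthGrid
    k_percent: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise SegmentationError(f"{self.sample_id}: empty leaf mask")
        if self.mean_spectrum.shape != (len(self.grid),):
            raise ValueError(
                f"{self.sample_id}: spectrum length {self.mean_spectrum.size} "
                f"!= grid length {len(self.grid)}")


@dataclass(frozen=True)
class LabAssay:
    """Flame-photometer readings for one dried leaf sample."""

    rho: float  # K mass concentration from the standard curve, ug/mL
    volume: float  # measuring liquid volume, mL
    ts: float  # separation multiple, unitless
    mass: float  # dry sample mass, g

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if self.volume <= 0 or self.ts <= 0:
            raise ValueError("volume and separation multiple must be positive")
        if self.mass <= 0:
            raise ValueError(f"dry sample mass must be positive, got {self.mass}")


def calibrate_reflectance(cube_dn: HyperCube,
                          panel_region: np.ndarray | None = None,
                          panel_reflectance: float = 0.60,
                          dark_level: float = 0.0) -> HyperCube:
    """Convert a DN cube to reflectance against its gray reference panel.

    ``reflectance(px, b) = (dn(px, b) - dark) / (mean_panel_dn(b) - dark)
    * panel_reflectance``. The ratio form makes the result invariant to any
    global gain: doubling every DN leaves reflectance unchanged.
    """
    if cube_dn.units != "dn":
        raise CalibrationError(f"expected a DN cube, got units={cube_dn.units!r}")
    panel = cube_dn.panel_region if panel_region is None else panel_region
    if panel is None or not panel.any():
        raise CalibrationError("panel region is empty")
    panel_dn = cube_dn.values[panel].mean(axis=0) - dark_level
    bad = np.nonzero(panel_dn <= 0)[0]
    if bad.size:
        nm = cube_dn.grid.centers[bad[0]]
        raise CalibrationError(
            f"non-positive panel mean DN at band {bad[0]} ({nm:.1f} nm)")
    refl = ((cube_dn.values.astype(float) - dark_level) / panel_dn
            * panel_reflectance)
    return HyperCube(values=refl, grid=cube_dn.grid, units="reflectance",
                     panel_region=cube_dn.panel_region,
                     background_region=cube_dn.background_region)


def segment_leaf(cube: HyperCube, band_nm: float = SEGMENTATION_BAND_NM,
                 low: float = SEGMENTATION_THRESHOLD) -> np.ndarray:
    """Single-band threshold segmentation at the band nearest ``band_nm``.

    Pixels with reflectance >= ``low`` at that band, minus the declared panel
    region, form the candidate foreground; the largest 4-connected component
    is retained as the leaf (drops isolated speckle).
    """
    if cube.units != "reflectance":
        raise SegmentationError("segment on a calibrated (reflectance) cube")
    b = cube.grid.nearest_index(band_nm)
    fg = cube.values[:, :, b] >= low
    if cube.panel_region is not None:
        fg &= ~cube.panel_region
    if not fg.any():
        raise SegmentationError(
            f"no pixel reaches reflectance {low} at {cube.grid.centers[b]:.1f} nm")
    labels = measure.label(fg, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background label
    return labels == int(np.argmax(counts))


def mean_spectrum(cube: HyperCube, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean of the cube over the masked pixels."""
    if mask.shape != cube.values.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} != cube spatial shape "
            f"{cube.values.shape[:2]}")
    if not mask.any():
        raise SegmentationError("empty mask")
    return cube.values[mask].mean(axis=0)


def trim_bands(obj, lo_nm: float = TRIM_LO_NM, hi_nm: float = TRIM_HI_NM):
    """Restrict a spectrum-with-grid, cube or bare grid to ``[lo, hi]`` nm.

    Accepts a :class:`HyperCube`, a ``(spectrum, grid)`` pair, or a
    :class:`WavelengthGrid`; returns the same kind of object with only bands
    whose centers fall in the closed interval. Idempotent.
    """
    if isinstance(obj, HyperCube):
        idx = obj.grid.window_indices(lo_nm, hi_nm)
        if idx.size == 0:
            raise ValueError(f"no band centers inside [{lo_nm}, {hi_nm}] nm")
        return HyperCube(values=obj.values[:, :, idx],
                         grid=WavelengthGrid(obj.grid.centers[idx]),
                         units=obj.units, panel_region=obj.panel_region,
                         background_region=obj.background_region)
    if isinstance(obj, WavelengthGrid):
        idx = obj.window_indices(lo_nm, hi_nm)
        if idx.size == 0:
            raise ValueError(f"no band centers inside [{lo_nm}, {hi_nm}] nm")
        return WavelengthGrid(obj.centers[idx])
    spectrum, grid = obj
    idx = grid.window_indices(lo_nm, hi_nm)
    if idx.size == 0:
        raise ValueError(f"no band centers inside [{lo_nm}, {hi_nm}] nm")
    return np.asarray(spectrum)[..., idx], WavelengthGrid(grid.centers[idx])


def lab_k_percent(assay: LabAssay) -> float:
    """Leaf potassium content (%) from flame-photometer assay readings."""
    return assay.rho * assay.volume * assay.ts * 1e-4 / assay.mass
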