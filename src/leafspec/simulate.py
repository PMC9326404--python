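"""Synthetic hyperspectral leaf scenes with known potassium ground truth.

Emulates a benchtop VNIR imaging-spectrometer acquisition of single cotton
leaves on a dark background plate with a gray reference panel: a 128-band
cube of raw digital numbers (DN), one lobed leaf per scene, and per-stage
leaf potassium content (LKC, % of dry mass) drawn from the field campaign's
stage distributions (60 leaves per growth stage, three stages).

Potassium is linked to the optical signal through three configurable linear
effects, each with known ground truth for recovery tests:

* **spectral** — the height of the near-infrared reflectance plateau
  (760-950 nm) decreases linearly with K, emulating the rise of VIS/NIR
  reflectance under K deficiency;
* **texture** — the amplitude of multiplicative per-pixel speckle decreases
  with K, so K-deficient leaves show rougher gray-level texture;
* **color** — overall leaf brightness decreases with K.

The generator makes no claim to radiative-transfer realism (no PROSPECT-type
leaf optics, line-spread functions or illumination geometry); it provides the
statistical structure the downstream analysis assumes, with ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as _draw_polygon

from .grid import InvalidConfigError, WavelengthGrid, make_band_grid

__all__ = [
    "STAGES",
    "STAGE_K_PARAMS",
    "StageKParams",
    "SceneConfig",
    "GroundTruth",
    "HyperCube",
    "CampaignSample",
    "Campaign",
    "make_band_grid",
    "reflectance_model",
    "render_scene",
    "generate_campaign",
    "GenerationError",
    "DomainError",
]

STAGES = ("budding", "flowering", "boll")


class GenerationError(RuntimeError):
    """Scene synthesis produced a degenerate result (e.g. empty leaf)."""


class DomainError(ValueError):
    """An input value lies outside its physically configured domain."""


@dataclass(frozen=True)
class StageKParams:
    """Truncated-normal LKC distribution for one growth stage (all in %)."""

    min: float
    max: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.min < self.mean < self.max):
            raise InvalidConfigError(
                f"stage K params need min < mean < max, got {self}")
        if self.sd <= 0:
            raise InvalidConfigError("stage K sd must be positive")


#: Per-stage LKC statistics of the field campaign (min, max, mean, sd in %).
STAGE_K_PARAMS: dict[str, StageKParams] = {
    "budding": StageKParams(min=0.51, max=3.56, mean=1.63, sd=0.81),
    "flowering": StageKParams(min=0.57, max=2.80, mean=1.18, sd=0.44),
    "boll": StageKParams(min=0.40, max=2.30, mean=1.25, sd=0.56),
}


@dataclass(frozen=True)
class SceneConfig:
    """All knobs of the synthetic acquisition.

    Sensor model: ``DN = reflectance * illumination_gain + dark_current +
    N(0, noise_sd)``, per pixel and band. Defaults are the study conditions;
    ``image_shape`` defaults to a desk-scale 192x192 scene (the full-frame
    692x520 sensor is available by config).
    """

    image_shape: tuple[int, int] = (192, 192)
    n_leaves_per_stage: int = 60
    stage_k_params: dict[str, StageKParams] = field(
        default_factory=lambda: dict(STAGE_K_PARAMS))
    # band grid (128 x 5.2 nm from 376 nm -> 106 bands inside 400-950 nm)
    n_bands: int = 128
    start_nm: float = 376.0
    spacing_nm: float = 5.2
    # radiometry
    panel_reflectance: float = 0.60
    background_reflectance: float = 0.12
    illumination_gain: float = 3000.0  # DN per unit reflectance
    dark_current: float = 100.0  # DN
    noise_sd: float = 8.0  # DN
    # K-linked optical effects (all linear in K around k_reference)
    k_reference: float = 1.3  # % ; pivot of the linear links
    nir_plateau: float = 0.60  # plateau reflectance at k = k_reference
    nir_k_slope: float = 0.04  # plateau drop per +1% K
    leaf_plateau_jitter_sd: float = 0.015  # per-leaf plateau variability
    speckle_base: float = 0.08  # speckle amplitude at k = k_reference
    speckle_k_slope: float = 0.03  # amplitude rise per -1% K
    brightness_k_slope: float = 0.02  # mean-brightness rise per -1% K
    spatial_variation_sd: float = 0.04  # smooth within-leaf field, rel. sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel_reflectance <= 0.25:
            raise InvalidConfigError(
                "panel reflectance must exceed the 0.25 segmentation threshold")
        if not (0 <= self.background_reflectance < 0.25):
            raise InvalidConfigError(
                "background reflectance must sit below the 0.25 threshold")
        if self.illumination_gain <= 0:
            raise InvalidConfigError("illumination gain must be positive")
        if min(self.image_shape) < 32:
            raise InvalidConfigError("scene must be at least 32x32 pixels")
        for name, p in self.stage_k_params.items():
            if not isinstance(p, StageKParams):
                raise InvalidConfigError(f"stage {name!r}: expected StageKParams")

    def grid(self) -> WavelengthGrid:
        return make_band_grid(self.n_bands, self.start_nm, self.spacing_nm)

    def k_domain(self) -> tuple[float, float]:
        """Union of the configured stage K ranges (%)."""
        return (min(p.min for p in self.stage_k_params.values()),
                max(p.max for p in self.stage_k_params.values()))


@dataclass(frozen=True)
class GroundTruth:
    """Per-leaf truth recorded at generation time for recovery tests."""

    k_percent: float
    informative_bands: np.ndarray  # nm centers where K affects reflectance
    texture_effect: float  # speckle amplitude of this leaf
    color_effect: float  # brightness multiplier of this leaf


@dataclass
class HyperCube:
    """A rows x cols x bands image cube with its band grid and scene regions.

    ``units`` is ``"dn"`` for raw sensor counts or ``"reflectance"`` after
    panel calibration. ``panel_region`` / ``background_region`` are boolean
    pixel masks declared by the acquisition (generator or config), not
    inferred from the data.
    """

    values: np.ndarray
    grid: WavelengthGrid
    units: str
    panel_region: np.ndarray
    background_region: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise InvalidConfigError("cube must be rows x cols x bands")
        if self.values.shape[2] != len(self.grid):
            raise InvalidConfigError(
                f"cube has {self.values.shape[2]} bands but grid has "
                f"{len(self.grid)}")
        if self.units not in ("dn", "reflectance"):
            raise InvalidConfigError(f"unknown units tag {self.units!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def reflectance_model(k_percent: float, grid: WavelengthGrid,
                      config: SceneConfig | None = None,
                      plateau_jitter: float = 0.0) -> np.ndarray:
    """Deterministic green-leaf reflectance spectrum for a leaf with given LKC.

    The curve has chlorophyll absorption minima near 450 and 680 nm, a green
    reflection maximum near 550 nm, a red-edge rise over 690-760 nm and a
    near-infrared plateau over 760-950 nm whose height decreases linearly
    with K: ``plateau = nir_plateau - nir_k_slope * (k - k_reference)``.
    ``plateau_jitter`` adds per-leaf biological variability (drawn by the
    scene renderer, zero here by default so the function stays deterministic).
    """
    config = config or SceneConfig()
    lo, hi = config.k_domain()
    if not (lo <= k_percent <= hi):
        raise DomainError(
            f"K = {k_percent}% outside configured domain [{lo}, {hi}]%")
    lam = grid.centers
    vis = (0.05
           + 0.10 * _gauss(lam, 550.0, 30.0)
           - 0.022 * _gauss(lam, 450.0, 16.0)
           - 0.032 * _gauss(lam, 680.0, 16.0))
    plateau = (config.nir_plateau
               - config.nir_k_slope * (k_percent - config.k_reference)
               + plateau_jitter)
    w = 1.0 / (1.0 + np.exp(-(lam - 715.0) / 13.0))
    r = vis * (1.0 - w) + plateau * w
    return np.clip(r, 0.0, 1.2)


def _leaf_mask(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Rasterize a randomized five-lobed polar polygon centered in the frame.

    Non-convex by construction so masked texture statistics are genuinely
    exercised on irregular regions.
    """
    rows, cols = shape
    cy = rows / 2 + rng.uniform(-0.02, 0.02) * rows
    cx = cols / 2 + rng.uniform(-0.02, 0.02) * cols
    r0 = 0.30 * min(rows, cols)
    phase5 = rng.uniform(0, 2 * np.pi)
    phase2 = rng.uniform(0, 2 * np.pi)
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    radius = r0 * (1.0
                   + 0.22 * np.cos(5 * theta + phase5)
                   + 0.05 * np.cos(2 * theta + phase2))
    rr = cy + radius * np.sin(theta)
    cc = cx + radius * np.cos(theta)
    pr, pc = _draw_polygon(rr, cc, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[pr, pc] = True
    return mask


def _panel_mask(shape: tuple[int, int]) -> np.ndarray:
    """Gray reference panel: a square block in the top-left corner."""
    side = max(6, min(shape) // 10)
    mask = np.zeros(shape, dtype=bool)
    mask[2:2 + side, 2:2 + side] = True
    return mask


def render_scene(config: SceneConfig, k_percent: float, seed: int,
                 ) -> tuple[HyperCube, np.ndarray, GroundTruth]:
    """Render one leaf scene as a raw-DN cube.

    Returns ``(cube, leaf_mask, truth)``. Per-pixel leaf spectra are
    ``reflectance_model(k) * smooth spatial field * (1 + speckle)``; the
    panel region sits at ``panel_reflectance`` and the background plate at
    ``background_reflectance``. DN counts follow the sensor model in
    :class:`SceneConfig`. Identical ``(config, k_percent, seed)`` give a
    bit-identical cube.
    """
    rng = np.random.default_rng(seed)
    grid = config.grid()
    shape = tuple(config.image_shape)

    leaf = _leaf_mask(shape, rng)
    panel = _panel_mask(shape)
    leaf &= ~panel
    if not leaf.any():
        raise GenerationError("leaf region empty after shape synthesis")
    background = ~leaf & ~panel

    jitter = rng.normal(0.0, config.leaf_plateau_jitter_sd)
    spectrum = reflectance_model(k_percent, grid, config, plateau_jitter=jitter)

    # smooth within-leaf field (illumination + leaf structure), mean 1
    raw = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(raw, sigma=min(shape) / 16.0)
    sd = smooth.std()
    if sd > 0 and config.spatial_variation_sd > 0:
        field2d = 1.0 + config.spatial_variation_sd * (smooth - smooth.mean()) / sd
    else:
        field2d = np.ones(shape)

    brightness = 1.0 + config.brightness_k_slope * (config.k_reference - k_percent)
    speckle_amp = float(np.clip(
        config.speckle_base + config.speckle_k_slope
        * (config.k_reference - k_percent), 0.0, 0.5))
    speckle = 1.0 + speckle_amp * rng.standard_normal(shape)

    field_px = np.clip(field2d * brightness * speckle, 0.05, None)

    refl = np.empty(shape + (len(grid),), dtype=float)
    refl[background] = config.background_reflectance
    refl[panel] = config.panel_reflectance
    refl[leaf] = field_px[leaf, None] * spectrum[None, :]
    np.clip(refl, 0.0, 1.2, out=refl)

    dn = refl * config.illumination_gain + config.dark_current
    if config.noise_sd > 0:
        dn += rng.normal(0.0, config.noise_sd, size=dn.shape)
    np.clip(dn, 0.0, None, out=dn)

    cube = HyperCube(values=dn, grid=grid, units="dn",
                     panel_region=panel, background_region=background)
    truth = GroundTruth(
        k_percent=float(k_percent),
        informative_bands=grid.centers[grid.window_indices(760.0, 950.0)],
        texture_effect=speckle_amp,
        color_effect=brightness,
    )
    return cube, leaf, truth


@dataclass(frozen=True)
class CampaignSample:
    """One leaf of a campaign: identity, truth and its private render seed."""

    sample_id: str
    stage: str
    seed: int
    truth: GroundTruth

    @property
    def k_percent(self) -> float:
        return self.truth.k_percent

    def render(self, config: SceneConfig) -> tuple[HyperCube, np.ndarray]:
        """(Re)render this sample's scene; cheap and exactly reproducible."""
        cube, mask, _ = render_scene(config, self.truth.k_percent, self.seed)
        return cube, mask


@dataclass(frozen=True)
class Campaign:
    """A full acquisition campaign: per-stage collections of leaf samples.

    Cubes are rendered on demand from per-sample seeds (``sample.render``)
    rather than held in memory; rendering is deterministic, so a campaign is
    fully defined by ``(config, seed)``.
    """

    config: SceneConfig
    seed: int
    samples: tuple[CampaignSample, ...]

    def stage_samples(self, stage: str) -> list[CampaignSample]:
        return [s for s in self.samples if s.stage == stage]

    def k_values(self, stage: str | None = None) -> np.ndarray:
        sel = self.samples if stage is None else self.stage_samples(stage)
        return np.array([s.k_percent for s in sel])

    def __iter__(self) -> Iterator[CampaignSample]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)


def noiseless_config(**overrides) -> SceneConfig:
    """A :class:`SceneConfig` with every stochastic amplitude set to zero.

    Under this config a calibrated leaf pixel reproduces
    :func:`reflectance_model` exactly; useful for identity and
    parameter-recovery tests.
    """
    base = dict(noise_sd=0.0, leaf_plateau_jitter_sd=0.0, speckle_base=0.0,
                speckle_k_slope=0.0, brightness_k_slope=0.0,
                spatial_variation_sd=0.0)
    base.update(overrides)
    return SceneConfig(**base)


@lru_cache(maxsize=None)
def _matched_parent(p: StageKParams) -> tuple[float, float]:
    """Parent-normal (mu, sigma) whose [min, max]-truncation has the stage's
    mean and sd.

    Truncation shifts moments, so drawing from N(mean, sd) directly would
    bias the sample mean and shrink the sd; this solves the two-moment
    matching problem instead (least squares, since a configured sd very
    close to the uniform-limit sd of the interval may be only approximately
    reachable).
    """
    from scipy import optimize, stats

    def moments(params):
        mu, log_sigma = params
        sigma = float(np.exp(log_sigma))
        a, b = (p.min - mu) / sigma, (p.max - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - p.mean, float(np.sqrt(v)) - p.sd]

    sol = optimize.least_squares(moments, x0=[p.mean, np.log(p.sd)],
                                 xtol=1e-12, ftol=1e-12)
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _truncnorm_rejection(rng: np.random.Generator, p: StageKParams,
                         n: int) -> np.ndarray:
    """Truncated-normal K draws by rejection: matches min/max/mean/sd jointly."""
    mu, sigma = _matched_parent(p)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mu, sigma, size=2 * (n - filled) + 8)
        ok = draw[(draw >= p.min) & (draw <= p.max)]
        take = min(ok.size, n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def generate_campaign(config: SceneConfig | None = None,
                      seed: int = 0) -> Campaign:
    """Generate a seeded campaign: ``n_leaves_per_stage`` leaves per stage.

    Defaults give 3 stages x 60 leaves = 180 samples with stage LKC drawn
    from truncated normals matching the field campaign's statistics.
    """
    config = config or SceneConfig()
    if config.n_leaves_per_stage < 3:
        raise InvalidConfigError(
            "need at least 3 leaves per stage for a calibration/validation split")
    rng = np.random.default_rng(seed)
    samples: list[CampaignSample] = []
    grid = config.grid()
    informative = grid.centers[grid.window_indices(760.0, 950.0)]
    for stage in STAGES:
        if stage not in config.stage_k_params:
            continue
        p = config.stage_k_params[stage]
        ks = _truncnorm_rejection(rng, p, config.n_leaves_per_stage)
        seeds = rng.integers(0, 2 ** 31, size=config.n_leaves_per_stage)
        for i, (k, s) in enumerate(zip(ks, seeds)):
            amp = float(np.clip(
                config.speckle_base
                + config.speckle_k_slope * (config.k_reference - k), 0.0, 0.5))
            truth = GroundTruth(
                k_percent=float(k),
                informative_bands=informative,
                texture_effect=amp,
                color_effect=1.0 + config.brightness_k_slope
                * (config.k_reference - k),
            )
            samples.append(CampaignSample(
                sample_id=f"{stage}_{i:03d}", stage=stage, seed=int(s),
                truth=truth))
    return Campaign(config=config, seed=seed, samples=tuple(samples))
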