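"""End-to-end orchestration: simulate -> preprocess -> CWT -> select ->
image features -> model, with reproducible seeding and report artifacts.

A single global seed expands into per-component sub-seeds by a documented
counter scheme (`subseed`): each (stage, component) pair hashes its textual
tags into a `numpy.random.SeedSequence` together with the global seed, so
every stochastic stage is independently reproducible and the whole run is
deterministic byte-for-byte.

Scenes are rendered on demand from per-sample seeds, twice per stage: once
to extract whole-leaf spectra, and again — after wavelength selection — to
build the characteristic-wavelength grayscale image database. Re-rendering
is bit-exact, so no cube is ever held for more than one sample at a time.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import (color_features, screen_image_features,
                       texture_features)
from .grid import WavelengthGrid
from .modeling import (ComparisonReport, SplitResult,
                       concentration_gradient_split, fit_plsr,
                       fuse_and_compare)
from .preprocess import calibrate_reflectance, mean_spectrum, segment_leaf, \
    trim_bands
from .selection import (STAGE_RF_THRESHOLDS, SelectionResult, cars_select,
                        random_frog_select)
from .simulate import (STAGES, Campaign, SceneConfig, StageKParams,
                       generate_campaign)
from .wavelet import CorrelationMap, correlation_map, cwt_matrix, \
    coefficient_image

__all__ = ["RunConfig", "StageResult", "PipelineResult", "subseed",
           "run_pipeline", "write_report"]

logger = logging.getLogger("leafspec")


def subseed(seed: int, *tags) -> int:
    """Derive a stable sub-seed (< 2^31) from a global seed and textual tags."""
    keys = [int(seed)]
    for t in tags:
        keys.append(zlib.crc32(str(t).encode()) if not isinstance(t, (int, np.integer))
                    else int(t))
    return int(np.random.SeedSequence(keys).generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one pipeline run (YAML round-trippable)."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    stages: tuple[str, ...] = STAGES
    scale_exponents: tuple[int, ...] = tuple(range(1, 11))
    selectors: tuple[str, ...] = ("CARS", "RF")
    rf_thresholds: dict = field(
        default_factory=lambda: dict(STAGE_RF_THRESHOLDS))
    cars_runs: int = 50
    rf_iterations: int = 10_000
    cv_folds: int = 5
    max_latent: int = 10
    selection_cap: int = 10
    glcm_distance: int = 1
    glcm_levels: int = 256
    seed: int = 0
    save_images: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scene"]["stage_k_params"] = {
            k: dataclasses.asdict(v)
            for k, v in self.scene.stage_k_params.items()}
        d["scene"]["image_shape"] = list(self.scene.image_shape)
        d["stages"] = list(self.stages)
        d["scale_exponents"] = list(self.scale_exponents)
        d["selectors"] = list(self.selectors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        scene = dict(d.pop("scene", {}))
        if "stage_k_params" in scene:
            scene["stage_k_params"] = {
                k: StageKParams(**v) for k, v in scene["stage_k_params"].items()}
        if "image_shape" in scene:
            scene["image_shape"] = tuple(scene["image_shape"])
        for key in ("stages", "scale_exponents", "selectors"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(scene=SceneConfig(**scene), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class StageResult:
    """Everything computed for one growth stage."""

    stage: str
    sample_ids: list[str]
    k: pd.Series
    grid: WavelengthGrid
    spectra: np.ndarray  # (n, bands) whole-leaf R spectra
    split: SplitResult
    corr_map: CorrelationMap
    selections: dict  # (selector, label) -> SelectionResult
    spectral_tables: dict  # (selector, label) -> DataFrame
    image_label: str  # feature set whose wavelengths built the image database
    image_wavelengths: np.ndarray
    color_selection: SelectionResult
    texture_selection: SelectionResult
    color_table: pd.DataFrame
    texture_table: pd.DataFrame
    report: ComparisonReport


@dataclass
class PipelineResult:
    config: RunConfig
    campaign: Campaign
    stages: dict[str, StageResult]

    def summary(self) -> pd.DataFrame:
        rows = []
        for stage, res in self.stages.items():
            for df in (res.report.spectral, res.report.fusion):
                part = df.copy()
                part.insert(0, "stage", stage)
                rows.append(part)
        return pd.concat(rows, ignore_index=True)


def _scale_exponent(label: str) -> int | None:
    return int(label.split("-")[1]) if label.startswith("CWT-") else None


def _stage_images(samples, config: RunConfig, label: str,
                  wavelengths: np.ndarray):
    """Yield (sample, mask, {wavelength: 8-bit image}) per leaf, re-rendered."""
    exp = _scale_exponent(label)
    for s in samples:
        cube, _ = s.render(config.scene)
        refl = calibrate_reflectance(
            cube, panel_reflectance=config.scene.panel_reflectance)
        refl = trim_bands(refl)
        mask = segment_leaf(refl)
        images = {
            float(wl): coefficient_image(refl, mask, exp or 1, wl,
                                         raw_band=exp is None)
            for wl in wavelengths
        }
        yield s, mask, images


def _run_stage(campaign: Campaign, config: RunConfig, stage: str,
               ) -> StageResult:
    seed = config.seed
    samples = campaign.stage_samples(stage)
    ids = [s.sample_id for s in samples]
    k = pd.Series(campaign.k_values(stage), index=ids, name="k_percent")
    logger.info("[%s] %d samples, K in [%.2f, %.2f]%%", stage, len(ids),
                k.min(), k.max())

    # whole-leaf spectra over the retained window
    spectra = []
    grid = None
    for s in samples:
        cube, _ = s.render(config.scene)
        refl = calibrate_reflectance(
            cube, panel_reflectance=config.scene.panel_reflectance)
        refl = trim_bands(refl)
        mask = segment_leaf(refl)
        spectra.append(mean_spectrum(refl, mask))
        grid = refl.grid
    R = np.vstack(spectra)

    coeffs = cwt_matrix(R, config.scale_exponents)
    corr = correlation_map(coeffs, k.to_numpy(), grid=grid)
    logger.info("[%s] correlation map maxima per scale: %s", stage,
                np.round(corr.per_scale_maxima(), 3))

    split = concentration_gradient_split(k.to_numpy(), ids)
    cal_pos = [ids.index(i) for i in split.calibration_ids]
    y_cal = k.loc[list(split.calibration_ids)].to_numpy()

    feature_sets: dict[str, np.ndarray] = {"R": R}
    for si, i in enumerate(config.scale_exponents):
        feature_sets[f"CWT-{i}"] = coeffs[:, si, :]

    selections: dict = {}
    tables: dict = {}
    for selector in config.selectors:
        for label, X in feature_sets.items():
            sel_seed = subseed(seed, stage, selector, label)
            X_cal = X[cal_pos]
            if selector == "CARS":
                sel = cars_select(X_cal, y_cal, n_runs=config.cars_runs,
                                  folds=config.cv_folds, seed=sel_seed,
                                  cap=config.selection_cap)
            elif selector == "RF":
                thr = config.rf_thresholds.get(stage, 0.40)
                sel = random_frog_select(X_cal, y_cal,
                                         n_iter=config.rf_iterations,
                                         threshold=thr, folds=config.cv_folds,
                                         seed=sel_seed,
                                         cap=config.selection_cap)
            else:
                raise ValueError(f"unknown selector {selector!r}")
            selections[(selector, label)] = sel
            cols = [f"{label}-{grid.centers[j]:g} nm"
                    for j in sel.selected_indices]
            tables[(selector, label)] = pd.DataFrame(
                X[:, sel.selected_indices], index=ids, columns=cols)
            logger.info("[%s] %s/%s selected %d wavelengths: %s", stage,
                        selector, label, len(cols),
                        [f"{grid.centers[j]:.0f}" for j in
                         sel.selected_indices])

    model_seed = subseed(seed, stage, "model")
    pre = fuse_and_compare(tables, None, None, k, split,
                           folds=config.cv_folds, max_lv=config.max_latent,
                           seed=model_seed)
    best_key = (pre.best_selector, pre.best_feature_set)
    best_sel = selections[best_key]
    wavelengths = grid.centers[best_sel.selected_indices]
    logger.info("[%s] best spectral model %s/%s (R2val=%.3f); image database "
                "at %d wavelengths", stage, *best_key,
                float(pre.spectral.loc[
                    (pre.spectral.selector == best_key[0])
                    & (pre.spectral.feature_set == best_key[1]),
                    "r2_val"].iloc[0]), wavelengths.size)

    tex_rows, col_rows = [], []
    for s, mask, images in _stage_images(samples, config, best_key[1],
                                         wavelengths):
        tex_rows.append(pd.concat([
            texture_features(img, mask, wl, distance=config.glcm_distance,
                             levels=config.glcm_levels)
            for wl, img in images.items()]))
        col_rows.append(pd.concat([
            color_features(img, mask, wl) for wl, img in images.items()]))
    texture_full = pd.DataFrame(tex_rows, index=ids)
    color_full = pd.DataFrame(col_rows, index=ids)

    tex_sel = screen_image_features(
        texture_full.loc[list(split.calibration_ids)], y_cal,
        seed=subseed(seed, stage, "screen", "texture"),
        cap=config.selection_cap)
    col_sel = screen_image_features(
        color_full.loc[list(split.calibration_ids)], y_cal,
        seed=subseed(seed, stage, "screen", "color"),
        cap=config.selection_cap)
    texture_sel_table = texture_full.iloc[:, tex_sel.selected_indices]
    color_sel_table = color_full.iloc[:, col_sel.selected_indices]
    logger.info("[%s] screened image features: %d texture %s, %d color %s",
                stage, texture_sel_table.shape[1],
                list(texture_sel_table.columns), color_sel_table.shape[1],
                list(color_sel_table.columns))

    report = fuse_and_compare(tables, color_sel_table, texture_sel_table, k,
                              split, folds=config.cv_folds,
                              max_lv=config.max_latent, seed=model_seed)
    logger.info("[%s] best combination: %s (selector %s)", stage,
                report.best_combination, report.best_selector)
    return StageResult(
        stage=stage, sample_ids=ids, k=k, grid=grid, spectra=R, split=split,
        corr_map=corr, selections=selections, spectral_tables=tables,
        image_label=best_key[1], image_wavelengths=wavelengths,
        color_selection=col_sel, texture_selection=tex_sel,
        color_table=color_sel_table, texture_table=texture_sel_table,
        report=report)


def run_pipeline(config: RunConfig | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute all stages and (optionally) persist report artifacts."""
    config = config or RunConfig()
    logger.info("pipeline seed %d, stages %s", config.seed, config.stages)
    campaign = generate_campaign(config.scene, subseed(config.seed, "campaign"))
    logger.info("campaign: %d samples", len(campaign))
    stages = {}
    for stage in config.stages:
        try:
            stages[stage] = _run_stage(campaign, config, stage)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    result = PipelineResult(config=config, campaign=campaign, stages=stages)
    if outdir is not None:
        write_report(result, outdir)
    return result


def _heatmap(corr: CorrelationMap, path: Path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    im = ax.pcolormesh(corr.grid.centers, list(corr.scale_exponents),
                       corr.abs_r, shading="nearest", cmap="viridis",
                       vmin=0, vmax=1)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("CWT scale exponent i")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="|R|")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _scatter(res: StageResult, config: RunConfig, path: Path) -> None:
    """Measured-vs-estimated scatter for the stage's best fusion model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base = res.spectral_tables[(res.report.best_selector,
                                res.report.best_feature_set)]
    parts = [base]
    name = res.report.best_combination
    if "color" in name:
        parts.append(res.color_table)
    if "texture" in name:
        parts.append(res.texture_table)
    joined = pd.concat(parts, axis=1)
    cal = list(res.split.calibration_ids)
    val = list(res.split.validation_ids)
    model = fit_plsr(joined.loc[cal].to_numpy(), res.k.loc[cal].to_numpy(),
                     folds=config.cv_folds, max_lv=config.max_latent,
                     seed=subseed(config.seed, res.stage, "model"))
    fig, ax = plt.subplots(figsize=(4, 4))
    for part, marker, lab in ((cal, "o", "calibration"),
                              (val, "s", "validation")):
        ax.scatter(res.k.loc[part],
                   model.predict(joined.loc[part].to_numpy()),
                   marker=marker, alpha=0.7, label=lab)
    lims = [res.k.min() * 0.9, res.k.max() * 1.1]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("measured K (%)")
    ax.set_ylabel("estimated K (%)")
    ax.set_title(f"{res.stage}: {name}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(result: PipelineResult, outdir: str | Path) -> Path:
    """Persist tables, correlation heatmaps, selections and the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    from .io import write_ground_truth_csv, write_mask_png  # noqa: F401
    write_ground_truth_csv(result.campaign, outdir / "ground_truth.csv")
    result.summary().to_csv(outdir / "summary.csv", index=False)

    for stage, res in result.stages.items():
        sdir = outdir / stage
        sdir.mkdir(exist_ok=True)
        res.report.spectral.to_csv(sdir / "spectral_models.csv", index=False)
        res.report.fusion.to_csv(sdir / "fusion_models.csv", index=False)
        cm = pd.DataFrame(res.corr_map.abs_r,
                          index=[f"CWT-{i}" for i in
                                 res.corr_map.scale_exponents],
                          columns=[f"{c:g}" for c in
                                   res.corr_map.grid.centers])
        cm.to_csv(sdir / "correlation_map.csv")
        _heatmap(res.corr_map, sdir / "correlation_heatmap.png",
                 f"{stage}: |R| between CWT coefficients and K")
        _scatter(res, result.config, sdir / "best_model_scatter.png")

        sel_rows = []
        for (selector, label), sel in res.selections.items():
            for j in sel.ranked_indices():
                sel_rows.append({
                    "selector": selector, "feature_set": label,
                    "wavelength_nm": float(res.grid.centers[j]),
                    "score": float(sel.scores[j])})
        pd.DataFrame(sel_rows).to_csv(sdir / "selected_wavelengths.csv",
                                      index=False)
        pd.DataFrame({
            "feature": list(res.texture_table.columns)
            + list(res.color_table.columns),
            "kind": ["texture"] * res.texture_table.shape[1]
            + ["color"] * res.color_table.shape[1],
        }).to_csv(sdir / "selected_image_features.csv", index=False)
        pd.DataFrame({
            "wavelength_nm": res.image_wavelengths,
            "feature_set": res.image_label,
        }).to_csv(sdir / "grayscale_database_index.csv", index=False)

        if result.config.save_images:
            idir = sdir / "grayscale_database"
            idir.mkdir(exist_ok=True)
            samples = result.campaign.stage_samples(stage)
            for s, mask, images in _stage_images(samples, result.config,
                                                 res.image_label,
                                                 res.image_wavelengths):
                for wl, img in images.items():
                    import imageio.v3 as iio
                    iio.imwrite(
                        idir / f"{s.sample_id}_{res.image_label}_{wl:g}nm.png",
                        img)

    manifest = {
        "package": "leafspec",
        "version": __version__,
        "config": result.config.to_dict(),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return outdir
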