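"""End-to-end hot-spot selection: specimen map -> artifact removal ->
vessel elimination -> cell extraction -> density map -> gradual extinction.

Stage order follows the processing dependencies; the vessel detector and
the texture-classifier cascade only depend on the tissue map, so they may
run concurrently -- their output masks are combined by set union, which is
deterministic regardless of completion order.  Every run echoes its
configuration and per-stage mask areas into a QC report, and the analysis
region always satisfies

    tumour analysis mask = tissue - hemorrhage - fold - vessel - artifact.
"""

from __future__ import annotations

import json
import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from . import cells as cells_mod
from . import classify as classify_mod
from . import color as color_mod
from . import hotspots as hs
from . import tissue as tissue_mod
from . import vessels as vessels_mod
from .masks import MaskRole, RegionMask
from .slide_io import DEFAULT_WORKING_DOWNSAMPLE, SlideImage, fov_geometry, read_slide
from .synthetic import texture_patch
from .texture import DEFAULT_TEST_RADIUS, DEFAULT_TRAIN_RADIUS

logger = logging.getLogger("ki67hotspot")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the documented defaults."""

    working_downsample: float = DEFAULT_WORKING_DOWNSAMPLE
    disk_radius: int = tissue_mod.DEFAULT_DISK_RADIUS
    train_radius: int = DEFAULT_TRAIN_RADIUS
    test_radius: int = DEFAULT_TEST_RADIUS
    classifier_planes: tuple = classify_mod.DEFAULT_CLASSIFIER_PLANES
    top_k_features: int = classify_mod.DEFAULT_TOP_K
    classify_stride: int | None = None  # None -> test_radius
    lbp_n_points: int = 8
    lbp_sampling_radius: float = 2.0
    corf: dict = field(default_factory=lambda: asdict(vessels_mod.CorfConfig()))
    vessel_min_object_px: int = vessels_mod.DEFAULT_MIN_OBJECT_PX
    h: float = cells_mod.DEFAULT_H
    h_neg: float = cells_mod.DEFAULT_H_NEG
    artifact_percent: float = cells_mod.ARTIFACT_CUTOFF_PERCENT
    artifact_gap: float = cells_mod.ARTIFACT_GAP_L
    artifact_l_ceiling: float = 15.0  # below the darkest credible DAB nucleus
    rho: float = hs.DEFAULT_RHO
    n_max: int = hs.MAX_FIELDS
    density_stride_xy: tuple | None = None  # None -> half a FOV
    min_fov_coverage: float = 0.5
    seed: int = 0
    # stage toggles (ablation runs)
    detect_artifact_classes: bool = True
    detect_vessels: bool = True
    parallel_stages: bool = False

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))

    @staticmethod
    def from_json(path) -> "PipelineConfig":
        return PipelineConfig(**json.loads(Path(path).read_text()))


@dataclass
class PipelineResult:
    hotspots: hs.HotspotSet
    masks: dict
    report: dict
    analysis_mask: np.ndarray | None = None
    pos_markers: cells_mod.CellMarkerMap | None = None
    neg_markers: cells_mod.CellMarkerMap | None = None


def train_default_model(
    config: PipelineConfig | None = None,
    n_per_class: int = 100,
    patch_size: int | None = None,
    seed: int | None = None,
) -> classify_mod.CascadeModel:
    """Train the artifact cascade on generated single-class texture patches.

    Patches are rendered with the same palettes as the synthetic slides;
    they are sampled well inside their class (never straddling a class
    boundary), which is what keeps the SVM margins clean.
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    if patch_size is None:
        patch_size = 4 * config.train_radius + 1
    feats = {}
    for ci, kind in enumerate(("tumour", "hemorrhage", "fold")):
        patches = [
            texture_patch(kind, patch_size, seed=seed * 97 + ci * 10_003 + k)
            for k in range(n_per_class)
        ]
        feats[kind] = classify_mod.extract_patch_features(
            patches,
            color_mod.color_planes,
            plane_ids=config.classifier_planes,
            radius_px=config.train_radius,
        )
    return classify_mod.train_cascade(
        feats,
        top_k=config.top_k_features,
        seed=seed,
        metadata={"train_radius": config.train_radius, "planes": list(config.classifier_planes)},
    )


def _stage(name: str, fn, report: dict):
    t0 = time.perf_counter()
    out = fn()
    report.setdefault("timings_s", {})[name] = round(time.perf_counter() - t0, 3)
    logger.info("stage %-18s %.2fs", name, report["timings_s"][name])
    return out


def run_pipeline(
    slide: SlideImage | str | Path,
    config: PipelineConfig | None = None,
    model: classify_mod.CascadeModel | None = None,
) -> PipelineResult:
    """Run the full hot-spot selection flow on one slide.

    ``slide`` may be a SlideImage or a path (read at the working level).
    With ``config.detect_artifact_classes`` and no model, a default model
    is trained on generated texture patches (seeded from the config).
    """
    config = config or PipelineConfig()
    if not isinstance(slide, SlideImage):
        slide = read_slide(slide, working_downsample=config.working_downsample)
    report: dict = {"config": asdict(config), "level": slide.level,
                    "um_per_px": slide.um_per_px}
    H, W = slide.shape

    tissue = _stage("specimen_map", lambda: tissue_mod.build_specimen_map(
        slide, disk_radius=config.disk_radius), report)
    planes = _stage("color_planes", lambda: color_mod.color_planes(slide.pixels), report)
    fov = fov_geometry(slide.um_per_px)
    report["fov_px"] = [fov.width_px, fov.height_px]

    empty = np.zeros((H, W), bool)
    masks = {
        "tissue": tissue,
        "hemorrhage": RegionMask(empty.copy(), MaskRole.HEMORRHAGE),
        "fold": RegionMask(empty.copy(), MaskRole.FOLD),
        "vessel": RegionMask(empty.copy(), MaskRole.VESSEL),
        "artifact": RegionMask(empty.copy(), MaskRole.ARTIFACT),
    }
    if not tissue.mask.any():
        logger.warning("empty tissue mask; returning empty result")
        report["warning"] = "empty tissue"
        return PipelineResult(hs.HotspotSet([], config.rho, 0, 0.0), masks, report)

    def _classify_stage():
        nonlocal model
        if model is None:
            model = train_default_model(config)
        return classify_mod.classify_tissue(
            planes, tissue.mask, model,
            stride=config.classify_stride, radius_px=config.test_radius,
            plane_ids=config.classifier_planes,
        )

    def _vessel_stage():
        lbp_m = vessels_mod.vessels_from_lbp(
            planes["Y"], tissue.mask,
            n_points=config.lbp_n_points, sampling_radius=config.lbp_sampling_radius)
        corf_m = vessels_mod.vessels_from_corf(
            planes["Y"], tissue.mask, vessels_mod.CorfConfig(**config.corf))
        return vessels_mod.vessel_map(lbp_m, corf_m, config.vessel_min_object_px)

    # the two artifact detectors are independent given the tissue map; the
    # union-combine below is order-insensitive, so scheduling cannot change
    # the result
    if config.parallel_stages and config.detect_artifact_classes and config.detect_vessels:
        with ThreadPoolExecutor(max_workers=2) as pool:
            f_cls = pool.submit(lambda: _stage("texture_cascade", _classify_stage, report))
            f_ves = pool.submit(lambda: _stage("vessel_detection", _vessel_stage, report))
            cascade_masks, vessel_mask = f_cls.result(), f_ves.result()
    else:
        cascade_masks = (
            _stage("texture_cascade", _classify_stage, report)
            if config.detect_artifact_classes else None
        )
        vessel_mask = (
            _stage("vessel_detection", _vessel_stage, report)
            if config.detect_vessels else None
        )
    if cascade_masks is not None:
        masks["hemorrhage"] = cascade_masks["hemorrhage"]
        masks["fold"] = cascade_masks["fold"]
    if vessel_mask is not None:
        masks["vessel"] = vessel_mask

    analysis = (
        tissue.mask
        & ~masks["hemorrhage"].mask
        & ~masks["fold"].mask
        & ~masks["vessel"].mask
    )

    # color-artifact detection on luminance within the analysis region: the
    # 5%-cut-off comparison raises the flag, and genuinely near-black
    # pixels (darker than any DAB nucleus can be) are excluded from the
    # mask together with a small halo for their blurred surroundings, so
    # they cannot masquerade as deep immunopositive wells
    lum = planes["L"]
    _, artifact_flag = cells_mod.color_artifact_cutoff(
        lum, analysis, percent=config.artifact_percent, gap_threshold=config.artifact_gap
    )
    artifact_mask = analysis & (lum < config.artifact_l_ceiling)
    if artifact_mask.any():
        artifact_mask = ndi.binary_dilation(artifact_mask, iterations=2) & analysis
    masks["artifact"] = RegionMask(artifact_mask, MaskRole.ARTIFACT)
    analysis = analysis & ~artifact_mask
    report["artifact_flag"] = bool(artifact_flag)

    pos = _stage("positive_cells", lambda: cells_mod.extract_positive_cells(
        lum, analysis, h=config.h, artifact_flag=artifact_flag), report)
    neg = _stage("negative_cells", lambda: cells_mod.extract_negative_cells(
        planes["hematoxylin"], analysis, h=config.h_neg,
        exclude_mask=pos.cell_mask), report)

    area_fovs = float(analysis.sum()) / fov.area_px
    n_max = min(config.n_max, hs.max_hotspot_count(area_fovs))
    eff_radius = float(ndi.distance_transform_edt(analysis).max()) / fov.circle_radius_px
    rho = hs.compactness_adjusted_rho(config.rho, area_fovs, eff_radius)
    report.update(
        {
            "tissue_area_px": tissue.area_px,
            "analysis_area_px": int(analysis.sum()),
            "area_fovs": area_fovs,
            "effective_radius_fov_radii": eff_radius,
            "rho_used": rho,
            "n_max_applied": n_max,
            "n_pos_markers": pos.count,
            "n_neg_markers": neg.count,
            "mask_areas_px": {k: m.area_px for k, m in masks.items()},
        }
    )

    dmap = _stage("density_map", lambda: hs.density_map(
        pos.centroids, analysis, fov,
        stride_xy=config.density_stride_xy, min_coverage=config.min_fov_coverage), report)

    def _field_ki67(rect_w):
        x0, y0, w, h = rect_w
        def _inside(c):
            return (c[:, 0] >= x0) & (c[:, 0] < x0 + w) & (c[:, 1] >= y0) & (c[:, 1] < y0 + h)
        p = int(_inside(pos.centroids).sum()) if pos.count else 0
        n = int(_inside(neg.centroids).sum()) if neg.count else 0
        return cells_mod.ki67_index(p, n) if p + n else 0.0

    selected = _stage("hotspot_selection", lambda: hs.select_hotspots(
        dmap, rho=rho, n_max=n_max, area_fovs=area_fovs,
        downsample=slide.downsample, ki67_fn=_field_ki67), report)
    report["n_fields_selected"] = len(selected)
    report["mean_ki67_selected"] = (
        float(np.mean([f.ki67_index for f in selected.fields])) if len(selected) else None
    )
    return PipelineResult(selected, masks, report, analysis_mask=analysis,
                          pos_markers=pos, neg_markers=neg)


def write_outputs(result: PipelineResult, out_dir: str | Path,
                  slide: SlideImage | None = None) -> None:
    """Write hotspots.csv, mask PNGs, a QC overlay and report.json."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.hotspots.to_dataframe().to_csv(out / "hotspots.csv", index=False)
    for name, m in result.masks.items():
        Image.fromarray(m.mask.astype(np.uint8) * 255).save(out / f"mask_{name}.png")
    (out / "report.json").write_text(json.dumps(result.report, indent=2, default=str))
    if slide is not None:
        overlay = slide.pixels.copy()
        for f in result.hotspots.fields:
            x0, y0, w, h = f.rect_working
            overlay[y0, x0 : x0 + w] = (255, 0, 0)
            overlay[min(y0 + h - 1, overlay.shape[0] - 1), x0 : x0 + w] = (255, 0, 0)
            overlay[y0 : y0 + h, x0] = (255, 0, 0)
            overlay[y0 : y0 + h, min(x0 + w - 1, overlay.shape[1] - 1)] = (255, 0, 0)
        Image.fromarray(overlay).save(out / "overlay.png")
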