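"""End-to-end orchestration: images -> metric table -> statistics report.

``run_image_pipeline`` measures the four SCP metrics in both macular
regions for a batch of en-face images; ``run_study_replica`` simulates the
two study cohorts from the published group distributions and runs the full
statistical battery, emitting tidy CSV-ready tables plus a text summary.
Failures are isolated per image (logged, pipeline continues), and every run
produces a manifest (config hash, seed, package versions) sufficient to
reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform

import numpy as np
import pandas as pd

from . import __version__
from .binarize import BinarizationParams, binarize_scp, quality_filter
from .cohort import (DEFAULT_GENDER_COUNTS, CohortSpec, generate_cohort)
from .config import PipelineConfig
from .image import EnFaceImage
from .roi import RegionMask, find_fovea_center, make_region_masks
from .skeleton import (analyze_branches, perfusion_density, prune_spurs,
                       skeletonize_mask, vessel_diameter_index,
                       vessel_length_density, vessel_tortuosity)
from . import stats as st

logger = logging.getLogger(__name__)


def measure_image(image: EnFaceImage, config: PipelineConfig | None = None,
                  regions: tuple[RegionMask, ...] | None = None) -> list[dict]:
    """Measure PD, VLD, VDI and VT of one image in each analysis region.

    Returns one record per region with the image's labels attached.  When
    ``regions`` is not supplied the parafoveal/perifoveal masks are built on
    the image grid (optionally centred on the detected fovea).
    """
    cfg = config or PipelineConfig()
    params = BinarizationParams(
        despeckle_px=cfg.despeckle_px,
        tophat_radius_px=cfg.tophat_radius_px,
        hessian_sigma_px=cfg.hessian_sigma_px,
        tubeness_floor=cfg.tubeness_floor,
        median_radius_px=cfg.median_radius_px,
        median_offset=cfg.median_offset,
        min_object_px=cfg.min_object_px,
        fill_holes_px=cfg.fill_holes_px,
    )
    if regions is None:
        center = find_fovea_center(image) if cfg.auto_center else None
        regions = make_region_masks(
            image.grid_px, image.pixel_pitch_um, center_px=center,
            faz_diameter_mm=cfg.faz_diameter_mm,
            parafoveal_diameter_mm=cfg.parafoveal_diameter_mm,
            perifoveal_diameter_mm=cfg.perifoveal_diameter_mm)

    mask = binarize_scp(image, params)
    skel = skeletonize_mask(mask)
    # PD/VLD/VDI use the raw skeleton (keeping their algebraic consistency);
    # branch statistics use the spur-pruned skeleton so thinning twigs do
    # not cut through-going centrelines into sub-tortuosity-scale chords
    branches = analyze_branches(prune_spurs(skel, cfg.vt_prune_px))

    records = []
    for roi in regions:
        rec = dict(eye_id=image.eye_id, visit=image.visit, grader=image.grader,
                   region=roi.region,
                   PD=perfusion_density(mask, roi),
                   VLD=vessel_length_density(skel, roi),
                   VDI=vessel_diameter_index(mask, skel, roi,
                                             image.pixel_pitch_um,
                                             as_pixels=cfg.vdi_as_pixels),
                   VT=vessel_tortuosity(branches, roi, cfg.vt_min_branch_px))
        records.append(rec)
    return records


def run_image_pipeline(images: list[EnFaceImage],
                       config: PipelineConfig | None = None) -> pd.DataFrame:
    """Quality-filter and measure a batch of images into a long metric table.

    Per-image errors are logged and the batch continues; the returned frame
    has one row per image x region x metric.
    """
    cfg = config or PipelineConfig()
    kept = quality_filter(images, cfg.min_ssi)
    long_rows = []
    for image in kept:
        try:
            for rec in measure_image(image, cfg):
                for metric in ("PD", "VLD", "VDI", "VT"):
                    long_rows.append(dict(eye_id=rec["eye_id"], group="",
                                          region=rec["region"], metric=metric,
                                          visit=rec["visit"], value=rec[metric],
                                          grader=rec["grader"]))
        except Exception:
            logger.exception("pipeline failed on image %r; continuing",
                             image.eye_id)
    return pd.DataFrame(long_rows)


def run_manifest(config: PipelineConfig) -> dict:
    return dict(config=dataclasses.asdict(config), config_hash=config.digest(),
                seed=config.seed, octaquant=__version__,
                numpy=np.__version__, pandas=pd.__version__,
                python=platform.python_version())


def run_study_replica(config: PipelineConfig | None = None,
                      seed: int | None = None) -> dict:
    """Simulate both cohorts and run the full statistical battery.

    Returns a dict of DataFrames: cohort summary (the published-table
    layout), between-group tests at baseline, within-group longitudinal
    tests, interobserver concordance, metric-vs-CMT Spearman correlations,
    the demographics chi-square, and the run manifest.
    """
    cfg = config or PipelineConfig()
    seed = cfg.seed if seed is None else seed
    spec = CohortSpec(n_per_group=cfg.n_per_group,
                      within_eye_corr=cfg.within_eye_corr,
                      interobserver_corr=cfg.interobserver_corr,
                      n_graders=2, seed=seed)
    df = generate_cohort(spec)
    primary = df[df.grader == "G1"]

    between = st.between_group_tests(primary)
    within = st.within_group_tests(primary, group="iERM")
    ccc = st.interobserver_ccc(df)
    summary = st.summarize_cohort(primary)

    # Spearman of each OCTA metric against CMT within the surgical group
    ierm = primary[(primary.group == "iERM") & (primary.visit == "baseline")]
    cmt = ierm[ierm.metric == "CMT"].set_index("eye_id").value
    sp_rows = []
    for (region, metric), cell in ierm[ierm.metric != "CMT"].groupby(
            ["region", "metric"], sort=True):
        vals = cell.set_index("eye_id").value.reindex(cmt.index).dropna()
        if len(vals) < 3:
            continue
        r = st.spearman_rho(cmt.loc[vals.index].to_numpy(), vals.to_numpy())
        sp_rows.append(dict(region=region, metric=metric, rho=r.statistic,
                            p=r.p_value, n=len(vals)))
    spearman = pd.DataFrame(sp_rows)

    gender = st.pearson_chi_square(np.array([DEFAULT_GENDER_COUNTS["iERM"],
                                             DEFAULT_GENDER_COUNTS["control"]]))
    demographics = pd.DataFrame([dict(variable="gender",
                                      statistic=gender.statistic,
                                      p=gender.p_value, method=gender.method)])

    return dict(summary=summary, between_group=between, within_group=within,
                interobserver=ccc, spearman_vs_cmt=spearman,
                demographics=demographics, manifest=run_manifest(cfg))


def report_text(report: dict) -> str:
    """Human-readable rendering of a study-replica report."""
    parts = []
    for name in ("summary", "between_group", "within_group", "interobserver",
                 "spearman_vs_cmt", "demographics"):
        frame = report[name]
        parts.append(f"== {name} ==")
        parts.append(frame.to_string(index=False,
                                     float_format=lambda v: f"{v:.4g}"))
        parts.append("")
    parts.append("== manifest ==")
    parts.append(json.dumps(report["manifest"], indent=2, sort_keys=True))
    return "\n".join(parts)
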