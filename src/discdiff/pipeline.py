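"""End-to-end pipeline: simulate -> segment -> quantify -> analyze.

Each stage reads and writes plain files in a run directory, so any stage
can be re-run in isolation; a manifest records the seed, the stages
executed and SHA-256 checksums of the result tables.  All randomness
flows through the single seed recorded in the manifest.
"""

from __future__ import annotations

import importlib.metadata
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .phantom import (DiscSpec, PhantomCohort, PhantomConfig, generate_cohort)
from .quantification import (assemble_timecurves, compute_csf_adj_t2,
                             compute_enhancement)
from .segmentation import (apply_exclusions, build_disc_rois,
                           select_timecurve_subset)
from .stats import run_paper_analyses

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_fixtures",
           "simulate_stage", "segment_stage", "quantify_stage",
           "analyze_stage"]

STAGES = ("simulate", "segment", "quantify", "analyze")


@dataclass
class RunConfig:
    """Settings of one reproducible pipeline run."""

    out_dir: Path
    seed: int = 0
    n_discs: int = 12
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    stages: tuple[str, ...] = STAGES
    height_distribution: str = "grade-coupled"
    grade_counts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _version() -> str:
    try:
        return importlib.metadata.version("discdiff")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


def simulate_stage(config: RunConfig) -> PhantomCohort:
    """Generate a cohort and write images, landmarks, metadata, truth."""
    out = config.out_dir
    cohort = generate_cohort(
        config.phantom, config.n_discs, seed=config.seed,
        grade_counts=config.grade_counts,
        height_distribution=config.height_distribution,
    )
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for series in cohort.series.values():
        dio.save_series(series, img_dir)
    rects = {d: t.csf_rect for d, t in cohort.ground_truth.items()}
    dio.save_landmarks(cohort.landmarks, out / "landmarks.json", rects)
    cohort.metadata.to_csv(out / "metadata.csv", index=False)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for disc_id, t in cohort.ground_truth.items():
        rois = build_disc_rois(t.landmarks, config.phantom.grid_shape)
        dio.save_masks(rois, truth_dir / f"{disc_id}_true_masks.nii.gz",
                       config.phantom.pixel_spacing)
    dio.save_config(replace(config.phantom, discs=()), out / "phantom.yaml")
    return cohort


def segment_stage(out_dir) -> pd.DataFrame:
    """Build ROIs from the landmark file; write masks and geometry table."""
    out = Path(out_dir)
    landmarks, _ = dio.load_landmarks(out / "landmarks.json")
    meta = pd.read_csv(out / "metadata.csv")
    shape = None
    masks_dir = out / "masks"
    masks_dir.mkdir(exist_ok=True)
    heights = {}
    for disc_id, lms in landmarks.items():
        series_dir = out / "images" / disc_id
        if shape is None:
            img, _ = dio.load_image(series_dir / "PRE.nii.gz")
            shape = img.shape
        rois = build_disc_rois(lms, shape)
        dio.save_masks(rois, masks_dir / f"{disc_id}.nii.gz",
                       lms.pixel_spacing)
        heights[disc_id] = rois.geometry.height_mm
    retained, excl = apply_exclusions(meta, heights)
    geo = pd.DataFrame({
        "disc_id": list(landmarks),
        "height_mm": [heights[d] for d in landmarks],
    })
    geo["excluded"] = geo["disc_id"].isin(excl["disc_id"])
    geo = geo.merge(excl, on="disc_id", how="left")
    geo["reason"] = geo["reason"].fillna("")
    geo.to_csv(out / "geometry.csv", index=False)
    retained.to_csv(out / "metadata_retained.csv", index=False)
    return geo


def quantify_stage(out_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute enhancement and CSF-adjusted T2 tables for retained discs."""
    out = Path(out_dir)
    landmarks, rects = dio.load_landmarks(out / "landmarks.json")
    retained = pd.read_csv(out / "metadata_retained.csv")
    keep = set(retained["disc_id"])
    enh_frames = []
    quant_rows = []
    for disc_id, lms in landmarks.items():
        if disc_id not in keep:
            continue
        series = dio.load_series(out / "images" / disc_id)
        masks, spacing = dio.load_masks(out / "masks" / f"{disc_id}.nii.gz")
        rois = build_disc_rois(lms, series.t2.shape)
        # masks on disk are authoritative for quantification
        rois.masks = masks
        enh_frames.append(compute_enhancement(series, rois))
        if disc_id in rects:
            q = compute_csf_adj_t2(series.t2, rois, rects[disc_id])
            quant_rows.append({"disc_id": disc_id,
                               "csf_adj_t2": q.csf_adj_t2,
                               "disc_t2_mean": q.disc_mean,
                               "csf_t2_mean": q.csf_mean})
    enh = pd.concat(enh_frames, ignore_index=True)
    quant = pd.DataFrame(quant_rows)
    enh.to_csv(out / "enhancement.csv", index=False)
    quant.to_csv(out / "quant.csv", index=False)
    return enh, quant


def analyze_stage(out_dir) -> None:
    """Run the statistical battery; write report tables and a text log."""
    out = Path(out_dir)
    enh = pd.read_csv(out / "enhancement.csv")
    quant = pd.read_csv(out / "quant.csv")
    meta = pd.read_csv(out / "metadata_retained.csv")
    subset = select_timecurve_subset(meta)
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    curves = assemble_timecurves(enh, subset or None)
    curves.to_csv(report_dir / "timecurves.csv", index=False)
    report = run_paper_analyses(enh, quant, meta, timecurve_subset=subset)
    report.tests.to_csv(report_dir / "tests.csv", index=False)
    report.pairwise.to_csv(report_dir / "pairwise.csv", index=False)
    report.anova.to_csv(report_dir / "anova.csv", index=False)
    lines = [f"discdiff analysis report ({len(meta)} discs, "
             f"{len(subset)} in time-curve subset)", ""]
    if not report.tests.empty:
        for _, r in report.tests.iterrows():
            mark = "*" if r["significant"] else " "
            t = r["time"] if isinstance(r["time"], str) else ""
            lines.append(f"[{mark}] {r['family']:<12} {r['name']:<45} {t:<11}"
                         f" stat={r['statistic']:9.3f} p={r['p']:.4g}")
    lines.extend("note: " + n for n in report.notes)
    (report_dir / "report.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the selected stages and write the run manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    done = []
    try:
        if "simulate" in config.stages:
            simulate_stage(config)
            done.append("simulate")
        if "segment" in config.stages:
            segment_stage(out)
            done.append("segment")
        if "quantify" in config.stages:
            quantify_stage(out)
            done.append("quantify")
        if "analyze" in config.stages:
            analyze_stage(out)
            done.append("analyze")
    except Exception as exc:  # partial outputs stay on disk for inspection
        raise RuntimeError(
            f"pipeline failed in stage "
            f"{'analyze' if len(done) == 3 else STAGES[len(done)]}: {exc}"
        ) from exc
    result_files = [out / "metadata.csv", out / "metadata_retained.csv",
                    out / "geometry.csv", out / "enhancement.csv",
                    out / "quant.csv", out / "report" / "tests.csv",
                    out / "report" / "anova.csv",
                    out / "report" / "timecurves.csv"]
    dio.write_manifest(out, {
        "seed": config.seed,
        "n_discs": config.n_discs,
        "stages": done,
        "version": _version(),
        "height_distribution": config.height_distribution,
    }, files=[f for f in result_files if f.exists()])
    return out


def make_fixtures(seed: int = 0, out_dir=None) -> PhantomCohort | Path:
    """Small 6-disc test cohort: one disc per grade plus one Modic disc.

    Fast enough for CI; returns the in-memory cohort, or the run
    directory when ``out_dir`` is given.
    """
    cfg = PhantomConfig(seed=seed)
    # fixed spec layout: one disc per grade, the sixth with MC type II
    specs = []
    for i, grade in enumerate((1, 2, 3, 4, 5, 2)):
        specs.append(DiscSpec(
            height_mm=11.5 - 1.5 * (grade - 1),
            pfirrmann=grade,
            hydration=max(0.05, 1.0 - 0.17 * (grade - 1)),
            mc_upper="II" if i == 5 else "0",
        ))
    from .phantom import _disc_kinetics, render_series, solve_disc_diffusion
    cfg = replace(cfg, discs=tuple(specs))
    ids = [f"disc_{i:04d}" for i in range(6)]
    rng = np.random.default_rng(seed)
    fields, params, lms = {}, {}, {}
    from .phantom import _disc_geometry_layout
    from .segmentation import LandmarkSet
    for disc_id, spec in zip(ids, specs):
        p = _disc_kinetics(cfg.kinetics, spec)
        params[disc_id] = p
        fields[disc_id] = solve_disc_diffusion(spec, p, cfg.time_points,
                                               n_nodes=cfg.n_nodes, dt=cfg.dt)
        upr, lwr = _disc_geometry_layout(cfg, spec, rng)
        lms[disc_id] = LandmarkSet(disc_id=disc_id, upper=upr, lower=lwr,
                                   pixel_spacing=cfg.pixel_spacing)
    series, truth = render_series(cfg, fields, params, landmarks=lms, rng=rng)
    ages = np.clip(rng.normal(42.4, 9.3, size=6), 18.0, 60.0)
    meta = pd.DataFrame([{
        "disc_id": d, "age": float(a), "pfirrmann": s.pfirrmann,
        "height_mm": s.height_mm, "hydration": s.hydration,
        "mc_upper": s.mc_upper, "mc_lower": s.mc_lower,
        "defect_upper": s.defect_upper, "defect_lower": s.defect_lower,
        "irregular": s.irregular, "spondylolisthesis": s.spondylolisthesis,
        "true_permeability": params[d].endplate_permeability,
        "true_perfusion": params[d].perfusion_rate,
        "true_diffusivity": params[d].diffusivity,
    } for d, s, a in zip(ids, specs, ages)])
    cohort = PhantomCohort(config=cfg, series=series, landmarks=lms,
                           metadata=meta, ground_truth=truth)
    if out_dir is None:
        return cohort
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for s in cohort.series.values():
        dio.save_series(s, img_dir)
    rects = {d: t.csf_rect for d, t in cohort.ground_truth.items()}
    dio.save_landmarks(cohort.landmarks, out / "landmarks.json", rects)
    cohort.metadata.to_csv(out / "metadata.csv", index=False)
    return out
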