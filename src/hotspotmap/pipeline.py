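"""End-to-end orchestration: load → project → segment → map → correlate.

These functions back the command-line interface and can be driven directly
from Python. A cohort is one manifest (one age group); multi-group analyses
compare cohort results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .imaging import PatchImage, load_mask, load_stack, max_intensity_projection
from .mapping import (
    GridMap,
    average_maps,
    grid_geometry,
    nuclei_count_map,
    spot_area_map,
    spot_count_map,
    uptake_maps,
    write_grid_csv,
)
from .segmentation import (
    SegmentationConfig,
    SegmentationResult,
    refilter_spots,
    segment_spots,
    write_spot_table,
)
from .stats import half_map_test, map_correlation, two_sample_t
from .synthgen import read_manifest

log = logging.getLogger("hotspotmap")

EBA_METRICS = ("spot_count", "spot_area", "spot_uptake", "nonspot_uptake", "total_uptake")


@dataclass
class BranchAnalysis:
    animal_id: int
    branch_id: int
    segmentation: SegmentationResult
    segmentation_refiltered: SegmentationResult | None
    maps: dict[str, GridMap]  # metric -> branch map (primary area filter)
    maps_refiltered: dict[str, GridMap]


@dataclass
class CohortAnalysis:
    branches: list[BranchAnalysis]
    animal_ids: np.ndarray
    cohort_maps: dict[str, "object"]
    cohort_maps_refiltered: dict[str, "object"]
    skipped: list[dict] = field(default_factory=list)

    def branch_maps(self, metric: str, refiltered: bool = False) -> list[GridMap]:
        source = "maps_refiltered" if refiltered else "maps"
        return [getattr(b, source)[metric] for b in self.branches]

    def spots_per_branch(self, refiltered: bool = False) -> np.ndarray:
        if refiltered:
            return np.array([b.segmentation_refiltered.n_spots for b in self.branches])
        return np.array([b.segmentation.n_spots for b in self.branches])


def analyse_branch(
    stack_path: str | Path,
    mask_path: str | Path,
    nuclei_path: str | Path | None,
    seg_config: SegmentationConfig,
    pixel_pitch_um: float,
    refilter_px: int | None = 450,
) -> tuple[SegmentationResult, SegmentationResult | None, dict, dict]:
    """Full single-branch analysis; returns the two segmentations and the
    metric→GridMap dicts at the primary and (optionally) refiltered cutoff."""
    stack = load_stack(stack_path)
    mip = max_intensity_projection(stack)
    mask = load_mask(mask_path)
    image = PatchImage(mip, pixel_pitch_um, mask)
    seg = segment_spots(image, seg_config)
    seg_big = refilter_spots(seg, refilter_px) if refilter_px else None

    geom = grid_geometry(image.intensity.shape[0])
    nuclei = (
        pd.read_csv(nuclei_path)[["row_px", "col_px"]].to_numpy()
        if nuclei_path is not None
        else np.empty((0, 2))
    )

    def build(segres: SegmentationResult) -> dict[str, GridMap]:
        spot_u, nonspot_u, total_u = uptake_maps(image, segres.label_image, geom)
        return {
            "spot_count": spot_count_map(segres.spots, geom, mask),
            "spot_area": spot_area_map(segres.spots, geom, mask),
            "spot_uptake": spot_u,
            "nonspot_uptake": nonspot_u,
            "total_uptake": total_u,
            "nuclei_count": nuclei_count_map(nuclei, geom, mask),
        }

    maps = build(seg)
    maps_big = build(seg_big) if seg_big is not None else {}
    return seg, seg_big, maps, maps_big


def analyse_cohort(
    manifest_path: str | Path,
    seg_config: SegmentationConfig | None = None,
    pixel_pitch_um: float = 3.2,
    refilter_px: int | None = 450,
) -> CohortAnalysis:
    """Analyse every branch in a manifest; corrupt branches are skipped with
    a logged error and recorded in the result."""
    if seg_config is None:
        seg_config = SegmentationConfig()
    manifest = read_manifest(manifest_path)
    if manifest.empty:
        raise ValueError(f"{manifest_path}: manifest lists no branches")
    branches: list[BranchAnalysis] = []
    skipped: list[dict] = []
    for _, row in manifest.iterrows():
        try:
            seg, seg_big, maps, maps_big = analyse_branch(
                row.stack_path,
                row.mask_path,
                row.nuclei_path,
                seg_config,
                pixel_pitch_um,
                refilter_px,
            )
        except Exception as exc:  # partial-failure policy: skip and report
            log.error("skipping branch %s/%s: %s", row.animal_id, row.branch_id, exc)
            skipped.append(
                {"animal_id": int(row.animal_id), "branch_id": int(row.branch_id), "error": str(exc)}
            )
            continue
        branches.append(
            BranchAnalysis(
                animal_id=int(row.animal_id),
                branch_id=int(row.branch_id),
                segmentation=seg,
                segmentation_refiltered=seg_big,
                maps=maps,
                maps_refiltered=maps_big,
            )
        )
    if not branches:
        raise ValueError(f"{manifest_path}: every branch failed analysis")
    metrics = list(EBA_METRICS) + ["nuclei_count"]
    cohort = {m: average_maps([b.maps[m] for b in branches]) for m in metrics}
    cohort_big = (
        {m: average_maps([b.maps_refiltered[m] for b in branches]) for m in metrics}
        if refilter_px
        else {}
    )
    return CohortAnalysis(
        branches=branches,
        animal_ids=np.array([b.animal_id for b in branches]),
        cohort_maps=cohort,
        cohort_maps_refiltered=cohort_big,
        skipped=skipped,
    )


def correlation_table(
    cohort: CohortAnalysis,
    metrics: tuple[str, ...] = EBA_METRICS + ("nuclei_count",),
    n_boot: int = 10_000,
    seed: int | None = None,
    hierarchical: bool = True,
) -> pd.DataFrame:
    """All pairwise bootstrap map correlations within one cohort.

    Metrics come from the same branches, so the same branch resample is used
    for both members of a pair.
    """
    rows = []
    ids = cohort.animal_ids if hierarchical else None
    for i, ma in enumerate(metrics):
        for j, mb in enumerate(metrics[i + 1 :], start=i + 1):
            res = map_correlation(
                cohort.branch_maps(ma),
                cohort.branch_maps(mb),
                n_boot=n_boot,
                seed=None if seed is None else (seed + 37 * i + j) % 2**31,
                animal_ids_a=ids,
                animal_ids_b=ids,
                share_resampling=True,
            )
            rows.append(
                {
                    "metric_a": ma,
                    "metric_b": mb,
                    "median_r": res.median_r,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "significant": res.significant,
                    "n_squares": res.n_squares,
                    "n_boot": res.n_boot,
                }
            )
    return pd.DataFrame(rows)


def write_cohort_outputs(cohort: CohortAnalysis, out_dir: str | Path) -> None:
    """Per-branch spot tables and maps, cohort maps, run report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for b in cohort.branches:
        stem = f"animal{b.animal_id:02d}_branch{b.branch_id:02d}"
        write_spot_table(b.segmentation, out_dir / f"{stem}_spots.csv")
        if b.segmentation_refiltered is not None:
            write_spot_table(b.segmentation_refiltered, out_dir / f"{stem}_spots_refiltered.csv")
        for metric, gm in b.maps.items():
            write_grid_csv(gm, out_dir / f"{stem}_map_{metric}.csv")
    for metric, cm in cohort.cohort_maps.items():
        write_grid_csv(cm, out_dir / f"cohort_map_{metric}.csv")
    for metric, cm in cohort.cohort_maps_refiltered.items():
        write_grid_csv(cm, out_dir / f"cohort_map_{metric}_refiltered.csv")
    report = {
        "n_branches": len(cohort.branches),
        "skipped": cohort.skipped,
        "spots_per_branch_mean": float(cohort.spots_per_branch().mean()),
    }
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=1))


def group_comparisons(
    cohorts: dict[str, CohortAnalysis],
    n_boot: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Between-group spots-per-branch t-test plus per-group half-map tests on
    nuclei maps."""
    out: dict = {"half_map_nuclei": {}, "spots_per_branch": {}}
    for name, cohort in cohorts.items():
        res = half_map_test(cohort.branch_maps("nuclei_count"), "downstream_greater")
        out["half_map_nuclei"][name] = {"t": res.statistic, "p": res.p_value, "df": res.df}
        out["spots_per_branch"][name] = {
            "mean": float(cohort.spots_per_branch().mean()),
            "sem": float(
                cohort.spots_per_branch().std(ddof=1) / np.sqrt(len(cohort.branches))
            ),
            "n": len(cohort.branches),
        }
    names = list(cohorts)
    if len(names) >= 2:
        a, b = cohorts[names[0]], cohorts[names[1]]
        t = two_sample_t(a.spots_per_branch(), b.spots_per_branch(), tails="two")
        out["spots_per_branch"]["t_test"] = {
            "groups": names[:2],
            "t": t.statistic,
            "p": t.p_value,
            "df": t.df,
        }
    return out


def provenance_record(config_like: dict, seed: int | None) -> dict:
    blob = json.dumps(config_like, sort_keys=True, default=str).encode()
    import scipy
    import skimage

    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "hotspotmap": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "pandas": pd.__version__,
    }
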