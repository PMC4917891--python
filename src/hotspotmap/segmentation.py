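"""Hotspot segmentation and spot/non-spot uptake decomposition.

A hotspot is a connected component of unmasked pixels strictly above an
intensity threshold whose area passes the minimum-area filter (default 50 px,
about one endothelial cell). Total uptake over unmasked pixels is decomposed
exactly into a spot and a non-spot compartment; pixels of rejected small
components count as non-spot, masked (ostium) pixels count in neither.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import filters, measure

from .imaging import PatchImage

THRESHOLD_METHODS = ("percentile", "median_plus_k_mad", "otsu", "fixed")


@dataclass(frozen=True)
class SegmentationConfig:
    """Threshold rule and area filter.

    ``threshold_param`` is the percentile (in (0, 100)) for ``percentile``,
    the multiplier k >= 0 for ``median_plus_k_mad`` (raw, unscaled MAD), and
    the intensity itself for ``fixed``; it is ignored by ``otsu``.
    """

    threshold_method: str = "median_plus_k_mad"
    threshold_param: float = 8.0
    min_area_px: int = 50
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.threshold_method not in THRESHOLD_METHODS:
            raise ValueError(
                f"unknown threshold_method {self.threshold_method!r}; "
                f"choose from {THRESHOLD_METHODS}"
            )
        if self.threshold_method == "percentile" and not (
            0 < self.threshold_param < 100
        ):
            raise ValueError("percentile threshold_param must be in (0, 100)")
        if self.threshold_method == "median_plus_k_mad" and self.threshold_param < 0:
            raise ValueError("k must be >= 0 for median_plus_k_mad")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class Spot:
    spot_id: int
    area_px: int
    area_um2: float
    integrated_intensity: float
    centroid_row: float  # intensity-weighted
    centroid_col: float


@dataclass
class SegmentationResult:
    spots: list[Spot]
    label_image: np.ndarray  # int, 0 = non-spot
    threshold_used: float
    spot_uptake: float
    nonspot_uptake: float
    total_uptake: float
    config: SegmentationConfig
    pixel_pitch_um: float
    image: PatchImage | None = None  # kept so refiltering can recompute sums

    @property
    def n_spots(self) -> int:
        return len(self.spots)


def estimate_threshold(image: PatchImage, config: SegmentationConfig) -> float:
    """Intensity threshold computed from unmasked pixels only."""
    values = image.intensity[~image.ostium_mask]
    if values.size == 0:
        raise ValueError("all pixels are masked; cannot estimate a threshold")
    method = config.threshold_method
    if method == "fixed":
        return float(config.threshold_param)
    if method == "percentile":
        return float(np.percentile(values, config.threshold_param))
    if method == "median_plus_k_mad":
        med = float(np.median(values))
        mad = float(np.median(np.abs(values - med)))
        return med + config.threshold_param * mad
    if method == "otsu":
        return float(filters.threshold_otsu(values))
    raise ValueError(f"unknown threshold_method {method!r}")


def segment_spots(
    image: PatchImage, config: SegmentationConfig | None = None
) -> SegmentationResult:
    """Segment hotspots and decompose uptake into spot/non-spot compartments."""
    if config is None:
        config = SegmentationConfig()
    threshold = estimate_threshold(image, config)
    unmasked = ~image.ostium_mask
    binary = (image.intensity > threshold) & unmasked
    skim_conn = 1 if config.connectivity == 4 else 2
    raw_labels = measure.label(binary, connectivity=skim_conn)

    areas = np.bincount(raw_labels.ravel())
    keep = np.flatnonzero(areas >= config.min_area_px)
    keep = keep[keep != 0]
    # relabel sequentially, preserving scan order
    remap = np.zeros(areas.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    label_image = remap[raw_labels]

    spots = _spot_records(image, label_image, keep.size, config)
    spot_uptake = float(image.intensity[(label_image > 0)].sum())
    total_uptake = float(image.intensity[unmasked].sum())
    nonspot_uptake = float(image.intensity[(label_image == 0) & unmasked].sum())
    return SegmentationResult(
        spots=spots,
        label_image=label_image,
        threshold_used=float(threshold),
        spot_uptake=spot_uptake,
        nonspot_uptake=nonspot_uptake,
        total_uptake=total_uptake,
        config=config,
        pixel_pitch_um=image.pixel_pitch_um,
        image=image,
    )


def _spot_records(
    image: PatchImage, label_image: np.ndarray, n_labels: int, config: SegmentationConfig
) -> list[Spot]:
    if n_labels == 0:
        return []
    pitch2 = image.pixel_pitch_um**2
    flat = label_image.ravel()
    inten = image.intensity.ravel()
    areas = np.bincount(flat, minlength=n_labels + 1)
    sums = np.bincount(flat, weights=inten, minlength=n_labels + 1)
    rows, cols = np.indices(label_image.shape)
    wr = np.bincount(flat, weights=inten * rows.ravel(), minlength=n_labels + 1)
    wc = np.bincount(flat, weights=inten * cols.ravel(), minlength=n_labels + 1)
    spots = []
    for lab in range(1, n_labels + 1):
        spots.append(
            Spot(
                spot_id=lab,
                area_px=int(areas[lab]),
                area_um2=float(areas[lab] * pitch2),
                integrated_intensity=float(sums[lab]),
                centroid_row=float(wr[lab] / sums[lab]),
                centroid_col=float(wc[lab] / sums[lab]),
            )
        )
    return spots


def refilter_spots(result: SegmentationResult, min_area_px: int) -> SegmentationResult:
    """Re-apply a larger area filter without re-segmenting.

    Spots below the new cutoff move to the non-spot compartment; the outcome
    is identical to segmenting from scratch at the larger cutoff (same
    threshold, same binary image). A smaller cutoff is rejected because the
    discarded components are gone.
    """
    if min_area_px < result.config.min_area_px:
        raise ValueError(
            f"cannot refilter below the original min_area_px="
            f"{result.config.min_area_px} (information lost)"
        )
    keep = [s for s in result.spots if s.area_px >= min_area_px]
    dropped = [s for s in result.spots if s.area_px < min_area_px]
    remap = np.zeros(len(result.spots) + 1, dtype=np.int32)
    new_spots = []
    for new_id, s in enumerate(keep, start=1):
        remap[s.spot_id] = new_id
        new_spots.append(replace(s, spot_id=new_id))
    label_image = remap[result.label_image]
    if result.image is not None:
        # recompute the compartments exactly as segment_spots does, so the
        # result is bit-identical to segmenting from scratch at the new cutoff
        intensity = result.image.intensity
        unmasked = ~result.image.ostium_mask
        spot_uptake = float(intensity[label_image > 0].sum())
        nonspot_uptake = float(intensity[(label_image == 0) & unmasked].sum())
        total_uptake = float(intensity[unmasked].sum())
    else:
        moved = float(np.sum([s.integrated_intensity for s in dropped]))
        spot_uptake = result.spot_uptake - moved
        nonspot_uptake = result.nonspot_uptake + moved
        total_uptake = result.total_uptake
    return SegmentationResult(
        spots=new_spots,
        label_image=label_image,
        threshold_used=result.threshold_used,
        spot_uptake=spot_uptake,
        nonspot_uptake=nonspot_uptake,
        total_uptake=total_uptake,
        config=replace(result.config, min_area_px=min_area_px),
        pixel_pitch_um=result.pixel_pitch_um,
        image=result.image,
    )


SPOT_TABLE_COLUMNS = [
    "spot_id",
    "area_px",
    "area_um2",
    "integrated_intensity",
    "centroid_row",
    "centroid_col",
]


def spot_table(result: SegmentationResult) -> pd.DataFrame:
    """One row per spot; empty (header-only when written) for zero spots."""
    return pd.DataFrame(
        [
            {
                "spot_id": s.spot_id,
                "area_px": s.area_px,
                "area_um2": s.area_um2,
                "integrated_intensity": s.integrated_intensity,
                "centroid_row": s.centroid_row,
                "centroid_col": s.centroid_col,
            }
            for s in result.spots
        ],
        columns=SPOT_TABLE_COLUMNS,
    )


def write_spot_table(result: SegmentationResult, path: str | Path) -> None:
    spot_table(result).to_csv(Path(path), index=False)


def read_spot_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
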