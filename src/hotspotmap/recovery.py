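"""Planted-spot recovery scoring against generator ground truth.

A detection matches when a planted spot centre falls inside a labeled
component. Recall is restricted to planted spots the segmentation could in
principle see: peak at least ``min_peak_snr`` noise SDs above background and
a predicted above-threshold footprint of at least the area filter.
"""

from __future__ import annotations

import numpy as np

from .segmentation import SegmentationResult
from .synthgen import GroundTruth, SpotTruth


def predicted_above_threshold_area(spot: SpotTruth, threshold: float) -> float:
    """Pixels of a Gaussian bump expected above the segmentation threshold.

    The profile is peak*exp(-d^2 / 2 sigma^2) on top of the local background,
    truncated at 3 sigma, so the radius where it crosses the threshold is
    sigma*sqrt(2 ln(peak/(threshold - background))).
    """
    excess = threshold - spot.background_at_centre
    full = np.pi * (3.0 * spot.radius_px) ** 2
    if excess <= 0:
        return full
    if spot.scaled_peak <= excess:
        return 0.0
    r2 = 2.0 * spot.radius_px**2 * np.log(spot.scaled_peak / excess)
    return float(np.pi * min(r2, (3.0 * spot.radius_px) ** 2))


def recoverable_spots(
    truth: GroundTruth,
    result: SegmentationResult,
    min_area_px: int | None = None,
    min_peak_snr: float = 5.0,
    noise_sd: float = 1.0,
) -> list[SpotTruth]:
    """Planted spots within the segmentation's operating regime."""
    if min_area_px is None:
        min_area_px = result.config.min_area_px
    out = []
    for s in truth.spots:
        if s.scaled_peak < min_peak_snr * noise_sd:
            continue
        if predicted_above_threshold_area(s, result.threshold_used) < min_area_px:
            continue
        out.append(s)
    return out


def match_spots(
    truth: GroundTruth,
    result: SegmentationResult,
    min_peak_snr: float = 5.0,
    noise_sd: float = 1.0,
) -> tuple[float, float, int, int]:
    """(recall, precision, n_recoverable, n_detected).

    Recall: fraction of recoverable planted spots whose centre lies in a
    labeled component. Precision: fraction of labeled components containing
    at least one planted centre (any planted spot counts, recoverable or
    not). Empty denominators give a score of 1.
    """
    lbl = result.label_image
    side = lbl.shape[0]

    def label_at(s: SpotTruth) -> int:
        return int(lbl[min(side - 1, int(s.centre_row)), min(side - 1, int(s.centre_col))])

    recoverable = recoverable_spots(truth, result, None, min_peak_snr, noise_sd)
    n_rec = len(recoverable)
    hits = sum(1 for s in recoverable if label_at(s) > 0)
    recall = hits / n_rec if n_rec else 1.0

    matched_labels = {label_at(s) for s in truth.spots} - {0}
    n_det = result.n_spots
    precision = len(matched_labels) / n_det if n_det else 1.0
    return recall, precision, n_rec, n_det
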