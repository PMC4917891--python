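"""10x10 grid-square maps, cohort averaging and Chauvenet outlier exclusion.

Every branch patch is divided into a fixed 10x10 grid (row 0 = most
upstream). Per-branch metrics are accumulated per square; squares touched by
the branch ostium are invalid and carry no value. Cohort maps average across
branches square by square, masking any square where an ostium was present in
any branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import erfc

from .imaging import PatchImage

GRID_N = 10

METRICS = (
    "spot_count",
    "spot_area",
    "spot_uptake",
    "nonspot_uptake",
    "total_uptake",
    "nuclei_count",
    "lesion_prevalence",
    "autofluorescence",
)


@dataclass(frozen=True)
class GridGeometry:
    """Half-open [lo, hi) square boundaries; the remainder of ``side`` mod 10
    is absorbed by the last row/column of squares."""

    side: int
    row_edges: np.ndarray  # length 11
    col_edges: np.ndarray

    @property
    def base(self) -> int:
        return self.side // GRID_N

    def square_of(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Grid indices (i, j) for point/pixel coordinates."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        i = np.minimum((rows // self.base).astype(int), GRID_N - 1)
        j = np.minimum((cols // self.base).astype(int), GRID_N - 1)
        return i, j


def grid_geometry(side: int) -> GridGeometry:
    if side < GRID_N:
        raise ValueError(f"image side must be >= {GRID_N} px")
    base = side // GRID_N
    edges = np.arange(GRID_N + 1) * base
    edges[-1] = side
    return GridGeometry(side=side, row_edges=edges.copy(), col_edges=edges.copy())


@dataclass
class GridMap:
    """10x10 metric values with a validity mask.

    ``valid`` is False for squares that carry no value: squares intersecting
    the ostium (also flagged in ``ostium``) and squares where the metric is
    undefined (e.g. per-spot area in a square without spots). Invalid squares
    hold NaN.
    """

    values: np.ndarray
    valid: np.ndarray
    metric: str
    units: str = "arbitrary"
    ostium: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != (GRID_N, GRID_N) or self.valid.shape != (GRID_N, GRID_N):
            raise ValueError(f"grid maps are fixed at {GRID_N}x{GRID_N}")
        if self.ostium is None:
            self.ostium = ~self.valid
        self.ostium = np.asarray(self.ostium, dtype=bool)
        self.values = np.where(self.valid, self.values, np.nan)


@dataclass
class CohortAverageMap:
    """Per-square mean across branches with union ostium mask."""

    mean_values: np.ndarray
    union_ostium: np.ndarray
    n_branches: int
    n_per_square: np.ndarray
    metric: str
    units: str = "arbitrary"

    @property
    def valid(self) -> np.ndarray:
        return ~self.union_ostium & (self.n_per_square > 0)

    def as_grid_map(self) -> GridMap:
        return GridMap(
            values=self.mean_values,
            valid=self.valid,
            metric=self.metric,
            units=self.units,
            ostium=self.union_ostium,
        )


def ostium_squares(ostium_mask: np.ndarray, geometry: GridGeometry) -> np.ndarray:
    """Boolean 10x10: True where any ostium pixel intersects the square."""
    out = np.zeros((GRID_N, GRID_N), dtype=bool)
    rows, cols = np.nonzero(ostium_mask)
    if rows.size:
        i, j = geometry.square_of(rows, cols)
        out[i, j] = True
    return out


def _point_counts(
    points: np.ndarray, geometry: GridGeometry, invalid: np.ndarray
) -> np.ndarray:
    counts = np.zeros((GRID_N, GRID_N))
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if points.shape[0]:
        if np.any(points < 0) or np.any(points >= geometry.side):
            raise ValueError("points must lie inside the image")
        i, j = geometry.square_of(points[:, 0], points[:, 1])
        np.add.at(counts, (i, j), 1)
    counts[invalid] = np.nan
    return counts


def spot_count_map(spots, geometry: GridGeometry, ostium_mask: np.ndarray) -> GridMap:
    """Spots per grid square, each spot assigned once by weighted centroid."""
    invalid = ostium_squares(ostium_mask, geometry)
    pts = np.array([[s.centroid_row, s.centroid_col] for s in spots], dtype=float)
    counts = _point_counts(pts.reshape(-1, 2), geometry, invalid)
    return GridMap(counts, ~invalid, "spot_count", units="spots/square", ostium=invalid)


def spot_area_map(spots, geometry: GridGeometry, ostium_mask: np.ndarray) -> GridMap:
    """Mean spot area (px) per grid square; squares without spots are
    undefined, not zero, so cohort averages stay per-spot."""
    invalid = ostium_squares(ostium_mask, geometry)
    total = np.zeros((GRID_N, GRID_N))
    count = np.zeros((GRID_N, GRID_N))
    for s in spots:
        i, j = geometry.square_of(np.array(s.centroid_row), np.array(s.centroid_col))
        total[i, j] += s.area_px
        count[i, j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / count
    valid = ~invalid & (count > 0)
    return GridMap(mean, valid, "spot_area", units="px/spot", ostium=invalid)


def nuclei_count_map(
    points: np.ndarray, geometry: GridGeometry, ostium_mask: np.ndarray
) -> GridMap:
    """BrdU-positive nuclei per grid square."""
    invalid = ostium_squares(ostium_mask, geometry)
    counts = _point_counts(points, geometry, invalid)
    return GridMap(counts, ~invalid, "nuclei_count", units="nuclei/square", ostium=invalid)


def uptake_maps(
    image: PatchImage, label_image: np.ndarray, geometry: GridGeometry
) -> tuple[GridMap, GridMap, GridMap]:
    """Per-square spot, non-spot and total uptake sums over unmasked pixels."""
    if label_image.shape != image.intensity.shape:
        raise ValueError("image and label image must share shape")
    invalid = ostium_squares(image.ostium_mask, geometry)
    unmasked = ~image.ostium_mask
    rows, cols = np.indices(image.intensity.shape)
    i, j = geometry.square_of(rows.ravel(), cols.ravel())
    flat_sq = i * GRID_N + j
    inten = image.intensity.ravel()
    in_spot = (label_image.ravel() > 0) & unmasked.ravel()
    in_non = (label_image.ravel() == 0) & unmasked.ravel()
    spot = np.bincount(flat_sq[in_spot], weights=inten[in_spot], minlength=GRID_N**2)
    non = np.bincount(flat_sq[in_non], weights=inten[in_non], minlength=GRID_N**2)
    total = np.bincount(
        flat_sq[unmasked.ravel()], weights=inten[unmasked.ravel()], minlength=GRID_N**2
    )
    maps = []
    for vals, metric in (
        (spot, "spot_uptake"),
        (non, "nonspot_uptake"),
        (total, "total_uptake"),
    ):
        maps.append(
            GridMap(vals.reshape(GRID_N, GRID_N), ~invalid, metric, ostium=invalid)
        )
    return tuple(maps)


def average_maps(branch_maps: list[GridMap]) -> CohortAverageMap:
    """Cohort average: per-square mean over branches with a defined value,
    with the union-ostium mask applied."""
    if not branch_maps:
        raise ValueError("need at least one branch map")
    metric = branch_maps[0].metric
    if any(m.metric != metric for m in branch_maps):
        raise ValueError("all branch maps must share the same metric")
    stack = np.stack([m.values for m in branch_maps])
    union = np.any(np.stack([m.ostium for m in branch_maps]), axis=0)
    defined = np.isfinite(stack)
    n_per_square = defined.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nansum(np.where(defined, stack, 0.0), axis=0) / n_per_square
    mean[union | (n_per_square == 0)] = np.nan
    n_per_square = np.where(union, 0, n_per_square)
    return CohortAverageMap(
        mean_values=mean,
        union_ostium=union,
        n_branches=len(branch_maps),
        n_per_square=n_per_square,
        metric=metric,
        units=branch_maps[0].units,
    )


def chauvenet_exclude(values) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass Chauvenet's criterion at the animal level.

    A value is excluded iff n * P(|Z| >= |z_i|) < 0.5 under a normal with the
    sample mean and (n-1)-denominator SD. Returns (kept, excluded) index
    arrays. All-equal samples exclude nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("Chauvenet's criterion needs >= 3 values")
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0:
        return np.arange(n), np.array([], dtype=int)
    z = np.abs(x - x.mean()) / sd
    p_tail = erfc(z / np.sqrt(2.0))  # = 2 * (1 - Phi(z))
    excluded = np.flatnonzero(n * p_tail < 0.5)
    kept = np.setdiff1d(np.arange(n), excluded)
    return kept, excluded


# ---- grid map I/O -------------------------------------------------------

def write_grid_csv(grid: GridMap | CohortAverageMap, path: str | Path) -> None:
    """10x10 CSV (row 0 = upstream) plus a JSON sidecar with metadata."""
    path = Path(path)
    if isinstance(grid, CohortAverageMap):
        sidecar = {
            "metric": grid.metric,
            "units": grid.units,
            "valid": grid.valid.astype(int).tolist(),
            "union_ostium": grid.union_ostium.astype(int).tolist(),
            "n_branches": int(grid.n_branches),
            "n_per_square": np.asarray(grid.n_per_square).astype(int).tolist(),
        }
        values = grid.mean_values
    else:
        sidecar = {
            "metric": grid.metric,
            "units": grid.units,
            "valid": grid.valid.astype(int).tolist(),
            "ostium": grid.ostium.astype(int).tolist(),
        }
        values = grid.values
    np.savetxt(path, values, delimiter=",", fmt="%.10g")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_grid_csv(path: str | Path, metric: str | None = None) -> GridMap:
    """Read a 10x10 grid CSV; uses the JSON sidecar when present, otherwise
    all squares with finite values are valid (the form externally supplied
    lesion-frequency maps take)."""
    path = Path(path)
    values = np.loadtxt(path, delimiter=",")
    if values.shape != (GRID_N, GRID_N):
        raise ValueError(f"{path}: expected a {GRID_N}x{GRID_N} grid")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        valid = np.asarray(meta["valid"], dtype=bool)
        ostium = np.asarray(
            meta.get("ostium", meta.get("union_ostium", (~valid).astype(int))), dtype=bool
        )
        return GridMap(values, valid, metric or meta["metric"], meta.get("units", ""), ostium)
    valid = np.isfinite(values)
    return GridMap(values, valid, metric or "lesion_prevalence", units="")
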