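"""Stack I/O, maximum-intensity projection and frame standardisation.

Coordinate convention: row-major, 0-based, row index increases downstream
(mean blood flow runs top to bottom); after standardisation the ostium centre
sits at the image centre.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

FLOW_DIRECTIONS = ("down", "up", "left", "right")


@dataclass
class ZStack:
    """Ordered z-slices of identical shape; spacing is informational only."""

    slices: np.ndarray  # (n, h, w)
    spacing_um: float | None = None

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ValueError("ZStack needs >= 1 slice of identical 2D shape")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


@dataclass
class PatchImage:
    """2D nonnegative intensity field with pixel pitch and an ostium mask."""

    intensity: np.ndarray
    pixel_pitch_um: float
    ostium_mask: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.ostium_mask = np.asarray(self.ostium_mask, dtype=bool)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2D")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensity must be finite and nonnegative")
        if self.ostium_mask.shape != self.intensity.shape:
            raise ValueError("ostium mask shape must match intensity shape")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")


def load_stack(path: str | Path) -> ZStack:
    """Read a multi-page grayscale TIFF as a ZStack, values unchanged.

    Rejects RGB/multisample pages, mixed page shapes and unreadable files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = set()
            for page in tif.pages:
                if page.samplesperpixel != 1:
                    raise ValueError(f"{path}: RGB/multisample TIFF is not supported")
                shapes.add(page.shape)
            if len(shapes) != 1:
                raise ValueError(f"{path}: pages have mixed shapes {sorted(shapes)}")
            arr = tif.asarray()
    except (tifffile.TiffFileError, OSError, ValueError) as exc:
        raise ValueError(f"{path}: unreadable TIFF ({exc})") from exc
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return ZStack(slices=arr)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a single-page 0/255 mask TIFF as a boolean array."""
    stack = load_stack(path)
    if stack.n_slices != 1:
        raise ValueError(f"{path}: mask must be a single-page TIFF")
    return stack.slices[0] > 0


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a 2D image as 16-bit TIFF (clipped/rounded)."""
    arr = np.clip(np.round(np.asarray(image, dtype=float)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), arr, photometric="minisblack")


def max_intensity_projection(stack: ZStack | np.ndarray) -> np.ndarray:
    """Per-pixel maximum across slices (brightest, inner-wall signal)."""
    slices = stack.slices if isinstance(stack, ZStack) else np.asarray(stack)
    if slices.ndim != 3 or slices.shape[0] < 1:
        raise ValueError("expected a non-empty stack of 2D slices")
    return slices.max(axis=0)


def _orient(arr: np.ndarray, flow_direction: str) -> np.ndarray:
    """Re-orient so flow runs toward increasing row index."""
    if flow_direction == "down":
        return arr
    if flow_direction == "up":
        return np.flipud(arr)
    if flow_direction == "left":
        return np.rot90(arr, 1)
    if flow_direction == "right":
        return np.rot90(arr, -1)
    raise ValueError(f"unknown flow_direction {flow_direction!r}; use {FLOW_DIRECTIONS}")


def _orient_point(point, shape, flow_direction: str):
    r, c = point
    h, w = shape
    if flow_direction == "down":
        return r, c
    if flow_direction == "up":
        return h - 1 - r, c
    if flow_direction == "left":
        # np.rot90(k=1): old (r, c) -> new (w - 1 - c, r)
        return w - 1 - c, r
    if flow_direction == "right":
        # np.rot90(k=-1): old (r, c) -> new (c, h - 1 - r)
        return c, h - 1 - r
    raise ValueError(f"unknown flow_direction {flow_direction!r}")


def standardise_frame(
    image: PatchImage,
    ostium_centre: tuple[float, float],
    flow_direction: str = "down",
    side: int | None = None,
    max_pad_px: int | None = None,
) -> PatchImage:
    """Bring a patch into the common analysis frame.

    The image is re-oriented in multiples of 90 deg (flow down rows),
    translated by whole pixels so the ostium centre lands at the centre of a
    ``side`` x ``side`` output, and cropped/padded as needed. Padded pixels
    get 0 intensity and mask=True so they never contribute to any metric.
    ``max_pad_px`` (default side//4) bounds how far the crop may exceed the
    original image.
    """
    h, w = image.intensity.shape
    r0, c0 = ostium_centre
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("ostium centre must lie inside the image")

    intensity = _orient(image.intensity, flow_direction)
    mask = _orient(image.ostium_mask, flow_direction)
    r0, c0 = _orient_point((r0, c0), (h, w), flow_direction)
    h, w = intensity.shape

    if side is None:
        side = max(h, w)
    if max_pad_px is None:
        max_pad_px = side // 4
    target = (side // 2, side // 2)
    # source window (in oriented coordinates) that maps onto the output
    top = int(round(r0)) - target[0]
    left = int(round(c0)) - target[1]
    pad = max(0, -top, -left, top + side - h, left + side - w)
    if pad > max_pad_px:
        raise ValueError(
            f"standardisation needs {pad} px of padding, more than max_pad_px={max_pad_px}"
        )

    out_int = np.zeros((side, side), dtype=image.intensity.dtype)
    out_mask = np.ones((side, side), dtype=bool)
    src_r = slice(max(0, top), min(h, top + side))
    src_c = slice(max(0, left), min(w, left + side))
    dst_r = slice(src_r.start - top, src_r.stop - top)
    dst_c = slice(src_c.start - left, src_c.stop - left)
    out_int[dst_r, dst_c] = intensity[src_r, src_c]
    out_mask[dst_r, dst_c] = mask[src_r, src_c]
    return PatchImage(out_int, image.pixel_pitch_um, out_mask)
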