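"""Configuration objects for the synthetic branch-patch generator.

The generator emulates en-face fluorescence patches of vessel wall centred on
a side-branch ostium: a smooth diffuse-uptake background, discrete
high-intensity spots (permeability hotspots), an elliptical ostium that is
excluded from every metric, and sparse nucleus point events (mitosis marker).
Two age-group presets set the spatial pattern of the spot process:
``immature`` concentrates spots downstream of the ostium, ``mature`` places
them in four corner patches; ``flat`` is spatially homogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

PRESETS = ("immature", "mature", "flat")

#: Default patch geometry: 750 px at 3.2 um/px makes a 2.4 mm side, one 10x10
#: grid square is 75 px (~57,600 um^2) and a 50 px area is ~512 um^2 -- about
#: one endothelial cell.
DEFAULT_SIDE_PX = 750
DEFAULT_PITCH_UM = 3.2

#: Spots per patch observed per age group (group means used as Poisson rates).
PRESET_SPOT_RATE = {"immature": 26.2, "mature": 49.6, "flat": 40.0}
#: Mitotic (BrdU-positive nucleus) events per patch per age group.
PRESET_NUCLEI_RATE = {"immature": 6.2, "mature": 3.9, "flat": 6.0}


@dataclass(frozen=True)
class LogNormal:
    """Log-normal distribution parameterised by its median and log-sigma."""

    median: float
    sigma: float

    def __post_init__(self) -> None:
        if self.median < 0 or self.sigma < 0:
            raise ValueError("log-normal median and sigma must be >= 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.median * np.exp(self.sigma * rng.standard_normal(n))


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in pixel coordinates (row/col centre, semi-axes)."""

    centre_row: float
    centre_col: float
    semi_row: float
    semi_col: float

    def __post_init__(self) -> None:
        if self.semi_row <= 0 or self.semi_col <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def mask(self, side: int) -> np.ndarray:
        """Boolean (side, side) array, True inside the ellipse."""
        rr = np.arange(side)[:, None] + 0.5
        cc = np.arange(side)[None, :] + 0.5
        return ((rr - self.centre_row) / self.semi_row) ** 2 + (
            (cc - self.centre_col) / self.semi_col
        ) ** 2 <= 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of one synthetic branch patch.

    Intensities are in arbitrary fluorescence units; lengths in pixels unless
    suffixed ``_um``. ``background_pattern_gain`` sets the spatial contrast of
    the preset pattern, both in the spot rate field and (when
    ``couple_background_to_rate``) in the diffuse background.
    """

    preset: str
    image_side_px: int = DEFAULT_SIDE_PX
    pixel_pitch_um: float = DEFAULT_PITCH_UM
    n_slices: int = 5
    ostium: Ellipse | None = None  # default: centred, semi-axes scaled to side
    background_amplitude: float = 100.0
    background_pattern_gain: float = 1.2
    spot_rate_per_patch: float = 40.0
    spot_amplitude_dist: LogNormal = field(default_factory=lambda: LogNormal(1200.0, 0.25))
    spot_radius_dist: LogNormal = field(default_factory=lambda: LogNormal(5.0, 0.35))
    branch_scale_sigma: float = 0.25
    couple_background_to_rate: bool = True
    noise_read_sigma: float = 4.0
    noise_shot: bool = True
    nuclei_rate_per_patch: float = 6.0
    nuclei_downstream_bias: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {PRESETS}")
        if self.image_side_px < 100:
            raise ValueError("image_side_px must be >= 100")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        for name in (
            "background_amplitude",
            "background_pattern_gain",
            "spot_rate_per_patch",
            "branch_scale_sigma",
            "noise_read_sigma",
            "nuclei_rate_per_patch",
            "nuclei_downstream_bias",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")
        if self.ostium is None:
            s = self.image_side_px
            object.__setattr__(
                self,
                "ostium",
                Ellipse(s / 2, s / 2, 80 * s / DEFAULT_SIDE_PX, 55 * s / DEFAULT_SIDE_PX),
            )
        ost = self.ostium
        s = self.image_side_px
        if not (
            0 < ost.centre_row - ost.semi_row
            and ost.centre_row + ost.semi_row < s
            and 0 < ost.centre_col - ost.semi_col
            and ost.centre_col + ost.semi_col < s
        ):
            raise ValueError("ostium ellipse must lie fully inside the image")

    @classmethod
    def for_preset(
        cls, preset: str, image_side_px: int = DEFAULT_SIDE_PX, **overrides
    ) -> "GeneratorConfig":
        """Config with the study-condition rates for an age-group preset.

        When ``image_side_px`` differs from the default, the pixel pitch,
        ostium and spot radii are rescaled so the patch still covers
        2.4 x 2.4 mm with the same physical spot sizes.
        """
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
        f = image_side_px / DEFAULT_SIDE_PX
        base = dict(
            preset=preset,
            image_side_px=image_side_px,
            pixel_pitch_um=DEFAULT_PITCH_UM / f,
            spot_rate_per_patch=PRESET_SPOT_RATE[preset],
            nuclei_rate_per_patch=PRESET_NUCLEI_RATE[preset],
            spot_radius_dist=LogNormal(5.0 * f, 0.35),
        )
        base.update(overrides)
        return cls(**base)

    def with_(self, **changes) -> "GeneratorConfig":
        return replace(self, **changes)

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if isinstance(d.get("ostium"), dict):
            d["ostium"] = Ellipse(**d["ostium"])
        for key in ("spot_amplitude_dist", "spot_radius_dist"):
            if isinstance(d.get(key), dict):
                d[key] = LogNormal(**d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
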