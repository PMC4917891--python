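"""Synthetic branch-patch generator with ground truth.

Each branch realisation is a z-stack of nonnegative images: a diffuse
background (optionally spatially coupled to the spot rate field), discrete
Gaussian-profile hotspots drawn from an inhomogeneous Poisson process, a
per-branch log-normal intensity scale, optional shot (Poisson) and read
(Gaussian) noise, plus an independent sparse point process of BrdU-positive
nuclei. Everything is reproducible from (config, branch_seed) and fully
described by the returned :class:`GroundTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .config import GeneratorConfig, PRESETS

MANIFEST_COLUMNS = [
    "animal_id",
    "branch_id",
    "stack_path",
    "mask_path",
    "nuclei_path",
    "truth_path",
    "seed",
]


def ostium_mask(config: GeneratorConfig) -> np.ndarray:
    """Boolean mask of the branch ostium (True = excluded pixel)."""
    return config.ostium.mask(config.image_side_px)


def rate_field(config: GeneratorConfig) -> np.ndarray:
    """Per-pixel relative spot intensity rate, normalised to mean 1.

    ``flat`` is constant; ``immature`` is a smooth lobe downstream of the
    ostium (rows increase downstream); ``mature`` is four corner patches.
    The mean is taken over pixels outside the ostium.
    """
    side = config.image_side_px
    if config.preset not in PRESETS:
        raise ValueError(f"unknown preset {config.preset!r}")
    rr = (np.arange(side)[:, None] + 0.5) / side
    cc = (np.arange(side)[None, :] + 0.5) / side
    if config.preset == "flat":
        pattern = np.zeros((side, side))
    elif config.preset == "immature":
        # downstream arrowhead: a broad lobe below the ostium, slightly
        # elongated across the flow axis
        pattern = np.exp(
            -((rr - 0.72) ** 2) / (2 * 0.16**2) - ((cc - 0.5) ** 2) / (2 * 0.22**2)
        )
    else:  # mature: four corner patches
        pattern = np.zeros((side, side))
        for r0 in (0.11, 0.89):
            for c0 in (0.11, 0.89):
                pattern += np.exp(
                    -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * 0.09**2)
                )
    peak = pattern.max()
    if peak > 0:
        pattern = pattern / peak
    f = 1.0 + config.background_pattern_gain * pattern
    valid = ~ostium_mask(config)
    return f / f[valid].mean()


@dataclass(frozen=True)
class SpotTruth:
    """One planted hotspot: geometry plus the local quantities needed to
    predict its above-threshold footprint."""

    centre_row: float
    centre_col: float
    radius_px: float  # Gaussian sigma of the profile
    amplitude: float  # unscaled peak intensity
    true_area_px: int  # pixel count of the 3-sigma support disc
    scaled_peak: float  # amplitude x branch scale
    background_at_centre: float  # scaled noiseless background under the peak


@dataclass
class GroundTruth:
    spots: list[SpotTruth]
    branch_scale: float
    background_kind: str  # "coupled" | "independent"
    nuclei: np.ndarray  # (n, 2) float, row/col
    seed: int

    def to_json(self, path: str | Path) -> None:
        d = {
            "spots": [asdict(s) for s in self.spots],
            "branch_scale": self.branch_scale,
            "background_kind": self.background_kind,
            "nuclei": np.asarray(self.nuclei).tolist(),
            "seed": int(self.seed),
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            spots=[SpotTruth(**s) for s in d["spots"]],
            branch_scale=d["branch_scale"],
            background_kind=d["background_kind"],
            nuclei=np.asarray(d["nuclei"], dtype=float).reshape(-1, 2),
            seed=d["seed"],
        )


@dataclass
class BranchSample:
    stack: np.ndarray  # (n_slices, side, side) uint16
    ostium: np.ndarray  # (side, side) bool
    nuclei: np.ndarray  # (n, 2) float
    truth: GroundTruth


def _sample_points(
    rng: np.random.Generator, weights: np.ndarray, n: int
) -> np.ndarray:
    """Draw n points with pixel probabilities proportional to `weights`,
    uniformly jittered within their pixel."""
    side = weights.shape[0]
    if n == 0:
        return np.empty((0, 2))
    flat = weights.ravel().astype(float)
    flat = flat / flat.sum()
    idx = rng.choice(flat.size, size=n, p=flat)
    rows = idx // side + rng.random(n)
    cols = idx % side + rng.random(n)
    return np.column_stack([rows, cols])


def generate_nuclei(
    config: GeneratorConfig,
    base_field: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Inhomogeneous Poisson point process of BrdU-positive nuclei.

    Intensity is ``base_field`` (default: homogeneous) times a downstream
    multiplicative tilt of ``1 + nuclei_downstream_bias`` on the lower half
    of the patch; the ostium is excluded. Returns (n, 2) row/col coordinates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    side = config.image_side_px
    if base_field is None:
        base_field = np.ones((side, side))
    mask = ostium_mask(config)
    tilt = np.ones((side, side))
    tilt[side // 2 :, :] = 1.0 + config.nuclei_downstream_bias
    weights = base_field * tilt * ~mask
    n = rng.poisson(config.nuclei_rate_per_patch)
    return _sample_points(rng, weights, n)


def _render_spots(
    side: int,
    centres: np.ndarray,
    sigmas: np.ndarray,
    amplitudes: np.ndarray,
) -> np.ndarray:
    """Sum of isotropic Gaussian bumps truncated at 3 sigma."""
    img = np.zeros((side, side))
    for (r0, c0), sig, amp in zip(centres, sigmas, amplitudes):
        rad = 3.0 * sig
        rlo, rhi = max(0, int(np.floor(r0 - rad))), min(side, int(np.ceil(r0 + rad)) + 1)
        clo, chi = max(0, int(np.floor(c0 - rad))), min(side, int(np.ceil(c0 + rad)) + 1)
        if rlo >= rhi or clo >= chi:
            continue
        rr = np.arange(rlo, rhi)[:, None] + 0.5
        cc = np.arange(clo, chi)[None, :] + 0.5
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        bump = amp * np.exp(-d2 / (2 * sig**2))
        bump[d2 > rad**2] = 0.0
        img[rlo:rhi, clo:chi] += bump
    return img


def _independent_background_pattern(
    rng: np.random.Generator, side: int, reference_sd: float
) -> np.ndarray:
    """Smooth random field with mean ~1 and spatial SD matched to the rate
    field's, used when the background is decoupled from the spot process."""
    noise = rng.standard_normal((side, side))
    smooth = gaussian_filter(noise, sigma=side / 8.0, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.ones((side, side))
    return np.clip(1.0 + smooth / sd * reference_sd, 0.0, None)


def generate_branch(config: GeneratorConfig, branch_seed: int) -> BranchSample:
    """Generate one branch patch: z-stack, ostium mask, nuclei and truth.

    All randomness derives from ``(config.seed, branch_seed)``, so identical
    inputs give bit-identical outputs. The stack is quantised to uint16, the
    same representation the files use.
    """
    if branch_seed < 0:
        raise ValueError("branch_seed must be a nonnegative integer")
    side = config.image_side_px
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, branch_seed]))
    mask = ostium_mask(config)
    rf = rate_field(config)

    branch_scale = float(np.exp(config.branch_scale_sigma * rng.standard_normal()))

    if config.couple_background_to_rate:
        background = config.background_amplitude * (
            1.0 + config.background_pattern_gain * rf
        )
        bg_kind = "coupled"
    else:
        pattern = _independent_background_pattern(rng, side, rf[~mask].std())
        background = config.background_amplitude * (
            1.0 + config.background_pattern_gain * pattern
        )
        bg_kind = "independent"

    n_spots = rng.poisson(config.spot_rate_per_patch)
    centres = _sample_points(rng, rf * ~mask, n_spots)
    sigmas = config.spot_radius_dist.sample(rng, n_spots)
    amplitudes = config.spot_amplitude_dist.sample(rng, n_spots)
    spot_img = _render_spots(side, centres, sigmas, amplitudes)

    noiseless = branch_scale * (background + spot_img)

    spots = []
    for (r0, c0), sig, amp in zip(centres, sigmas, amplitudes):
        bg_c = branch_scale * background[
            min(side - 1, int(r0)), min(side - 1, int(c0))
        ]
        true_area = int(np.round(np.pi * (3.0 * sig) ** 2))
        spots.append(
            SpotTruth(
                centre_row=float(r0),
                centre_col=float(c0),
                radius_px=float(sig),
                amplitude=float(amp),
                true_area_px=true_area,
                scaled_peak=float(branch_scale * amp),
                background_at_centre=float(bg_c),
            )
        )

    # z-stack: one focal slice carries full signal, the rest are attenuated
    atten = rng.uniform(0.6, 0.95, config.n_slices)
    atten[rng.integers(config.n_slices)] = 1.0
    stack = np.empty((config.n_slices, side, side), dtype=np.uint16)
    for i in range(config.n_slices):
        img = noiseless * atten[i]
        if config.noise_shot:
            img = rng.poisson(img).astype(float)
        if config.noise_read_sigma > 0:
            img = img + rng.normal(0.0, config.noise_read_sigma, img.shape)
        stack[i] = np.clip(np.round(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)

    nuclei = generate_nuclei(config, base_field=None, rng=rng)

    truth = GroundTruth(
        spots=spots,
        branch_scale=branch_scale,
        background_kind=bg_kind,
        nuclei=nuclei,
        seed=int(branch_seed),
    )
    return BranchSample(stack=stack, ostium=mask, nuclei=nuclei, truth=truth)


def branch_seed_for(seed: int, animal: int, branch: int) -> int:
    """Deterministic per-branch seed below 2**31 derived from a root seed."""
    ss = np.random.SeedSequence([seed, animal, branch])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    config: GeneratorConfig,
    n_animals: int,
    branches_per_animal: int,
    seed: int,
    out_dir: str | Path,
    force: bool = False,
) -> pd.DataFrame:
    """Write a full synthetic cohort to disk and return its manifest.

    One multi-page 16-bit TIFF stack, one 8-bit mask TIFF, one nuclei CSV and
    one truth JSON per branch; the manifest CSV lists animal id, branch id,
    file paths and per-branch seed. Refuses to overwrite an existing manifest
    unless ``force``.
    """
    if n_animals < 1 or branches_per_animal < 1:
        raise ValueError("n_animals and branches_per_animal must be >= 1")
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for a in range(n_animals):
        for b in range(branches_per_animal):
            bseed = branch_seed_for(seed, a, b)
            sample = generate_branch(config, bseed)
            stem = f"animal{a:02d}_branch{b:02d}"
            stack_path = out_dir / f"{stem}_stack.tif"
            mask_path = out_dir / f"{stem}_mask.tif"
            nuclei_path = out_dir / f"{stem}_nuclei.csv"
            truth_path = out_dir / f"{stem}_truth.json"
            tifffile.imwrite(stack_path, sample.stack, photometric="minisblack")
            tifffile.imwrite(mask_path, sample.ostium.astype(np.uint8) * 255,
                             photometric="minisblack")
            pd.DataFrame(sample.nuclei, columns=["row_px", "col_px"]).to_csv(
                nuclei_path, index=False
            )
            sample.truth.to_json(truth_path)
            rows.append(
                {
                    "animal_id": a,
                    "branch_id": b,
                    "stack_path": stack_path.name,
                    "mask_path": mask_path.name,
                    "nuclei_path": nuclei_path.name,
                    "truth_path": truth_path.name,
                    "seed": bseed,
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(manifest_path, index=False)
    config.to_yaml(out_dir / "generator_config.yaml")
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest, resolving file paths relative to its folder."""
    path = Path(path)
    manifest = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    for col in ("stack_path", "mask_path", "nuclei_path", "truth_path"):
        manifest[col] = [str(path.parent / p) for p in manifest[col]]
    return manifest
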