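# hotspotmap

Quantitative mapping of endothelial permeability **hotspots** around
arterial branch ostia, for vascular biologists and biomedical image
analysts studying macromolecule transport into the arterial wall.

Tracer studies (e.g. Evans' Blue dye bound to albumin) show that uptake of
plasma macromolecules by the aortic wall is focally elevated in scattered
hotspots, concentrated near side-branch mouths where early atherosclerotic
lesions form — and the spatial pattern changes with age. `hotspotmap`
implements the full quantitative workflow for such experiments:

1. **Imaging** — read multi-page TIFF z-stacks of en-face patches, compute
   the maximum-intensity projection `MIP(x) = max_z I(x, z)`, and
   standardise every branch into a common frame (ostium centred, flow down
   rows).
2. **Segmentation** — hotspots are connected components of pixels strictly
   above an intensity threshold *T* (default: median + 8·MAD of unmasked
   pixels) that pass an area filter *A*min (default 50 px ≈ 506 µm², about
   one endothelial cell; a nine-fold larger 450 px filter probes only the
   largest spots). Summed intensity is decomposed exactly into spot,
   non-spot and total uptake.
3. **Mapping** — per-branch metrics (spot count, per-spot area, the three
   uptake compartments, BrdU-positive nucleus counts) on a fixed 10×10 grid
   over the 2.4 × 2.4 mm patch; cohort averages under the union-ostium
   mask; Chauvenet's criterion (exclude a value iff `n·P(|Z| ≥ |z|) < 0.5`)
   for animal-level outliers.
4. **Statistics** — bootstrap map correlation (median Pearson *r* with
   percentile 95 % CI from resampling whole branch maps, hierarchically by
   animal when ids are given; significant iff the CI excludes zero),
   Student's *t*-test on spots per branch, and the paired 1-tailed
   half-map test of downstream vs upstream grid rows.
5. **Synthetic data** — a fully ground-truthed generator of branch patches
   (inhomogeneous Poisson spot process with age-group spatial presets,
   coupled diffuse background, per-branch random scale, shot + read noise,
   nucleus point events) so the whole pipeline is testable end to end
   without any image download.

## Worked example

Simulate a 15-branch immature-pattern cohort, segment it, and test the two
headline spatial hypotheses:

```python
import numpy as np
from hotspotmap import (GeneratorConfig, generate_branch, max_intensity_projection,
                        PatchImage, SegmentationConfig, segment_spots,
                        grid_geometry, spot_count_map, uptake_maps,
                        map_correlation, half_map_test)

cfg = GeneratorConfig.for_preset("immature", seed=0)
geom = grid_geometry(cfg.image_side_px)
count_maps, spot_maps, nonspot_maps = [], [], []
for branch in range(15):
    sample = generate_branch(cfg, branch)
    image = PatchImage(max_intensity_projection(sample.stack),
                       cfg.pixel_pitch_um, sample.ostium)
    seg = segment_spots(image, SegmentationConfig(min_area_px=50))
    count_maps.append(spot_count_map(seg.spots, geom, sample.ostium))
    spot_u, nonspot_u, _ = uptake_maps(image, seg.label_image, geom)
    spot_maps.append(spot_u); nonspot_maps.append(nonspot_u)

print(f"spots per branch: {np.mean([np.nansum(m.values) for m in count_maps]):.1f}")
print(f"spot / total uptake: {seg.spot_uptake / seg.total_uptake:.3f}")
corr = map_correlation(spot_maps, nonspot_maps, n_boot=2000, seed=0)
print(f"spot vs non-spot uptake: median r = {corr.median_r:.3f} "
      f"[{corr.ci_low:.3f}, {corr.ci_high:.3f}], significant = {corr.significant}")
half = half_map_test(count_maps, "downstream_greater")
print(f"downstream > upstream: t = {half.statistic:.2f}, p = {half.p_value:.4f}")
```

which prints

```
spots per branch: 22.1
spot / total uptake: 0.053
spot vs non-spot uptake: median r = 0.455 [0.289, 0.588], significant = True
downstream > upstream: t = 2.83, p = 0.0066
```

Read: hotspots carry only ~5 % of total uptake yet their map correlates
positively with the much larger non-hotspot uptake (shared spatial
mechanism), and the immature pattern puts significantly more hotspots
downstream of the ostium.

The same pipeline is scriptable from the shell:

```bash
hotspotmap simulate --preset immature --out runs/imm --seed 1 \
    --n-animals 5 --branches-per-animal 12
hotspotmap analyse runs/imm/manifest.csv --out runs/analysis --seed 1
hotspotmap report runs/analysis     # PNG heat maps + correlation grid
```

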