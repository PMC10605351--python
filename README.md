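# chromagrain

Quantification of chromatin-mark and cohesin organization in confocal
fluorescence images of cell nuclei.

Interphase nuclei imaged with a DNA counterstain (DAPI) plus antibody
labels for euchromatin (H3K4me3), constitutive heterochromatin
(H3K9me3) and cohesin show two complementary readouts: how much of
each label a nucleus carries, and how granular its spatial distribution
is. `chromagrain` turns calibrated multichannel TIFF frames into both,
for biologists comparing treatment groups (irradiation doses, repair
times, drug treatments, proliferation states) at diffraction-limited
resolution.

## What it computes

For every nucleus segmented from the DAPI channel (Otsu threshold,
hole filling, rule-based QC with logged exclusion reasons):

- **size** `A` in µm² from the mask pixel count and the pixel
  calibration (default 25.88 nm edge, 669.77 nm² per pixel);
- **amount** of each label, `mean intensity × nucleus size in pixels`
  (the integrated within-mask intensity, a.u. in 0–4095 × pixels);
- **granularity** of a label: the within-nucleus intensity histogram is
  smoothed by an iterated 3-bin moving average into a bimodal shape
  with local maxima `j` (diffuse signal) and `k` (granules); pixels
  strictly above the midpoint threshold

  `t = 0.5 (j + k)`

  survive a mask-aware median filter, and their 8-connected components
  of ≥ 5 pixels are the granules. Reported per nucleus: granule count,
  mean granule area (px), and the *pixel-weighted* mean granule
  intensity (all granule pixels pooled — a pixel in a large granule
  counts the same as one in a small granule).

Groups are compared with a two-sample Welch t-test for nucleus size and
the Kruskal–Wallis rank test for everything else, with significance
tiers n.s. / * / ** / *** at p ≥ 0.05 / < 0.05 / < 0.01 / < 0.001, and
summarized by median, quartiles, mean and ±2 SD whiskers with outliers.

Because such studies rarely deposit raw images, the package ships a
synthetic-scene generator that plants elliptical nuclei and hard-disk
granules with exact ground truth, so the whole chain is testable
end-to-end. See `docs/methods.md` for the model, parameters and
limitations.

## Worked example

```python
from chromagrain import (ChannelRole, generate_scene, preset_highsnr,
                         segment_nuclei, mask_background, channel_amount,
                         analyze_granularity, nucleus_area_um2)

scene = generate_scene(preset_highsnr(seed=1, granule_count=20))
image = scene.image
masks = segment_nuclei(image.dna, pixel_edge_nm=image.pixel_edge_nm)
clean = mask_background(image, masks)
nucleus = masks.mask_of(1)

area = nucleus_area_um2(nucleus, image.pixel_edge_nm)
amount = channel_amount(clean.channels[ChannelRole.COHESIN], nucleus)
gset, summary = analyze_granularity(clean.channels[ChannelRole.COHESIN],
                                    nucleus, nucleus_label=1)
bt = gset.threshold_used
print(f"nucleus area: {area:.1f} um^2")
print(f"cohesin amount: {amount.amount:.0f} intensity*px (mean {amount.mean_intensity:.1f})")
print(f"modes j={bt.mode_lo:.1f}, k={bt.mode_hi:.1f} -> threshold t={bt.threshold:.1f}")
print(f"granules: n={summary.n_granules}, mean area {summary.mean_area_px:.1f} px, "
      f"pixelwise mean intensity {summary.pixelwise_mean_intensity:.0f}")
```

prints

```
nucleus area: 499.0 um^2
cohesin amount: 39478913 intensity*px (mean 847.9)
modes j=807.5, k=2599.5 -> threshold t=1703.5
granules: n=20, mean area 60.6 px, pixelwise mean intensity 2599
```

The scene planted 20 disk granules at intensity 2600 on a diffuse level
of 800: the adaptive threshold lands at the mode midpoint (1700 planted,
1703.5 recovered), all 20 granules are found, and the pixel-weighted
granule intensity matches the planted level to a fraction of a percent.
The amount is dominated by the diffuse component (mean ≈ 848 over a
46 560-px nucleus).

## Command line

```bash
chromagrain simulate --preset paperlike --seed 3 --out-dir scene/
chromagrain segment scene/scene.tif --channel-map scene/channel_map.yaml --out-dir seg/
chromagrain run config.yaml          # full batch: segment -> quantify -> granules -> compare
```

`run` takes a YAML config with an image manifest (path + group label
per image), a channel map, the calibration, per-stage parameter blocks
and an output directory; it writes per-nucleus metrics, per-granule
tables, granularity summaries, threshold provenance (j, k, t, passes,
bimodality), pairwise comparisons, boxplot summaries and a JSON run log
recording every parameter and every QC exclusion.

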