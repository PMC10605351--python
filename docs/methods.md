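# Methods

## Scope and model

`chromagrain` quantifies how chromatin marks and cohesin are organized
in interphase cell nuclei imaged by diffraction-limited confocal
microscopy. Its inputs are multichannel 2D frames: a DAPI counterstain
channel that defines nucleus masks, plus up to three label channels —
H3K4me3 (euchromatin), H3K9me3 (constitutive heterochromatin) and
cohesin. Intensities are arbitrary units on a declared integer range
(default 12-bit, 0–4095); a single isotropic calibration scalar (nm per
pixel edge, default 25.88 nm, i.e. 669.77 nm² per pixel) converts pixel
counts to physical areas.

Three quantities are computed per nucleus:

1. **Size** — mask pixel count converted to µm².
2. **Amount** of each label — the within-mask mean intensity times the
   nucleus size in pixels, i.e. the integrated within-mask intensity in
   intensity·pixels (a derived intensity·µm² column is emitted as
   well). No background subtraction is applied inside the mask; the
   background outside nuclei is zeroed before any label-channel
   measurement.
3. **Granularity** of a label — the triple (granule count, mean granule
   area in pixels, mean granule intensity), where a granule is a
   connected set of at least 5 pixels whose intensity exceeds an
   adaptive per-nucleus threshold.

## Nucleus segmentation

Foreground is pixels strictly above a global Otsu threshold on the DNA
channel (the standard default for a bright-nucleus/dark-background
counterstain; overridable); holes are filled and 8-connected components
become candidate nuclei. QC is rule-based and fully logged: components
touching the frame edge are excluded as incomplete (reason `border`),
components below `min_area_um2` (default 20 µm²) as debris
(`too_small`), and — optionally, per label channel — nuclei whose
within-mask mean intensity falls below `min_mean_intensity` (default 0,
i.e. off; the value used is recorded in the run log) as `too_weak`.
Touching nuclei are not split: the pipeline targets isolated nuclei
from low-background fields, and the synthetic generator plants
non-overlapping nuclei. A constant DNA frame yields an empty mask set,
not an error.

## Adaptive bimodal threshold

Granule detection assumes the within-nucleus intensity histogram of a
label channel is a two-mode mixture: diffuse (non-granular) signal plus
brighter granules. For each nucleus and channel:

1. The histogram of within-mask intensities is built over 256 uniform
   bins. Bin edges sit on integer multiples of `(intensity_max+1)/256`
   so every bin holds the same number of integer levels (16 for 12-bit
   data); unequal bins would imprint a sawtooth on integer-valued data
   and fabricate spurious local maxima. Only within-nucleus pixels
   enter the histogram — background was already eliminated, and
   including zeroed background would fabricate a spurious low mode.
2. The histogram is smoothed by an iterated 3-bin unweighted moving
   average (edge bins average their available neighbors) until exactly
   two local maxima survive, up to `max_smoothing_passes` (default
   1000). Plateaus of equal bins collapse to their midpoint bin. A
   maximum only counts as a mode if its smoothed height is at least
   `min_mode_fraction` (default 0.002) of the tallest peak: a handful
   of extreme-value noise pixels form an isolated tail bin that is
   formally a local maximum but is not granulation; 0.2% sits well
   above such outlier bins (≲0.05% of the peak) and well below the
   smallest real granule mode we aim to detect (a few granules are
   already ≳0.5%). Iteration stops early once fewer than two raw
   maxima remain, since moving-average smoothing never creates modes.
3. On success, `j` and `k` are the bin-center intensities of the lower
   and upper mode of the smoothed histogram, and the cutoff is their
   midpoint `t = 0.5 (j + k)`. Being per-nucleus and per-channel, `t`
   absorbs slide-to-slide staining differences. Nuclei whose histogram
   never reaches bimodality show no granulation; they are excluded
   from granularity outputs with the reason logged.

## Granule extraction

Pixels strictly above `t` (`> t`, never `≥`) are granule candidates. A
median filter (default 3×3, mask-aware: pixels outside the nucleus mask
never enter a neighborhood's median, so boundary granules are not
diluted by zeroed background) replaces each within-mask intensity by
its neighborhood median, and the selection is re-derived at the same
`t` — this removes isolated bright noise pixels while leaving solid
granule interiors intact. Connected components (8-connectivity by
default; 4 available) of at least `min_size_px = 5` pixels (inclusive)
are the granules; the 5-pixel floor excludes detections below the
~250 nm optical resolution limit. Per-granule mean intensity is always
computed from the original, unfiltered intensities.

Per nucleus, the summary reports the granule count, the mean granule
area in pixels, and the **pixel-weighted** mean intensity: the mean
over all granule pixels pooled, so a pixel in a large granule weighs
the same as one in a small granule. The granule-weighted alternative
(mean of per-granule means) is emitted as a secondary column. With no
granules the means are absent (empty cells), never zero.

Merged foci appear as single enlarged granules; no watershed splitting
or sub-pixel fitting is attempted, preserving the diffraction-limited
reading of the data.

## Statistics

Test selection is a fixed assignment: nucleus size (approximately
normal) is compared with a two-sample t-test, all other metrics with
the Kruskal–Wallis rank test, used even for two groups, with tie
correction. The t-test is Welch's unequal-variance variant by default
(the pooled-variance form is a flag); an optional Shapiro–Wilk
normality gate exists but is off by default so the procedure stays
deterministic and reproducible. Significance tiers: n.s. (p ≥ 0.05),
\* (p < 0.05), ** (p < 0.01), *** (p < 0.001); the 0.05 boundary is
inclusive on the non-significant side, the others strict. Degenerate
inputs use an explicit convention: two identical zero-variance groups
(t-test) or a fully tied pooled sample (Kruskal–Wallis) carry no
evidence and report p = 1. Raw pairwise p-values are reported without
multiple-testing correction; Holm adjustment is opt-in. Boxplot
summaries use linear-interpolation quantiles, the sample SD (n − 1),
whiskers at mean ± 2 SD, and list values outside the whiskers as
outliers.

## Synthetic scenes

The generator emulates exactly the structure the procedure assumes:
elliptical nuclei (random semi-axes, orientation and position; pairwise
non-overlapping; never touching the border) on a low background, and
label channels that are a diffuse within-nucleus level plus hard-disk
granules of configurable count, radius and amplitude, with additive
per-pixel Gaussian noise, rounded and bounded to the 12-bit range.
Parameters whose means would need clamping are rejected up front.
Hard disks rather than Gaussian spots keep truth pixel sets exact and
the two-mode histogram assumption explicit; a Gaussian-spot mode exists
behind a flag for realism checks only. Granule centers keep a minimum
edge-to-edge separation (default 5 px) so planted counts are
unambiguous; packing is by rejection sampling with a bounded attempt
budget, and infeasible requests raise a generation error rather than
silently under-filling.

Default intensity structure: background 100, DNA level 3000, diffuse
label level 800, granule amplitude 1800 (granule level 2600, matching
the intensity scale typical of the cohesin/H3K9me3 granules this
pipeline is built for), noise SD 20 in the high-SNR preset and 60 in
the noisier `paperlike` preset. The spatial scale uses a pixel edge of
103.52 nm — four times the reference instrument's 25.88 nm pixel — so
that nuclei with realistic areas (the `paperlike` preset spans roughly
120–250 µm²) fit desk-scale 512×512 frames; the analysis itself is
scale-free, and the unit-conversion path is exercised separately at
the instrument calibration. Presets: `highsnr` (exact-recovery regime:
one 768×768 frame with a larger nucleus, semi-axes 100–130 px, that
comfortably hosts 60 well-separated granules; disk radii 4–5 px),
`paperlike` (two nuclei, granule counts drawn from 5–60, radii
2–4.5 px, noise SD 60), `unimodal` (amplitude 0 — the negative control
for bimodality detection).

What the generator does **not** emulate: the microscope point-spread
function, photobleaching, chromatin texture inside nuclei, or
correlated detector noise. Passing recovery tests therefore shows the
procedure is correct on data satisfying its own assumptions, not that
those assumptions hold for any particular instrument.

## Numerical and design choices

- Histograms, means and amounts are computed in float64 from integer
  inputs; amounts are exact integer sums.
- `j`/`k` are read from the smoothed histogram (the vector that is
  bimodal), not the raw one.
- The mask-aware median filter uses a plain `ndimage.median_filter`
  fast path for pixels whose window lies entirely inside the mask and
  an explicit NaN-median only on the boundary band, which keeps a
  768×768 nucleus analysis near 0.1 s without changing any value.
- Granule-count monotonicity: the count is non-increasing in
  `min_size_px` always, and non-increasing in `t` in the operating
  regime (cutoffs between and beyond the two modes, where thresholding
  only shrinks or removes solid granules). Across the *low* tail —
  sweeping `t` from below the diffuse mode upward — the count first
  rises from one giant component to N granules by construction, so the
  property is stated and tested over the inter-mode and upper range
  where the adaptive threshold actually operates.
- A 5-pixel minimum granule area at the 25.88 nm reference pixel is
  ~3350 nm², smaller than the area of a 250 nm-diameter spot; the
  5-pixel rule is implemented exactly as specified, and the floor is
  configurable for instruments where the discrepancy matters.
- All analysis steps are deterministic; the only randomness in the
  package is scene generation, driven by a single integer seed.
  Identical inputs and configuration give bit-identical output tables.

## Validation problem sizes

The validation suites run on desk-scale scenes chosen to exercise every
code path while keeping a full run in tens of seconds: 256×256
single-nucleus scenes (100 replicates) for threshold recovery, the
768×768 `highsnr` preset (20 replicates at each planted count of 5, 20
and 60) for granule recovery, 100 random 64×64 grids for the
flood-fill labeling cross-check, and 1000-replicate null simulations at
n = 30 per group for the type-I error of both tests.

## Known limitations

- No declumping: touching nuclei are excluded (border/QC rules) rather
  than split, so dense fields lose nuclei.
- One threshold per nucleus per channel; within-nucleus staining
  gradients can bias granule extent.
- The bimodality decision is binary; weak granulation near the
  prominence floor is classed as "no granulation" rather than
  estimated with uncertainty.
- Group comparisons assume independent nuclei; nuclei from the same
  frame share acquisition conditions and are not modeled
  hierarchically.
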