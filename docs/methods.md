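# Methods

## Problem and approach

Single-particle cryo-EM reconstructs a macromolecule's 3-D density from many
2-D projections picked out of micrographs. The picking step is hard because
the electron dose is limited: particles sit barely above shot noise, and many
interesting specimens (ribosomes, beta-galactosidase) have irregular
projected shapes that defeat template matching. `cryopick` implements a fully
automated, clustering-based picker. The idea is to cluster *intensities*
rather than match shapes, and to stabilize that clustering against noise by
first over-segmenting the micrograph into superpixels:

1. **Pre-processing** — downscale (optional), normalize, global histogram
   equalization, adaptive Wiener denoising, CLAHE, guided filtering, and
   (before base clustering only) a morphological open/close localization.
2. **Superpixel posterization** — SLIC partitions the image into ~N/256
   superpixels; each pixel is replaced by its superpixel's mean intensity,
   averaging noise down by ~16x while preserving particle-scale structure.
3. **Intensity clustering** — one of three interchangeable 1-D clusterers
   (interval-initialized IBC, k-means, fuzzy c-means) splits the posterized
   (super-clustering) or raw preprocessed (base) intensities into K clusters,
   with K derived from the intensity range divided into 0.15-wide intervals.
4. **Automatic cluster selection** — the cluster whose binary mask has the
   fewest 8-connected components is taken as the particle cluster: particles
   form a handful of compact blobs while background clusters shatter into
   many fragments. Ties break by smaller foreground area, then lower index.
5. **Cleaning and picking** — base-clustering masks are opened and
   size-filtered (super-clustering masks skip this stage); every connected
   component at least `min_area` pixels large becomes one particle with
   centroid, bounding box and area.

## SLIC distance and convergence

Centers are seeded on a regular grid of spacing `S = sqrt(N/k)`, nudged to
the lowest-gradient position in a 3x3 neighborhood (the seed wins ties, so a
flat image keeps its grid). Each center competes only for pixels within
`|dy| <= S` and `|dx| <= S` of itself, under

    D = sqrt(dc^2 + (ds / S)^2 * m^2)

with `dc` the absolute intensity difference, `ds` the Euclidean spatial
distance and `m` the compactness constant. Assignment ties go to the lowest
center id; pixels covered by no window join the spatially nearest center.
Centers move to the member mean of (intensity, x, y); iteration stops when
the summed spatial displacement E falls below `residual_tol` (default 1 px
total) or after `max_iters` (default 10).

Two numerical notes. First, mean updates minimize the *squared* assignment
cost; iteration history therefore records both `sum(D)` and `sum(D^2)`, and
only the squared sum is guaranteed (and tested) to be non-increasing — the
unsquared sum tracks it but can fluctuate by parts in 10^3. Second,
**compactness defaults to m = 1.5** on the [0, 1] intensity scale. This is
deliberately large: after equalization the per-pixel noise is comparable to
the particle/background separation, and with a small m (e.g. 0.1) the
intensity term dominates D, so a "superpixel" degenerates into scattered
same-intensity speckle across its window (measured: 5400 connected fragments
for 256 superpixels). Posterization then no longer averages noise, every
cluster mask shatters, and component-count selection becomes meaningless.
At m = 1.5 superpixels are spatially coherent (fragments ~= superpixels)
while still letting strong intensity edges bend their boundaries.

No connectivity enforcement is run after SLIC (a deliberate simplification;
downstream clustering uses intensities only). The picking stage compensates
by refusing to emit particles smaller than `min_area` — stray pixels of a
non-contiguous superpixel are never particles.

## Clusterers

All three clusterers operate on scalar intensities and are fully
deterministic — no random initialization anywhere, so a pipeline run is
bit-reproducible.

* **IBC**: `K = round((v_max - v_min) / interval_size)` (minimum 2,
  `interval_size` default 0.15); initial centers are the interval midpoints;
  Lloyd iterations (nearest center by |Δintensity|, ties to lower id; center
  := member mean; empty cluster keeps its center) run to exact fixed point.
* **k-means**: identical Lloyd machinery, K supplied (the pipeline takes it
  from the IBC initialization), centers initialized at the midpoints of K
  equal intervals. Because initialization is deterministic, a `seed`
  parameter would be dead weight and the API omits one. Lloyd is a local
  optimizer: tests assert fixed-point self-consistency and closeness to the
  exhaustive-partition optimum at tiny n, not exact global optimality.
* **FCM**: canonical fuzzy c-means with membership
  `u_nk = [ sum_i (d_nk / d_ni)^(2/(f-1)) ]^-1` (fuzzifier f default 2),
  center update by `u^f`-weighted mean, stop when the largest center move is
  <= `tol` (default 1e-5). A pixel coinciding exactly with a center gets an
  indicator membership. Hard assignment is argmax, ties to lower id.

Clustering depends on the intensity histogram only, so all three iterate on
weighted unique values; `base_cluster` additionally quantizes input to 256
levels (the native resolution of 8-bit PNG micrographs) by default, which
makes even FCM on a 1024^2 image sub-second without changing results beyond
the 1/255 quantum.

## Cluster selection

The particle cluster is chosen as the mask with the smallest positive count
of 8-connected components. This works when background clusters fragment into
many pieces — true at production scale (1024^2+ images, thousands of
superpixels), where every background cluster is a speckled level-set band.
**Known limitation:** on small images (~256^2) with few superpixels, a
background cluster can consist of a handful of large blobs and undercut the
particle cluster's count; the selection then fails. The foreground-area
tie-break mitigates exact ties only. Users working at small crops should
inspect the selected index (reported in the run manifest).

## Pre-processing defaults

`downscale_factor` 1 (2 is sensible for 4096^2 archive micrographs),
`wiener_window` 5, `clahe_tile` 64, `clahe_clip` 0.01, `guided_radius` 4,
`guided_eps` 1e-4, `morph_radius` 2 (disk). All steps clip to [0, 1], are
individually callable, and can be disabled; the chain applies them in a
fixed canonical order regardless of listing order. Morphological
localization is enabled automatically before base clustering and disabled
before super-clustering (posterized masks are already clean); set
`morph_auto=False` to control it manually.

On the SNR statistic (RMS / sample-std, in dB): the *denoising* steps raise
it sharply (~+9 dB on the synthetic fixtures), while the equalization steps
deliberately spend dynamic range on contrast, i.e. they raise the intensity
std and can lower the statistic slightly. The chain's purpose is
separability for clustering, not maximizing this one number; tests assert
the SNR gain on the denoising sub-chain.

The "sane" global intensity stretch clamps to mean ± 3·std (intersected with
the data range) and rescales to [0, 1]. It is contractive rather than
exactly idempotent — saturated tails shrink the std, pulling the bounds
slightly inward on re-application — converging to a fixed point within ~1%
after one pass.

## Mask cleaning and picking

Cleaning: binary opening (disk radius 1), component labeling (8-connected),
drop components with area < `min_area` (default: area of a disk of half the
expected particle radius, i.e. 177 px at the default radius 15) or >
`size_max`; an optional circularity band `4*pi*A/P^2` exists but is disabled
by default because the target particles are deliberately irregular.
Cleaning is anti-extensive and idempotent. When the pipeline downscales, the
default `min_area` is rescaled into the working frame.

Picking emits one particle per component with `area >= min_area` (enforced
for every method, including super-clustering runs that skip mask cleaning),
numbered in raster order. Tight boxes hug the component; fixed boxes center
a square on the centroid, clipped at borders. Components touching the border
are kept but flagged. Coordinates are reported in the input frame even when
the pipeline works on a downscaled copy.

## Evaluation

Image quality: `SNR = 20*log10(RMS / std)` (amplitude ratio, hence factor
20), `MSE = mean((a - b)^2)`, `PSNR = 10*log10(max_i^2 / MSE)` (infinite,
flagged, for identical images). Picking quality: detections are matched
one-to-one to ground-truth centers greedily by ascending distance under a
tolerance of one expected particle radius; then
`recall = TP/(TP+FN)`, `precision = TP/(TP+FP)`,
`accuracy = TP/(TP+FN+FP)`, `F1 = 2PR/(P+R)`; zero-denominator ratios report
0 and are flagged.

## Synthetic micrographs

The generator emulates the statistics that make picking hard while staying
bit-reproducible from a seed:

* **Background**: level 0.6, plus a smooth low-frequency illumination field
  (Gaussian-filtered noise, correlation ~1/8 of the image, amplitude 0.05)
  and a band-limited ice-thickness texture (correlation 1.5 particle radii,
  std 0.02). The texture matters: real micrographs carry vitreous-ice and
  support-film structure at intermediate scales, and it is precisely this
  structure that fragments background clusters and makes component-count
  selection work. A texture-free background would collapse each background
  cluster into one giant blob and make the selection problem degenerate in a
  way real data is not.
* **Particles**: star-convex blobs — radius modulated by 4 seeded random
  harmonics scaled by `shape_irregularity` (default 0.3) — drawn *darker*
  than background by `particle_contrast` (default 0.25), since protein is
  denser than vitreous ice; ~1 px soft edges; centers rejection-sampled at
  `min_separation_px` (default 4 radii) with explicit failure if placement
  is impossible.
* **Decoys**: small high-contrast blobs (0.35 particle radius, alternating
  darker/brighter by 0.3) to bait false positives.
* **Noise**: additive Gaussian, sigma 0.25, clipped to [0, 1]; on the 0.6
  background this lands the amplitude SNR near 8 dB, the order of magnitude
  of raw archival micrographs.

What the generator does **not** model: contrast transfer function, 3-D
projection, correlated detector noise, carbon edges, aggregates. Passing the
synthetic suites therefore demonstrates the pipeline's noise robustness and
the correctness of its machinery, not performance on real archive data.

Fixture suites (seeds fixed in `cryopick.synthetic`): `tiny` = 5 images of
256^2 with 12 particles of radius 10 (unit tests); `standard` = 20 images of
1024^2 with 40-80 particles of radius 14 (end-to-end evaluation). These
sizes keep a full six-method evaluation of the standard suite under three
minutes on one CPU while leaving dozens of particles per image for stable
pooled statistics.

## Degenerate inputs and tie-breaks

Flat images raise a degenerate-input error from clustering (there is nothing
to cluster); K larger than the number of distinct intensities likewise.
All argmin/argmax tie-breaks go to the lowest index; greedy matching breaks
distance ties by (detected index, truth index). These choices exist purely
to make every code path deterministic.

## Known limitations

* Component-count cluster selection can fail on small images (see above).
* Touching particles merge into one component (no watershed splitting).
* The 8-bit quantization in `base_cluster` is the right resolution for
  PNG-derived micrographs but discards sub-quantum float detail; pass
  `quantize_levels=None` for raw-float clustering.
* The RMS/std "SNR" on a single image is a contrast statistic, not a true
  signal/noise decomposition; use it comparatively, not absolutely.
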