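# cryopick

Fully automated single-particle picking for cryo-EM micrographs.

Particle picking — locating individual macromolecule projections in electron
micrographs — is an early bottleneck of single-particle cryo-EM structure
determination. Template- and classifier-based pickers need manually curated
references, and both struggle when particles have irregular shapes and the
signal-to-noise ratio is extremely low. `cryopick` needs no references and no
human in the loop: it clusters *intensities*, stabilized by superpixel
posterization, and selects the particle cluster automatically.

The pipeline:

1. **Pre-process**: anti-aliased downscaling, normalization, global histogram
   equalization, adaptive Wiener denoising, CLAHE, guided filtering.
2. **Posterize**: SLIC superpixels (distance
   `D = sqrt(dc² + (ds/S)²·m²)` over intensity difference `dc` and spatial
   distance `ds`, grid interval `S = sqrt(N/k)`) replace each pixel by its
   superpixel's mean intensity, averaging noise away below the particle scale.
3. **Cluster**: one of three interchangeable 1-D intensity clusterers —
   interval-initialized intensity-based clustering (IBC, with
   `K = round(range / 0.15)` clusters), deterministic k-means, or fuzzy
   c-means — run on the posterized image (`sp-*` methods) or on raw
   preprocessed pixels (base methods).
4. **Select**: the cluster whose binary mask has the fewest 8-connected
   components is the particle cluster (particles form few compact blobs;
   background shatters into many fragments).
5. **Pick**: clean the mask (base methods), then emit one particle per
   connected component with centroid, bounding box and area; score picks as
   `recall = TP/(TP+FN)`, `precision = TP/(TP+FP)`,
   `accuracy = TP/(TP+FN+FP)`, `F1 = 2PR/(P+R)` against ground truth under a
   one-particle-radius matching tolerance.

Every stage is deterministic — two runs with the same config produce
byte-identical coordinates. A seeded synthetic-micrograph generator (star-
convex dark particles, ice-like texture, decoy blobs, ~8 dB amplitude SNR)
makes the whole pipeline testable without downloading archive data. See
`docs/methods.md` for the model details and design rationale.

## Worked example

Generate synthetic micrographs with known ground truth, pick particles with
super-clustered IBC, and score the picks:

```sh
cryopick simulate --out-dir demo --scale tiny
cryopick pick --input demo/micrograph_000.png --method sp-ibc \
              --out-coords demo/picks.csv
cryopick evaluate --detected demo/picks.csv \
                  --truth demo/micrograph_000_truth.csv --tolerance 10
```

which prints

```
picked 11 particles -> demo/picks.csv (manifest: demo/picks.manifest.json)
{
  "tp": 11,
  "fn": 1,
  "fp": 0,
  "recall": 0.9166666666666666,
  "precision": 1.0,
  "accuracy": 0.9166666666666666,
  "f1": 0.9565217391304348,
  "match_tolerance": 10.0,
  "undefined": []
}
```

Of the 12 planted particles, 11 were picked within 10 px of their true
centers (one missed, none spurious): recall 0.917 at precision 1.0. The
`.manifest.json` written next to the coordinates records the full config
snapshot, input checksum, per-stage timings and counts, so the run is
reproducible from the manifest alone. `--method` accepts `kmeans`, `fcm`,
`ibc` and their superpixel variants `sp-kmeans`, `sp-fcm`, `sp-ibc`;
`--out-format box` writes EMAN-style box files; `--overlay out.png` burns the
picked boxes into the image for visual inspection. `cryopick quality
--before a.png --after b.png` reports PSNR/SNR/MSE for pre-processing checks.

The same pipeline is available as a library:

```python
import cryopick as cp

m, truth, _ = cp.generate_micrograph(cp.SyntheticConfig(seed=1))
picks = cp.pick(m, cp.PipelineConfig(cluster=cp.ClusterConfig(method="sp_ibc")))
print(cp.evaluate_picking(picks, truth, tolerance=14.0))
```

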