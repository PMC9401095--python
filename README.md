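# ratcapsnet

A dual-pipeline convolutional classifier for wireless-capsule-endoscopy
(WCE) abnormality detection, implemented from scratch on NumPy, together
with the class-imbalance data protocol it is trained under, a synthetic
WCE-image generator, evaluation metrics, and a CLI.

The network has three parts:

* **Compression pipeline** — five encoder stages, each two 3×3 conv+LeakyReLU
  blocks, a *volumetric attention mechanism* (VAM) and a 2×2 max-pool.  The
  VAM condenses the map with a stride-2 convolution to half the channels,
  re-weights it with a depthwise convolution, sums the two, and upsamples
  through a transposed convolution into a single-channel sigmoid mask `m`;
  the block output is `x · (1 + m)`.  Channels follow 32, 64, 128, 256, 512.
* **Regional correlative pipeline** — for each pre-attention stage tap, a
  *pyramid feature extractor* (PFE): four parallel convolutions with kernels
  1/3/5/7 at ϱ channels, pairwise concatenation, fusion convolutions with
  kernels 8/9/10, and a final kernel-11 fusion down to 2ϱ channels.
* **Decision pipeline** — global-average-pooled vectors from the last stage
  and every PFE output, concatenated through dense layers (512, 128) into a
  softmax (or single sigmoid unit for binary tasks).

The data protocol splits by the smallest class (its 20% share fixes the
validation count drawn from every class) and upsamples each training pool to
a common target (default 3000) by attaching random augmentation recipes
(rotation, flips, shearing, warping, erasing, additive noise, blur).

Everything runs on plain NumPy/SciPy — no deep-learning framework is
required; convolutions, the depthwise and transposed variants, pooling and
Adam are implemented in `ratcapsnet.nn` with explicit backward passes.

## CLI

```sh
# synthetic class-imbalanced dataset (PNG directories + manifest)
ratcapsnet synth --classes normal,blood --counts 200,40 --hw 64,64 --seed 1 --out data/

# train (config optional; YAML mirroring RunConfig)
ratcapsnet -v train --data data/ --config run.yaml --out runs/demo

# evaluate a checkpoint on the stored split
ratcapsnet eval --checkpoint runs/demo --data data/ --partition val

# single-image probabilities
ratcapsnet predict --checkpoint runs/demo --image data/blood/blood_00000.png

# per-stage attention masks, masked inputs, contrast-stretched renderings,
# and three pyramid-map channels
ratcapsnet visualize --checkpoint runs/demo --image data/blood/blood_00000.png --out viz/
```

A checkpoint directory is self-describing: `model.npz` (weights),
`config.yaml` (full run configuration), `classes.json`,
`split_manifest.csv` (identifier, class, partition, augmentation recipe) and
`history.csv`.

## Notes

* Default input is 256×256 (divisible by 2^5); native 336×336 sources are
  resized bilinearly at load time.
* ϱ (PFE width) defaults to 16; the fusion kernels 8/9/10 include even
  sizes — same padding places the extra pixel right/bottom.  Both are
  configurable in `NetworkConfig`.
* All randomness (weights, splits, augmentation recipes, batch order) flows
  from a single seed per run.
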