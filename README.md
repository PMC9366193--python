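# boundaryseg

Boundary-structure-preserving segmentation of ultrasound images.

Ultrasound boundaries are ambiguous — speckle, attenuation and low
contrast blur the edge of structures such as the prostate — and manual
delineations occupy several pixels, scattering "disturbing points"
around the true contour. `boundaryseg` addresses both problems for
people building segmentation models on such data:

1. **Key-point contour extraction.** A delineated mask is reduced to an
   ordered, near-equidistant set of boundary key points: Otsu
   binarization, morphological clean-up (opening with a 2×2 all-ones
   template, closing with a 5×5 disk), one-pixel contour tracing, then a
   coarse-to-fine refinement that keeps two points per image column,
   seeds four salient extremes (topmost / rightmost / bottommost /
   leftmost) and repeatedly inserts, between each adjacent pair
   (x₁, y₁), (x₂, y₂), the contour point nearest the chord's
   perpendicular bisector, whose normal is the unit chord vector

   (Dx, Dy) = ((x₁−x₂)/‖p₁−p₂‖, (y₁−y₂)/‖p₁−p₂‖).

2. **Deep boundary supervision.** The key points (stamped as small
   disks) or the full boundary mask become the [0,1] target map M of a
   U-Net whose convolution blocks carry auxiliary prediction heads.
   With per-stage predicted maps M̂ᵢ and segmentation S against ground
   truth G, training minimises

   L_map = Σᵢ BCE(Mᵢ, M̂ᵢ),  L_seg = BCE(G, S),  L_total = L_map + L_seg,

   with heads attachable to the encoder blocks, the decoder blocks or
   both (depth d gives d, d or 2d supervision stages).

3. **Phantoms and metrics.** A synthetic generator produces smooth
   star-convex blobs with multiplicative gamma speckle, blur and low
   fg/bg contrast, so every stage — including training — runs
   reproducibly on CPU with no data download. Evaluation covers pixel
   accuracy, two-class mean IOU, Dice, Jaccard and region IOU of
   key-point polygons.

The network is implemented in NumPy (im2col convolutions, hand-written
backpropagation and Adam); it is small enough for desk-scale CPU
experiments while keeping the full-scale schedule (lr 1e-4, 1200
epochs, batch 8, 10-fold cross-validation) reachable through
configuration.

## Worked example

```bash
python examples/03_train_smoke.py
```

prints (about a minute on one CPU core):

```
supervision stages: 8 (placement=both)
total loss epoch 1: 6.182 (map 5.490 + seg 0.692)
total loss epoch 30: 1.788 (map 1.685 + seg 0.103)
held-out Dice: [0.886, 0.832, 0.845, 0.911, 0.735] (mean 0.842)
```

Epoch 1 starts at the theoretical chance level (every output probability
is exactly 0.5, so each of the 8 map stages and the segmentation term
contribute ln 2 ≈ 0.693); after 30 epochs of Adam at 1e-4 the model
segments unseen speckled phantoms at Dice ≈ 0.84. The other examples
(`examples/01…05`) each demonstrate one capability — key-point
extraction, supervision maps, the comparison against random contour
sampling, and the metric suite — and print what their numbers mean.

A thin CLI wraps the same functions:

```bash
boundaryseg simulate --n 100 --seed 7 --out data/
boundaryseg extract-keypoints --in data/mask_000.png --n 16 --out kp.csv
boundaryseg train --out runs/smoke --n 20 --seed 0
boundaryseg evaluate --data data/ --checkpoint runs/smoke/checkpoint.npz --out report/
boundaryseg compare-sampling --data data/ --seed 7 --out cmp.csv
```

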