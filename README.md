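# gbseg

Semantic segmentation of gallbladder B-mode ultrasound with a SegNet-style
encoder–decoder augmented by pyramid pooling, together with the evaluation
metrics and the clinical contingency statistics that accompany such a study.

Gallbladder carcinoma frequently co-occurs with gallstones and is hard to
delineate on conventional ultrasound. Two questions drive this package:

1. **Can an encoder–decoder network segment the lesion from B-mode images,
   and does multi-scale (pyramid pooling) context help?**  The network is a
   symmetric encoder–decoder in which each encoder stage is
   conv → batch-norm → ReLU followed by a 2×2 max pool that *stores the
   argmax index of every pooling window*; each decoder stage scatters its
   input back to those stored positions (max-unpooling) before convolving,
   so boundary localization survives the bottleneck without memorizing
   full-resolution feature maps.  Optionally, a pyramid pooling module at
   the bottleneck average-pools the deepest feature map to 1×1, 2×2, 3×3 and
   6×6 grids, projects each with a learned 1×1 convolution, bilinearly
   upsamples, concatenates all branches with the original map and fuses them
   with a final convolution.
2. **How do diagnostic modalities and tumor biology relate?**  The
   `diagstats` module recomputes, from raw case counts of a 300-patient
   gallbladder cohort, the diagnostic coincidence rates of conventional vs
   contrast-enhanced ultrasound against pathology, P16 (MTS-1)
   immunohistochemistry positivity rates by lesion type / stage /
   differentiation, the four-level IHC grading rubric, and Pearson χ² tests.

Segmentation quality is scored pixel-wise with the count-based metrics

    IoU = TP / (TP + FP + FN),  Pre = TP / (TP + FP),  Recall = TP / (TP + FN)

micro-averaged over a dataset (counts pooled first, scores computed once).

No clinical images are distributed; the `phantom` module generates seeded
synthetic B-mode gallbladder phantoms — hypoechoic lumen in an echogenic
wall, lesion blobs of intermediate echogenicity, optional stone arc with
acoustic shadow, multiplicative gamma speckle — with pixel-exact ground
truth, so every pipeline stage is runnable and testable end to end. The
entire network stack (convolution, batch-norm, pooling with indices,
unpooling, pyramid module, Adam, cross-entropy) is implemented in NumPy
with explicit backpropagation; see `docs/methods.md`.

## Worked example

```sh
gbseg phantom --n 120 --seed 1 --out runs/data          # images+masks+manifest
gbseg compare --manifest runs/data/manifest.csv --out runs/cmp --seeds 1
gbseg diagstats --out runs/report
```

A comparison run of this size (120 phantoms of 64×64 pixels, encoder widths
16/32, 10 epochs, one seed) prints validation metrics per arm, e.g.:

```
 variant  n_seeds  iou_mean  ...  precision_mean  recall_mean
   plain        1    0.8632  ...          0.9202       0.9331
 pyramid        1    0.9233  ...          0.9519       0.9685
   delta        1    0.0601  ...          0.0317       0.0354
```

Read: on held-out phantoms the plain encoder–decoder reaches lesion IoU
0.86; adding the pyramid pooling module lifts IoU by ~6 points, precision by
~3 and recall by ~3.5 — the multi-scale context mainly recovers lesion
pixels the plain variant misses. (Stochastic: exact numbers vary with the
seed.)  `gbseg diagstats` prints the cohort's χ² tests, e.g. adenocarcinoma
vs acute cholecystitis P16 positivity: statistic 7.575, df 1, p = 0.0059 —
P16 loss is significantly more common in carcinoma.

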