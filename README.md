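# wbcseg

Segmentation of single white blood cells (leukocytes) in stained blood-smear
microscopy images. WBC morphology examination is a routine step in diagnosing
blood disorders, and its first automated stage is separating the cell from the
background — difficult precisely where it matters most: lymphocyte and
monocyte cytoplasm is close in color to the background, illumination is
uneven, and cell boundaries are irregular and blurred.

`wbcseg` implements an encoder–decoder segmentation network for this task,
together with its losses, evaluation metrics, morphological postprocessing,
and a synthetic single-cell image generator so the entire pipeline can be
trained and evaluated end-to-end without any external data.

## The model

The network is a U-Net-style encoder–decoder:

* **Encoder** — a ResNet50-style convolutional trunk: a 7×7 stride-2
  convolution with 3×3 max pooling, then four stages of bottleneck residual
  blocks (3, 4, 6, 3 blocks; each block is a 1×1 → 3×3 → 1×1 convolution
  stack with BN/ReLU and an identity or projection shortcut), producing
  256/512/1024/2048-channel features at 1/4 … 1/32 resolution.
* **Decoder** — four upsampling units. Each unit bilinearly upsamples 2×,
  concatenates the matching encoder skip, mixes channels with a 1×1
  convolution, then applies a 3×3 convolution and a 3×3 *atrous* convolution
  (dilation d = 2) with BN/ReLU, and finally a squeeze-and-excitation (SE)
  channel-attention block with reduction ratio R = 6. A last bilinear 2×
  upsampling, 1×1 convolution and sigmoid yield a full-resolution
  foreground-probability map. Transposed convolutions are avoided
  (checkerboard artifacts); all upsampling is bilinear.

For a 3×3 kernel with dilation rate d, the package reports the receptive
field as v = (k+1)(d−1) + k (so 7 at d = 2); the conventional effective
kernel size k + (k−1)(d−1) is exposed separately as
`effective_kernel_size`.

Training minimizes pixelwise binary cross-entropy, or the focal loss
(α = 0.25, γ = 2) for datasets dominated by hard low-contrast cells, with
Adam (lr 1e-4, batch 8, 200 epochs at full scale). Predictions are
thresholded at 0.5 and cleaned up morphologically (small non-cell fragments
removed, small holes filled). Evaluation reports Dice, mIOU, PPV,
sensitivity and Hausdorff distance per image and as dataset means.

The tensor layer under the network (`wbcseg.nn`) is a compact reverse-mode
automatic-differentiation core over NumPy, implementing exactly the
operators this architecture needs (convolution with stride/dilation, batch
norm, max pooling, bilinear upsampling, SE primitives, Adam).

## Worked example

A desk-scale experiment (width-1/8 network at 64×64, 200 synthetic images
split 8:1:1, 20 epochs, BCE, seed 1) runs in about a minute on one CPU core:

```python
import wbcseg as w

net_cfg, tr_cfg, scene, n_img = w.desk_profile(seed=1)
pairs = w.generate_dataset(scene, n_img)
train, val, test = w.split_dataset(pairs, (8, 1, 1), seed=1)
model = w.assemble_network(net_cfg, seed=1)
model, history = w.train(model, train, val, tr_cfg)
report = w.evaluate(model, test)
print(f"dice={report.dice:.4f} miou={report.miou:.4f} "
      f"ppv={report.ppv:.4f} se={report.sensitivity:.4f} hd={report.hd:.2f}")
```

which prints

```
dice=0.9747 miou=0.9511 ppv=0.9791 se=0.9714 hd=0.97
```

i.e. the trained model recovers 97.5% Dice overlap with the ground-truth
cell masks on the held-out synthetic test split, with sub-pixel mean contour
error (HD in pixels). The same protocol on lymphocyte-like hard scenes
(cytoplasm color distance 0.08 from background) trained with the focal loss
reaches `dice=0.8975` — the low-contrast task stays within a tenth of a
Dice point of the easy case.

The same workflow is available from the shell:

```bash
wbcseg synth --out data/demo --n-sources 50 --side 64 --seed 1
wbcseg train --data data/demo --out runs/demo --seed 1
wbcseg eval --checkpoint runs/demo/best.npz --data data/demo --out runs/demo/report
wbcseg rf 3 2    # receptive field v = 7 (conventional effective kernel 5)
```

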