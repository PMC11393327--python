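# virtpol

Label-free virtual Congo-red staining and birefringence imaging of amyloid
deposits. A single conditional adversarial image-translation network maps
4-channel autofluorescence tissue stacks (DAPI / FITC / TxRed / Cy5) to three
output modalities — brightfield Congo red, cross-polarized birefringence, and
angle-shifted birefringence — selected by a constant *digital staining
matrix* (DSM) channel with values 1, −1 and 2. The package also provides the
paired-image registration pipeline used to build pixel-aligned training data
and a full quantitative evaluation suite.

Because the corresponding clinical imaging data is IRB-restricted, the
package ships a seeded phantom generator that emulates the statistical
structure of the real data (pink-salmon congophilic regions and dark
red-purple nuclei in brightfield; apple-green deposits on a near-black
background under crossed polarizers), so every component is testable and
demonstrable offline.

The neural networks run on a small, self-contained NumPy autodiff backend
(`virtpol.nn`) — no GPU framework is required. Desk-scale instantiations
(base width 8) train in minutes on one CPU; the full-width configuration
matches the published architecture.

## Modules

| module | contents |
| --- | --- |
| `virtpol.phantoms` | seeded paired phantom generation, synthetic deformations, Gaussian noise |
| `virtpol.dataprep` | feature-based global projective registration, tiling, pyramid elastic registration, displacement fields, warping |
| `virtpol.networks` | DSM-conditioned attention U-Net generator, residual discriminator, displacement-field registration module, checkpoints |
| `virtpol.losses` | smooth-L1, BCE, total variation, field smoothness, and the composite generator / discriminator / registration objectives |
| `virtpol.training` | adversarial loop with 4:1:1 update schedule, modality mixing, random crops, fine-tuning for noise resilience |
| `virtpol.inference` | deterministic tile inference with pad/crop contract, feathered whole-slide stitching |
| `virtpol.evaluation` | MAE, PSNR, 6-scale MS-SSIM, FID (pluggable extractor), apple-green segmentation, D-IoU, YCbCr histograms, nuclei quantification, angle-shift emulation |

## CLI

```bash
# generate paired phantom data
virtpol simulate --out data/ -n 8 --seed 1

# train a small model (YAML configs mirror TrainConfig / NetworkConfig)
virtpol train --data data/ --config train.yaml --net-config net.yaml --out runs/demo

# virtually stain a stack in all three modalities
virtpol infer --checkpoint runs/demo/final --stack data/sample_0000_stack.tiff \
    --modality brightfield,crosspol,angleshift --out virtual/

# register a stained WSI against an autofluorescence stack into tile pairs
virtpol register --fixed stack.tiff --moving stained.tiff --out pairs/

# paired quantitative evaluation
virtpol evaluate --pairs eval_pairs/ --modality crosspol --out report.csv
```

## Conventions

- images are float32 in [0, 1]; stacks are `(C, H, W)`, RGB images
  `(H, W, 3)`; 8/16-bit quantisation happens only at file I/O.
- displacement fields store `(dx, dy)` pixel offsets, 0-based row/col
  coordinates, and map moving → fixed: `warp(I, f)(r, c) = I(r + dy, c + dx)`
  with border replication.
- training step = one optimizer update of one module; the 4:1:1 schedule
  cycles generator ×4, discriminator ×1, registration ×1.
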