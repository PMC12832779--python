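# gliotask

Multi-task glioma IDH genotyping and grading from multimodal 3D MRI,
re-implemented as a size-configurable, CPU-only Python package and exercised
end to end on synthetic glioma phantoms.

The model combines:

- **MFEB** — a T2-FLAIR mismatch feature extraction block: average/max pooled
  overviews pass through shared-weight multi-scale dilated blocks (kernels
  7→5→3, dilation 3); a transposed convolution and sigmoid yield per-voxel
  weight maps, and the mismatch map is `w(T2)·T2 − w(FLAIR)·FLAIR`. A bypass
  flag reduces it to plain subtraction (the "without MFEB" ablation).
- **Customized 3D transformer encoder** — patch embedding expanded fivefold to
  accept 4 MRI modalities + the mismatch map; at reference scale a 128³ input
  becomes an (8,8,8)×384 token grid. Each transformer block carries a
  **MVAdapter** (bilinear gating of image tokens by pooled image features and
  the 101 radiomic+clinical features, both reduced to 48-wide bottlenecks) and
  a **DGCB** (multi-scale dilated grouped convolutions projected to QKV width)
  whose output is added to the block's query/key/value tensor. The backbone is
  frozen by default; only patch embedding, adapters and heads train.
- **Losses** — per-task weighted cross-entropy
  `−α(1−y_t)^γ log y_t + β·H(y_t)` with α the training-split class ratio and
  γ=2, combined by an uncertainty-weighted joint loss
  `Σ L_i/(2γ_i²) + Σ log γ_i` with trainable γ_i (initialized at 1).
- **Feature selection** — standardization plus 5-fold cross-validated Lasso
  with union pooling and a p ≤ 0.05 filter from an unpenalized refit.
- **Pipeline** — augmentation, Ranger/RAdam/Adam optimization with cosine
  decay, AUC/ACC/F1 with percentile-bootstrap 95% CIs, and Grad-CAM
  explanation.

Because no deep-learning framework is assumed, the package ships a compact
numpy reverse-mode autograd stack (`gliotask.nn`) with dilated/grouped 3D
convolutions, attention plumbing and optimizers, all gradient-checked.

Real cohorts are not required: `gliotask.phantom` generates deterministic
multimodal phantoms with a 3-compartment tumor mask and two planted signals —
an IDH-linked T2-FLAIR mismatch and a grade-linked necrotic-core inflation —
so every stage is testable offline.

## CLI

```bash
gliotask simulate --n 40 --grid 32 --seed 7 --mismatch-effect 2 --necrosis-effect 2 --out runs/cohort
gliotask select-features --features runs/cohort/features.csv --labels labels.csv --out runs/selection.json
gliotask train --cohort runs/cohort --config configs/scaled.yaml --out runs/exp1
gliotask eval  --cohort runs/cohort --checkpoint runs/exp1/checkpoint.npz --out runs/exp1/report.json
gliotask explain --cohort runs/cohort --checkpoint runs/exp1/checkpoint.npz --task idh --out runs/exp1/cams
```

`configs/reference.yaml` mirrors the published training settings (128³
patches, batch 4, lr 2e-5, Ranger); `configs/scaled.yaml` is the desk-scale
configuration (32³, embed 48, 2 blocks) that trains on one CPU in minutes.

Ablation switches in the config reproduce the comparison axes as code paths:
`bypass_mfeb: true`, `use_adapters: false`, `tasks: idh|grade`.

## Layout

```
src/gliotask/
  nn/              numpy autograd, layers, optimizers
  phantom.py       synthetic cohorts, ROI-centered patch extraction, NIfTI/CSV I/O
  mfeb.py          mismatch feature extraction block
  encoder.py       patch-embed expansion, MVAdapter, DGCB, QKV injection, encoder
  losses.py        task heads, weighted CE, uncertainty-weighted joint loss
  feature_select.py  standardization + Lasso selection + task union
  pipeline.py      augmentation, training, metrics + bootstrap CIs, Grad-CAM
  cli.py           simulate / select-features / train / eval / explain
```
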