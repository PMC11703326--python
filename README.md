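# contrastnav

Self-navigated retrospective rigid-motion correction for transient-state
quantitative MRI (MR-Fingerprinting-like acquisitions), built around a
**contrast-optimized temporal basis**.

## The problem

Quantitative MRI sequences that drive the magnetization through a transient
state acquire data for many minutes, so subject motion is the rule rather
than the exception. Because every few seconds of a golden-angle radial
acquisition cover k-space densely at low resolution, each repetition of the
flip-angle pattern (one ~4 s "block") can be reconstructed into a
low-resolution snapshot in a low-rank temporal subspace and used as its own
motion navigator: register the per-block images, score the motion, discard
blocks around large jumps, counter-rotate the k-space trajectory and cancel
the translation phase, and reconstruct.

The catch is the subspace. The truncated SVD basis maximizes captured
signal *intensity*, so its first coefficient image tends to be bright in
every tissue — and an image without tissue contrast is a poor registration
target. This package rotates the SVD subspace to maximize the generalized
Rayleigh quotient between two tissue classes (brain parenchyma b over
CSF f):

```
C_b = mean_k c_b c_b^H,   C_f = mean_k c_f c_f^H,   c = U_SVD^H s
w_1 = argmax_w (w^H C_b w) / (w^H C_f w)     ⇔     C_b w = λ C_f w
U_opt(i) = U_SVD w_i,  followed by Gram–Schmidt keeping column 1
```

The rotated basis spans the same subspace (zero extra reconstruction cost)
but concentrates parenchyma/CSF contrast in the first coefficient, which is
the image the rigid registration is driven by.

## What's in the package

| module | role |
|---|---|
| `fingerprints` | single-pool Bloch fingerprint simulation, dictionaries |
| `basis` | truncated SVD, generalized eigendecomposition, contrast-optimized rotation |
| `trajectory` | 2D golden-angle and 3D koosh-ball radial plans with block structure |
| `recon` | exact radial non-uniform DFT, temporal-TV ADMM navigators, CG final recon, dictionary matching |
| `registration` | NCC rigid registrar (pluggable), per-pattern series registration |
| `motion` | motion scores, block rejection, pose algebra, k-space correction |
| `motionsim` | digital phantoms, motion traces, k-space corruption, RMSE score, TV-weight calibration, end-to-end study |
| `evaluate` | ROI standard-deviation vs. motion-score regression, paired slope tests |
| `io`, `cli` | HDF5 / NIfTI / CSV containers and the `contrastnav` command line |

## Worked example

```python
import numpy as np
from contrastnav import (build_dictionary, default_schedules, default_tissue_grid,
                         compute_svd_basis, build_contrast_basis, project)

sched = default_schedules(n_patterns=6, n_pulses=1141)[0]
d = build_dictionary(default_tissue_grid(), sched)

svd = compute_svd_basis(d, rank=3)
opt = build_contrast_basis(d, rank=3)
print("generalized eigenvalues:", np.round(opt.eigenvalues, 3))

c_par = np.abs(project(d.subset("parenchyma"), opt)).mean(axis=1)
c_csf = np.abs(project(d.subset("csf"), opt)).mean(axis=1)
print("parenchyma coefficients:", np.round(c_par, 3))
print("CSF coefficients:       ", np.round(c_csf, 3))
```

prints (default seeds):

```
generalized eigenvalues: [7.1473313e+05 1.5150000e+00 0.0000000e+00]
parenchyma coefficients: [2.169 1.887 1.576]
CSF coefficients:        [2.0000e-03 4.0600e-01 1.2888e+01]
```

The first optimized coefficient retains parenchyma signal (mean magnitude
2.17) while the mean CSF projection is 0.002 — that ~10⁶ first eigenvalue
is the contrast ratio the rotation buys on this dictionary (in the
navigation pipeline a small ridge on C_f tempers that extreme suppression;
see `docs/methods.md`). The last coefficient has the opposite behaviour:
CSF-bright (12.9), parenchyma-poor.

An end-to-end simulated motion-correction experiment (corrupt a phantom
acquisition, navigate, register, score, reject, correct, reconstruct):

```bash
contrastnav study --seed 1 --out report.json
```

which logs, among other quantities, the RMSE score of the motion estimates
for the SVD and the contrast-optimized basis, the temporal-resolution lower
bound (from the block-averaged ground truth), and the parameter-map NRMSE
with and without correction.

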