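# diffatlas

Purely geometric, deep-diffeomorphic construction of **conditional brain
templates**: template images tailored to a covariate value (here, age),
all linked to one group template by smooth, invertible deformations.

Conventional conditional-template pipelines build one template per covariate
bin by repeated nonlinear registration, which needs large, evenly spread
cohorts. `diffatlas` instead learns two coupled deformation models:

- **Stage 1** — a generator mapping the (normalized) covariate α through
  fully connected layers to a latent code z<sub>α</sub>, decoded by
  transposed convolutions into a stationary velocity field v<sub>α</sub>.
  Its unit-time flow φ<sub>α</sub> (scaling and squaring) deforms the group
  template *T* into the conditional template
  T<sub>α</sub> = T ∘ φ<sub>α</sub>.
- **Stage 2** — a U-Net that registers T<sub>α</sub> onto each participant
  scan X<sub>p</sub> via a second velocity field v<sub>p|α</sub>, predicting
  X̂<sub>p</sub> = T<sub>α</sub> ∘ φ<sub>p|α</sub>.

Because both stages act only by diffeomorphisms, every conditional template
is topology-consistent with the group template and with individual anatomy
(Jacobian determinants |J<sub>φ</sub>| > 0 everywhere).

**Local mean-deformation tracking.** A conditional template should sit at
the *centre* of the Stage-2 deformations of scans with that covariate value.
The covariate axis is soft-binned (triangular weights ζ summing to 1 over
the two nearest bins) and each bin tracks an EMA of Stage-2 velocities,

    v̄_k ← (1 − λ ζ_k(α)) v̄_k + λ ζ_k(α) v_{p|α},   λ = 0.1.

The combined field v̂<sub>α</sub> = v<sub>α</sub> + ζ<sub>k</sub>v̄<sub>k</sub> +
ζ<sub>k+1</sub>v̄<sub>k+1</sub> builds a *mean-adjusted* template
T̂<sub>α</sub>, and a penalty on the difference between T<sub>α</sub> and
T̂<sub>α</sub> pulls Stage 1 toward absorbing any systematic, age-linked
deformation that Stage 2 is carrying.

**Training objective** (weights γ₁…γ₆ = 1, 0.01, 0.01, 0.01, 0.01, 1):

    L = γ₁·MSE(X̂, X) + γ₂·bend(φ_α) + γ₃·bend(φ_{p|α})
      + γ₄·|u_α|² + γ₅·|u_{p|α}|² + γ₆·MSE(T_α, T̂_α)

with `bend` the mean squared Laplacian (bending energy, zero for affine
maps) and |u|² the mean squared displacement magnitude. Optimization is
AdamW (lr 1e-4 in 3-D defaults, β = 0.9/0.999, weight decay 1e-2).

Because training needs only images plus a covariate table, the package ships
a synthetic-phantom generator producing 2-D T1-like slices whose anatomy
changes smoothly with age (ventricles grow 50% across 50–90 y, hippocampus
−15%, cortical grey matter −10%, white matter mildly), with optional
noise (relative SNR target) and random-gamma contrast corruption. The whole
method is testable end to end at desk scale on these phantoms. There is no
deep-learning framework dependency: a compact numpy reverse-mode autodiff
core (`diffatlas.autodiff`) powers the networks, spatial transformer and
optimizer.

## Worked example

```bash
diffatlas synth --n 200 --ages 50:90 --seed 7 --out data/
diffatlas train --manifest data/manifest.csv --template data/group_template.nii.gz \
    --epochs 40 --seed 1 --out runs/full
diffatlas template --checkpoint runs/full/checkpoint.npz --ages 50:90:5 --out templates/
diffatlas evaluate --checkpoint runs/full/checkpoint.npz --manifest data/manifest.csv \
    --ages 50:90:5 --out report/
```

The same experiment through the library:

```python
from diffatlas.experiment import run_experiment, evaluate_experiment
model, history, data = run_experiment(seed=1)   # 200 phantoms, 40 epochs
res = evaluate_experiment(model, data)
print(round(res["stage1_jac"].min, 2), res["stage1_jac"].nonpos_count)
print(round(res["trends"]["ventricles"]["spearman"], 2))
```

prints (seed 1)

```
0.7 0
0.99
```

i.e. the pooled Stage-1 Jacobian determinants stay strictly positive (no
topology violations across ages 50–90) and the ventricle-volume curve read
off the conditional templates tracks the ground-truth per-scan curve with
Spearman correlation above 0.9. `report/` contains Jacobian summaries,
adjacent-template SSIM/RMSD before and after an internal small-deformation
registration, and normalized volume curves per structure.

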