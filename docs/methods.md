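# Methods

## Model

A group template image `T` is deformed into conditional templates and onward
into participant scans by stationary velocity fields (SVFs). An SVF `v` is a
time-constant vector field whose unit-time flow solves
`∂φ(x,t)/∂t = v(φ(x,t))`, `φ(x,0) = x`. The flow is computed by scaling and
squaring: `u₀ = v / 2^s` followed by `s` self-compositions of the
displacement field (default `s = 7`). Flows of smooth SVFs are
diffeomorphisms — smooth, invertible, with smooth inverse — so warped
templates preserve the topology of `T`.

- Stage 1 (generator): covariate α (age, linearly normalized to [−1, 1]
  over the training range; sex, when present, encoded ±1) → fully connected
  layers → mean and log-variance of a latent code `z_α` → transposed-conv
  decoder → `v_α`. During training `z_α` is sampled by reparameterization;
  template export uses the mean (deterministic). No KL penalty is applied
  by default: the training objective contains no divergence term, and the
  latent acts as a smooth conditioning bottleneck rather than a calibrated
  posterior.
- Stage 2 (registration): U-Net over the 2-channel input
  (T_α, X_p) → `v_{p|α}`; X̂_p = T_α ∘ φ_{p|α}.

Both networks predict velocities at half resolution; integration runs on
that native grid and the resulting displacement is bilinearly upsampled and
rescaled (voxel units) to the full grid, the usual cost saving for
downsampled velocity fields. Final layers are zero-initialized so training
starts exactly at identity deformations.

## Loss

`L = γ₁ L_recon + γ₂ L_bend1 + γ₃ L_bend2 + γ₄ L_disp1 + γ₅ L_disp2 + γ₆ L_mean`
with defaults γ = (1, 0.01, 0.01, 0.01, 0.01, 1).

- `L_recon`: MSE between X̂_p and X_p.
- `L_bend*`: bending energy — mean over interior voxels of the squared
  Laplacian of the *output deformations* of each stage (central second
  differences; borders excluded because one-sided second differences are
  noisy). Computed on the displacement `u` rather than `φ = id + u`; the two
  are identical since the Laplacian of the identity vanishes. Affine fields
  score zero, so global scale changes are not penalized.
- `L_disp*`: mean squared displacement magnitude of each stage's deformation.
- `L_mean`: MSE between the conditional template T_α and the mean-adjusted
  template T̂_α (an L1 variant is available via `mean_loss_kind="l1"`).

### Mean tracking and the centring penalty

Bin centres default to every 5 years across the training age range; each bin
stores an EMA of Stage-2 velocities with global rate λ = 0.1 modulated by
the triangular soft-bin weight (the two bracketing bins partition unity).
Updates happen once per sample in the forward pass and persist across
batches; ages outside the bin range clamp to the edge bin. The tracker is
updated first and the combined velocity formed afterwards within the same
forward pass. Tracked means are pure state: no gradients flow into them, and
they are checkpointed with the model so template export after reload is
bit-identical.

**T̂_α is a detached target.** The centring penalty is
`MSE(T_α, stopgrad(T̂_α))`. With gradients flowing through both templates
the penalty is translation-invariant to first order — for a locally
constant mean shift `m`, `|T(x+u) − T(x+u+m)|²` does not depend on `u` — and
exerts essentially no centring force (we observed exactly this: conditional
templates stayed age-constant). Treating the mean-adjusted template as the
target pulls Stage 1 toward absorbing the tracked age-systematic component
of Stage-2 deformations; Stage 2 then re-registers from the moved template,
its per-bin mean decays, and the equilibrium has centred templates.

## Optimization

AdamW (decoupled weight decay), β₁ = 0.9, β₂ = 0.999, weight decay 1e-2.
The 3-D-scale default learning rate is 1e-4; the desk-scale 2-D experiment
uses 1e-3, matched to its much smaller model and short 40-epoch schedule.
One master seed fans out (via `SeedSequence`-style keyed generators) to
weight initialization, latent sampling, and epoch shuffling; resuming from a
checkpoint reproduces the uninterrupted loss trace exactly.

A loss-ablation mode re-runs training with one of γ₂…γ₆ set to zero
(`TrainConfig.with_ablation`, CLI `ablate`). Components with zero weight are
skipped entirely, which is what makes the γ₆ = 0 run a true removal of the
mean-consistency mechanism.

## Synthetic phantoms

Each phantom is a 64×64 T1-like slice: white-matter ellipse (intensity
0.85) inside a cortical grey ribbon (0.55), with paired dark ventricles
(0.12) and hippocampus blobs (0.45), background 0, light Gaussian
anti-alias blur (σ 0.6). Structure areas follow linear trends over ages
50–90: ventricles +50%, hippocampus −15%, cortical grey matter −10%, white
matter −5% nominal (its label also cedes voxels to the growing ventricles).
Axis lengths scale as the square root of the area factor; the grey ribbon
is sized so its area follows its own trend exactly. Per-subject variability
is multiplicative log-normal size jitter (σ = 0.03) plus 0.5-voxel centre
jitter; structures that collide after jitter are re-drawn (capped retries).
The anatomy centre sits 0.27/0.13 voxels off the grid centre so that
rasterized volumes change in small increments rather than symmetric jumps.

What the phantoms do *not* model: MRI physics (bias fields, partial volume,
demyelination-driven intensity change), 3-D anatomy, nonlinear age effects,
and any covariate beyond age and a dummy sex column. Passing tests show the
method recovers smooth geometric trends under mild inter-subject jitter;
they do not certify performance on real T1 scans.

Corruptions: (i) additive Gaussian noise targeting a relative SNR — the
convention is SNR = mean foreground intensity / noise std, with a clean
phantom assigned a nominal acquisition SNR of 100 (noise floor 1% of the
foreground mean), so `snr_fraction=0.35` yields a measured SNR ratio inside
the 0.30–0.40 band; (ii) random gamma, `I → I^γ`, `γ = e^β`,
`β ~ U(−a, a)`, one draw per image, default a = 0.3.

## Evaluation battery

- **Topology**: per-voxel `det(∇φ)` with `∇φ = I + ∇u`, central differences
  (one-sided at borders); counts of voxels with det ≤ 0, per-field and
  pooled summaries and histograms.
- **Structural similarity**: SSIM with the standard parameters (Gaussian
  window σ = 1.5, 11-wide, K₁ = 0.01, K₂ = 0.03, population covariance,
  whole-image evaluation at data range 1) and RMSD. Pre- vs
  post-registration comparison of adjacent-age templates uses an internal
  small-deformation SVF registration (Adam on MSE + 0.05 × bending energy,
  150 iterations, zero-initialized velocity) — an internal tool, evaluated
  as such, not a claim about any external registration package.
- **Dice**: per-label overlap `2|A∩B|/(|A|+|B|)` on phantom ground-truth
  labels; empty-in-both labels are reported missing.
- **Volume trends**: template volumes are measured geometrically from the
  group template's ground-truth labels. By the change of variables, the
  volume of a structure in T_α = T ∘ φ_α equals the integral of
  det(∇φ_α⁻¹) over the structure's region in the group template; the
  inverse flow comes free with SVFs (integrate −v_α). This is the default
  because it is continuous in α — the learned trend amplitude at desk
  scale is below one label voxel per age step, which integer label
  counting would quantize away. The discrete alternative (labels warped
  through φ_α with nearest-neighbour interpolation, voxels counted) is
  available as `method="count"`. Per ROI, volumes are normalized by their mean over
  the conditioning set (so curves average to 1); per-scan reference volumes
  are averaged in 2-year age bins and normalized the same way, with a 95%
  interval for plotting. Trend recovery reports fitted-slope signs, the
  Spearman correlation between the curves (template curve averaged within
  the reference bins), and the largest normalized gap.

## Desk-scale experiment

Study conditions: 200 phantoms, ages uniform on 50–90, default slopes and
jitter; full loss with default γ; 5-year bins; batch 8; 40 epochs; lr 1e-3.
Evaluation uses ages 50…90 in 5-year steps for Stage-1 templates, the first
50 cohort scans for Stage-2 Jacobians, and all 200 scans for the per-bin
mean Stage-2 displacement score (occupancy-weighted mean magnitude of each
bin's average displacement field). The γ₆ = 0 ablation runs on identical
seeds and data. These sizes were chosen so the whole experiment, including
the ablation, runs in minutes on one CPU while leaving the age trend
clearly measurable.

## Numerical choices and limitations

- Geometry runs in voxel space on 0-based indices; deformations are stored
  as displacement-from-identity in voxel units; the NIfTI affine is carried
  as metadata (inputs are assumed affinely pre-aligned).
- Out-of-bounds samples clamp to the border voxel (no zero halo around
  warped templates); zero padding is available as an option.
- The numpy geometry (`diffeo`) and the differentiable route (`spatial`,
  `autodiff.grid_sample2d`) implement the same convention and are
  cross-checked against each other in the tests; gradients of every
  operator are verified against central finite differences in float64.
- Training runs in float32; scalar constants are kept in float32 so they
  never upcast the graph.
- For linear velocity fields the integrator equals `(I + A/2^s)^(2^s)`,
  whose distance to the exact flow `expm(A)` scales as `‖A‖²/2^(s+1)`;
  accuracy-sensitive uses can raise `steps`.
- The trainable networks are 2-D; the geometric core, losses, phantoms
  (shape permitting) and evaluation support 2-D and 3-D. Tracked means live
  at the full velocity-grid resolution.
- Small structures (the ~40-voxel hippocampus) are strongly quantized by
  rasterization, so their phantom volume trends are noisier than the
  ventricle trend; evaluation asserts only the direction of such trends.
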