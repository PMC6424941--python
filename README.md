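# t1forge

Multi-contrast 3D Beltrami denoising and saturation-recovery T1 mapping for
quantitative cardiac MRI — with a synthetic phantom generator and an
accuracy/precision evaluation layer, so the whole pipeline can be validated
end-to-end without scanner data.

## The problem

Saturation-recovery T1 mapping (SASHA-type sequences) estimates the
spin-lattice relaxation time T1 per voxel from a set of co-registered
T1-weighted volumes acquired at different saturation times TS. It is highly
accurate — the recovery curve is not confounded by readout history — but its
low dynamic range makes the voxel-wise fit noise-sensitive, so the resulting
T1 maps are imprecise. Denoising the T1-weighted volumes *before* fitting
can recover precision, provided tissue edges shared across the contrasts are
preserved.

## The method

All `n` contrasts are denoised jointly by solving

```
min_{m}  Σ_i ‖m_i − d_i‖₂²  +  λ Σ_x √(1 + β² Σ_i |∇ʷ m_i(x)|²)
```

where `d_i` are the observed volumes, `∇ʷ m_i = w(m_i) ∇ m_i` is a weighted
3D spatial gradient with per-voxel edge weights
`w(m_i) = exp(−|∇m_i|²/h²)` (re-estimated at each iteration), and the single
square root couples all contrasts at every voxel — edges present in several
contrasts survive, uncorrelated fluctuations are smoothed. The Beltrami
constant `β` interpolates between quadratic and total-variation-like
penalties, avoiding TV's staircase artifact. Defaults: `λ = 0.25`, `h = 5`,
`β = 1.0`.

The convex (fixed-weight) problem is solved with a primal–dual hybrid
gradient (Chambolle–Pock) scheme; the coupled square root is dualized
exactly as a Euclidean norm over `3n + 1` components per voxel, so the dual
step is a closed-form ball projection. Gradients use forward differences
with Neumann boundary, scaled by the physical voxel spacing (anisotropic
voxels such as 1.4 × 1.4 × 8 mm are handled consistently).

T1 maps are then fitted voxel-wise with the standard three-parameter
saturation-recovery model `S(TS) = A(1 − B e^{−TS/T1})`, the unprepared
(no-preparation) image entering as the `TS → ∞` asymptote. The fit uses
variable projection (for fixed T1 the model is linear in `A` and `A·B`) over
a logarithmic T1 grid with golden-section refinement — vectorized,
deterministic, bounded.

Evaluation follows the field's conventions: per-ROI mean T1 as the accuracy
proxy, per-ROI SD as the precision proxy, Bland–Altman bias and 95% limits
of agreement between techniques, and a simplified AHA 16-segment (+ blood
pool) summary for cardiac geometries.

## Worked example

Paired experiment on the nine-vial phantom (T1 log-spaced 250–1500 ms, one
unprepared image plus eight saturation times in 100–700 ms, Gaussian noise
σ = 20 on an equilibrium signal of 1000, five noise replicates):

```python
import t1forge as tf

spec = tf.nine_vial_spec(noise_sigma=20.0, seed=42)
cfg = tf.ExperimentConfig(phantom=spec, replicates=5)
report = tf.run_paired_experiment(cfg)
cols = ["label", "true_t1_ms", "sd_raw_ms", "sd_denoised_ms",
        "bias_raw_ms", "bias_denoised_ms"]
print(report.table[cols].round(1).to_string(index=False))
print(f"precision improved in all vials: {report.precision_improved_everywhere}")
print(f"max |bias change|: {report.max_abs_bias_change_ms:.2f} ms")
```

```
 label  true_t1_ms  sd_raw_ms  sd_denoised_ms  bias_raw_ms  bias_denoised_ms
     1       250.0       19.0            15.9          0.5               0.5
     2       312.8       21.3            17.7          0.1               0.1
     3       391.3       24.1            20.1          0.0               0.0
     4       489.5       28.8            24.1          1.4               1.4
     5       612.4       34.9            29.0          1.1               1.1
     6       766.1       44.0            36.8          3.2               3.3
     7       958.4       58.5            48.5          2.7               2.6
     8      1199.0       80.0            66.6          2.8               2.4
     9      1500.0      115.4            95.5          8.7               7.5
precision improved in all vials: True
max |bias change|: 1.21 ms
```

Read: within-vial T1 standard deviation (precision) drops in every vial
after denoising, while the per-vial bias (accuracy) moves by about a
millisecond — precision improves, accuracy is preserved. Both arms fit the
*same* noise realization, mirroring how one acquisition yields both maps.

A command-line interface wraps the same functions:

```bash
t1forge simulate --preset vials --sigma 20 --seed 1 --out stack.nii.gz --times times.txt
t1forge denoise --in stack.nii.gz --times times.txt --lam 0.25 --h 5 --out denoised.nii.gz
t1forge fit --in denoised.nii.gz --times denoised.nii.gz.times.txt --out t1map.nii.gz
t1forge sweep --h 1,2,5,10 --lam 0.05,0.25,1.0 --out sweep.csv
```

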