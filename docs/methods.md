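# Methods

## Signal model and forward simulation

The phantom generator produces multi-contrast saturation-recovery stacks
under the ideal-saturation two-parameter model

    S(TS) = A · (1 − e^(−TS/T1)),

with the unprepared image equal to `A` exactly (it is represented by a
contrast time of `+inf`, never a fake large number; serialization writes the
literal `inf`). The *fitting* model is the more general three-parameter form
`S = A(1 − B e^(−TS/T1))` with `B` the effective saturation efficiency; the
generator deliberately produces `B = 1` data so that fit identifiability of
the extra parameter is exercised rather than assumed.

Geometry is declarative: labelled primitives (cylinder, annulus, box) with
per-region true `T1` and equilibrium signal `A`, rasterized by the
voxel-center rule in physical millimetre coordinates (voxel center of index
`i` at `i · spacing`, 0-based). Overlaps are an error unless the spec opts
into later-wins override. A region that covers zero voxels warns instead of
failing, so degenerate geometries in sweeps do not abort a run.

Two noise models are available, applied voxel-wise i.i.d. from a seeded
`numpy` generator (same seed + same spec → bit-identical stack):

* `gaussian` (default): plain additive; may produce negative intensities
  and is *not* clipped.
* `rician`: `|S + η_r + i·η_i|` with independent Gaussian channels —
  magnitude-image statistics, everywhere ≥ 0.

Preset conditions: the vial phantom has nine cylinders with T1 evenly
log-spaced over 250–1500 ms (the published phantom's range; the individual
vial values are not public, so log-spacing was chosen once as the natural
coverage of the range), `A = 1000`, sampled at one unprepared image plus
eight saturation times evenly covering 100–700 ms, on 1.4 × 1.4 × 8 mm
voxels. The noisy-experiment default is σ = 20 (SNR 50 against `A`), which
puts the within-vial T1 SD in the tens of milliseconds before denoising —
the regime the denoiser targets. The cardiac preset (blood disk ~1700 ms
inside a myocardial annulus ~1100 ms) uses typical native 1.5 T values and
exists to exercise the AHA summary; neither value is asserted anywhere.

What the generator does *not* emulate: readout physics (bSSFP weighting,
flip angles, slice profiles), B0/B1 inhomogeneity, parallel-imaging noise
correlation, motion, or partial-volume mixtures beyond voxel-center
rasterization. Passing tests therefore demonstrate correctness of the
estimation pipeline under its own signal model, not robustness to every
in-vivo confounder.

## Denoising energy

All `n` contrasts are denoised jointly:

    min_m  Σ_i ‖m_i − d_i‖₂² + λ Σ_x √(1 + β² Σ_i |∇ʷ m_i(x)|²),

with `∇ʷ m_i = w(m_i) ∇ m_i` and `w(m_i) = exp(−|∇m_i|²/h²)` per voxel.
The fidelity term carries no ½ factor; λ is documented against exactly this
convention. The inner sum over contrasts inside one square root is the
multi-contrast coupling: a shared edge contributes once, so it is cheap to
keep; a fluctuation present in a single contrast is smoothed.

Numerical choices:

* **Discretization.** Forward differences with replicate-edge (Neumann)
  boundary; the divergence is the exact negative adjoint (dot-product test
  holds to ~1e−14, enforced in the suite). Differences are divided by the
  physical spacing per axis so the 8 mm slice direction is penalized
  consistently with the 1.4 mm in-plane directions; an
  `index_space_gradients` flag provides index-space behaviour for
  comparison.
* **Intensity normalization.** λ and h are scale-dependent and their
  defaults were calibrated on scanner-unit data, so inputs are scaled so
  that the 99th percentile of the unprepared image maps to 1 before
  solving, and rescaled after; the constant is recorded in the
  `SolveReport`. With `normalize=False` the solver is exactly equivariant
  to global intensity shifts (tested); with normalization on, that
  equivariance is intentionally traded for parameter transferability.
* **Defaults** λ = 0.25, h = 5, β = 1.0; `max_iters = 300`;
  stopping when the relative change of the primal iterate over a
  5-iteration window falls below `tol = 1e−5`.

## PDHG solver

For fixed weights the energy is convex. Writing `K m = (w_i ∇ m_i)_i` and
noting `√(1 + β²|y|²) = β‖(y, 1/β)‖₂`, the regularizer's conjugate turns
into the indicator of a Euclidean ball of radius λβ over the `3n + 1`
augmented components per voxel. The Chambolle–Pock iteration is then

1. dual: `(p, p0) ← Proj_{‖·‖ ≤ λβ}((p, p0) + σ(K m̄, 1/β))`,
2. primal: `m ← (m − τ Kᵀp + 2τ d) / (1 + 2τ)` (exact prox of the
   un-halved fidelity),
3. over-relaxation: `m̄ ← 2m − m_old`.

Step sizes default to `τ = σ = 0.99/L`, with `L` obtained by power
iteration on the *unweighted* gradient operator (deterministic fixed start);
since `w ≤ 1` this bounds the weighted operator for every weight field, so
one estimate covers all iterations. The condition `τσL² ≤ 1` is validated
whenever steps are user-supplied. A guard raises `DivergenceError` if the
energy increases for 30 consecutive iterations.

**Weight updates and the energy trace.** Weights are re-estimated from the
current iterate every iteration by default (`weight_update_every = 1`),
making the overall scheme a lagged-diffusivity fixed-point over convex
subproblems; `weight_update_every = 0` freezes the weights computed from
the input. With frozen weights the energy trace is non-increasing (the
suite checks this at 1e−8 relative after a 5-iteration burn-in). With
per-iteration updates the *objective itself* changes between iterations —
a smoother iterate has smaller gradients, hence weights nearer 1 and a
larger measured penalty — so consecutive trace entries compare different
objectives and may drift upward by ~1e−6 relative; this is a property of
the weight-adaptive scheme, not solver failure. The `SolveReport` therefore
stores the final iterate's energy under both the initial and the final
weights, alongside the per-iteration trace.

`λ = 0` is solved analytically (the fidelity-only minimizer is the input);
the report records zero iterations.

## Three-parameter fit

`S(TS) = A(1 − B e^(−TS/T1))` is separable: for fixed T1 it is linear in
`(A, C) = (A, A·B)`, solved in closed form from 2×2 normal equations. The
fit scans 64 log-spaced T1 candidates in [1, 5000] ms (this grid subsumes a
coarse multi-start over short/typical/long T1), takes the first minimum
(ties break toward the smallest T1), and refines the bracketing cell by 40
golden-section steps on log T1 — bracket reduction ~0.618⁴⁰, far below the
0.1% accuracy demanded of noiseless recovery. Everything is vectorized over
voxels and strictly deterministic.

Validity of a voxel's fit requires: finite non-zero input, `A > 0`,
`B ∈ [0, 2]`, `B ≥ 0.01` (a flat curve with `B ≈ 0` leaves T1
unidentifiable — e.g. constant signals — and is flagged rather than
reported), and T1 strictly inside its bounds. Invalid voxels carry NaN in
all maps; degenerate inputs are signalled through `converged = False`,
never through exceptions. No Rician magnitude-bias correction is applied —
magnitude images are fitted directly, which biases very low-SNR voxels
(known limitation, consistent with common offline practice).

## Evaluation layer

* **ROI statistics**: per-label mean (accuracy proxy) and sample (n−1) SD
  (precision proxy) over *valid* voxels only; labels with no valid voxels
  are excluded with a warning. With ground truth attached, bias =
  mean − truth.
* **Bland–Altman**: differences `a − b`, bias = mean difference, 95% limits
  of agreement = bias ± 1.96 × sample SD.
* **AHA summary**: basal and mid rings in 6 segments of 60°, apical ring in
  4 of 90°, angles measured counterclockwise from the anterior RV-insertion
  reference supplied by the caller (anterior → anteroseptal ordering);
  segments 1–6 basal, 7–12 mid, 13–16 apical, and segment 17 reports the
  blood pool (replacing the true-apex segment, which a short-axis stack
  does not resolve). LV center and RV-insertion angle are explicit inputs —
  automatic landmark detection is out of scope. The per-voxel segment-label
  volume is returned so the partition property (segments disjoint, union =
  myocardium within the declared slice ranges) is directly checkable.

## I/O conventions

NIfTI-1 is the interchange format (4D stack or one 3D file per contrast,
canonical RAS orientation on load, float32 on write) with a plain-text
sidecar of saturation times, one per line, `inf` for the unprepared image.
DICOM series are read-only input: one directory per contrast, slices sorted
by position along the series normal (so file discovery order is
irrelevant), mixed series UIDs and irregular slice gaps are errors, and
contrast times come from an explicit list — vendor timing tags are only
used when a tag name is explicitly requested, and the tag used is logged.
No resampling is ever performed; geometry mismatches are errors.

## Paired experiment

`run_paired_experiment` fits T1 maps from the *same* noise realization
before and after denoising (one acquisition yields both maps), per
replicate; replicates vary only the noise seed. The aggregate table
averages per-ROI mean/SD/bias over replicates; a Bland–Altman of denoised
vs raw per-ROI means summarizes agreement. The acceptable accuracy change
defaults to 5 ms — an engineering threshold for synthetic data, not a
published value. `sweep` emits the precision/bias trade-off over a (h, λ)
grid: SD decreases monotonically in λ near the default while bias grows.

Problem sizes: unit tests use a 40×40×4 nine-vial phantom (~410 voxels per
vial); the acceptance checks use 60×60×6 (~600 voxels per vial) with ten
replicates, and 6×6×4 two-contrast instances for solver-vs-oracle
equivalence. These sizes make every statistic stable at a few seconds per
solve; nothing in the method depends on grid size beyond noise-of-noise in
the statistics.

## Known limitations

* Edge voxels of a structure are slightly biased by denoising (smoothing
  across the boundary with background); on the noiseless vial phantom the
  per-vial mean shifts by up to ~0.3% on small grids, well under the 5 ms
  paired-experiment threshold at the default λ.
* The Beltrami weights adapt to the normalized intensity scale; for data
  whose edges are weak relative to the 99th-percentile normalization, `h`
  may need retuning.
* No pulse-sequence physics, motion, or multi-subject statistics; MOLLI
  and IRSE comparison maps are external inputs, not simulated.
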