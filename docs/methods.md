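# Methods note

This note records what `digitsel` computes, how the synthetic generator is
parameterized, and which numerical and design choices were made where more
than one defensible option existed.

## 1. Generative model

Neural tuning for digit d is an isotropic 3-D Gaussian bump of unit peak,

    f_d(x) = exp(−‖x − c_d‖² / (2 σ²)),

with centers c_d ordered somatotopically along the first grid axis
(D1 → D2 → D5) and centered on the other two axes. A shared-activation
parameter λ ∈ [0, 1) mixes each field with the mean of the other two,
f_d ← (1−λ) f_d + λ·mean(f_others), modelling genuinely overlapping neural
recruitment (e.g. enslaving of neighbouring fingers). Ground-truth labels are
the argmax of the mixed fields inside the "ribbon" support
(max field > ribbon_floor).

The measured response applies a contrast-specific vascular point-spread
function — Gaussian blur with the given FWHM (σ_b = FWHM/2.3548, reflect
padding) — scales by the contrast amplitude, and adds i.i.d. Gaussian noise:

    z_d(v) = A · (G_psf * f_d)(v) + ε,  ε ~ N(0, noise_sd²).

Noise streams are keyed by (seed, contrast name, digit) via numpy
`SeedSequence` spawn keys, so noise is independent of the blur width: two
contrasts with the same name share a realization, which makes fixed-seed
point-spread sweeps paired comparisons.

Blurring a Gaussian bump attenuates its peak by
(σ²/(σ²+σ_b²))^{3/2} (`gaussian_peak_attenuation`). At fixed amplitude and
fixed threshold, widening the PSF therefore *shrinks* suprathreshold masks
whenever the attenuation outpaces the spreading; the cluster radius grows
with blur only when ln(A/thr) > 1.5·(1 + ln(1 + σ_b²/σ²)).
`constant_peak_profile` divides the amplitude by the attenuation so the
blurred-peak contrast-to-noise stays constant across widths; point-spread
sweeps use it so they isolate spatial spreading from trivial peak loss. This
mirrors the empirical situation where the blurrier contrast (BOLD) also has
the higher raw amplitude.

### Default parameters

| Parameter | Default | Unit | Rationale |
|---|---|---|---|
| grid_shape | 48 × 48 × 48 | voxels | patch covering one region at high-field resolution |
| voxel_size_mm | 1.0 iso | mm | typical sub-millimetre-to-1 mm digit-mapping protocols |
| digit_centers_mm (M1) | 20, 24, 28 | mm | ~4 mm inter-digit spacing along the ribbon axis |
| digit_centers_mm (S1) | 19.5, 24, 28.5 | mm | slightly wider spacing; S1 maps separate a bit more |
| tuning_sigma_mm | 3.0 | mm | sets non-dominant crosstalk at ~30–55 % of dominant |
| neural_overlap (λ) | 0.3 | — | shared activation between digits; same crosstalk regime |
| VASO-CBV profile | PSF 1.0 mm, amplitude 3.5 | | narrow point-spread, lower CNR |
| BOLD profile | PSF 2.5 mm, amplitude 6.0 | | wide point-spread, higher CNR |
| noise_sd | 1.0 | z units | z maps are standard-normal under the null |
| ribbon_floor | 0.05 | — | support cut-off defining the synthetic ribbon |
| threshold | 2.5 | z | strict "greater than" activation rule |

Tuning width, λ and the digit spacing were calibrated once, against the
crosstalk regime the analysis is meant to operate in, before any tests were
frozen; they were not adjusted afterwards.

## 2. Paradigm and GLM

The block paradigm is 30 s baseline followed by ten cycles of 30 s task /
30 s rest: 630 s, 210 frames at TR 3 s, 100 task frames. The TR must tile
every block exactly; anything else is an error, not a rounding. The task
regressor convolves the boxcar with a canonical double-gamma HRF (response
gamma peaking near 6 s minus an undershoot gamma near 16 s, ratio 1/6,
unit-sum kernel) and is peak-normalized. The GLM is ordinary least squares
with an intercept (optional linear drift), rank-checked. t statistics are
converted to z by two-sided tail matching computed in log space
(`stats.t.logsf` + `special.ndtri_exp`) so extreme t values map to finite,
accurate z. Voxels with numerically zero residual variance are flagged and
given z = 0 rather than ±∞.

## 3. Analysis definitions

- Activation mask: ROI ∧ max(z_D1, z_D2, z_D5) > threshold, strict. NaN
  thresholds are rejected; ±∞ is allowed (empty/full masks are meaningful).
- Winner-takes-all: argmax over digits; ties break to the lowest digit
  ordinal and are counted (`tie_count`) rather than silently resolved.
- Dice/Jaccard are computed on integer voxel counts; the identity
  J = D/(2−D) holds exactly (rational arithmetic is exposed via
  `PairOverlap.dice_exact`/`jaccard_exact`). Both-empty pairs return 0 with
  a `both_empty` flag instead of NaN or an error.
- Crosstalk table: mean z of every digit inside every dominant-digit WTA
  cluster; empty clusters yield NaN rows and are listed in
  `empty_clusters`. A label map whose clusters are not diagonally dominant
  for the supplied z maps is rejected — it cannot have come from them.
- OS: voxels with any z ≤ 0 or a denominator below ε = 1e−9 are flagged.
  Policies: `exclude` (default; flagged voxels are dropped from the ROI mean
  and the flagged fraction is reported), `clamp` (values clipped to
  [1/3, 1]), `raw` (reported as computed). An absolute-value variant
  max(z)/Σ|z| is provided for sensitivity analyses.
- DS is computed per WTA cluster, by default as the voxel-mean of the
  per-voxel statistic (`voxel-mean`); `means-of-means` first averages the z
  maps over the cluster and applies the formula once.
- ROI conjunction across contrasts: the default rule (`and`) keeps voxels
  active in *both* contrasts, so both are scored on a common support;
  `or` and `per-contrast` are available as switches.
- Group statistics: paired two-sided t-tests on per-subject differences.
  The Bonferroni family defaults to the number of levels per
  (region, metric): 3 for Dice/Jaccard and DS, 1 for OS. The reported
  families are explicit in the output (`family_m`) and can be overridden.

## 4. Design choices on open questions

- **Family size.** Published digit-mapping analyses rarely state the exact
  correction family. The per-(region, metric) default above is the most
  conservative reading that still matches the number of reported
  comparisons; it is overridable rather than hard-coded.
- **Enslaving.** There is no separate "D5 enslaving" switch; the λ mixing
  term covers shared activation generically and symmetrically. An
  asymmetric per-digit mixing matrix would be a natural extension.
- **Configuration validation** is explicit field-by-field Python (precise
  error messages, no schema-library dependency).
- **Determinism.** All randomness flows through numpy `SeedSequence`
  spawning; per-subject seeds derive from (master seed, subject index,
  region) and stay below 2³¹. Pipeline reruns with the same config and seed
  are bit-identical for every CSV output, and the manifest records a
  SHA-256 config hash.

## 5. What the generator does and does not emulate

It emulates: ordered digit representations, genuinely shared neural
activation, contrast-specific vascular blur and amplitude, thermal noise,
block-design hemodynamics, and the full multi-subject, two-region,
two-contrast study layout.

It does not emulate: physiological (cardiac/respiratory) noise and motion,
draining-vein geometry (blur is isotropic Gaussian, real BOLD point-spread is
anisotropic and vein-directed), cortical surface topology and folding (the
grid is flat; no laminar axis), between-subject anatomical variability
(subjects differ only by noise realization), or partial-volume effects.

## 6. Known limitations

- The fraction of OS-flagged voxels in simulation (~15–30 % at the default
  noise level) is much higher than in well-averaged empirical data, because
  every voxel carries unit noise and non-dominant responses near cluster
  edges frequently dip below zero. The fraction is always reported alongside
  OS so the `exclude` policy is auditable.
- With the default BOLD profile the realized dominant-cluster mean z is
  ~4 rather than ~5.5–6, because the 2.5 mm blur attenuates the amplitude-6
  peaks by ~0.56; crosstalk *ratios*, which drive every comparison in the
  package, sit in the intended regime.
- Strict monotonicity of Dice/DS in the PSF width is a property of the
  paired, constant-peak-CNR sweep; with independent noise per width or
  fixed (unattenuated) amplitudes near threshold it need not hold.
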