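# digitsel

Digit-selectivity analysis for somatotopic fMRI mapping.

High-resolution fMRI can resolve the ordered representation of individual
fingers (thumb D1, index D2, little finger D5) in primary motor (M1) and
somatosensory (S1) cortex. How cleanly those representations separate depends
not only on neural tuning but on the *vascular point-spread function* of the
contrast used: BOLD is sensitive but blurred by draining veins, while
CBV-weighted contrasts such as VASO have a narrower point-spread at the cost
of amplitude. `digitsel` quantifies that trade-off: given per-digit
z-statistic maps for two contrasts in the same subjects, it measures how much
digit clusters overlap, how much response each digit's cluster shows to the
*other* digits (crosstalk), and how selective individual voxels are — then
tests the between-contrast differences across subjects.

## The model

For each digit d ∈ {D1, D2, D5} and voxel v with z-scores
z₁(v), z₂(v), z₅(v):

- **Activation mask**: v enters the analysis when it lies inside the ROI and
  max(z₁, z₂, z₅) > threshold (strictly; default 2.5).
- **Winner-takes-all parcellation**: each active voxel is assigned to the
  digit with the largest z (ties to the lowest digit ordinal, tallied).
- **Overlap**: per-digit suprathreshold masks may overlap; each digit pair is
  scored with Dice = 2|A∩B|/(|A|+|B|) and Jaccard = |A∩B|/|A∪B|
  (J = D/(2−D) exactly).
- **Crosstalk**: mean z of every digit inside every dominant-digit cluster.
- **Overall selectivity** OS(v) = max(z₁,z₂,z₅)/(z₁+z₂+z₅) ∈ [1/3, 1] for
  positive responses; voxels with a non-positive response or vanishing
  denominator are flagged and, by default, excluded (policies: `exclude`,
  `clamp`, `raw`; an absolute-value variant is also provided).
- **Digit selectivity** DS = ½[(z_dom−z_nd1)+(z_dom−z_nd2)]/z_dom, the mean
  dominant-minus-non-dominant difference normalized by the dominant response.
- **Group statistics**: paired two-sided t-tests of contrast A vs B per
  metric, Bonferroni-corrected over the levels tested (three digit pairs for
  Dice/Jaccard, three digits for DS, one ROI-wide OS test).

A synthetic generator produces all of this from first principles: isotropic
Gaussian tuning bumps placed somatotopically along a cortical-ribbon axis,
optional shared neural activation between digits, contrast-specific Gaussian
vascular blur and response amplitude, i.i.d. Gaussian noise, and a
block-design paradigm (30 s baseline + 10 × [30 s task / 30 s rest] = 630 s at
TR 3 s) with a canonical double-gamma HRF and OLS GLM for time-series data.
The default configuration *is* the simulated study: a VASO-like contrast
(PSF 1.0 mm, amplitude 3.5) vs a BOLD-like contrast (PSF 2.5 mm, amplitude
6.0) on 48³ 1 mm grids for M1 and S1.

## Worked example

Simulate the default six-subject, two-region, two-contrast study and compare
the contrasts:

```python
from digitsel.pipeline import simulate_study

study = simulate_study(n_subjects=6, seed=1)
for region in ("M1", "S1"):
    for contrast in ("VASO-CBV", "BOLD"):
        os_ = study.group_mean("os", region, contrast)
        ds = sum(study.group_mean("ds", region, contrast, d) for d in ("D1", "D2", "D5")) / 3
        dice = sum(
            study.group_mean("dice", region, contrast, f"{a}-{b}")
            for a, b in (("D1", "D2"), ("D1", "D5"), ("D2", "D5"))
        ) / 3
        print(f"{region} {contrast:8s}  OS={os_:.3f}  DS={ds:.3f}  Dice={dice:.3f}")
```

prints

```
M1 VASO-CBV  OS=0.544  DS=0.648  Dice=0.199
M1 BOLD      OS=0.520  DS=0.563  Dice=0.452
S1 VASO-CBV  OS=0.559  DS=0.683  Dice=0.177
S1 BOLD      OS=0.535  DS=0.599  Dice=0.392
```

— the narrow-PSF contrast is more selective (higher OS and DS) and its digit
clusters overlap far less (lower Dice), in both regions. The paired tests are
in `study.group_stats.frame`; every comparison above survives Bonferroni
correction, e.g.

```
 metric region level          t  p_adjusted
   dice     M1 D1-D2 -16.240401    0.000048
     ds     M1    D2  18.915974    0.000023
     os     M1         7.954723    0.000506
     os     S1         3.705410    0.013921
```

The same pipeline runs from the shell against real or simulated NIfTI data:

```
digitsel simulate  --config config.yaml --out sim/
digitsel parcellate --zmaps sim/zmap_BOLD_D1.nii.gz sim/zmap_BOLD_D2.nii.gz \
    sim/zmap_BOLD_D5.nii.gz --roi sim/ribbon_mask.nii.gz --out labels.nii.gz
digitsel run --config config.yaml --out results/
```

`digitsel run` writes tidy CSVs (metrics, overlap, crosstalk, selectivity,
group stats), a threshold-sweep JSON and a manifest with a config hash;
reruns with the same config and seed are bit-identical.

## Documentation

See `docs/methods.md` for the generative model, parameter defaults and
rationale, numerical choices, and known limitations.
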