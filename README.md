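# axonquant

Quantification of early-stage axon regeneration inside synthetic nerve
conduits from 3D fluorescence microscopy stacks.

After a peripheral nerve is transected and its stumps are bridged with a
conduit (e.g. chitosan), regenerating GFP-labelled axons can be imaged in 3D
by long-working-distance confocal microscopy of cleared tissue. Quantifying
that regrowth is a pipeline problem: the conduit wall retains
autofluorescence that contaminates the fiber channel; fibers must be counted
*en face* (in planes perpendicular to the nerve axis) rather than traced; and
nerves differ in how many axons carry the label, so raw counts are not
comparable across animals. `axonquant` implements the full chain for users
analysing such stacks — and, because animal-derived stacks are rarely
shareable, ships a synthetic-scene simulator with exact ground truth that
stands in for them and validates every stage.

## The measurement

For each nerve, the read-out is the **intersection profile**
`N(x)` — the number of fiber crossings of the transverse plane at axial
position `x`, in 1 µm increments on the closed grid `x ∈ [−1000, 2000]` µm,
with the lesion plane at `x = 0` and proximal→distal as increasing `x`.
Profiles are normalized per nerve by the pre-lesion baseline

    n(x) = N(x) / mean{ N(x) : x ∈ [−1000, −500] },

so `n ≈ 1` in the intact proximal stump regardless of how many axons express
the label. Each nerve is then summarised by trapezoidal areas under `n(x)`
over fixed segments (proximal `[−1000, 0]`, distal `[0, 2000]`, and the two
distal 1000 µm halves), and groups are compared per segment with two-tailed
unpaired t-tests and with a two-way mixed ANOVA (between: treatment, within:
segment) followed by Bonferroni-adjusted post-hoc tests, at significance
threshold p ≤ 0.05. Curves are displayed smoothed with a 50 µm centred
moving average; statistics always run on unsmoothed values.

Pipeline stages (each an importable module):

| stage | module | method |
| --- | --- | --- |
| simulate | `axonquant.scene` / `render` | fiber paths as damped random walks; exact plane-crossing ground truth; Gaussian-tube rendering with Poisson + read noise |
| mask | `axonquant.masking` | random-forest pixel classification (intensity / smoothed / gradient / windowed-variance features), conduit voxels replaced by the background median |
| detect | `axonquant.detect` | trilinear en-face reslicing; single-scale Laplacian-of-Gaussian spot detection with MAD-relative threshold and non-maximum suppression |
| profile | `axonquant.profiles` | lesion alignment, baseline normalization, 50 µm smoothing |
| stats | `axonquant.stats` | segment AUCs, t-tests, mixed ANOVA + Bonferroni |
| orchestrate | `axonquant.pipeline` / `cli` | `run-all` with a manifest of per-stage output hashes |

## Worked example

Simulate ten untreated-control nerves and ten nerves with a neurotrophic-
factor-like effect (boosted regrowth, excessive sprouting just distal of the
lesion, more backward-projecting fibers), and compare the groups:

```sh
python examples/04_group_study.py
```

```
 segment  mean_control  sd_control  mean_ntf  sd_ntf       t  p_raw  p_bonferroni  significant
proximal      1024.734      14.453  1035.147  27.692  -1.054  0.306         0.917        False
  distal        78.520      46.881   519.618 117.733 -11.007  0.000           NaN         True
distal_1        73.371      39.603   489.475 113.897 -10.912  0.000         0.000         True
distal_2         5.148      16.281    30.143  21.463  -2.934  0.009         0.027         True
```

The proximal segment is a true null (both groups have intact proximal
stumps): AUC ≈ 1000 ≈ segment length × 1, and the test is not significant.
Distally the treated group retains several-fold more fiber crossings, and
both distal sub-segments are flagged. The other examples exercise individual
stages: `01_simulate_scene.py` (ground-truth profiles), `02_mask_and_subtract.py`
(conduit Dice 0.999, residual wall signal 0.3% on a held-out stack),
`03_detect_and_profile.py` (detected counts within 0.77% of ground truth over
the full 3 mm window on a noiseless render).

A shell interface wraps the same functions
(`axonquant simulate|mask|detect|profile|stats|run-all|plot`); `run-all`
executes a whole two-group study from one YAML config and one seed and writes
a run directory with a reproducibility manifest.

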