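# Methods

This note documents the models, conventions and numerical choices behind
`axonquant`, in the order data flows through the pipeline.

## Coordinate and grid conventions

Stacks are `(z, y, x)` arrays with physical voxel sizes `(dz, dy, dx)` in
micrometres; stack coordinates are voxel index × spacing. Default spacing is
the acquisition this pipeline targets: 1.24 µm laterally and a 2.45 µm
z-step. The analysis grid is the **closed** integer set −1000..2000 µm
(3001 positions) relative to the lesion plane at 0, proximal→distal
increasing. The baseline segment is likewise closed, [−1000, −500]
(501 samples). "Between −1000 and −500 µm" admits either endpoint
convention; the inclusive one is fixed here and used consistently by the
normalizer, the tests and the AUC segment bounds. Unacquired positions are
*missing* (NaN), never zero: a plane that was not imaged is not evidence of
zero fibers, and normalization requires at least 100 acquired baseline
positions before it will divide.

## Synthetic scenes

The simulator emulates a transected nerve bridged by a conduit two weeks
into regeneration, with ground truth exact by construction.

**Fiber geometry.** Each of `n_fibers` axons runs proximal→distal with a
fixed 1 µm axial step; the lateral position follows a damped random walk
(discrete Ornstein–Uhlenbeck, mean-reversion rate 0.03 per step) around a
per-fiber anchor, with equilibrium wander SD `lateral_wander_sd_um`
(default 1.2 µm) and radial reflection at `nerve_radius_um`. Anchors are
dart-thrown with a minimum pairwise separation (`fiber_min_sep_um`,
default 8 µm). The separation models the sparse mosaic GFP labelling that
makes single-fiber counting possible in the first place — a densely labelled
nerve would not be countable by any per-plane spot detector, ours included.
Per-step lateral displacement is clamped to 1.5 µm so polyline spacing never
exceeds the 2 µm bound that keeps crossing counts exact.

**Fates at the lesion.** Each fiber first draws a U-turn with probability
`p_backward` (the "retrograde fiber" phenomenon: the return strand
re-anchors to a fresh, separation-respecting position and extends proximally
an exponential distance); otherwise it regrows distally with probability
`p_regen` for an exponential(`regen_length_mean_um`) distance, or aborts at
the lesion. Poisson(`sprout_rate`) collateral sprouts per fiber originate
uniformly within 100 µm distal of the lesion, offset 4–8 µm laterally from
the parent anchor (growth cones veer off; the offset also keeps sprouts
resolvable from their parents), with exponential(`sprout_length_mean_um`)
lengths. Sprout origins are placed in the lesion neighbourhood without
explicit branch geometry connecting them to the parent tube — a rendering
simplification that does not affect counts.

**Ground truth.** `true_profile` counts transversal crossings of all
polyline segments with each plane. A segment with axial span `[x1, x2]`
contributes to every grid position in the half-open interval
`[min, max)`. Consequences of this tie-break: a crossing passing exactly
through a shared polyline vertex counts once; an exact tangential touch (a
vertex that is a local axial extremum on the plane) counts zero; both are
measure-zero for generated scenes. A U-turning fiber therefore contributes
two crossings at every plane its return strand re-covers — the source of the
proximal "backward-projection bump". The implementation is a vectorised
difference-array accumulation; the test suite checks it against a
brute-force triple loop.

**Defaults as study conditions.** Axial dimensions are at study scale
(≈500 µm gap, 3000 µm window, lesion at scene coordinate 1000 µm). Lateral
geometry is scaled down roughly five-fold (nerve radius 40 µm, conduit inner
radius 50 µm, wall 12 µm versus a ≈0.5 mm nerve in a ≈1 mm conduit) so that
default stacks stay desk-sized; nothing in the method depends on the
absolute cross-section, only on fiber density and the wall annulus being
present. `n_fibers = 20` is a plausible mosaic-label count, not a measured
value — no per-nerve fiber count is available for the labelling used.
Presets: `control_params()` (p_regen 0.25, no sprouting) and
`ntf_like_params()` (p_regen 0.55, sprout_rate 3.0, p_backward 0.2). The
sprouting intensity of the treated preset was chosen from the closed-form
expectation of the normalized profile: a distal peak exceeding the intact
baseline (normalized value > 1, the "marked peak immediately distal to the
lesion") requires roughly `p_regen + 0.6·sprout_rate > 1` at this geometry,
i.e. genuinely *excessive* sprouting; modest sprouting (rate ≈ 1) produces
an inflection but no super-baseline peak.

**Rendering.** Fiber centrelines are splatted trilinearly (one unit weight
per 1 µm point) and blurred with a 3D Gaussian of sigma `fiber_radius_um`
per axis (physical units), giving Gaussian-profile tubes. Amplitude is
calibrated analytically so that an ideal straight on-grid tube peaks at
`peak_intensity`; sub-voxel placement at the coarse 2.45 µm z-sampling can
lose up to half the peak, as it does in real undersampled acquisitions. The
conduit wall is the exact annulus `[inner, inner + wall]` carrying
smoothed-noise autofluorescence texture (Gaussian-filtered white noise,
correlation length `autofluorescence_texture_um` = 5 µm, ±30% contrast
around `autofluorescence_level`). Everything radially inside the conduit is
multiplied by `attenuation_in_conduit` (default 0.7: signal inside the
conduit is dimmer but usable). Noise is Poisson shot noise (rate scaled by
`photon_scale`) plus Gaussian read noise, then clipped at zero. All
randomness derives from the single scene seed, so scenes and renders are
bit-reproducible; the optical model deliberately stops at Gaussian tubes (no
PSF anisotropy, scattering or depth dependence) — see Limitations.

## Conduit masking

Pixel classification uses per-voxel features — raw intensity and, per
physical scale (defaults 2 and 5 µm): Gaussian-smoothed intensity, Gaussian
gradient magnitude, and windowed variance (uniform window of half-width
equal to the scale per axis). Scales below half a voxel are rejected. The
classifier is a 50-tree random forest with a fixed seed; training labels
come from ground-truth geometry for synthetic data or from sparse scribbles
(CSV of `z,y,x,label`) for real stacks. The feature set and
forest mirror the behaviour of interactive pixel-classification tools
commonly used for this task; the exact features and settings used in any
given lab workflow are typically unrecorded, so this is a documented
stand-in, not a re-implementation of a specific tool. Predicted conduit
voxels are closed morphologically (physical-radius ball, default 2 µm) to
yield a contiguous wall; closing never overwrites fiber-labelled voxels.

Subtraction replaces conduit voxels with the median of background-class
voxels rather than zero: zeroing would carve dark edges into the stack whose
intensity steps later excite the spot detector. Voxels outside the conduit
class are returned bit-identically.

Offset robustness: the gradient and variance features are exactly invariant
under a constant intensity offset, the raw/smoothed features are not. A
forest trained on one illumination keys partly on absolute intensity;
training with an offset-augmented copy of the stack (the standard
illumination-robustness recipe) makes held-out accuracy stable to within two
percentage points under a +10% offset, which is how the property is tested.

## En-face counting

The stack is resliced perpendicular to the annotated nerve axis (two points
in stack µm), one plane per 1 µm, sampled at isotropic 1 µm in-plane spacing
by trilinear interpolation; out-of-volume samples are zero. Planes are
processed independently — the read-out is crossings per position, not
tracks, so no 3D linking is attempted.

The detector computes the scale-normalised negative Laplacian-of-Gaussian
response at a single scale (default 1.06 µm ≈ fiber radius/√2) and keeps
local maxima (8-neighbourhood, in-bounds neighbours only) exceeding
`rel_threshold` (default 5) times the plane's MAD-based noise scale
(1.4826 × median absolute deviation). A second floor, `peak_floor_frac`
(default 0.05) times the plane's maximum response, suppresses sub-resolution
Gaussian tails just past fiber endpoints, which would otherwise register in
noiseless planes where the MAD is zero. Both thresholds scale with the data,
so counting is invariant under global intensity rescaling. Maxima closer
than `min_sep_um` (default 3 µm) are suppressed greedily, strongest first;
exact response ties keep the candidate first in row-major order. The
original analysis used closed-source spot detection whose algorithm and
settings are unpublished; this detector is a transparent, fully
parameterised stand-in, and the suite verifies it exactly against an
exhaustive brute-force search.

On noiseless default scenes the end-to-end count error over the full window
is ≈1% of the true total; the residue is fiber pairs transiently closer than
the ≈3 µm two-point resolution (sprouts near their branch point, U-turn
strands near the turn) and the ±2–3 µm blur halo beyond fiber endpoints.

## Profiles and statistics

Alignment re-expresses counts relative to the lesion (rounded to the 1 µm
grid), cropping/padding to the window with missing values. Normalization
divides by the closed-baseline mean and refuses zero or under-sampled
baselines (such nerves are excluded upstream and reported). Smoothing is a
51-sample centred moving average (window 50 µm → half-width 25), truncated
at the edges and skipping missing values; a periodic variant (exactly
mean-preserving) and a disjoint-bin variant exist behind flags. "Smoothed
over 50 µm intervals" is read as a sliding window; the binned reading is the
config switch. Smoothing is display-only: AUCs and tests always use
unsmoothed normalized values, since smoothing belongs to the plotted curves,
not to the statistic.

Segment AUCs are trapezoidal integrals on the shared grid, so
AUC[0,2000] = AUC[0,1000] + AUC[1000,2000] holds exactly. The headline
per-segment test is the pooled-variance two-tailed unpaired t-test (the
conventional default of mainstream statistics software; Welch behind a
flag; zero variance with equal means returns t = 0, p = 1 by convention).
The family over the three 1000 µm segments is additionally tested with a
classical two-way mixed ANOVA (between: treatment; within: segment; subject
nested in treatment; computed via `pingouin.mixed_anova`, cross-checked in
the tests against a brute-force sums-of-squares decomposition) followed by
Bonferroni-adjusted per-segment comparisons (multiplier = number of
segments). No sphericity correction is applied to the three-level within
factor — a documented limitation. Both routes are reported because either
is defensible for this design; significance is called at p ≤ 0.05.

## Validation strategy and problem sizes

Every stage is validated against an independent oracle: crossing counts
against a brute-force segment/plane loop; the detector against exhaustive
local-maximum search; windowed variance, smoothing and AUC against direct
loops or refined Riemann sums; the ANOVA against the cell-mean
decomposition. The acceptance script and tests use desk-scale problem
sizes chosen as the package's own defaults: full-window renders at
≈2400×115×58 voxels, masking on ≈650×115×58-voxel windows around the lesion
with five held-out stacks, and a 50-replicate simulated treatment study at
the study group size of n = 10 nerves per group. The replicate study runs
on ground-truth intersection profiles (generator → exact counts →
normalization → AUC → test): its purpose is the statistical chain, and
detection fidelity is established separately by the exact-recovery and
oracle-equivalence checks.

What passing on synthetic data does *not* show: robustness to real-tissue
nuisances the generator omits — depth-dependent attenuation and PSF
broadening, scattering artefacts from the conduit wall, axon fasciculation
(bundles tighter than the detector's two-point resolution), Schwann-cell or
macrophage autofluorescence, stitching seams, and lesion-plane annotation
error. Real densely-labelled nerves would undercount systematically; the
method presumes sparse labelling.

## Known limitations

* Per-plane counting cannot distinguish one long axon from several short
  ones crossing the same planes; branch points and fiber diameters are out
  of scope (diameter morphometry needs higher-resolution modalities).
* The detector is single-scale; fibers far from the default radius need the
  scale re-set in config.
* The lesion plane is a manual annotation input; no automatic detection.
* Mixed ANOVA is uncorrected for sphericity; with three within levels the
  distortion is small but nonzero.
* Tile acquisition/stitching is assumed done upstream; inputs are single
  calibrated stacks.
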