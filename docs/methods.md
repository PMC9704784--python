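# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model

A voxel in a gradient-echo EPI slice of thickness Δz experiencing a
residual through-slice field gradient g (mT/m) at echo time TE accrues a
linear phase ramp across the slice.  For an ideal rectangular slice
profile the net magnitude is

    A(g) = | sin(π u) / (π u) |,   u = γ̄ · g · TE · Δz,

with γ̄ = 42.577 kHz/mT (proton gyromagnetic ratio over 2π), TE in
seconds and Δz in meters.  A is even in g, equals 1 at g = 0, and has
exact nulls at integer u; the first null at TE 40 ms / Δz 5 mm sits at
g ≈ 0.1174 mT/m.  The slice profile of a real excitation pulse is not
rectangular; a Gaussian-profile alternative A = exp(−(πu)²/6) — the unique
Gaussian matching the sinc to second order in u — is available behind the
`profile="gaussian"` flag for robustness checks.  Both selection methods
only depend on A decreasing with |u| near its peak, so the profile choice
does not alter which index wins on clean data.

## The compensation grid

The scanner applies one of `n_steps` equidistant compensation gradients
symmetric about zero (default 21 values spanning ±0.21 mT/m, i.e.
0.021 mT/m spacing).  `n_steps` must be odd so the neutral (zero) value
exists; indices are 1-based everywhere, with the neutral index at
(n_steps + 1)/2.  The grid stores the *field gradient to be compensated*;
the pulsed gradient moment is g·TE, so a selected index remains valid
across echo times.  Grids may equally be specified in moment units (the
15-step ±4.9 mT/m·ms validation-style grid) — the arithmetic is
unit-agnostic.

Tie and boundary policy (not constrained by any measurement, so fixed by
design): exact midpoint ties in nearest-value rounding and exact intensity
ties in the argmax both resolve toward the smaller |gradient| (minimal
perturbation under uncertainty), then the lower index; gradients beyond
the grid range clamp to the end value with a logged warning, because the
scanner can only apply grid values.

## EPI-reference-based selection

The intensity matrix holds the plain mean over cord-mask voxels per
(slice, step); no within-slice trimming is applied.  Slices whose mask is
empty yield NaN rows — an explicit missing flag, never 0, so they cannot
fake an argmax winner — and fall back to the neutral index with a
warning.  The mean-across-steps volume is exposed for segmentation/QC
purposes only; selection itself uses the matrix.  Cord segmentation is an
upstream concern: masks are inputs (the simulator provides exact cylinder
masks; real data would come from a cord segmentation tool).

## Field-map-based selection

**Frequency estimation.**  Two echoes: Δν = wrap(φ₂ − φ₁)/(2π·ΔTE),
unambiguous for |Δν| < 1/(2ΔTE) (≈ 203 Hz at ΔTE 2.46 ms).  Multi-echo:
phases are unwrapped per voxel along the echo axis only (`np.unwrap`; the
short 1.3 ms inter-echo spacing keeps genuine phase advances below π
inside |Δν| < ~385 Hz, so no spatial unwrapping is needed) and Δν is the
OLS slope of phase versus TE over 2π.  Beyond the aliasing limit the
estimate wraps by 1/ΔTE — a documented failure mode, exercised by a test,
not an error.  Bipolar odd/even-echo phase offsets are assumed corrected
upstream; the simulator generates phases without them.

**Slab fit.**  The field map is smoothed with an isotropic 1 mm Gaussian
(sigma converted to voxels per axis; `mode="nearest"` so constant fields
are fixed points).  For each EPI slice, cord voxels whose z-coordinate
lies within Δz/2 + 2 mm of the slice center (a 9 mm slab at the 5 mm
default) enter an OLS fit of Δν on [x, y, z, 1].  Coordinates are centered
on the slab's mask centroid — the data do not constrain this choice; it
decorrelates the offset from the slopes and improves conditioning.  The
fit is unweighted.  Slabs with fewer than 4 voxels or a rank-deficient
design (e.g. a single column, where x and y do not vary) are flagged and
fall back to the neutral index.  Slopes convert as
G [mT/m] = slope [Hz/mm] / 42.577; all unit bridges go through one
function (`slope_to_gradient`).

**Histogram estimator.**  Compensating the slab-*mean* gradient is
suboptimal when a few extreme voxels shift the mean: the compensation then
suits neither the bulk nor the extremes.  The variant computes voxelwise
through-slice gradients by finite differences along z (`np.gradient`:
central in the interior, one-sided at slab edges), histograms them over
their observed range (21 bins by default), and returns the mean of the
gradients in the modal bin ± one neighbor.  Bin count and the modal ± 1
window are package choices and are exposed as parameters.  Note the finite
differences at non-cord neighbors of mask voxels do use the field values
outside the mask; on real data the map should therefore be reasonably
smooth (it is smoothed first) for this estimator to behave.

**Geometry contract.**  Field maps are consumed on a grid whose third
axis is the EPI slice axis, in the same coordinate frame as the EPI slice
centers (the NIfTI z-translation anchors the frame).  Resampling a
sagittal acquisition into this frame, and any EPI/field-map registration,
is upstream and out of scope; a mismatch is a violated precondition, not
a handled case.

## Synthetic-data generator

The phantom is a cylinder (radius 4 mm, intensity 1000) in a background of
20 on a 32 × 32 × 24 grid with 1 × 1 × 5 mm voxels — the cord
cross-section, in-plane resolution, slice count and thickness of a typical
cervical protocol at desk scale (the in-plane matrix is cropped to the
cord neighborhood; nothing depends on the full 128 × 128 FOV).  Default
image noise is σ = 50, i.e. SNR 20 in the cord.

The field has two modes.  *Sinusoidal* (default): gz(z) =
A·sin(2π(z − φ)/P) with A = 0.15 mT/m and P = 15 mm, emulating the
periodic inhomogeneity driven by vertebral spacing; Δν is its analytic
integral plus in-plane terms and a global offset.  *Table*: an exactly
constant through-slice slope per EPI slice, for scenarios requiring
on-grid ground truth.  The per-slice true gradient is defined as the
analytic mean of gz over the slice extent, so reference-scan ground truth
and field-map fits coincide by construction.  The reference simulator
attenuates the whole tissue volume (cord and background) per slice and
step and reports the true optimal indices alongside.

Two deliberate simplifications: noise is Gaussian rather than Rician
(immaterial for argmax/least-squares behavior at the simulated SNRs, and
it keeps estimator tests analytic), and in-plane gradients gx/gy affect
the field map but not the simulated EPI intensity (echo-shift physics is
out of scope) — so cross-method comparisons remain valid by construction.
The generator does not model geometric distortion, motion, physiological
noise or respiration-driven dynamic fields; passing tests demonstrate
correctness of the estimators under the stated model, not robustness to
those real-world effects.

**On-grid test scenarios.**  Exact-recovery tests use a triangle-wave
per-slice index profile (amplitude 3 steps, unit steps between adjacent
slices; `sim.demo_per_slice_indices`).  The 9 mm fitting slab averages
over neighboring slices with weights ≈ 0.75 / 0.125 / 0.125; with at most
one-step neighbor differences the slab-weighted gradient stays within
half a grid spacing of the central slice's value, so "exact recovery" is
well-defined for the field-map route.  A 15 mm-period sinusoid is *not*
resolvable by a 9 mm slab without amplitude bias (the slab average
attenuates the modulation by ~50%); that physically honest limitation is
why the sinusoidal default is used for dropout/benefit scenarios and the
table mode for exactness claims.

## Evaluation metrics

- Slice profiles: plain means over mask voxels per slice; NaN for empty
  slices.  Summaries use the sample variance (n − 1) and CV = SD/mean
  (flagged NaN at zero mean).  Sample statistics are used throughout.
- tSNR: voxelwise temporal mean / sample SD; zero-SD voxels yield inf
  (flagged, not an error).
- Outlier censoring: dVARS (RMS difference to the previous volume) and
  refRMS (RMS difference to the temporal-mean reference), both computed
  within the cord mask by default (configurable region); a volume is
  flagged when either metric exceeds its run mean + 2 SD.  The first
  volume's dVARS is undefined and excluded from that metric's mean/SD.
  Censoring is implemented as volume exclusion, equivalent to delta
  regressors of no interest up to degrees-of-freedom bookkeeping.
- Bootstrap: percentile-type with paired resampling of units; BCa is not
  implemented.  pct_diff = 100·(mean(a) − mean(b))/mean(b).
- Reconstruction: slice s of the output is slice s of the reference
  volume at the selected index — the "artificial volume" used to compare
  selection schemes without reacquisition.

## Problem sizes

Replicated/randomized checks use sizes chosen to keep the full suite fast
while leaving comfortable statistical margins: 100 replicates for noisy
recovery (a one-step error costs ~5% signal against a ~1% SEM, so ±1-step
recovery has a wide margin), 1000 × 1000 resamples for bootstrap coverage
(accepted band 90–98.5% around the nominal 95%), 12 phantom subjects ×
100 volumes for the tSNR-benefit cohort, and 5 seeds for the every-seed
benefit property.

## Known limitations

- No spatial phase unwrapping; severely aliased field maps are out of
  range by design.
- The fit does not weight voxels by magnitude/SNR; on real data low-signal
  voxels contribute equally.
- Histogram-estimator finite differences can straddle the cord boundary.
- Selection quality on real data depends on the upstream cord mask, which
  this package treats as given.
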