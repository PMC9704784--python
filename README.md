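# zshim

Automated slice-specific z-shim selection for gradient-echo EPI of the
human spinal cord.

## The problem

Susceptibility differences between vertebrae and connective tissue impose
a spatially periodic B0 gradient along the cord (roughly one cycle per
~15 mm vertebral segment).  The through-slice component G_z of that
gradient dephases spins across each axial EPI slice and attenuates the
gradient-echo signal approximately as

    A(G_z) = | sinc( γ̄ · G_z · TE · Δz ) |

with γ̄ = 42.577 kHz/mT, echo time TE and slice thickness Δz.  At TE =
40 ms and Δz = 5 mm the signal vanishes completely at G_z ≈ 0.117 mT/m —
well within the range encountered in vivo.  A slice-specific *z-shim* is a
small compensation gradient pulse, chosen from a discrete grid (here 21
equidistant values spanning ±0.21 mT/m in 0.021 mT/m steps), that cancels
the local G_z before readout.  Choosing those 24 per-slice values by hand
takes ~10 minutes of expert time per session; this package automates the
choice.

## The two automated methods

**EPI-reference-based.**  A reference scan acquires one EPI volume per
candidate compensation.  Within a spinal-cord mask the mean intensity is
extracted for every (slice, step) pair — a 24 × 21 matrix — and each
slice's argmax step is selected.

**Field-map-based.**  A per-voxel frequency-offset map Δν₀ (Hz), obtained
from a two-echo phase difference or a linear fit to a multi-echo phase
train, is smoothed (1 mm Gaussian) and fitted slice-by-slice with linear
spatial basis functions [x, y, z, 1] over a 9 mm slab (5 mm slice + 2 mm
margins) restricted to cord voxels.  The fitted through-slice slope is
converted to a gradient (G_z = slope / 42.577 per Hz/mm) and rounded to
the nearest grid compensation.  A histogram-based variant estimates the
*most probable* voxelwise gradient instead of the mean one, which resists
a few extreme voxels dragging the compensation away from the bulk of the
cord.

The package also ships the evaluation toolbox (slice-intensity profiles,
mean/variance/CV across slices, voxelwise tSNR, 2-SD dVARS/refRMS outlier
censoring, paired percentile-bootstrap CIs, reference-scan volume
reconstruction, step-difference characterization) and a physics-based
synthetic-data generator (cylindrical cord phantom, periodic through-slice
field, sinc dephasing, Gaussian noise) so every stage is testable without
any scanner data.

## Worked example

```python
import numpy as np
from zshim import (ZShimGrid, AcquisitionParams, sim,
                   select_from_stack, simulate_reference_scan)

grid = ZShimGrid(n_steps=21, g_max=0.21)       # +0.21 ... -0.21 mT/m
params = AcquisitionParams(te=40.0, slice_thickness=5.0, n_slices=24)
phantom = sim.PhantomSpec()                    # 32x32x24, 4 mm cord radius
field = sim.FieldSpec()                        # 15 mm periodic dropout
ref = simulate_reference_scan(phantom, field, grid, params,
                              noise=sim.NoiseSpec(sigma_image=50.0, seed=0))
sel = select_from_stack(ref.stack, ref.mask)
print(sel.indices)
print(np.round(sel.moments, 2))
print((sel.indices == ref.true_indices).sum(),
      "of 24 slices match the simulated optimum")
```

prints

```
[ 6 11 16  6 11 16  6 11 16  6 11 16  6 11 16  6 11 16  6 11 16  6 11 16]
[ 4.2  0.  -4.2  4.2  0.  -4.2  4.2  0.  -4.2  4.2  0.  -4.2  4.2  0.
 -4.2  4.2  0.  -4.2  4.2  0.  -4.2  4.2  0.  -4.2]
24 of 24 slices match the simulated optimum
```

The phantom's field oscillates with a 15 mm period, i.e. one cycle every
three 5 mm slices, so the selected indices cycle 6 → 11 → 16: a +0.105
mT/m compensation (index 6, moment +4.2 mT/m·ms at TE 40 ms), none
(neutral index 11), then −0.105 mT/m.  Despite image noise at SNR 20,
every slice recovers the simulated optimum.

The same workflows are available from the shell:

```bash
zshim simulate   --config scenario.yaml --out-dir data/
zshim select-epi --stack data/refstack.nii.gz --mask data/mask.nii.gz --out-dir out/
zshim select-fm  --fieldmap data/fieldmap.nii.gz --mask data/fm_mask.nii.gz \
                 --n-slices 24 --out-dir out_fm/
zshim metrics    --series series.nii.gz --mask mask.nii.gz --out-dir qc/
zshim reconstruct --stack data/refstack.nii.gz --selection out/selection.json \
                  --out recon.nii.gz
```

`select-*` writes the scanner text file (one 1-based index per line, one
line per slice), a JSON selection record and CSV diagnostics, and prints a
per-slice report.

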