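"""Evaluation metrics: slice profiles, tSNR, outlier censoring,
reference-scan reconstruction, step differences and bootstrap CIs.

Sample (n-1) variants of variance and standard deviation are used
throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .epi_select import ReferenceStack, validate_mask
from .grid import ZShimGrid
from .selection import ZShimSelection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SliceProfile:
    """One scalar (intensity or tSNR) per slice; NaN marks missing slices."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))

    @property
    def n_slices(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class OutlierFlags:
    """Per-volume dVARS / refRMS values and the union outlier flags.

    The first volume has no predecessor, so its dVARS is NaN and excluded
    from that metric's mean/SD (it can still be flagged via refRMS).
    """

    dvars: np.ndarray
    refrms: np.ndarray
    flagged: np.ndarray

    @property
    def n_volumes(self) -> int:
        return int(self.flagged.shape[0])


def slicewise_mean(volume: np.ndarray, mask: np.ndarray) -> SliceProfile:
    """Mean intensity over mask voxels, one value per slice.

    Slices with an empty mask yield NaN (flagged missing, never zero).
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("volume must be 3D")
    mask = validate_mask(mask, volume.shape)
    n_slices = volume.shape[2]
    out = np.full(n_slices, np.nan)
    for s in range(n_slices):
        m = mask[:, :, s]
        if m.any():
            out[s] = volume[:, :, s][m].mean()
    return SliceProfile(values=out)


def profile_summary(profile: SliceProfile) -> dict:
    """Mean, sample variance and coefficient of variation across slices.

    Missing (NaN) slices are excluded.  CV = SD/mean is NaN-flagged when
    the mean is zero.
    """
    vals = profile.values[~np.isnan(profile.values)]
    if vals.size < 2:
        raise ValueError("need at least 2 non-missing slices")
    mean = float(vals.mean())
    var = float(vals.var(ddof=1))
    if mean == 0.0:
        logger.warning("zero mean across slices: CV undefined")
        cv = np.nan
    else:
        cv = float(np.sqrt(var) / mean)
    return {"mean": mean, "variance": var, "cv": cv}


def tsnr_map(series: np.ndarray) -> np.ndarray:
    """Voxelwise temporal mean over temporal SD (sample SD, n-1).

    Zero-SD voxels (e.g. a constant series) come out infinite — flagged
    rather than erroring, since they indicate degenerate input, not a bug.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4 or series.shape[3] < 2:
        raise ValueError("series must be 4D with at least 2 volumes")
    mean = series.mean(axis=3)
    sd = series.std(axis=3, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return mean / sd


def detect_outlier_volumes(series: np.ndarray, mask: np.ndarray,
                           threshold_sd: float = 2.0) -> OutlierFlags:
    """Flag volumes with dVARS or refRMS above mean + threshold_sd * SD.

    dVARS_t is the RMS (over mask voxels) of the difference to the previous
    volume; refRMS_t the RMS of the difference to the temporal-mean
    reference volume.  A volume is an outlier if either metric exceeds its
    run mean plus ``threshold_sd`` run SDs (union of the two criteria).
    Constant series have zero metric SD and produce no flags.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4 or series.shape[3] < 3:
        raise ValueError("series must be 4D with at least 3 volumes")
    mask = validate_mask(mask, series.shape[:3])
    voxels = series[mask]                     # [n_mask, n_volumes]
    n_vol = voxels.shape[1]

    dvars = np.full(n_vol, np.nan)
    diffs = np.diff(voxels, axis=1)
    dvars[1:] = np.sqrt(np.mean(diffs ** 2, axis=0))
    reference = voxels.mean(axis=1, keepdims=True)
    refrms = np.sqrt(np.mean((voxels - reference) ** 2, axis=0))

    def _exceeds(metric: np.ndarray) -> np.ndarray:
        valid = ~np.isnan(metric)
        m = metric[valid].mean()
        sd = metric[valid].std(ddof=1)
        if sd == 0.0:
            return np.zeros(n_vol, dtype=bool)
        out = np.zeros(n_vol, dtype=bool)
        out[valid] = metric[valid] > m + threshold_sd * sd
        return out

    flagged = _exceeds(dvars) | _exceeds(refrms)
    return OutlierFlags(dvars=dvars, refrms=refrms, flagged=flagged)


def censored_tsnr(series: np.ndarray, flags: OutlierFlags) -> np.ndarray:
    """tSNR computed over unflagged volumes only.

    Excluding a volume is equivalent (up to degrees-of-freedom bookkeeping)
    to modelling it with a delta regressor of no interest in a GLM.
    """
    series = np.asarray(series, dtype=float)
    if flags.n_volumes != series.shape[3]:
        raise ValueError("flags length must match the number of volumes")
    keep = ~flags.flagged
    n_keep = int(keep.sum())
    if n_keep < 2:
        raise ValueError(f"only {n_keep} unflagged volumes remain; need >= 2")
    if n_keep <= 2:
        logger.warning("censored tSNR computed from only %d volumes", n_keep)
    return tsnr_map(series[:, :, :, keep])


def reconstruct_from_reference(stack: ReferenceStack,
                               selection: ZShimSelection) -> np.ndarray:
    """Artificially reconstruct one EPI volume from the reference scan.

    Slice ``s`` of the output is slice ``s`` of the reference volume at the
    selected index — the image the scanner would have produced had the
    selection been applied (to noise and drift).
    """
    if selection.n_slices != stack.params.n_slices:
        raise ValueError("selection must cover every stack slice")
    idx = selection.indices
    if np.any(idx < 1) or np.any(idx > stack.grid.n_steps):
        raise IndexError("selection index outside the stack's step range")
    slices = np.arange(stack.params.n_slices)
    return stack.data[:, :, slices, idx - 1]


STEP_CATEGORIES = ("0", "1", "2", "3", ">3")


def step_difference_profile(selection: ZShimSelection,
                            grid: ZShimGrid) -> dict:
    """Absolute per-slice step difference from the neutral (no-shim) index.

    Returns the per-slice integer steps and the fraction of slices falling
    in the categories {0, 1, 2, 3, >3}.
    """
    steps = np.abs(selection.indices - grid.neutral_index)
    n = steps.size
    fractions = {
        "0": float(np.mean(steps == 0)),
        "1": float(np.mean(steps == 1)),
        "2": float(np.mean(steps == 2)),
        "3": float(np.mean(steps == 3)),
        ">3": float(np.mean(steps > 3)),
    }
    assert abs(sum(fractions.values()) - 1.0) < 1e-12 or n == 0
    return {"steps": steps, "fractions": fractions}


def percent_difference_ci(a, b, n_boot: int = 10000, seed: int = 0) -> dict:
    """Percentage difference of paired means with a percentile bootstrap CI.

    pct_diff = 100 * (mean(a) - mean(b)) / mean(b); units (participants or
    replicates) are resampled in pairs, and the 2.5/97.5 percentiles of the
    bootstrap distribution give the 95% CI.  Deterministic given ``seed``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("a and b must be equal-length 1D arrays, length >= 2")
    if b.mean() == 0.0:
        raise ValueError("mean of b is zero: percentage difference undefined")
    pct = 100.0 * (a.mean() - b.mean()) / b.mean()
    rng = np.random.default_rng(seed)
    n = a.size
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_a = a[idx].mean(axis=1)
    boot_b = b[idx].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot = 100.0 * (boot_a - boot_b) / boot_b
    lo, hi = np.nanpercentile(boot, [2.5, 97.5])
    return {"pct_diff": float(pct), "ci_low": float(lo), "ci_high": float(hi)}
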