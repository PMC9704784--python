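"""Field-map-based z-shim estimation.

Per-voxel B0 frequency offsets are estimated from gradient-echo phase data
(two-echo difference or a linear fit across a multi-echo train), optionally
smoothed, and then reduced to one through-slice gradient per EPI slice:
either by an ordinary least-squares fit of linear spatial basis functions
over a slab around the slice, or by a histogram-based estimate of the
voxelwise through-slice gradients that is robust to extreme values.  The
fitted gradient Gz is the field slope the z-shim has to cancel; rounding it
to the nearest grid value gives the selected index.

Unit conventions (fixed across the package): frequency offsets in Hz,
spatial slopes in Hz/mm, gradients in mT/m, gamma-bar = 42.577 kHz/mT for
protons.  All conversions go through :func:`slope_to_gradient`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grid import AcquisitionParams, ZShimGrid
from .selection import ZShimSelection, selection_from_indices

logger = logging.getLogger(__name__)

#: Proton gyromagnetic ratio over 2*pi, Hz per mT.
GAMMA_BAR_HZ_PER_MT = 42577.0

#: Frequency slope (Hz/mm) produced by a 1 mT/m field gradient.
HZ_PER_MM_PER_MT_M = GAMMA_BAR_HZ_PER_MT / 1000.0  # 42.577


def slope_to_gradient(slope_hz_per_mm):
    """Convert a spatial frequency slope (Hz/mm) to a field gradient (mT/m)."""
    return np.asarray(slope_hz_per_mm, dtype=float) / HZ_PER_MM_PER_MT_M


def gradient_to_slope(g_mt_per_m):
    """Convert a field gradient (mT/m) to a spatial frequency slope (Hz/mm)."""
    return np.asarray(g_mt_per_m, dtype=float) * HZ_PER_MM_PER_MT_M


def wrap_phase(phi):
    """Wrap phase(s) into (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi, dtype=float)))


@dataclass(frozen=True)
class PhaseSeries:
    """4D phase data [x, y, z, echo] in radians with echo times in ms."""

    phases: np.ndarray
    echo_times: np.ndarray

    def __post_init__(self) -> None:
        phases = np.asarray(self.phases, dtype=float)
        tes = np.asarray(self.echo_times, dtype=float)
        object.__setattr__(self, "phases", phases)
        object.__setattr__(self, "echo_times", tes)
        if phases.ndim != 4:
            raise ValueError(f"phases must be 4D, got {phases.ndim}D")
        if tes.ndim != 1 or tes.shape[0] != phases.shape[3]:
            raise ValueError("echo_times must match the echo axis length")
        if tes.shape[0] < 2:
            raise ValueError("at least 2 echoes are required")
        if np.any(np.diff(tes) <= 0):
            raise ValueError("echo times must be strictly increasing")

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times.shape[0])


@dataclass(frozen=True)
class FieldMap:
    """3D frequency-offset map (Hz) with geometry along the EPI slice axis.

    ``voxel_size`` is (dx, dy, dz) in mm with the third axis aligned to the
    EPI slice direction; ``z0`` is the coordinate (mm) of the first voxel
    center along that axis, in the same frame as the EPI slice centers.
    """

    dnu: np.ndarray
    voxel_size: tuple
    z0: float = 0.0

    def __post_init__(self) -> None:
        dnu = np.asarray(self.dnu, dtype=float)
        object.__setattr__(self, "dnu", dnu)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        if dnu.ndim != 3:
            raise ValueError(f"field map must be 3D, got {dnu.ndim}D")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (mm)")

    @property
    def z_coords(self) -> np.ndarray:
        """Voxel-center coordinates along the slice axis, mm."""
        return self.z0 + np.arange(self.dnu.shape[2]) * self.voxel_size[2]


@dataclass(frozen=True)
class SliceFit:
    """Linear field coefficients fitted over one EPI slice's slab.

    gx, gy, gz in mT/m along the main imaging axes; offset_hz is the
    homogeneous field term at the slab's mask centroid.  ``valid`` is False
    when the slab held too few voxels (or a rank-deficient design) for a
    full-rank fit; callers should then fall back to the neutral index.
    """

    slice_index: int
    gx: float
    gy: float
    gz: float
    offset_hz: float
    n_voxels: int
    residual_rms: float
    valid: bool = True

    @classmethod
    def failed(cls, slice_index: int, n_voxels: int = 0) -> "SliceFit":
        return cls(slice_index, np.nan, np.nan, np.nan, np.nan,
                   n_voxels, np.nan, valid=False)


# ---------------------------------------------------------------------------
# Frequency-offset estimation from phase data
# ---------------------------------------------------------------------------

def frequency_from_two_echoes(series: PhaseSeries,
                              voxel_size: tuple = (1.0, 1.0, 1.0),
                              z0: float = 0.0) -> FieldMap:
    """Two-echo frequency map: wrapped phase difference over delta-TE.

    Unambiguous for |dnu| < 1/(2*dTE); beyond that the estimate aliases.
    """
    if series.n_echoes != 2:
        raise ValueError("frequency_from_two_echoes requires exactly 2 echoes")
    dte_s = (series.echo_times[1] - series.echo_times[0]) / 1000.0
    dphi = wrap_phase(series.phases[..., 1] - series.phases[..., 0])
    dnu = dphi / (2.0 * np.pi * dte_s)
    return FieldMap(dnu=dnu, voxel_size=voxel_size, z0=z0)


def unwrap_echo_train(series: PhaseSeries) -> np.ndarray:
    """Unwrap phases along the echo axis, per voxel; first echo unchanged.

    The short inter-echo spacing of the multi-echo acquisition keeps the
    per-echo phase advance below pi inside the valid frequency range, so a
    simple 1D unwrap along echoes suffices — no spatial unwrapping is done.
    Noise-induced mis-unwraps are a documented limitation, not an error.
    """
    if series.n_echoes < 3:
        raise ValueError("echo-train unwrapping requires at least 3 echoes")
    return np.unwrap(series.phases, axis=3)


def frequency_from_multiecho(series: PhaseSeries,
                             voxel_size: tuple = (1.0, 1.0, 1.0),
                             z0: float = 0.0) -> FieldMap:
    """Frequency map from an OLS fit of unwrapped phase versus echo time.

    Valid while the per-echo phase advance |2*pi*dnu*dTE| stays below pi
    (for a 1.3 ms echo spacing: |dnu| < ~385 Hz); beyond that the phase
    evolution is undersampled and the estimate aliases.
    """
    if series.n_echoes >= 3:
        phases = unwrap_echo_train(series)
    else:
        phases = series.phases
    t = series.echo_times / 1000.0  # s
    tc = t - t.mean()
    slope = np.tensordot(phases - phases.mean(axis=3, keepdims=True),
                         tc, axes=([3], [0])) / np.sum(tc * tc)
    dnu = slope / (2.0 * np.pi)
    return FieldMap(dnu=dnu, voxel_size=voxel_size, z0=z0)


def smooth_fieldmap(fm: FieldMap, sigma_mm: float = 1.0) -> FieldMap:
    """Isotropic Gaussian smoothing with a physical-units kernel.

    ``sigma_mm`` is converted per axis via the voxel size.  Constant fields
    are fixed points; linear fields are unchanged away from the volume
    boundary.
    """
    if not sigma_mm > 0:
        raise ValueError("sigma_mm must be strictly positive")
    sigma_vox = [sigma_mm / v for v in fm.voxel_size]
    smoothed = ndimage.gaussian_filter(fm.dnu, sigma=sigma_vox, mode="nearest")
    return FieldMap(dnu=smoothed, voxel_size=fm.voxel_size, z0=fm.z0)


# ---------------------------------------------------------------------------
# Slice-wise gradient estimation
# ---------------------------------------------------------------------------

def _slab_selector(fm: FieldMap, slice_center: float, params: AcquisitionParams,
                   slab_margin_mm: float) -> np.ndarray:
    """Boolean z-axis selector for the slab around one EPI slice center."""
    half = params.slice_thickness / 2.0 + slab_margin_mm
    return np.abs(fm.z_coords - slice_center) <= half + 1e-9


def fit_slicewise_basis(fm: FieldMap, mask: np.ndarray, slice_index: int,
                        params: AcquisitionParams,
                        slab_margin_mm: float = 2.0) -> SliceFit:
    """OLS fit of linear spatial basis functions over one EPI slice's slab.

    The slab spans ``slice_thickness/2 + slab_margin_mm`` on either side of
    the slice center (5 mm slice + 2 mm margins = a 9 mm slab by default);
    the margin stabilizes the through-slice slope estimate.  Only cord-mask
    voxels contribute.  The design is [x, y, z, 1] with coordinates centered
    on the slab's mask centroid, which decorrelates the offset from the
    slopes.  Slopes (Hz/mm) are converted to gradients (mT/m).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != fm.dnu.shape:
        raise ValueError("mask must match the field-map shape")
    centers = params.slice_centers
    if not 0 <= slice_index < params.n_slices:
        raise IndexError(f"slice_index out of range [0, {params.n_slices})")
    sel_z = _slab_selector(fm, centers[slice_index], params, slab_margin_mm)
    slab_mask = mask & sel_z[None, None, :]
    n_vox = int(slab_mask.sum())
    if n_vox < 4:
        logger.warning("slice %d: only %d mask voxels in slab, fit flagged",
                       slice_index, n_vox)
        return SliceFit.failed(slice_index, n_vox)

    dx, dy, dz = fm.voxel_size
    ix, iy, iz = np.nonzero(slab_mask)
    x = ix * dx
    y = iy * dy
    z = fm.z_coords[iz]
    coords = np.column_stack([x, y, z])
    coords -= coords.mean(axis=0)
    design = np.column_stack([coords, np.ones(n_vox)])
    target = fm.dnu[slab_mask]
    coef, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < 4:
        logger.warning("slice %d: rank-deficient design (rank %d), fit flagged",
                       slice_index, rank)
        return SliceFit.failed(slice_index, n_vox)
    residual = target - design @ coef
    gx, gy, gz = slope_to_gradient(coef[:3])
    return SliceFit(
        slice_index=slice_index,
        gx=float(gx), gy=float(gy), gz=float(gz),
        offset_hz=float(coef[3]),
        n_voxels=n_vox,
        residual_rms=float(np.sqrt(np.mean(residual ** 2))),
    )


def fit_all_slices(fm: FieldMap, mask: np.ndarray, params: AcquisitionParams,
                   slab_margin_mm: float = 2.0) -> list:
    """Run :func:`fit_slicewise_basis` for every EPI slice."""
    return [fit_slicewise_basis(fm, mask, s, params, slab_margin_mm)
            for s in range(params.n_slices)]


def select_zshim_fm(fits: Sequence[SliceFit], grid: ZShimGrid,
                    params: AcquisitionParams) -> ZShimSelection:
    """Round each slice's fitted Gz to the nearest grid compensation.

    Equivalent to rounding the dephasing moment Gz*TE to the nearest grid
    moment, since the grid scales with TE.  Failed fits fall back to the
    neutral index; gradients beyond the grid range clamp to the end values.
    """
    indices = np.empty(len(fits), dtype=int)
    warnings = []
    g_edge = grid.g_max + grid.spacing / 2.0
    for i, fit in enumerate(fits):
        if not fit.valid:
            indices[i] = grid.neutral_index
            msg = (f"slice {fit.slice_index}: fit failed "
                   f"({fit.n_voxels} voxels), falling back to neutral index")
            warnings.append(msg)
            continue
        if abs(fit.gz) > g_edge:
            warnings.append(
                f"slice {fit.slice_index}: fitted gz = {fit.gz:.4f} mT/m "
                f"outside grid range, clamped")
        indices[i] = grid.nearest_index(fit.gz)
    return selection_from_indices(indices, grid, params, method="fm_fit",
                                  warnings=tuple(warnings))


def histogram_gradient(fm: FieldMap, mask: np.ndarray, slice_index: int,
                       params: AcquisitionParams, n_bins: int = 21,
                       slab_margin_mm: float = 2.0):
    """Mode-centered trimmed-mean estimate of the through-slice gradient.

    Compensating the slab-mean gradient is suboptimal when a few extreme
    voxels drag the mean away from the bulk of the cord.  This estimator
    computes voxelwise through-slice gradients by finite differences of the
    frequency map along z (central in the slab interior, one-sided at slab
    edges), histograms them, and returns the mean of the gradients falling
    in the modal bin and its two neighbors — compensating the most probable
    gradient rather than the average one.

    Returns the estimate in mT/m, or None when the slab holds too few mask
    voxels (< 3) or fewer than 2 field-map slices along z.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != fm.dnu.shape:
        raise ValueError("mask must match the field-map shape")
    centers = params.slice_centers
    sel_z = np.flatnonzero(_slab_selector(fm, centers[slice_index], params,
                                          slab_margin_mm))
    if sel_z.size < 2:
        logger.warning("slice %d: slab spans %d field-map slice(s), "
                       "histogram estimate flagged", slice_index, sel_z.size)
        return None
    slab = fm.dnu[:, :, sel_z]
    slab_mask = mask[:, :, sel_z]
    if int(slab_mask.sum()) < 3:
        logger.warning("slice %d: %d mask voxels in slab, histogram estimate "
                       "flagged", slice_index, int(slab_mask.sum()))
        return None
    slopes = np.gradient(slab, fm.voxel_size[2], axis=2)  # Hz/mm
    grads = slope_to_gradient(slopes[slab_mask])
    lo, hi = float(grads.min()), float(grads.max())
    if hi == lo:
        return lo
    counts, edges = np.histogram(grads, bins=n_bins, range=(lo, hi))
    modal = int(counts.argmax())
    sel_lo = edges[max(modal - 1, 0)]
    sel_hi = edges[min(modal + 2, n_bins)]
    selected = grads[(grads >= sel_lo) & (grads <= sel_hi)]
    return float(selected.mean())


def select_zshim_histogram(fm: FieldMap, mask: np.ndarray, grid: ZShimGrid,
                           params: AcquisitionParams, n_bins: int = 21,
                           slab_margin_mm: float = 2.0) -> ZShimSelection:
    """Histogram-based selection for every slice (fm_histogram method)."""
    indices = np.empty(params.n_slices, dtype=int)
    warnings = []
    for s in range(params.n_slices):
        g = histogram_gradient(fm, mask, s, params, n_bins=n_bins,
                               slab_margin_mm=slab_margin_mm)
        if g is None:
            indices[s] = grid.neutral_index
            warnings.append(f"slice {s}: histogram estimate failed, "
                            f"falling back to neutral index")
        else:
            indices[s] = grid.nearest_index(g)
    return selection_from_indices(indices, grid, params, method="fm_histogram",
                                  warnings=tuple(warnings))
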