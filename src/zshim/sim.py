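"""Physics-based synthetic data: cord phantom, structured B0 field,
through-slice dephasing, reference scans, time series and phase images.

The phantom emulates the cervical spinal cord as a bright cylinder in a
dimmer tissue background.  The B0 field carries a rostro-caudally periodic
through-slice gradient (the ~15 mm vertebral periodicity of susceptibility
inhomogeneities), optional in-plane linear terms and a global offset.
Gradient-echo signal attenuation from through-slice dephasing follows the
ideal rectangular slice-profile model: A = |sinc(gamma_bar * g * TE * dz)|.
Every generator is deterministic given its spec and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .epi_select import ReferenceStack
from .fieldmap import (FieldMap, GAMMA_BAR_HZ_PER_MT, HZ_PER_MM_PER_MT_M,
                       PhaseSeries, slope_to_gradient, wrap_phase)
from .grid import AcquisitionParams, ZShimGrid
from .selection import ZShimSelection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhantomSpec:
    """Cylindrical cord phantom on the EPI grid.

    ``matrix`` is (nx, ny, n_slices) voxels; ``voxel_size`` in mm with the
    third axis the EPI slice axis; ``cord_center`` is the cylinder axis
    offset (mm) from the in-plane field-of-view center.  ``s0`` is the
    unattenuated cord intensity, ``background`` the surrounding-tissue
    intensity (arbitrary units).
    """

    matrix: tuple = (32, 32, 24)
    voxel_size: tuple = (1.0, 1.0, 5.0)
    cord_radius: float = 4.0
    cord_center: tuple = (0.0, 0.0)
    s0: float = 1000.0
    background: float = 20.0

    def __post_init__(self) -> None:
        if self.cord_radius < 0:
            raise ValueError("cord_radius must be non-negative")
        if not self.s0 > self.background or self.background < 0:
            raise ValueError("need s0 > background >= 0")
        fov_x = self.matrix[0] * self.voxel_size[0]
        fov_y = self.matrix[1] * self.voxel_size[1]
        if (abs(self.cord_center[0]) + self.cord_radius > fov_x / 2
                or abs(self.cord_center[1]) + self.cord_radius > fov_y / 2):
            logger.warning("cord cylinder extends beyond the field of view "
                           "and will be cropped")


@dataclass(frozen=True)
class FieldSpec:
    """Structured B0 field along and across the cord.

    ``gz_amplitude`` (mT/m) is the peak through-slice gradient; in
    ``sinusoidal`` mode the gradient is modulated along z with period
    ``period_mm`` (default 15 mm, the vertebral spacing that drives the
    field modulation) and spatial phase ``phase_mm``.  ``per_slice_table``
    mode instead imposes an exactly constant through-slice slope per EPI
    slice, given by ``per_slice_gz``.  ``gx``/``gy`` are in-plane linear
    terms (mT/m) and ``offset_hz`` a global frequency offset.
    """

    gz_amplitude: float = 0.15
    period_mm: float = 15.0
    phase_mm: float = 0.0
    gx: float = 0.0
    gy: float = 0.0
    offset_hz: float = 0.0
    mode: str = "sinusoidal"
    per_slice_gz: Optional[tuple] = None
    gz_cap: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("sinusoidal", "per_slice_table"):
            raise ValueError("mode must be 'sinusoidal' or 'per_slice_table'")
        if not self.period_mm > 0:
            raise ValueError("period_mm must be strictly positive")
        if self.mode == "per_slice_table":
            if self.per_slice_gz is None:
                raise ValueError("per_slice_table mode requires per_slice_gz")
            object.__setattr__(self, "per_slice_gz",
                               tuple(float(g) for g in self.per_slice_gz))
            peak = max(abs(g) for g in self.per_slice_gz)
        else:
            peak = abs(self.gz_amplitude)
        if peak > self.gz_cap:
            raise ValueError(
                f"peak through-slice gradient {peak} mT/m exceeds cap "
                f"{self.gz_cap}")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: Gaussian image noise, Gaussian phase noise, and an
    optional linear intensity drift per volume (fraction of signal)."""

    sigma_image: float = 50.0
    sigma_phase_rad: float = 0.05
    drift_per_volume: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_image < 0 or self.sigma_phase_rad < 0:
            raise ValueError("noise standard deviations must be non-negative")


NOISELESS = NoiseSpec(sigma_image=0.0, sigma_phase_rad=0.0)


@dataclass(frozen=True)
class SimulatedReference:
    """Reference stack plus the ground truth it was generated from."""

    stack: ReferenceStack
    mask: np.ndarray
    g_true: np.ndarray
    true_indices: np.ndarray


# ---------------------------------------------------------------------------
# Phantom and field construction
# ---------------------------------------------------------------------------

def _inplane_coords(shape, voxel_size):
    """Voxel-center in-plane coordinates (mm) relative to the FOV center."""
    nx, ny = shape[0], shape[1]
    x = (np.arange(nx) - (nx - 1) / 2.0) * voxel_size[0]
    y = (np.arange(ny) - (ny - 1) / 2.0) * voxel_size[1]
    return np.meshgrid(x, y, indexing="ij")


def cylinder_mask(shape, voxel_size, center_xy, radius) -> np.ndarray:
    """Binary cylinder along the slice axis (voxel centers within radius)."""
    X, Y = _inplane_coords(shape, voxel_size)
    inside = (X - center_xy[0]) ** 2 + (Y - center_xy[1]) ** 2 <= radius ** 2
    return np.repeat(inside[:, :, None], shape[2], axis=2)


def make_phantom(spec: PhantomSpec):
    """Return (3D intensity volume, boolean cord mask) on the EPI grid."""
    mask = cylinder_mask(spec.matrix, spec.voxel_size, spec.cord_center,
                         spec.cord_radius)
    vol = np.where(mask, spec.s0, spec.background).astype(float)
    return vol, mask


def _gz_integral_mm(spec: FieldSpec, z, params: AcquisitionParams):
    """Integral of gz from 0 to z, in mT/m * mm (z in mm, scalar or array)."""
    z = np.asarray(z, dtype=float)
    if spec.mode == "sinusoidal":
        k = 2.0 * np.pi / spec.period_mm
        a = spec.gz_amplitude / k
        return a * (np.cos(k * (0.0 - spec.phase_mm))
                    - np.cos(k * (z - spec.phase_mm)))
    gz = np.asarray(spec.per_slice_gz, dtype=float)
    dz = params.slice_thickness
    cum = np.concatenate([[0.0], np.cumsum(gz) * dz])  # value at slice floors
    s = np.clip(np.floor(z / dz).astype(int), 0, gz.size - 1)
    return cum[s] + gz[s] * (z - s * dz)


def make_field(spec: FieldSpec, shape, voxel_size, z0: float,
               params: AcquisitionParams) -> FieldMap:
    """Frequency-offset map on a field-map grid aligned with the EPI slices.

    dnu(x, y, z) = 42.577 * (gx*x + gy*y + integral of gz along z) +
    offset_hz, with coordinates in mm and gradients in mT/m.  In table mode
    the through-slice slope inside EPI slice ``s`` is exactly
    ``per_slice_gz[s]`` (end slices extend their slope beyond the EPI
    coverage so edge slabs see a consistent field).
    """
    X, Y = _inplane_coords(shape, voxel_size)
    z = z0 + np.arange(shape[2]) * voxel_size[2]
    phi_z = _gz_integral_mm(spec, z, params)
    dnu = HZ_PER_MM_PER_MT_M * (
        spec.gx * X[:, :, None] + spec.gy * Y[:, :, None]
        + phi_z[None, None, :]
    ) + spec.offset_hz
    return FieldMap(dnu=dnu, voxel_size=voxel_size, z0=z0)


def fieldmap_grid(phantom: PhantomSpec, params: AcquisitionParams,
                  margin_mm: float = 8.0):
    """Field-map grid matching the phantom in-plane, finely sampled along z.

    The z range extends ``margin_mm`` beyond the EPI coverage so that edge
    slabs (and the smoothing kernel) never run off the sampled volume.
    Returns (shape, voxel_size, z0).
    """
    dz = params.slice_spacing_fm
    z_lo = -margin_mm
    z_hi = params.n_slices * params.slice_thickness + margin_mm
    nz = int(np.floor((z_hi - z_lo) / dz)) + 1
    shape = (phantom.matrix[0], phantom.matrix[1], nz)
    voxel_size = (phantom.voxel_size[0], phantom.voxel_size[1], dz)
    return shape, voxel_size, float(z_lo)


def true_slice_gradients(field: FieldSpec | FieldMap,
                         params: AcquisitionParams,
                         mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Mean through-slice gradient (mT/m) over each EPI slice's extent.

    For a :class:`FieldSpec` this is the analytic mean of gz(z) over the
    slice, so reference-scan ground truth and field-map fits coincide by
    construction.  For a sampled :class:`FieldMap` it is the mean
    finite-difference slope over (mask) voxels within the slice extent.
    """
    centers = params.slice_centers
    dz = params.slice_thickness
    if isinstance(field, FieldSpec):
        lo = _gz_integral_mm(field, centers - dz / 2.0, params)
        hi = _gz_integral_mm(field, centers + dz / 2.0, params)
        return (hi - lo) / dz
    slopes = np.gradient(field.dnu, field.voxel_size[2], axis=2)
    g = slope_to_gradient(slopes)
    out = np.empty(params.n_slices)
    for s in range(params.n_slices):
        in_slice = np.abs(field.z_coords - centers[s]) <= dz / 2.0 + 1e-9
        sub = g[:, :, in_slice]
        if mask is not None:
            sub = sub[mask[:, :, in_slice]]
        out[s] = sub.mean()
    return out


# ---------------------------------------------------------------------------
# Signal model
# ---------------------------------------------------------------------------

def through_slice_attenuation(g_residual, params: AcquisitionParams,
                              profile: str = "rect"):
    """Gradient-echo attenuation from through-slice dephasing, in [0, 1].

    For an ideal rectangular slice profile the intravoxel phase dispersion
    across the slice gives A = |sin(pi*u)/(pi*u)| with the dimensionless
    dephasing u = gamma_bar * g * TE * dz (g residual gradient in mT/m, TE
    in s, dz in m).  A Gaussian-profile alternative, A = exp(-(pi*u)^2/6),
    matches the rect model to second order in u and is available for
    robustness checks.
    """
    g = np.asarray(g_residual, dtype=float)
    u = GAMMA_BAR_HZ_PER_MT * g * (params.te / 1000.0) * (
        params.slice_thickness / 1000.0)
    if profile == "rect":
        a = np.abs(np.sinc(u))
    elif profile == "gaussian":
        a = np.exp(-((np.pi * u) ** 2) / 6.0)
    else:
        raise ValueError("profile must be 'rect' or 'gaussian'")
    if np.isscalar(g_residual):
        return float(a)
    return a


def simulate_reference_scan(phantom: PhantomSpec, field: FieldSpec | FieldMap,
                            grid: ZShimGrid, params: AcquisitionParams,
                            noise: NoiseSpec = NOISELESS,
                            profile: str = "rect") -> SimulatedReference:
    """Simulate the z-shim reference acquisition (one volume per step).

    Volume ``k`` attenuates each slice by A(g_true(slice) - grid value k);
    i.i.d. Gaussian image noise is added on top.  The per-slice true
    gradients and the ground-truth optimal indices (nearest grid entries)
    are returned alongside the stack.
    """
    vol, mask = make_phantom(phantom)
    if phantom.matrix[2] != params.n_slices:
        raise ValueError("phantom slice count must equal params.n_slices")
    g_true = true_slice_gradients(field, params, mask=mask)
    residual = g_true[:, None] - grid.values[None, :]  # [slice, step]
    atten = through_slice_attenuation(residual, params, profile=profile)
    data = vol[:, :, :, None] * atten[None, None, :, :]
    if noise.sigma_image > 0:
        rng = np.random.default_rng(noise.seed)
        data = data + rng.normal(0.0, noise.sigma_image, size=data.shape)
    data = np.clip(data, 0.0, None)
    stack = ReferenceStack(data=data, grid=grid, params=params)
    return SimulatedReference(stack=stack, mask=mask, g_true=g_true,
                              true_indices=grid.nearest_index(g_true))


def simulate_timeseries(phantom: PhantomSpec, field: FieldSpec | FieldMap,
                        selection: ZShimSelection, n_volumes: int,
                        params: AcquisitionParams,
                        noise: NoiseSpec = NOISELESS,
                        spikes: Optional[dict] = None,
                        profile: str = "rect") -> np.ndarray:
    """Simulate an EPI time series under a given z-shim selection.

    Volume ``t`` is phantom * A(g_true - g_selected) * (1 + drift*t) plus
    Gaussian noise.  ``spikes`` maps volume indices to amplitudes in units
    of ``sigma_image`` added uniformly to that volume (for censoring tests).
    """
    if selection.n_slices != params.n_slices:
        raise ValueError("selection must have one index per slice")
    vol, mask = make_phantom(phantom)
    g_true = true_slice_gradients(field, params, mask=mask)
    atten = through_slice_attenuation(g_true - selection.gradients, params,
                                      profile=profile)
    base = vol * atten[None, None, :]
    t = np.arange(n_volumes, dtype=float)
    series = base[:, :, :, None] * (1.0 + noise.drift_per_volume * t)
    if noise.sigma_image > 0:
        rng = np.random.default_rng(noise.seed)
        series = series + rng.normal(0.0, noise.sigma_image, size=series.shape)
    if spikes:
        for t_idx, amp in spikes.items():
            series[:, :, :, int(t_idx)] += amp * noise.sigma_image
    return series


def simulate_fieldmap_phases(fm: FieldMap, echo_times_ms,
                             noise: NoiseSpec = NOISELESS,
                             phi0: float = 0.0) -> PhaseSeries:
    """Gradient-echo phase images from a frequency-offset map.

    phi(TE) = wrap(2*pi*dnu*TE + phi0 + Gaussian phase noise), one 3D phase
    volume per echo.
    """
    tes = np.asarray(echo_times_ms, dtype=float)
    if tes.size < 2:
        raise ValueError("at least 2 echoes are required")
    phases = 2.0 * np.pi * fm.dnu[..., None] * (tes / 1000.0) + phi0
    if noise.sigma_phase_rad > 0:
        rng = np.random.default_rng(noise.seed + 1)
        phases = phases + rng.normal(0.0, noise.sigma_phase_rad,
                                     size=phases.shape)
    return PhaseSeries(phases=wrap_phase(phases), echo_times=tes)


def ernst_angle(tr_ms: float, t1_ms: float) -> float:
    """Ernst angle (degrees) maximizing spoiled gradient-echo signal:
    arccos(exp(-TR/T1))."""
    if tr_ms <= 0 or t1_ms <= 0:
        raise ValueError("TR and T1 must be strictly positive")
    return float(np.degrees(np.arccos(np.exp(-tr_ms / t1_ms))))


def demo_per_slice_indices(grid: ZShimGrid, n_slices: int,
                           amplitude_steps: int = 3) -> np.ndarray:
    """Deterministic per-slice 1-based indices for on-grid test scenarios.

    A triangle wave around the neutral index with unit steps between
    neighboring slices, peaking ``amplitude_steps`` away from neutral —
    a grid-resolvable stand-in for the periodic rostro-caudal dropout
    pattern along the cord (most in-vivo slices sit within three steps of
    neutral).  Because adjacent slices differ by at most one step, the
    slab-averaged gradient seen by the field-map fit still rounds to the
    correct index on every slice.
    """
    if amplitude_steps < 0 or amplitude_steps > grid.neutral_index - 1:
        raise ValueError("amplitude_steps must fit inside the grid")
    period = max(4 * amplitude_steps, 1)
    s = np.arange(n_slices) % period
    tri = np.minimum(s, period - s)  # 0..2A..0
    offsets = tri - amplitude_steps
    return grid.neutral_index + offsets


def snap_to_grid(g_per_slice, grid: ZShimGrid) -> tuple:
    """Snap per-slice gradients onto exact grid values (for on-grid truth
    scenarios in tests and simulations)."""
    idx = grid.nearest_index(np.asarray(g_per_slice, dtype=float))
    return tuple(grid.gradient_for_index(idx))
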