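"""EPI-reference-based automated z-shim selection.

The z-shim reference scan acquires one EPI volume per candidate
compensation value.  Within a spinal-cord mask, the mean signal intensity
is extracted for every (slice, compensation) pair; the compensation that
maximizes the per-slice cord intensity is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import AcquisitionParams, ZShimGrid
from .selection import ZShimSelection, selection_from_indices

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceStack:
    """4D z-shim reference acquisition: axes [x, y, slice, step].

    Volume ``k`` (0-based axis position ``k``) was acquired with the
    compensation gradient of 1-based grid index ``k + 1``.
    """

    data: np.ndarray
    grid: ZShimGrid
    params: AcquisitionParams

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 4:
            raise ValueError(f"reference stack must be 4D, got {data.ndim}D")
        if data.shape[3] != self.grid.n_steps:
            raise ValueError(
                f"stack has {data.shape[3]} volumes but grid has "
                f"{self.grid.n_steps} steps"
            )
        if data.shape[2] != self.params.n_slices:
            raise ValueError(
                f"stack has {data.shape[2]} slices but params declare "
                f"{self.params.n_slices}"
            )
        if np.any(data < 0):
            raise ValueError("reference intensities must be non-negative")


def validate_mask(mask: np.ndarray, shape3d: tuple) -> np.ndarray:
    """Check a 3D binary cord mask and return it as boolean."""
    mask = np.asarray(mask)
    if mask.shape != tuple(shape3d):
        raise ValueError(f"mask shape {mask.shape} does not match data {shape3d}")
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask must be binary (values in {0, 1})")
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    return mask


def mean_reference_volume(stack: ReferenceStack) -> np.ndarray:
    """Voxelwise mean across all compensation steps, shape [x, y, slice].

    This is the image the operator (or an upstream segmentation tool) uses
    to delineate the cord: averaging over all steps avoids biasing the
    anatomy toward any one compensation or respiratory state.
    """
    return stack.data.mean(axis=3)


def intensity_matrix(stack: ReferenceStack, mask: np.ndarray) -> np.ndarray:
    """Mean cord intensity per (slice, step); shape [n_slices, n_steps].

    Slices without any mask voxel yield NaN rows (an explicit missing
    flag — never 0, which would fake an argmax winner).
    """
    mask = validate_mask(mask, stack.data.shape[:3])
    n_slices, n_steps = stack.params.n_slices, stack.grid.n_steps
    out = np.full((n_slices, n_steps), np.nan)
    for s in range(n_slices):
        m = mask[:, :, s]
        if m.any():
            out[s, :] = stack.data[:, :, s, :][m].mean(axis=0)
    return out


def select_zshim_epi(matrix: np.ndarray, grid: ZShimGrid,
                     params: AcquisitionParams | None = None) -> ZShimSelection:
    """Pick, per slice, the compensation step of maximum cord intensity.

    Exact intensity ties resolve toward the smaller |gradient|, then the
    lower index (minimal perturbation when the data cannot discriminate).
    All-NaN rows (empty-mask slices) fall back to the neutral index with a
    warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != grid.n_steps:
        raise ValueError(
            f"matrix must be [n_slices, {grid.n_steps}], got {matrix.shape}"
        )
    if params is None:
        params = AcquisitionParams(n_slices=matrix.shape[0])
    vals = grid.values
    tie_rank = np.abs(vals) + np.arange(grid.n_steps) * 1e-12
    indices = np.empty(matrix.shape[0], dtype=int)
    warnings = []
    for s, row in enumerate(matrix):
        if np.all(np.isnan(row)):
            indices[s] = grid.neutral_index
            msg = f"slice {s}: empty mask, falling back to neutral index"
            warnings.append(msg)
            logger.warning(msg)
            continue
        best = np.nanmax(row)
        candidates = np.flatnonzero(row == best)
        indices[s] = candidates[np.argmin(tie_rank[candidates])] + 1
    return selection_from_indices(indices, grid, params, method="epi",
                                  warnings=tuple(warnings))


def select_from_stack(stack: ReferenceStack, mask: np.ndarray) -> ZShimSelection:
    """Full EPI-based pipeline: intensity matrix then per-slice argmax."""
    matrix = intensity_matrix(stack, mask)
    return select_zshim_epi(matrix, stack.grid, stack.params)
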