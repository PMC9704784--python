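"""Per-slice z-shim selection record shared by all selection methods."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import AcquisitionParams, ZShimGrid

METHODS = ("epi", "fm_fit", "fm_histogram", "manual", "neutral")


@dataclass(frozen=True)
class ZShimSelection:
    """One chosen grid index per EPI slice, with derived gradients/moments.

    ``indices`` are 1-based grid indices; ``gradients`` (mT/m) and
    ``moments`` (mT/m*ms) are the corresponding compensation values;
    ``method`` records which procedure produced the selection.  Per-slice
    fallbacks (empty mask, failed fit, clamped gradient) are listed in
    ``warnings``.
    """

    indices: np.ndarray
    gradients: np.ndarray
    moments: np.ndarray
    method: str
    grid: ZShimGrid
    warnings: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "gradients", np.asarray(self.gradients, dtype=float))
        object.__setattr__(self, "moments", np.asarray(self.moments, dtype=float))
        n = self.indices.shape[0]
        if self.gradients.shape != (n,) or self.moments.shape != (n,):
            raise ValueError("indices, gradients and moments must have equal length")

    @property
    def n_slices(self) -> int:
        return int(self.indices.shape[0])


def selection_from_indices(
    indices,
    grid: ZShimGrid,
    params: AcquisitionParams,
    method: str,
    warnings: tuple = (),
) -> ZShimSelection:
    """Build a :class:`ZShimSelection` from 1-based indices alone."""
    idx = np.asarray(indices, dtype=int)
    gradients = grid.gradient_for_index(idx)
    moments = gradients * params.te
    return ZShimSelection(
        indices=idx,
        gradients=gradients,
        moments=moments,
        method=method,
        grid=grid,
        warnings=tuple(warnings),
    )
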