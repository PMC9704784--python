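"""Discrete z-shim compensation grid and index/gradient/moment arithmetic.

A z-shim sequence can apply one of a small, fixed set of compensation
gradients along the slice axis.  The grid is equidistant and symmetric
about zero, so an odd number of steps guarantees a "neutral" entry with no
compensation.  Indices are 1-based throughout, matching how scanner
operators and the selection text file refer to the reference-scan volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_ORDERINGS = ("descending", "ascending")


@dataclass(frozen=True)
class ZShimGrid:
    """Equidistant, zero-symmetric set of compensable field gradients.

    Parameters
    ----------
    n_steps:
        Number of compensation values; must be odd so that an exact zero
        (neutral) value exists.
    g_max:
        Magnitude of the gradient at the first grid value, mT/m.  The grid
        spans ``[+g_max, -g_max]`` for descending ordering.
    ordering:
        ``"descending"`` places ``+g_max`` at index 1 (the default, matching
        a reference scan sweeping from positive to negative compensation);
        ``"ascending"`` reverses this.
    """

    n_steps: int = 21
    g_max: float = 0.21
    ordering: str = "descending"

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.n_steps % 2 == 0:
            raise ValueError(
                f"n_steps must be a positive odd integer, got {self.n_steps}"
            )
        if not np.isfinite(self.g_max) or self.g_max < 0:
            raise ValueError(f"g_max must be finite and non-negative, got {self.g_max}")
        if self.ordering not in _ORDERINGS:
            raise ValueError(f"ordering must be one of {_ORDERINGS}, got {self.ordering!r}")

    @property
    def spacing(self) -> float:
        """Gradient increment between adjacent grid values, mT/m."""
        if self.n_steps == 1:
            return 0.0
        return 2.0 * self.g_max / (self.n_steps - 1)

    @property
    def neutral_index(self) -> int:
        """1-based index of the zero-compensation grid entry."""
        return (self.n_steps + 1) // 2

    @property
    def values(self) -> np.ndarray:
        """All grid gradients in index order (index 1 first), mT/m."""
        idx = np.arange(1, self.n_steps + 1)
        return self.gradient_for_index(idx)

    def gradient_for_index(self, index):
        """Compensation gradient (mT/m) at a 1-based ``index``.

        Accepts scalars or integer arrays.  The value at ``neutral_index``
        is exactly 0.
        """
        idx = np.asarray(index)
        if np.any(idx < 1) or np.any(idx > self.n_steps):
            raise IndexError(
                f"index must lie in [1, {self.n_steps}], got {index}"
            )
        # Anchor on the neutral index so the zero value is exact in floats.
        offset = (idx - self.neutral_index).astype(float)
        if self.ordering == "descending":
            g = -offset * self.spacing
        else:
            g = offset * self.spacing
        g = g + 0.0  # normalize -0.0 at the neutral index
        if np.isscalar(index):
            return float(g)
        return g

    def nearest_index(self, g):
        """1-based grid index whose gradient is closest to ``g`` (mT/m).

        Out-of-range gradients clamp to the end index (the scanner can only
        apply grid values) with a logged warning.  Exact midpoint ties
        resolve toward the value of smaller magnitude, then the lower index.
        """
        g_arr = np.atleast_1d(np.asarray(g, dtype=float))
        if not np.all(np.isfinite(g_arr)):
            raise ValueError("gradients must be finite")
        vals = self.values
        half = self.spacing / 2.0 if self.n_steps > 1 else 0.0
        lo, hi = vals.min(), vals.max()
        clamped = (g_arr > hi + half) | (g_arr < lo - half)
        if np.any(clamped):
            logger.warning(
                "%d gradient value(s) outside the grid range [%g, %g] mT/m; "
                "clamped to the nearest end of the grid",
                int(clamped.sum()), lo, hi,
            )
        dist = np.abs(vals[None, :] - g_arr[:, None])
        dmin = dist.min(axis=1, keepdims=True)
        tol = 1e-12 * max(1.0, float(np.abs(vals).max(initial=0.0)))
        tie = dist <= dmin + tol
        # Among tied candidates prefer the smaller |gradient|, then the
        # lower index: rank by (|value|, position) and mask non-candidates.
        rank = np.abs(vals)[None, :] + np.arange(self.n_steps)[None, :] * tol
        rank = np.where(tie, rank, np.inf)
        idx = rank.argmin(axis=1) + 1
        if np.isscalar(g):
            return int(idx[0])
        return idx

    def moment_for_index(self, index, params: "AcquisitionParams"):
        """Gradient moment (mT/m*ms) of the compensation pulse at ``index``.

        The grid stores the field gradient to be compensated; the pulsed
        moment scales with the echo time, so the same index is valid at any
        TE.
        """
        g = self.gradient_for_index(index)
        return g * params.te


@dataclass(frozen=True)
class AcquisitionParams:
    """EPI protocol parameters needed for selection and simulation.

    te: echo time, ms.  slice_thickness: EPI slice thickness, mm.
    n_slices: number of EPI slices.  slice_spacing_fm: sampling interval of
    the field map along the EPI slice axis, mm.
    """

    te: float = 40.0
    slice_thickness: float = 5.0
    n_slices: int = 24
    slice_spacing_fm: float = 1.0

    def __post_init__(self) -> None:
        for name in ("te", "slice_thickness", "slice_spacing_fm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.n_slices > 0:
            raise ValueError("n_slices must be strictly positive")

    @property
    def slice_centers(self) -> np.ndarray:
        """Slice-center coordinates along the slice axis, mm.

        Slice ``s`` is centered at ``(s + 1/2) * slice_thickness``, i.e. the
        bottom face of slice 0 sits at z = 0.
        """
        return (np.arange(self.n_slices) + 0.5) * self.slice_thickness
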