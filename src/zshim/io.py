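"""File I/O: NIfTI volumes, scanner selection text files, JSON records,
CSV tables and YAML configuration."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .grid import AcquisitionParams, ZShimGrid
from .selection import ZShimSelection, selection_from_indices


class ZShimIOError(Exception):
    """Raised for unreadable, malformed or dimensionally wrong inputs."""


def read_nifti(path, expected_ndim: int | None = None):
    """Load a NIfTI file; returns (data, voxel_sizes, affine).

    The EPI slice axis is assumed to be array axis 3 (axis 2 in 0-based
    terms); inputs not in this orientation must be reoriented upstream.
    Both plain ``.nii`` and gzipped ``.nii.gz`` files are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise ZShimIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise ZShimIOError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=float)
    if expected_ndim is not None and data.ndim != expected_ndim:
        raise ZShimIOError(
            f"{path}: expected a {expected_ndim}D image, got {data.ndim}D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:min(data.ndim, 3)])
    return data, zooms, img.affine


def write_nifti(data: np.ndarray, voxel_size, path, z0: float = 0.0) -> None:
    """Write an array as NIfTI with a diagonal affine.

    ``z0`` places the first voxel center along the slice axis (mm), so that
    EPI stacks and field maps written by the simulator share one frame.
    """
    data = np.asarray(data)
    affine = np.eye(4)
    for i, v in enumerate(voxel_size[:3]):
        affine[i, i] = v
    affine[2, 3] = z0
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def write_selection_txt(selection: ZShimSelection, path) -> None:
    """Write the scanner text file: one 1-based index per line, LF-ended."""
    Path(path).write_text(
        "".join(f"{int(i)}\n" for i in selection.indices))


def read_selection_txt(path, grid: ZShimGrid,
                       params: AcquisitionParams,
                       method: str = "manual") -> ZShimSelection:
    """Read a scanner selection text file back into a selection record."""
    lines = Path(path).read_text().splitlines()
    indices = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            indices.append(int(line))
        except ValueError as exc:
            raise ZShimIOError(
                f"{path}:{lineno}: not an integer index: {line!r}") from exc
    if len(indices) != params.n_slices:
        raise ZShimIOError(
            f"{path}: {len(indices)} indices for {params.n_slices} slices")
    return selection_from_indices(indices, grid, params, method=method)


def selection_to_json(selection: ZShimSelection, path) -> None:
    """Write the canonical JSON selection record."""
    record = {
        "indices": [int(i) for i in selection.indices],
        "gradients_mT_per_m": [float(g) for g in selection.gradients],
        "moments_mT_per_m_ms": [float(m) for m in selection.moments],
        "method": selection.method,
        "grid": {
            "n_steps": selection.grid.n_steps,
            "g_max_mT_per_m": selection.grid.g_max,
            "ordering": selection.grid.ordering,
        },
        "warnings": list(selection.warnings),
    }
    Path(path).write_text(json.dumps(record, indent=2) + "\n")


def selection_from_json(path, params: AcquisitionParams) -> ZShimSelection:
    record = json.loads(Path(path).read_text())
    grid = ZShimGrid(
        n_steps=record["grid"]["n_steps"],
        g_max=record["grid"]["g_max_mT_per_m"],
        ordering=record["grid"]["ordering"],
    )
    return selection_from_indices(record["indices"], grid, params,
                                  method=record["method"],
                                  warnings=tuple(record.get("warnings", ())))


def intensity_matrix_to_csv(matrix: np.ndarray, path) -> None:
    """Write the [n_slices x n_steps] intensity matrix as CSV (1-based
    slice rows and step columns)."""
    n_slices, n_steps = matrix.shape
    df = pd.DataFrame(
        matrix,
        index=pd.RangeIndex(1, n_slices + 1, name="slice"),
        columns=[f"step_{k}" for k in range(1, n_steps + 1)],
    )
    df.to_csv(path)


def slice_fits_to_csv(fits, path) -> None:
    """Per-slice fit table: slice, gx, gy, gz, offset, n_voxels, rms."""
    rows = [{
        "slice": f.slice_index + 1,
        "gx_mT_per_m": f.gx,
        "gy_mT_per_m": f.gy,
        "gz_mT_per_m": f.gz,
        "offset_hz": f.offset_hz,
        "n_voxels": f.n_voxels,
        "residual_rms_hz": f.residual_rms,
        "valid": f.valid,
    } for f in fits]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML configuration file into a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ZShimIOError(f"{path}: config must be a YAML mapping")
    return cfg


def grid_from_config(cfg: dict) -> ZShimGrid:
    return ZShimGrid(
        n_steps=int(cfg.get("n_steps", 21)),
        g_max=float(cfg.get("g_max_mT_per_m", 0.21)),
        ordering=cfg.get("ordering", "descending"),
    )


def params_from_config(cfg: dict) -> AcquisitionParams:
    return AcquisitionParams(
        te=float(cfg.get("te_ms", 40.0)),
        slice_thickness=float(cfg.get("slice_thickness_mm", 5.0)),
        n_slices=int(cfg.get("n_slices", 24)),
        slice_spacing_fm=float(cfg.get("slice_spacing_fm_mm", 1.0)),
    )
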