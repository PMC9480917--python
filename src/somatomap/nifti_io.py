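"""Optional NIfTI export of simulated runs and voxelwise maps.

The synthetic patch is a 2-D grid; volumes are written as single-slice
3-D (maps) or 4-D (runs) images with the voxel spacing in mm.  Requires
nibabel.
"""

from __future__ import annotations

import numpy as np


def _affine(spacing_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = spacing_mm
    return aff


def export_run_nifti(run, path) -> None:
    """Write a simulated run as a 4-D NIfTI (rows x cols x 1 x TRs)."""
    import nibabel as nib

    rows, cols = run.patch.grid_shape
    data = run.values.reshape(rows, cols, 1, -1).astype(np.float32)
    img = nib.Nifti1Image(data, _affine(run.patch.spacing_mm))
    img.header.set_zooms((run.patch.spacing_mm, run.patch.spacing_mm, 1.0, run.tr))
    nib.save(img, str(path))


def export_map_nifti(values, grid_shape, path, spacing_mm: float = 1.5) -> None:
    """Write a per-voxel map (flat or grid-shaped) as a single-slice NIfTI."""
    import nibabel as nib

    data = np.asarray(values, dtype=np.float32).reshape(*grid_shape, 1)
    nib.save(nib.Nifti1Image(data, _affine(spacing_mm)), str(path))
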