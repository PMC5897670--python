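"""Optional volume utilities: spherical-ROI extraction and global-mean scaling.

These operate on preprocessed 4-D volumes; no motion correction, smoothing
or template normalization is performed here — inputs are assumed fully
preprocessed, and ROI centers are interpreted in the volume's own
world-space millimeters via its affine (no atlas-space conversion is
attempted).
"""

from __future__ import annotations

from typing import Sequence, Tuple, Union

import numpy as np

try:  # nibabel images are accepted but not required
    import nibabel as nib
except Exception:  # pragma: no cover
    nib = None

__all__ = ["extract_sphere_roi", "scale_by_global_mean"]


def _as_array_affine(volume_4d, affine):
    if nib is not None and hasattr(volume_4d, "get_fdata"):
        data = np.asarray(volume_4d.get_fdata())
        affine = volume_4d.affine if affine is None else affine
    else:
        data = np.asarray(volume_4d, dtype=float)
    if affine is None:
        raise ValueError("an affine is required for plain-array input")
    if data.ndim != 4:
        raise ValueError("expected a 4-D volume (x, y, z, t)")
    return data, np.asarray(affine, float)


def extract_sphere_roi(
    volume_4d,
    center_mm: Sequence[float],
    radius_mm: float = 3.0,
    affine: Union[np.ndarray, None] = None,
) -> np.ndarray:
    """Mean time series over voxels whose world-space centers lie within
    ``radius_mm`` of ``center_mm`` (boundary inclusive).

    ``volume_4d`` may be a nibabel image (affine taken from the header) or
    a plain (x, y, z, t) array with an explicit ``affine``.
    """
    data, aff = _as_array_affine(volume_4d, affine)
    nx_, ny, nz, _ = data.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx_), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).reshape(-1, 4)
    world = vox @ aff.T
    center = np.asarray(center_mm, float)
    dist = np.linalg.norm(world[:, :3] - center[None, :], axis=1)
    mask = (dist <= radius_mm + 1e-9).reshape(nx_, ny, nz)
    if not mask.any():
        raise ValueError(
            f"sphere of radius {radius_mm} mm at {tuple(center)} contains no voxels"
        )
    return data[mask].mean(axis=0)


def scale_by_global_mean(volume_4d, affine=None) -> np.ndarray:
    """Divide every voxel by the volume-wide mean of its own time point.

    Accepts a 4-D volume (or nibabel image) or a plain T x N matrix (rows
    time).  After scaling, each time point's global mean is exactly 1.
    """
    if hasattr(volume_4d, "get_fdata") or (
        isinstance(volume_4d, np.ndarray) and volume_4d.ndim == 4
    ):
        data, _ = _as_array_affine(volume_4d, affine if affine is not None
                                   else np.eye(4))
        gm = data.mean(axis=(0, 1, 2))
        if np.any(gm == 0):
            raise ValueError("zero global mean at some time point")
        return data / gm[None, None, None, :]
    data = np.asarray(volume_4d, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected a 4-D volume or a T x N matrix")
    gm = data.mean(axis=1)
    if np.any(gm == 0):
        raise ValueError("zero global mean at some time point")
    return data / gm[:, None]
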