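"""Volume resampling and fixed-bin-width discretization for feature extraction."""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

from ..types import DegenerateInputError, DoseVolume, ValidationError

__all__ = ["resample_volume", "resample_array", "discretize"]


def resample_array(grid: np.ndarray, spacing, target_mm: float, order: int = 1):
    """Trilinear resampling of a 3D array onto an isotropic grid.

    Corner-aligned: the new grid covers the same physical extent, with
    side counts ``round(extent / target) + 1``.  Returns
    ``(resampled, new_spacing)``; when the input spacing already equals
    the target on all axes the array is returned unchanged.
    """
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValidationError("volume contains non-finite values")
    if target_mm <= 0:
        raise ValidationError("target spacing must be > 0")
    spacing = np.asarray(spacing, dtype=float)
    if np.allclose(spacing, target_mm):
        return grid, np.full(3, float(target_mm))
    extent = spacing * (np.array(grid.shape) - 1)
    new_shape = np.maximum(np.round(extent / target_mm).astype(int) + 1, 2)
    coords = np.meshgrid(
        *[np.arange(new_shape[a]) * target_mm / spacing[a] for a in range(3)], indexing="ij"
    )
    out = ndimage.map_coordinates(grid, np.stack(coords), order=order, mode="nearest")
    return out, np.full(3, float(target_mm))


def resample_volume(volume: DoseVolume, spacing_mm: float) -> DoseVolume:
    """Resample a dose volume to isotropic spacing (trilinear)."""
    out, new_sp = resample_array(volume.grid, volume.spacing, spacing_mm)
    return DoseVolume(
        np.clip(out, 0.0, None),
        new_sp,
        volume.origin,
        volume.isocenter,
        prescription_dose=volume.prescription_dose,
    )


def discretize(values: np.ndarray, mask: Optional[np.ndarray] = None, bin_width: float = 1.0):
    """Fixed-bin-width gray-level discretization.

    ``level(v) = floor((v - min) / bin_width) + 1`` over in-mask voxels,
    anchored at the masked minimum so levels start at 1.  Returns
    ``(levels, n_levels)`` with out-of-mask entries set to 0.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    values = np.asarray(values, dtype=float)
    mask = np.ones(values.shape, bool) if mask is None else np.asarray(mask, bool)
    if not mask.any():
        raise DegenerateInputError("empty mask")
    vmin = values[mask].min()
    levels = np.zeros(values.shape, dtype=np.int64)
    lv = np.floor((values[mask] - vmin) / bin_width).astype(np.int64) + 1
    levels[mask] = lv
    return levels, int(lv.max())
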