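"""Standardization of 2D dose planes before metric computation.

Fixed pipeline order: resample to a 45 x 45 matrix -> zero entries below
70% of the plane maximum -> optional relative-dose normalization.  The
threshold is read as *strictly below* (ties kept) and uses each plane's
own maximum by default; a pair-shared reference maximum can be supplied.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

from .types import DegenerateInputError, DosePlane, ValidationError

__all__ = ["resample_to_grid", "threshold_low_dose", "normalize", "standardize"]

DEFAULT_GRID_N = 45
DEFAULT_THRESHOLD_FRACTION = 0.70

_ORDERS = {"bilinear": 1, "cubic": 3}


def resample_to_grid(plane: DosePlane, n: int = DEFAULT_GRID_N, method: str = "bilinear") -> DosePlane:
    """Interpolate a plane onto an ``n x n`` matrix over the same physical extent.

    Output node ``j`` maps to input coordinate ``j * (m - 1) / (n - 1)``
    (corner-aligned), so the physical extent is preserved and spacing is
    rescaled accordingly.  Bilinear interpolation reproduces the input
    exactly when ``n`` equals the input side length.
    """
    if n < 2:
        raise ValidationError("target side length must be >= 2")
    if method not in _ORDERS:
        raise ValidationError(f"unknown interpolation method {method!r}")
    m0, m1 = plane.shape
    ii = np.arange(n) * (m0 - 1) / (n - 1)
    jj = np.arange(n) * (m1 - 1) / (n - 1)
    I, J = np.meshgrid(ii, jj, indexing="ij")
    out = ndimage.map_coordinates(plane.matrix, [I, J], order=_ORDERS[method], mode="nearest")
    out = np.clip(out, 0.0, None)  # cubic can overshoot below zero
    new_spacing = plane.spacing_mm * (m0 - 1) / (n - 1)
    return DosePlane(out, spacing_mm=new_spacing, mode=plane.mode)


def threshold_low_dose(
    plane: DosePlane,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    reference_max: Optional[float] = None,
) -> DosePlane:
    """Zero every entry strictly below ``fraction`` of the maximum dose.

    ``reference_max`` substitutes a pair-shared maximum for the plane's
    own; entries at or above the cut are untouched, so the maximum is
    unchanged.
    """
    if not 0 <= fraction <= 1:
        raise ValidationError("threshold fraction must lie in [0, 1]")
    ref = plane.max_dose if reference_max is None else float(reference_max)
    if ref <= 0:
        raise DegenerateInputError("cannot threshold an all-zero plane")
    cut = fraction * ref
    out = np.where(plane.matrix < cut, 0.0, plane.matrix)
    return plane.copy_with(out)


def normalize(plane: DosePlane, mode: str = "relative", reference_max: Optional[float] = None) -> DosePlane:
    """Convert a plane between absolute-Gy and relative-fraction scales.

    ``absolute`` returns the plane unchanged.  ``relative`` divides by
    ``reference_max`` (the plane's own maximum when unset) and flags the
    result as relative.
    """
    if mode == "absolute":
        return plane.copy_with(plane.matrix.copy(), mode="absolute")
    if mode != "relative":
        raise ValidationError(f"unknown normalization mode {mode!r}")
    ref = plane.max_dose if reference_max is None else float(reference_max)
    if ref <= 0:
        raise DegenerateInputError("normalization reference maximum must be > 0")
    return plane.copy_with(plane.matrix / ref, mode="relative")


def standardize(
    plane: DosePlane,
    n: int = DEFAULT_GRID_N,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    mode: str = "absolute",
    reference_max: Optional[float] = None,
    method: str = "bilinear",
) -> DosePlane:
    """Full standardization pipeline: resample -> threshold -> normalize.

    Idempotent at fixed ``n``/fraction/mode: a standardized plane passes
    through unchanged.
    """
    out = resample_to_grid(plane, n=n, method=method)
    out = threshold_low_dose(out, fraction=threshold_fraction)
    return normalize(out, mode=mode, reference_max=reference_max)
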