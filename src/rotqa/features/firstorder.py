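"""The 18 standard first-order intensity statistics.

Entropy and uniformity are computed on the fixed-bin-width discretized
histogram; everything else on raw in-mask values.  Skewness and kurtosis
are the population (biased) moment ratios, with kurtosis *not* excess-
corrected; variance is the population variance.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..types import DegenerateInputError
from .preprocessing import discretize

__all__ = ["FIRSTORDER_NAMES", "first_order_features"]

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)

_EPS = np.spacing(1.0)


def first_order_features(
    values: np.ndarray,
    mask: Optional[np.ndarray] = None,
    voxel_volume_mm3: float = 1.0,
    bin_width: float = 25.0,
) -> dict[str, float]:
    """Compute the 18 first-order descriptors over in-mask voxels."""
    values = np.asarray(values, dtype=float)
    mask = np.ones(values.shape, bool) if mask is None else np.asarray(mask, bool)
    if not mask.any():
        raise DegenerateInputError("empty mask")
    v = values[mask]

    levels, _ = discretize(values, mask, bin_width)
    counts = np.bincount(levels[mask])[1:]
    p = counts[counts > 0] / v.size

    mean = float(v.mean())
    var = float(v.var())  # population
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]
    sd = np.sqrt(var)
    if var > 0:
        skew = float(((v - mean) ** 3).mean() / sd**3)
        kurt = float(((v - mean) ** 4).mean() / var**2)
    else:
        skew, kurt = 0.0, 0.0

    return {
        "Energy": float((v**2).sum()),
        "TotalEnergy": float(voxel_volume_mm3 * (v**2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()) if p.size > 1 else 0.0,
        "Minimum": float(v.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(v.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "RobustMeanAbsoluteDeviation": (
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((v**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }
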