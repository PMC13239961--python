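"""Radiomic and dosiomic feature extraction.

Two fixed feature censuses:

* **radiomics** — 18 first-order + 14 shape features from the original,
  unfiltered image volume and its structure mask: 32 features.
* **dosiomics** — 18 first-order + 75 texture features
  (GLCM 24 / GLRLM 16 / GLSZM 16 / GLDM 14 / NGTDM 5) on the original
  dose volume, plus the same 93 on each of the 8 single-level wavelet
  sub-bands (744): 837 features.  Shape features are not re-extracted
  from dose (identical to the imaging ones by construction).

Volumes are resampled to isotropic spacing and discretized with a fixed
bin width (25 intensity units for images, 1 Gy for dose) before the
texture matrices are built.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from ..types import DoseVolume, StructureMask, ValidationError
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .preprocessing import discretize, resample_array, resample_volume
from .shape import SHAPE_NAMES, shape_features
from .texture import TEXTURE_CATEGORIES, texture_features
from .wavelet import WAVELET_BANDS, wavelet_bands

__all__ = [
    "ExtractionConfig",
    "FeatureVector",
    "extract_radiomics",
    "extract_dosiomics",
    "first_order_features",
    "shape_features",
    "texture_features",
    "wavelet_bands",
    "resample_volume",
    "discretize",
    "FIRSTORDER_NAMES",
    "SHAPE_NAMES",
    "TEXTURE_CATEGORIES",
    "WAVELET_BANDS",
]

_ALL_CATEGORIES = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm", "wavelet")


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction settings shared by radiomic and dosiomic workflows."""

    resample_spacing_mm: float = 1.0
    bin_width: float = 1.0
    wavelet_name: str = "coif1"
    enabled_categories: tuple[str, ...] = _ALL_CATEGORIES

    def __post_init__(self) -> None:
        if self.resample_spacing_mm <= 0 or self.bin_width <= 0:
            raise ValidationError("spacing and bin_width must be > 0")
        for c in self.enabled_categories:
            if c not in _ALL_CATEGORIES:
                raise ValidationError(f"unknown feature category {c!r}")

    @classmethod
    def for_images(cls, **kw) -> "ExtractionConfig":
        kw.setdefault("bin_width", 25.0)
        return cls(**kw)

    @classmethod
    def for_dose(cls, **kw) -> "ExtractionConfig":
        kw.setdefault("bin_width", 1.0)
        return cls(**kw)


@dataclass
class FeatureVector:
    """Ordered named feature values from one extraction."""

    names: tuple[str, ...]
    values: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValidationError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ValidationError(f"non-finite feature values: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.names)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def _coerce(volume, mask, default_spacing=1.0):
    if isinstance(volume, DoseVolume):
        grid, spacing = volume.grid, volume.spacing
    else:
        grid = np.asarray(volume, dtype=float)
        spacing = np.full(3, float(default_spacing))
    m = mask.grid if isinstance(mask, StructureMask) else np.asarray(mask, bool)
    if m is not None and m.shape != grid.shape:
        raise ValidationError("volume and mask shapes differ")
    return grid, spacing, m


def _texture_block(grid, mask, config: ExtractionConfig, prefix: str) -> tuple[list, list]:
    levels, _ = discretize(grid, mask, config.bin_width)
    names: list[str] = []
    values: list[float] = []
    for cat in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"):
        if cat not in config.enabled_categories:
            continue
        feats = texture_features(levels, cat)
        for fname in TEXTURE_CATEGORIES[cat]:
            names.append(f"{prefix}{cat}_{fname}")
            values.append(feats[fname])
    return names, values


def _firstorder_block(grid, mask, spacing, config, prefix: str) -> tuple[list, list]:
    feats = first_order_features(
        grid, mask, voxel_volume_mm3=float(np.prod(spacing)), bin_width=config.bin_width
    )
    names = [f"{prefix}firstorder_{n}" for n in FIRSTORDER_NAMES]
    return names, [feats[n] for n in FIRSTORDER_NAMES]


def extract_radiomics(
    volume: Union[DoseVolume, np.ndarray],
    mask: Union[StructureMask, np.ndarray],
    config: Optional[ExtractionConfig] = None,
    spacing_mm: Optional[float] = None,
) -> FeatureVector:
    """32 radiomic features: 18 first-order + 14 shape, original image only."""
    config = config or ExtractionConfig.for_images()
    grid, spacing, m = _coerce(volume, mask, spacing_mm or config.resample_spacing_mm)
    grid, new_sp = resample_array(grid, spacing, config.resample_spacing_mm)
    m_f, _ = resample_array(np.asarray(m, float), spacing, config.resample_spacing_mm)
    m = m_f >= 0.5

    names, values = _firstorder_block(grid, m, new_sp, config, "radiomics_")
    sfeats = shape_features(m, new_sp)
    names += [f"radiomics_shape_{n}" for n in SHAPE_NAMES]
    values += [sfeats[n] for n in SHAPE_NAMES]
    return FeatureVector(tuple(names), np.array(values), source="radiomics")


def extract_dosiomics(
    dose_volume: Union[DoseVolume, np.ndarray],
    mask: Union[StructureMask, np.ndarray, None] = None,
    config: Optional[ExtractionConfig] = None,
    spacing_mm: Optional[float] = None,
) -> FeatureVector:
    """Dosiomic features from a 3D dose volume (837 with all categories).

    ``mask=None`` uses the whole dose field (dose > 0).  Categories can
    be disabled through the config; the full census is 18 first-order +
    75 texture on the original volume + 93 per wavelet band.
    """
    config = config or ExtractionConfig.for_dose()
    if mask is None:
        grid0 = dose_volume.grid if isinstance(dose_volume, DoseVolume) else np.asarray(dose_volume)
        mask = grid0 > 0
    grid, spacing, m = _coerce(dose_volume, mask, spacing_mm or config.resample_spacing_mm)
    grid, new_sp = resample_array(grid, spacing, config.resample_spacing_mm)
    m_f, _ = resample_array(np.asarray(m, float), spacing, config.resample_spacing_mm)
    m = m_f >= 0.5

    names: list[str] = []
    values: list[float] = []
    if "firstorder" in config.enabled_categories:
        n, v = _firstorder_block(grid, m, new_sp, config, "dosiomics_original_")
        names += n
        values += v
    n, v = _texture_block(grid, m, config, "dosiomics_original_")
    names += n
    values += v

    if "wavelet" in config.enabled_categories:
        bands = wavelet_bands(grid, config.wavelet_name)
        for band, bgrid in bands.items():
            prefix = f"dosiomics_wavelet-{band}_"
            if "firstorder" in config.enabled_categories:
                n, v = _firstorder_block(bgrid, m, new_sp, config, prefix)
                names += n
                values += v
            n, v = _texture_block(bgrid, m, config, prefix)
            names += n
            values += v
    return FeatureVector(tuple(names), np.array(values), source="dosiomics")
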