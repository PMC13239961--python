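"""Dose-comparison metrics: SSIM, gamma index, dose-difference pass rates, ΔV100.

SSIM follows the standard windowed formulation

    SSIM(x, y) = l(x,y)^a * c(x,y)^b * s(x,y)^g
    l = (2 μx μy + C1) / (μx² + μy² + C1)
    c = (2 δx δy + C2) / (δx² + δy² + C2)
    s = (δxy + C3) / (δx δy + C3),      C1 = (K1 L)², C2 = (K2 L)², C3 = C2/2

with a 7 x 7 uniform sliding window, sample covariance, and the scalar
score the mean of the local map — the conventions of the common
image-library implementation, which is cross-checked in the tests.  With
a = b = g = 1 the product collapses to the combined closed form

    SSIM = (2 μx μy + C1)(2 δxy + C2) / ((μx² + μy² + C1)(δx² + δy² + C2)).

The gamma index at criterion dd%/dta mm is, per scored reference point r,
the minimum over evaluated positions e within the search radius of
sqrt(|e − r|²/dta² + ΔD(e, r)²/dd²); the evaluated plane is upsampled by
bilinear interpolation for the spatial search.  Points zeroed by the
low-dose preprocessing threshold are excluded from scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .types import (
    DegenerateInputError,
    DosePlane,
    DoseVolume,
    StructureMask,
    ValidationError,
)

__all__ = [
    "SSIMParams",
    "WindowStats",
    "GammaCriteria",
    "MetricRecord",
    "ssim",
    "ssim_components",
    "gamma_map",
    "gamma_pass_rate",
    "dose_difference_pass_rate",
    "v100",
    "delta_v100",
    "score_pair",
]


# --------------------------------------------------------------------------- SSIM


@dataclass(frozen=True)
class SSIMParams:
    """Regularization and windowing parameters for SSIM."""

    K1: float = 0.01
    K2: float = 0.03
    L: Optional[float] = None  # dynamic range; None -> max of the two planes
    alpha: float = 1.0
    beta: float = 1.0
    gamma_exp: float = 1.0
    window: int = 7  # odd side length; 0 = single global window
    sample_covariance: bool = True

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValidationError("K1 and K2 must be > 0")
        if self.L is not None and self.L <= 0:
            raise ValidationError("dynamic range L must be > 0")
        if self.window < 0 or (self.window > 0 and self.window % 2 == 0):
            raise ValidationError("window must be odd or 0 (global)")

    def constants(self, data_range: float) -> tuple[float, float, float]:
        c1 = (self.K1 * data_range) ** 2
        c2 = (self.K2 * data_range) ** 2
        return c1, c2, c2 / 2.0


@dataclass(frozen=True)
class WindowStats:
    """Local first/second-order statistics of one comparison window."""

    mu_x: float
    mu_y: float
    var_x: float
    var_y: float
    cov_xy: float

    def __post_init__(self) -> None:
        if self.var_x < 0 or self.var_y < 0:
            raise ValidationError("variances must be >= 0")
        if abs(self.cov_xy) > np.sqrt(self.var_x * self.var_y) + 1e-12:
            raise ValidationError("covariance violates the Cauchy-Schwarz bound")


def ssim_components(stats: WindowStats, params: SSIMParams, data_range: float = 1.0):
    """Luminance, contrast and structure comparison terms for one window.

    The constants keep every denominator positive, so no special-casing
    is needed; ``l**alpha * c**beta * s**gamma`` equals the combined
    closed form when all exponents are 1.
    """
    c1, c2, c3 = params.constants(data_range)
    sx = np.sqrt(stats.var_x)
    sy = np.sqrt(stats.var_y)
    l = (2 * stats.mu_x * stats.mu_y + c1) / (stats.mu_x**2 + stats.mu_y**2 + c1)
    c = (2 * sx * sy + c2) / (stats.var_x + stats.var_y + c2)
    s = (stats.cov_xy + c3) / (sx * sy + c3)
    return l, c, s


def _check_pair(ref: DosePlane, ev: DosePlane) -> None:
    if ref.shape != ev.shape:
        raise ValidationError(f"plane shapes differ: {ref.shape} vs {ev.shape}")
    if not np.isclose(ref.spacing_mm, ev.spacing_mm):
        raise ValidationError("plane spacings differ")


def ssim(ref: DosePlane, ev: DosePlane, params: Optional[SSIMParams] = None):
    """SSIM between two identically preprocessed dose planes.

    Returns ``(scalar, local_map)``; the scalar is the mean of the local
    map (or the single global value when ``window == 0``).  Symmetric in
    its arguments; identical inputs give exactly 1.
    """
    params = params or SSIMParams()
    _check_pair(ref, ev)
    x = ref.matrix.astype(float)
    y = ev.matrix.astype(float)
    data_range = params.L if params.L is not None else max(x.max(), y.max())
    if data_range <= 0:
        raise DegenerateInputError("both planes are all-zero; SSIM undefined")
    c1, c2, _ = params.constants(data_range)

    win = params.window
    if win == 0:
        npix = x.size
        norm = npix / (npix - 1) if params.sample_covariance else 1.0
        ux, uy = x.mean(), y.mean()
        vx = norm * ((x * x).mean() - ux * ux)
        vy = norm * ((y * y).mean() - uy * uy)
        cxy = norm * ((x * y).mean() - ux * uy)
        ux_m, uy_m, vx_m, vy_m, cxy_m = (np.array([[v]]) for v in (ux, uy, vx, vy, cxy))
    else:
        if win > min(x.shape):
            raise ValidationError(f"window {win} larger than plane {x.shape}")
        norm = win**2 / (win**2 - 1) if params.sample_covariance else 1.0
        f = lambda a: ndimage.uniform_filter(a, size=win)
        ux_f, uy_f = f(x), f(y)
        vx_f = norm * (f(x * x) - ux_f * ux_f)
        vy_f = norm * (f(y * y) - uy_f * uy_f)
        cxy_f = norm * (f(x * y) - ux_f * uy_f)
        pad = win // 2
        crop = (slice(pad, -pad), slice(pad, -pad))
        ux_m, uy_m, vx_m, vy_m, cxy_m = (a[crop] for a in (ux_f, uy_f, vx_f, vy_f, cxy_f))

    if params.alpha == params.beta == params.gamma_exp == 1.0:
        smap = ((2 * ux_m * uy_m + c1) * (2 * cxy_m + c2)) / (
            (ux_m * ux_m + uy_m * uy_m + c1) * (vx_m + vy_m + c2)
        )
    else:
        vx_p = np.clip(vx_m, 0.0, None)
        vy_p = np.clip(vy_m, 0.0, None)
        sx, sy = np.sqrt(vx_p), np.sqrt(vy_p)
        c3 = c2 / 2.0
        l = (2 * ux_m * uy_m + c1) / (ux_m * ux_m + uy_m * uy_m + c1)
        c = (2 * sx * sy + c2) / (vx_p + vy_p + c2)
        s = (cxy_m + c3) / (sx * sy + c3)
        smap = np.sign(l) * np.abs(l) ** params.alpha
        smap = smap * np.sign(c) * np.abs(c) ** params.beta
        smap = smap * np.sign(s) * np.abs(s) ** params.gamma_exp
    return float(smap.mean()), smap


# --------------------------------------------------------------------------- gamma


@dataclass(frozen=True)
class GammaCriteria:
    """A dd%/dta-mm gamma criterion with its search configuration."""

    dd_percent: float = 2.0
    dta_mm: float = 2.0
    normalization: str = "global_reference_max"  # or "local"
    pass_threshold_percent: float = 95.0
    search_radius_factor: float = 3.0
    upsample_factor: int = 10

    def __post_init__(self) -> None:
        if self.dd_percent <= 0 or self.dta_mm <= 0:
            raise ValidationError("dd_percent and dta_mm must be > 0")
        if not 0 < self.pass_threshold_percent <= 100:
            raise ValidationError("pass threshold must lie in (0, 100]")
        if self.normalization not in ("global_reference_max", "local"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")
        if self.search_radius_factor <= 0 or self.upsample_factor < 1:
            raise ValidationError("invalid search configuration")

    @property
    def label(self) -> str:
        return f"{self.dd_percent:g}%/{self.dta_mm:g}mm"


def _upsample_plane(matrix: np.ndarray, factor: int) -> np.ndarray:
    """Corner-aligned bilinear upsampling; original nodes are reproduced exactly."""
    if factor == 1:
        return matrix.astype(float)
    n0, n1 = matrix.shape
    ii = np.arange((n0 - 1) * factor + 1) / factor
    jj = np.arange((n1 - 1) * factor + 1) / factor
    I, J = np.meshgrid(ii, jj, indexing="ij")
    return ndimage.map_coordinates(matrix.astype(float), [I, J], order=1, mode="nearest")


def gamma_map(ref: DosePlane, ev: DosePlane, criteria: Optional[GammaCriteria] = None) -> np.ndarray:
    """Gamma index at every scored reference point (NaN where unscored).

    Scored points are the reference entries left nonzero by the upstream
    low-dose threshold.  The evaluated plane is upsampled for the spatial
    search, which is limited to ``search_radius_factor * dta_mm``.
    """
    criteria = criteria or GammaCriteria()
    _check_pair(ref, ev)
    ref_max = ref.max_dose
    if ref_max <= 0:
        raise DegenerateInputError("reference plane has zero maximum")

    scored = ref.matrix > 0
    if not scored.any():
        raise DegenerateInputError("no scored points (reference all zero)")

    f = criteria.upsample_factor
    up = _upsample_plane(ev.matrix, f)
    sp_up = ref.spacing_mm / f
    radius_mm = criteria.search_radius_factor * criteria.dta_mm
    k = int(np.floor(radius_mm / sp_up))

    # squared spatial term per window offset, inf outside the search disc
    d = np.arange(-k, k + 1) * sp_up
    D2 = d[:, None] ** 2 + d[None, :] ** 2
    spatial = np.where(D2 <= radius_mm**2 + 1e-12, D2 / criteria.dta_mm**2, np.inf)

    big = np.full((up.shape[0] + 2 * k, up.shape[1] + 2 * k), np.inf)
    big[k : k + up.shape[0], k : k + up.shape[1]] = up
    windows = sliding_window_view(big, (2 * k + 1, 2 * k + 1))

    ri, rj = np.nonzero(scored)
    ref_vals = ref.matrix[ri, rj]
    if criteria.normalization == "global_reference_max":
        dd_abs = np.full(ref_vals.shape, criteria.dd_percent / 100.0 * ref_max)
    else:
        dd_abs = criteria.dd_percent / 100.0 * np.abs(ref_vals)
        dd_abs = np.where(dd_abs > 0, dd_abs, np.nan)

    out = np.full(ref.shape, np.nan)
    # chunk over scored points to bound the temporary (npts, 2k+1, 2k+1) array
    chunk = max(1, int(4e6 // max(1, (2 * k + 1) ** 2)))
    for start in range(0, ri.size, chunk):
        sl = slice(start, start + chunk)
        w = windows[ri[sl] * f, rj[sl] * f]  # (m, 2k+1, 2k+1) eval windows
        diff = w - ref_vals[sl, None, None]
        with np.errstate(invalid="ignore", over="ignore"):
            g2 = spatial[None] + (diff / dd_abs[sl, None, None]) ** 2
            out[ri[sl], rj[sl]] = np.sqrt(np.nanmin(np.where(np.isnan(g2), np.inf, g2), axis=(1, 2)))
    return out


def gamma_pass_rate(gmap: np.ndarray, criteria: Optional[GammaCriteria] = None) -> float:
    """Percent of scored points with gamma <= 1."""
    scored = np.isfinite(gmap)
    n = int(scored.sum())
    if n == 0:
        raise DegenerateInputError("gamma map contains no scored points")
    return 100.0 * float((gmap[scored] <= 1.0).sum()) / n


def dose_difference_pass_rate(
    ref: DosePlane,
    ev: DosePlane,
    dd_percent: float = 2.0,
    normalization: str = "global_reference_max",
) -> float:
    """Percent of scored points with |ΔD| within the dose-difference criterion.

    Scoring and normalization match :func:`gamma_map` with the same
    criterion, so the DD pass rate never exceeds the gamma pass rate.
    """
    if dd_percent <= 0:
        raise ValidationError("dd_percent must be > 0")
    _check_pair(ref, ev)
    ref_max = ref.max_dose
    if ref_max <= 0:
        raise DegenerateInputError("reference plane has zero maximum")
    scored = ref.matrix > 0
    if not scored.any():
        raise DegenerateInputError("no scored points")
    diff = np.abs(ev.matrix - ref.matrix)[scored]
    if normalization == "global_reference_max":
        tol = dd_percent / 100.0 * ref_max
        passing = diff <= tol
    elif normalization == "local":
        tol = dd_percent / 100.0 * ref.matrix[scored]
        passing = diff <= tol
    else:
        raise ValidationError(f"unknown normalization {normalization!r}")
    return 100.0 * float(passing.sum()) / int(scored.sum())


# --------------------------------------------------------------------------- DVH


def _check_aligned(volume: DoseVolume, mask: StructureMask) -> None:
    if volume.shape != mask.grid.shape:
        raise ValidationError("volume and mask shapes differ")


def v100(volume: DoseVolume, mask: StructureMask, prescription: float) -> float:
    """Percent of target voxels receiving at least the prescription dose."""
    if prescription <= 0:
        raise ValidationError("prescription must be > 0")
    _check_aligned(volume, mask)
    m = mask.grid
    return 100.0 * float((volume.grid[m] >= prescription).sum()) / int(m.sum())


def delta_v100(ref: DoseVolume, rot: DoseVolume, mask: StructureMask, prescription: float) -> float:
    """Coverage loss ΔV100 = V100(reference) − V100(rotated), in percentage points."""
    return v100(ref, mask, prescription) - v100(rot, mask, prescription)


# --------------------------------------------------------------------------- per-pair scoring


@dataclass
class MetricRecord:
    """All similarity scores for one (reference, perturbed) pair."""

    ssim: float
    gamma_pass: dict = field(default_factory=dict)  # label -> percent
    dd_pass: dict = field(default_factory=dict)
    delta_v100: Optional[float] = None
    angle_total_deg: float = 0.0
    n_directions: int = 0

    def __post_init__(self) -> None:
        if self.ssim > 1 + 1e-9:
            raise ValidationError("SSIM cannot exceed 1")
        for d in (self.gamma_pass, self.dd_pass):
            for v in d.values():
                if not 0 <= v <= 100:
                    raise ValidationError("pass rates must lie in [0, 100]")


DEFAULT_CRITERIA = (
    GammaCriteria(1.0, 1.0),
    GammaCriteria(1.5, 1.5),
    GammaCriteria(2.0, 2.0),
)


def score_pair(
    ref: DosePlane,
    ev: DosePlane,
    ssim_params: Optional[SSIMParams] = None,
    criteria: tuple = DEFAULT_CRITERIA,
    modes: tuple = ("rd", "ad"),
    dd_percent: float = 2.0,
    delta_v100: Optional[float] = None,
    angle_total_deg: float = 0.0,
    n_directions: int = 0,
) -> MetricRecord:
    """Score one standardized pair with SSIM, gamma and DD pass rates.

    ``rd`` normalizes each plane to its own maximum before comparison
    (relative dose); ``ad`` compares on the absolute Gy scale.  Gamma dose
    differences are normalized to the reference-plane maximum in both
    modes (global normalization).
    """
    from .preprocess import normalize

    s, _ = ssim(ref, ev, ssim_params)
    gamma_pass: dict[str, float] = {}
    dd_pass: dict[str, float] = {}
    for mode in modes:
        if mode == "rd":
            r, e = normalize(ref, "relative"), normalize(ev, "relative")
        elif mode == "ad":
            r, e = ref, ev
        else:
            raise ValidationError(f"unknown dose mode {mode!r}")
        for crit in criteria:
            gmap = gamma_map(r, e, crit)
            gamma_pass[f"{mode}_{crit.label}"] = gamma_pass_rate(gmap, crit)
        dd_pass[f"{mode}_dd{dd_percent:g}%"] = dose_difference_pass_rate(r, e, dd_percent)
    return MetricRecord(
        ssim=s,
        gamma_pass=gamma_pass,
        dd_pass=dd_pass,
        delta_v100=delta_v100,
        angle_total_deg=angle_total_deg,
        n_directions=n_directions,
    )
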