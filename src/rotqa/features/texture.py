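"""Gray-level texture-matrix features: GLCM, GLRLM, GLSZM, GLDM, NGTDM.

All matrices are built on a fixed-bin-width discretized volume (levels
starting at 1; 0 marks out-of-mask voxels) over the 13 unique 3D
directions at distance 1.  GLCM and GLRLM are computed per direction
(symmetric co-occurrence) and feature values averaged over directions;
GLSZM (26-connected zones), GLDM (dependence with tolerance alpha = 0)
and NGTDM (26-neighborhood gray-tone difference) are directionless.

Feature lists follow the IBSI-aligned standard set: 24 GLCM, 16 GLRLM,
16 GLSZM, 14 GLDM and 5 NGTDM features.  Degenerate inputs (a single
gray level, vanishing marginals) take the documented conventional
values instead of dividing by zero.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..types import DegenerateInputError

__all__ = [
    "DIRECTIONS_13",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
    "TEXTURE_CATEGORIES",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "texture_features",
]

_EPS = np.spacing(1.0)

#: the 13 unique 3D offsets at Chebyshev distance 1 (one per +/- pair)
DIRECTIONS_13 = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

GLCM_NAMES = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

TEXTURE_CATEGORIES = {
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}


def _check_input(levels: np.ndarray) -> np.ndarray:
    levels = np.asarray(levels)
    if levels.ndim != 3:
        raise DegenerateInputError("texture input must be a 3D level volume")
    if int((levels > 0).sum()) < 2:
        raise DegenerateInputError("texture matrices need at least 2 in-mask voxels")
    return levels


def _dir_slices(shape, d):
    """Source/destination slice pairs for offset ``d`` on a grid of ``shape``."""
    src, dst = [], []
    for dim, step in zip(shape, d):
        if step == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif step > 0:
            src.append(slice(0, dim - step))
            dst.append(slice(step, dim))
        else:
            src.append(slice(-step, dim))
            dst.append(slice(0, dim + step))
    return tuple(src), tuple(dst)


# ----------------------------------------------------------------------- GLCM


def _glcm_matrix(levels: np.ndarray, d, n_levels: int) -> np.ndarray:
    src, dst = _dir_slices(levels.shape, d)
    a = levels[src].ravel()
    b = levels[dst].ravel()
    ok = (a > 0) & (b > 0)
    a, b = a[ok], b[ok]
    P = np.bincount((a - 1) * n_levels + (b - 1), minlength=n_levels * n_levels).reshape(
        n_levels, n_levels
    ).astype(float)
    return P + P.T  # symmetric co-occurrence


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    total = P.sum()
    p = P / total
    present = np.nonzero(p.sum(axis=1) > 0)[0]
    i_vals = (present + 1).astype(float)
    p = p[np.ix_(present, present)]
    Ng = len(present)
    px = p.sum(axis=1)
    I, J = np.meshgrid(i_vals, i_vals, indexing="ij")

    mu = float((px * i_vals).sum())  # symmetric: mu_x == mu_y
    sigma2 = float((px * (i_vals - mu) ** 2).sum())
    sigma = np.sqrt(sigma2)

    # difference and sum distributions
    k_diff = np.arange(0, int(i_vals[-1] - i_vals[0]) + 1, dtype=float)
    p_diff = np.bincount(np.abs(I - J).astype(int).ravel(), weights=p.ravel(), minlength=k_diff.size)
    k_sum = np.arange(int(2 * i_vals[0]), int(2 * i_vals[-1]) + 1, dtype=float)
    p_sum = np.bincount(
        (I + J).astype(int).ravel() - int(2 * i_vals[0]), weights=p.ravel(), minlength=k_sum.size
    )

    da = float((p_diff * k_diff).sum())
    nz = p > 0
    joint_entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    pxy = np.outer(px, px)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz] + _EPS)).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())

    if sigma2 > 0:
        corr = float(((p * I * J).sum() - mu * mu) / sigma2)
    else:
        corr = 1.0

    # MCC: second largest eigenvalue of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) px(k))
    if Ng > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            Q = (p / px[:, None]) @ (p / px[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(np.clip(eig[-2], 0.0, None)))
    else:
        mcc = 1.0

    off = ~np.eye(Ng, dtype=bool)
    inv_var = float((p[off] / (I - J)[off] ** 2).sum()) if Ng > 1 else 0.0
    denom_imc1 = max(hx, hx)  # symmetric marginals
    imc1 = float((joint_entropy - hxy1) / denom_imc1) if denom_imc1 > 0 else 0.0
    imc2 = float(np.sqrt(1.0 - np.exp(-2.0 * max(hxy2 - joint_entropy, 0.0))))

    pd_nz = p_diff > 0
    ps_nz = p_sum > 0
    return {
        "Autocorrelation": float((p * I * J).sum()),
        "JointAverage": mu,
        "ClusterProminence": float((p * (I + J - 2 * mu) ** 4).sum()),
        "ClusterShade": float((p * (I + J - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((p * (I + J - 2 * mu) ** 2).sum()),
        "Contrast": float((p * (I - J) ** 2).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(p_diff[pd_nz] * np.log2(p_diff[pd_nz])).sum()),
        "DifferenceVariance": float((p_diff * (k_diff - da) ** 2).sum()),
        "Id": float((p / (1.0 + np.abs(I - J))).sum()),
        "Idm": float((p / (1.0 + (I - J) ** 2)).sum()),
        "Idmn": float((p / (1.0 + (I - J) ** 2 / Ng**2)).sum()),
        "Idn": float((p / (1.0 + np.abs(I - J) / Ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": joint_entropy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((p_sum * k_sum).sum()),
        "SumEntropy": float(-(p_sum[ps_nz] * np.log2(p_sum[ps_nz])).sum()),
        "SumSquares": sigma2,
    }


def glcm_features(levels: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    """24 GLCM features, averaged over the 13 directions."""
    levels = _check_input(levels)
    n_levels = n_levels or int(levels.max())
    acc: dict[str, float] = {}
    n_dirs = 0
    for d in DIRECTIONS_13:
        P = _glcm_matrix(levels, d, n_levels)
        if P.sum() == 0:
            continue
        feats = _glcm_features_single(P)
        n_dirs += 1
        for k, v in feats.items():
            acc[k] = acc.get(k, 0.0) + v
    if n_dirs == 0:
        raise DegenerateInputError("no co-occurring in-mask voxel pairs")
    return {k: v / n_dirs for k, v in acc.items()}


# ----------------------------------------------------------------------- runs and zones (shared core)


def _distribution_features(i, j, n, Np: int, names: tuple[str, ...]) -> dict[str, float]:
    """Features of a sparse (gray level i, size/length j) count distribution.

    Shared by GLRLM and GLSZM, whose formulas are identical up to naming
    (run <-> zone).  ``names`` supplies the 16 output names in canonical
    order.
    """
    i = np.asarray(i, float)
    j = np.asarray(j, float)
    n = np.asarray(n, float)
    Nr = n.sum()
    p = n / Nr
    row = {}  # sum of counts per gray level
    for lv, cnt in zip(i.astype(int), n):
        row[lv] = row.get(lv, 0.0) + cnt
    col = {}
    for sz, cnt in zip(j.astype(int), n):
        col[sz] = col.get(sz, 0.0) + cnt
    row_sq = sum(v * v for v in row.values())
    col_sq = sum(v * v for v in col.values())

    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    nz = p > 0
    return {
        names[0]: float((n / j**2).sum() / Nr),  # short/small emphasis
        names[1]: float((n * j**2).sum() / Nr),  # long/large emphasis
        names[2]: float(row_sq / Nr),  # GLN
        names[3]: float(row_sq / Nr**2),  # GLNN
        names[4]: float(col_sq / Nr),  # RLN / SZN
        names[5]: float(col_sq / Nr**2),  # RLNN / SZNN
        names[6]: float(Nr / Np),  # run/zone percentage
        names[7]: float((p * (i - mu_i) ** 2).sum()),  # gray-level variance
        names[8]: float((p * (j - mu_j) ** 2).sum()),  # run/zone variance
        names[9]: float(-(p[nz] * np.log2(p[nz] + _EPS)).sum()),  # entropy
        names[10]: float((n / i**2).sum() / Nr),
        names[11]: float((n * i**2).sum() / Nr),
        names[12]: float((n / (i**2 * j**2)).sum() / Nr),
        names[13]: float((n * i**2 / j**2).sum() / Nr),
        names[14]: float((n * j**2 / i**2).sum() / Nr),
        names[15]: float((n * i**2 * j**2).sum() / Nr),
    }


def _runs_along(levels: np.ndarray, d) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode in-mask voxels along direction ``d``.

    Voxels are grouped into lines by the invariant ``idx * |d|^2 - t * d``
    (``t`` the integer step index along the line); sorting by (line, t)
    exposes runs as maximal blocks of equal gray level at consecutive
    ``t``.  Returns (level, length, count) arrays.
    """
    idx = np.nonzero(levels > 0)
    lv = levels[idx]
    d = np.asarray(d)
    w = int((d**2).sum())
    t = sum(idx[a] * int(d[a]) for a in range(3))
    lid = [idx[a] * w - t * int(d[a]) for a in range(3)]
    order = np.lexsort((t, *lid[::-1]))
    lv_s = lv[order]
    t_s = t[order]
    lids = [c[order] for c in lid]

    brk = np.ones(lv_s.size, dtype=bool)
    if lv_s.size > 1:
        same_line = np.ones(lv_s.size - 1, dtype=bool)
        for c in lids:
            same_line &= c[1:] == c[:-1]
        contiguous = (t_s[1:] - t_s[:-1]) == w
        same_level = lv_s[1:] == lv_s[:-1]
        brk[1:] = ~(same_line & contiguous & same_level)
    starts = np.nonzero(brk)[0]
    lengths = np.diff(np.append(starts, lv_s.size))
    run_levels = lv_s[starts]

    key = run_levels.astype(np.int64) * (int(lengths.max()) + 1) + lengths
    uniq, counts = np.unique(key, return_counts=True)
    L = int(lengths.max()) + 1
    return uniq // L, uniq % L, counts


def glrlm_features(levels: np.ndarray) -> dict[str, float]:
    """16 GLRLM features, averaged over the 13 directions."""
    levels = _check_input(levels)
    Np = int((levels > 0).sum())
    acc: dict[str, float] = {}
    for d in DIRECTIONS_13:
        i, j, n = _runs_along(levels, d)
        feats = _distribution_features(i, j, n, Np, GLRLM_NAMES)
        for k, v in feats.items():
            acc[k] = acc.get(k, 0.0) + v
    return {k: v / len(DIRECTIONS_13) for k, v in acc.items()}


_STRUCT_26 = np.ones((3, 3, 3), dtype=int)


def glszm_features(levels: np.ndarray) -> dict[str, float]:
    """16 GLSZM features from 26-connected equal-level zones."""
    levels = _check_input(levels)
    Np = int((levels > 0).sum())
    ivals, jvals, counts = [], [], []
    for lv in np.unique(levels[levels > 0]):
        lab, nz = ndimage.label(levels == lv, structure=_STRUCT_26)
        if nz == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        uniq, cnt = np.unique(sizes, return_counts=True)
        ivals.append(np.full(uniq.size, lv))
        jvals.append(uniq)
        counts.append(cnt)
    i = np.concatenate(ivals)
    j = np.concatenate(jvals)
    n = np.concatenate(counts)
    return _distribution_features(i, j, n, Np, GLSZM_NAMES)


def gldm_features(levels: np.ndarray) -> dict[str, float]:
    """14 GLDM features (distance 1, dependence tolerance alpha = 0).

    A voxel's dependence is 1 plus the number of its 26-neighbors that
    are in-mask with the same gray level.
    """
    levels = _check_input(levels)
    mask = levels > 0
    dep = np.ones(levels.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        for dd in (d, tuple(-x for x in d)):
            src, dst = _dir_slices(levels.shape, dd)
            eq = np.zeros(levels.shape, dtype=bool)
            eq[dst] = (levels[dst] == levels[src]) & (levels[src] > 0)
            dep += eq & mask
    lv = levels[mask]
    dj = dep[mask]
    Nz = lv.size
    maxd = int(dj.max()) + 1
    key = lv.astype(np.int64) * maxd + dj
    uniq, counts = np.unique(key, return_counts=True)
    i = (uniq // maxd).astype(float)
    j = (uniq % maxd).astype(float)
    n = counts.astype(float)
    p = n / Nz
    row = np.bincount((uniq // maxd).astype(int), weights=n)
    col = np.bincount((uniq % maxd).astype(int), weights=n)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    nzp = p > 0
    return {
        "SmallDependenceEmphasis": float((n / j**2).sum() / Nz),
        "LargeDependenceEmphasis": float((n * j**2).sum() / Nz),
        "GrayLevelNonUniformity": float((row**2).sum() / Nz),
        "DependenceNonUniformity": float((col**2).sum() / Nz),
        "DependenceNonUniformityNormalized": float((col**2).sum() / Nz**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(p[nzp] * np.log2(p[nzp] + _EPS)).sum()),
        "LowGrayLevelEmphasis": float((n / i**2).sum() / Nz),
        "HighGrayLevelEmphasis": float((n * i**2).sum() / Nz),
        "SmallDependenceLowGrayLevelEmphasis": float((n / (i**2 * j**2)).sum() / Nz),
        "SmallDependenceHighGrayLevelEmphasis": float((n * i**2 / j**2).sum() / Nz),
        "LargeDependenceLowGrayLevelEmphasis": float((n * j**2 / i**2).sum() / Nz),
        "LargeDependenceHighGrayLevelEmphasis": float((n * i**2 * j**2).sum() / Nz),
    }


def ngtdm_features(levels: np.ndarray) -> dict[str, float]:
    """5 NGTDM features from the 26-neighborhood gray-tone difference."""
    levels = _check_input(levels)
    mask = levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nbr_sum = ndimage.correlate(levels.astype(float) * mask, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.correlate(mask.astype(float), kernel, mode="constant", cval=0.0)
    valid = mask & (nbr_cnt > 0)
    if not valid.any():
        raise DegenerateInputError("no voxel has in-mask neighbors")
    A = nbr_sum[valid] / nbr_cnt[valid]
    lv = levels[valid]
    Nvp = lv.size
    n_i = np.bincount(lv)
    s_i = np.bincount(lv, weights=np.abs(lv - A))
    present = np.nonzero(n_i)[0]
    i = present.astype(float)
    p = n_i[present] / Nvp
    s = s_i[present]
    Ngp = present.size

    coarse_den = float((p * s).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if Ngp > 1:
        diff2 = (i[:, None] - i[None, :]) ** 2
        contrast = float((p[:, None] * p[None, :] * diff2).sum() / (Ngp * (Ngp - 1))) * float(
            s.sum() / Nvp
        )
        busy_den = float(np.abs(i[:, None] * p[:, None] - i[None, :] * p[None, :]).sum())
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        absdiff = np.abs(i[:, None] - i[None, :])
        pair = (p[:, None] * s[:, None] + p[None, :] * s[None, :]) / (p[:, None] + p[None, :])
        complexity = float((absdiff * pair).sum() / Nvp)
        strength_num = float(((p[:, None] + p[None, :]) * diff2).sum())
        strength = strength_num / float(s.sum()) if s.sum() > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


_CATEGORY_FUNCS = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "gldm": gldm_features,
    "ngtdm": ngtdm_features,
}


def texture_features(levels: np.ndarray, category: str) -> dict[str, float]:
    """Dispatch to one texture category ('glcm', 'glrlm', 'glszm', 'gldm', 'ngtdm')."""
    key = category.lower()
    if key not in _CATEGORY_FUNCS:
        raise ValueError(f"unknown texture category {category!r}")
    return _CATEGORY_FUNCS[key](levels)
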