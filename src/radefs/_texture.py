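"""Gray-level texture matrices on a quantized 3D region of interest.

All five matrix families (GLCM, GLRLM, GLSZM, GLDM, NGTDM) are computed on a
volume quantized to ``n_bins`` equal-width gray levels inside the mask, with
26-connectivity (13 unique direction offsets) throughout.  Matrices are
aggregated over directions before feature computation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_EPS = np.finfo(float).eps

#: the 13 unique direction offsets of a 26-neighborhood (z, y, x)
OFFSETS_13 = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
]


def quantize(image: np.ndarray, mask: np.ndarray, n_bins: int = 16) -> np.ndarray:
    """Equal-width quantization of in-mask intensities to levels 1..n_bins.

    Returns an integer volume with 0 outside the mask.  A constant region maps
    to level 1 everywhere.
    """
    q = np.zeros(image.shape, dtype=np.int32)
    vals = image[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < _EPS:
        q[mask] = 1
        return q
    edges = np.linspace(lo, hi, n_bins + 1)
    # digitize: right edge closed for the last bin
    lev = np.digitize(vals, edges[1:-1], right=False) + 1
    q[mask] = lev
    return q


def _shifted_pairs(q: np.ndarray, mask: np.ndarray, off: tuple[int, int, int]):
    """Gray levels of all in-mask voxel pairs separated by ``off``."""
    sl_a, sl_b = [], []
    for o in off:
        if o == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif o > 0:
            sl_a.append(slice(None, -o))
            sl_b.append(slice(o, None))
        else:
            sl_a.append(slice(-o, None))
            sl_b.append(slice(None, o))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    valid = mask[sl_a] & mask[sl_b]
    return q[sl_a][valid], q[sl_b][valid]


# --------------------------------------------------------------------------
# GLCM


def glcm_matrix(q: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Symmetric co-occurrence matrix summed over the 13 directions."""
    P = np.zeros((n_bins, n_bins), dtype=float)
    for off in OFFSETS_13:
        a, b = _shifted_pairs(q, mask, off)
        if a.size:
            np.add.at(P, (a - 1, b - 1), 1.0)
    P = P + P.T
    s = P.sum()
    return P / s if s > 0 else P


def glcm_features(P: np.ndarray) -> dict[str, float]:
    Ng = P.shape[0]
    i = np.arange(1, Ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sig_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    k_diff = np.arange(0, Ng)  # |i-j|
    p_diff = np.zeros(Ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())
    k_sum = np.arange(2, 2 * Ng + 1)
    p_sum = np.zeros(2 * Ng - 1)
    np.add.at(p_sum, (ii + jj - 2).ravel(), P.ravel())

    da = float((k_diff * p_diff).sum())
    hx = -float((px * np.log2(px + _EPS)).sum())
    hy = -float((py * np.log2(py + _EPS)).sum())
    hxy = -float((P * np.log2(P + _EPS)).sum())
    pxy = np.outer(px, py)
    hxy1 = -float((P * np.log2(pxy + _EPS)).sum())
    hxy2 = -float((pxy * np.log2(pxy + _EPS)).sum())

    out = {
        "Autocorrelation": float((ii * jj * P).sum()),
        "ClusterProminence": float(((ii + jj - mu_x - mu_y) ** 4 * P).sum()),
        "ClusterShade": float(((ii + jj - mu_x - mu_y) ** 3 * P).sum()),
        "ClusterTendency": float(((ii + jj - mu_x - mu_y) ** 2 * P).sum()),
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlation": (
            float(((ii - mu_x) * (jj - mu_y) * P).sum() / (sig_x * sig_y))
            if sig_x > _EPS and sig_y > _EPS
            else 1.0
        ),
        "DifferenceAverage": da,
        "DifferenceEntropy": -float((p_diff * np.log2(p_diff + _EPS)).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((P / (1.0 + (ii - jj) ** 2 / Ng**2)).sum()),
        "Idn": float((P / (1.0 + np.abs(ii - jj) / Ng)).sum()),
        "Imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > _EPS else 0.0,
        "Imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
        "InverseVariance": float(
            (P[ii != jj] / (ii - jj)[ii != jj] ** 2).sum()
        ),
        "JointAverage": mu_x,
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(P.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": -float((p_sum * np.log2(p_sum + _EPS)).sum()),
        "SumSquares": float(((ii - mu_x) ** 2 * P).sum()),
    }
    # MCC: square root of the second-largest eigenvalue of Q
    nz = px > _EPS
    if nz.sum() > 1:
        Pn = P[np.ix_(nz, nz)]
        pxn, pyn = px[nz], py[nz]
        Q = (Pn / pxn[:, None]) @ (Pn / pyn[:, None]).T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))
        out["MCC"] = float(np.sqrt(max(0.0, ev[-2])))
    else:
        out["MCC"] = 1.0
    return out


# --------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(q: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Run-length matrix R[level, length-1] summed over the 13 directions."""
    coords = np.argwhere(mask)
    voxels = {tuple(c): int(q[tuple(c)]) for c in coords}
    max_run = int(max(q.shape))
    R = np.zeros((n_bins, max_run), dtype=float)
    for off in OFFSETS_13:
        for c, lev in voxels.items():
            prev = (c[0] - off[0], c[1] - off[1], c[2] - off[2])
            if voxels.get(prev) == lev:
                continue  # not a run start
            length = 1
            nxt = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            while voxels.get(nxt) == lev:
                length += 1
                nxt = (nxt[0] + off[0], nxt[1] + off[1], nxt[2] + off[2])
            R[lev - 1, length - 1] += 1.0
    return R


def _rl_features(R: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas.

    ``kind`` picks the naming convention: 'run' for GLRLM, 'zone' for GLSZM.
    """
    Nr = R.sum()
    if Nr <= 0:
        R = R.copy()
        R[0, 0] = 1.0
        Nr = 1.0
    i = np.arange(1, R.shape[0] + 1)[:, None].astype(float)
    j = np.arange(1, R.shape[1] + 1)[None, :].astype(float)
    p = R / Nr
    pg = R.sum(axis=1)
    pl = R.sum(axis=0)
    mu_i = float((i[:, 0] * pg / Nr).sum())
    mu_j = float((j[0] * pl / Nr).sum())

    if kind == "run":
        names = {
            "short": "ShortRunEmphasis",
            "long": "LongRunEmphasis",
            "glnu": "GrayLevelNonUniformity",
            "glnun": "GrayLevelNonUniformityNormalized",
            "lnu": "RunLengthNonUniformity",
            "lnun": "RunLengthNonUniformityNormalized",
            "pct": "RunPercentage",
            "glv": "GrayLevelVariance",
            "lv": "RunVariance",
            "ent": "RunEntropy",
            "lgl": "LowGrayLevelRunEmphasis",
            "hgl": "HighGrayLevelRunEmphasis",
            "short_lgl": "ShortRunLowGrayLevelEmphasis",
            "short_hgl": "ShortRunHighGrayLevelEmphasis",
            "long_lgl": "LongRunLowGrayLevelEmphasis",
            "long_hgl": "LongRunHighGrayLevelEmphasis",
        }
    else:
        names = {
            "short": "SmallAreaEmphasis",
            "long": "LargeAreaEmphasis",
            "glnu": "GrayLevelNonUniformity",
            "glnun": "GrayLevelNonUniformityNormalized",
            "lnu": "SizeZoneNonUniformity",
            "lnun": "SizeZoneNonUniformityNormalized",
            "pct": "ZonePercentage",
            "glv": "GrayLevelVariance",
            "lv": "ZoneVariance",
            "ent": "ZoneEntropy",
            "lgl": "LowGrayLevelZoneEmphasis",
            "hgl": "HighGrayLevelZoneEmphasis",
            "short_lgl": "SmallAreaLowGrayLevelEmphasis",
            "short_hgl": "SmallAreaHighGrayLevelEmphasis",
            "long_lgl": "LargeAreaLowGrayLevelEmphasis",
            "long_hgl": "LargeAreaHighGrayLevelEmphasis",
        }

    return {
        names["short"]: float((R / j**2).sum() / Nr),
        names["long"]: float((R * j**2).sum() / Nr),
        names["glnu"]: float((pg**2).sum() / Nr),
        names["glnun"]: float((pg**2).sum() / Nr**2),
        names["lnu"]: float((pl**2).sum() / Nr),
        names["lnun"]: float((pl**2).sum() / Nr**2),
        names["pct"]: float(Nr / max(n_voxels, 1)),
        names["glv"]: float((p * (i - mu_i) ** 2).sum()),
        names["lv"]: float((p * (j - mu_j) ** 2).sum()),
        names["ent"]: -float((p * np.log2(p + _EPS)).sum()),
        names["lgl"]: float((R / i**2).sum() / Nr),
        names["hgl"]: float((R * i**2).sum() / Nr),
        names["short_lgl"]: float((R / (i**2 * j**2)).sum() / Nr),
        names["short_hgl"]: float((R * i**2 / j**2).sum() / Nr),
        names["long_lgl"]: float((R * j**2 / i**2).sum() / Nr),
        names["long_hgl"]: float((R * i**2 * j**2).sum() / Nr),
    }


def glrlm_features(q, mask, n_bins) -> dict[str, float]:
    R = glrlm_matrix(q, mask, n_bins)
    # run percentage uses voxel count per direction aggregate
    return _rl_features(R, int(mask.sum()) * len(OFFSETS_13), "run")


# --------------------------------------------------------------------------
# GLSZM


def glszm_matrix(q: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Size-zone matrix Z[level, size-1] using 26-connected zones."""
    structure = np.ones((3, 3, 3), dtype=bool)
    max_size = int(mask.sum())
    Z = np.zeros((n_bins, max(max_size, 1)), dtype=float)
    for lev in range(1, n_bins + 1):
        region = q == lev
        if not region.any():
            continue
        labeled, n_zones = ndimage.label(region, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            Z[lev - 1, s - 1] += 1.0
    return Z


def glszm_features(q, mask, n_bins) -> dict[str, float]:
    Z = glszm_matrix(q, mask, n_bins)
    return _rl_features(Z, int(mask.sum()), "zone")


# --------------------------------------------------------------------------
# GLDM


def gldm_matrix(
    q: np.ndarray, mask: np.ndarray, n_bins: int, alpha: int = 0
) -> np.ndarray:
    """Dependence matrix D[level, k] where k = dependent 26-neighbors."""
    padded_q = np.pad(q, 1)
    padded_m = np.pad(mask, 1)
    dep = np.zeros(q.shape, dtype=np.int32)
    for off in OFFSETS_13:
        for sign in (1, -1):
            dz, dy, dx = (sign * x for x in off)
            sl = (
                slice(1 + dz, padded_q.shape[0] - 1 + dz),
                slice(1 + dy, padded_q.shape[1] - 1 + dy),
                slice(1 + dx, padded_q.shape[2] - 1 + dx),
            )
            neigh_q = padded_q[sl]
            neigh_m = padded_m[sl]
            dep += (mask & neigh_m & (np.abs(neigh_q - q) <= alpha)).astype(
                np.int32
            )
    levels = q[mask] - 1
    deps = dep[mask]  # 0..26
    D = np.zeros((n_bins, 27), dtype=float)
    np.add.at(D, (levels, deps), 1.0)
    return D


def gldm_features(q, mask, n_bins) -> dict[str, float]:
    D = gldm_matrix(q, mask, n_bins)
    Nz = D.sum()
    i = np.arange(1, n_bins + 1)[:, None].astype(float)
    j = np.arange(1, D.shape[1] + 1)[None, :].astype(float)  # dependence size
    p = D / Nz
    pg = D.sum(axis=1)
    pd = D.sum(axis=0)
    mu_i = float((i[:, 0] * pg / Nz).sum())
    mu_j = float((j[0] * pd / Nz).sum())
    return {
        "SmallDependenceEmphasis": float((D / j**2).sum() / Nz),
        "LargeDependenceEmphasis": float((D * j**2).sum() / Nz),
        "GrayLevelNonUniformity": float((pg**2).sum() / Nz),
        "DependenceNonUniformity": float((pd**2).sum() / Nz),
        "DependenceNonUniformityNormalized": float((pd**2).sum() / Nz**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": -float((p * np.log2(p + _EPS)).sum()),
        "LowGrayLevelEmphasis": float((D / i**2).sum() / Nz),
        "HighGrayLevelEmphasis": float((D * i**2).sum() / Nz),
        "SmallDependenceLowGrayLevelEmphasis": float(
            (D / (i**2 * j**2)).sum() / Nz
        ),
        "SmallDependenceHighGrayLevelEmphasis": float(
            (D * i**2 / j**2).sum() / Nz
        ),
        "LargeDependenceLowGrayLevelEmphasis": float(
            (D * j**2 / i**2).sum() / Nz
        ),
        "LargeDependenceHighGrayLevelEmphasis": float(
            (D * i**2 * j**2).sum() / Nz
        ),
    }


# --------------------------------------------------------------------------
# NGTDM


def ngtdm_features(q, mask, n_bins) -> dict[str, float]:
    padded_q = np.pad(q.astype(float), 1)
    padded_m = np.pad(mask, 1)
    neigh_sum = np.zeros(q.shape, dtype=float)
    neigh_cnt = np.zeros(q.shape, dtype=np.int32)
    for off in OFFSETS_13:
        for sign in (1, -1):
            dz, dy, dx = (sign * x for x in off)
            sl = (
                slice(1 + dz, padded_q.shape[0] - 1 + dz),
                slice(1 + dy, padded_q.shape[1] - 1 + dy),
                slice(1 + dx, padded_q.shape[2] - 1 + dx),
            )
            m = padded_m[sl]
            neigh_sum += np.where(m, padded_q[sl], 0.0)
            neigh_cnt += m.astype(np.int32)
    valid = mask & (neigh_cnt > 0)
    levels = q[valid]
    diffs = np.abs(levels - neigh_sum[valid] / neigh_cnt[valid])
    n_i = np.zeros(n_bins)
    s_i = np.zeros(n_bins)
    np.add.at(n_i, levels - 1, 1.0)
    np.add.at(s_i, levels - 1, diffs)
    N = n_i.sum()
    p_i = n_i / N if N > 0 else n_i
    i = np.arange(1, n_bins + 1, dtype=float)
    nz = p_i > 0
    Ngp = int(nz.sum())

    coarseness = 1.0 / max((p_i * s_i).sum(), _EPS)
    coarseness = min(coarseness, 1e6)  # cap when all differences vanish
    if Ngp > 1:
        ip, jp = np.meshgrid(i[nz], i[nz], indexing="ij")
        pp = np.outer(p_i[nz], p_i[nz])
        contrast = float(
            (pp * (ip - jp) ** 2).sum() / (Ngp * (Ngp - 1)) * (s_i.sum() / N)
        )
        denom_busy = float(np.abs(ip * p_i[nz][:, None] - jp * p_i[nz][None, :]).sum())
        busyness = float((p_i * s_i).sum() / denom_busy) if denom_busy > _EPS else 0.0
        si, sj = np.meshgrid(s_i[nz], s_i[nz], indexing="ij")
        pi_m, pj_m = np.meshgrid(p_i[nz], p_i[nz], indexing="ij")
        complexity = float(
            (np.abs(ip - jp) * (pi_m * si + pj_m * sj) / (pi_m + pj_m)).sum() / N
        )
        strength_num = float(((pi_m + pj_m) * (ip - jp) ** 2).sum())
        strength = strength_num / max(float(s_i.sum()), _EPS)
        strength = min(strength, 1e6)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
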