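"""Gray-level texture matrices and the 74-feature texture panel.

Conventions (IBSI / pyradiomics style):

* input is a 3-D integer volume, 0 outside the region and ``1..Ng``
  inside (fixed-bin-count discretization from the preprocessing stage);
* GLCM: distance 1, 13 unique 3-D direction pairs, symmetric
  accumulation; features are computed per direction and averaged;
* GLRLM: maximal runs along the same 13 directions; per-direction
  features averaged;
* GLSZM: 26-connected iso-intensity zones;
* GLDM: dependence = 1 + number of 26-neighbors with identical level
  (dependence tolerance alpha = 0);
* NGTDM: 26-neighborhood mean gray-tone difference; voxels with no
  in-region neighbor are excluded.

The standard families total 75 features (GLCM 24, GLRLM 16, GLSZM 16,
GLDM 14, NGTDM 5); GLCM SumAverage — identically ``2 * JointAverage``
for a symmetric matrix — is excluded, leaving the 74-feature panel.
Features that are undefined on degenerate matrices (e.g. correlation of
a constant region) are 0 by convention.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage

EPS = float(np.spacing(1.0))

#: 13 unique direction pairs of the 3-D 26-neighborhood (one per +/- pair).
ANGLES: Tuple[Tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_ALL_OFFSETS = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

GLCM_NAMES = (
    "Autocorrelation",
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
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
)
GLRLM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)
GLDM_NAMES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)
NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


@dataclass
class TextureMatrices:
    """Raw (unnormalized) texture matrices of one region."""

    glcm: np.ndarray  # (13, Ng, Ng) symmetric counts per angle
    glrlm: np.ndarray  # (13, Ng, Lmax) run counts per angle
    glszm: np.ndarray  # (Ng, Smax) zone counts
    gldm: np.ndarray  # (Ng, Dmax) dependence counts
    ngtdm_s: np.ndarray  # (Ng,) summed |i - neighborhood average|
    ngtdm_n: np.ndarray  # (Ng,) voxel counts with a valid neighborhood
    n_levels: int
    n_voxels: int


def _crop(region_levels: np.ndarray) -> np.ndarray:
    """Crop to the region bounding box and pad one voxel of background."""
    mask = region_levels > 0
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    return np.pad(region_levels[sl], 1)


def _shift_views(a: np.ndarray, off: Tuple[int, int, int]):
    """Aligned views (center, shifted-by-off) of equal shape."""
    sl_c, sl_s = _slices_for(off)
    return a[sl_c], a[sl_s]


def texture_matrices(region_levels: np.ndarray, n_levels: int) -> TextureMatrices:
    """Build all five texture matrices for one discretized region.

    ``region_levels`` is a 3-D integer array, 0 outside the region.
    """
    img = np.asarray(region_levels)
    if img.ndim != 3:
        raise ValueError("region_levels must be 3-D")
    n_vox = int((img > 0).sum())
    if n_vox < 1:
        raise ValueError("empty region")
    ng = int(n_levels)
    if img.max() > ng:
        raise ValueError("levels exceed n_levels")
    img = _crop(img).astype(np.int64)
    shape = img.shape
    flat = img.ravel()
    idx = np.flatnonzero(flat)  # in-region flat indices (padding guards bounds)
    vals = flat[idx]
    strides = (shape[1] * shape[2], shape[2], 1)

    def _step(off):
        return off[0] * strides[0] + off[1] * strides[1] + off[2] * strides[2]

    # ---- GLCM + GLRLM (per direction) ------------------------------
    max_run = max(shape)
    n_ang = len(ANGLES)
    steps = np.array([_step(off) for off in ANGLES])
    # one gather for all directions: neighbor level per (voxel, angle)
    nb_all = flat[idx[:, None] + steps[None, :]]  # (n_vox, 13)
    valid_all = nb_all > 0
    # co-occurrence counts for every angle in a single bincount
    ai_idx = np.broadcast_to(np.arange(n_ang), nb_all.shape)[valid_all]
    a_lv = np.broadcast_to(vals[:, None], nb_all.shape)[valid_all]
    b_lv = nb_all[valid_all]
    counts = np.bincount(
        (ai_idx * ng + (a_lv - 1)) * ng + (b_lv - 1), minlength=n_ang * ng * ng
    ).reshape(n_ang, ng, ng).astype(np.float64)
    glcm = counts + counts.transpose(0, 2, 1)

    glrlm = np.zeros((n_ang, ng, max_run), dtype=np.float64)
    eq_all = nb_all == vals[:, None]  # (n_vox, 13)
    eq_flat = np.zeros(flat.size, dtype=bool)
    for ai in range(n_ang):
        step = steps[ai]
        eq_flat[idx] = eq_all[:, ai]
        # v starts a run unless continued from v-off
        starts = idx[~eq_flat[idx - step]]
        lengths = np.ones(starts.size, dtype=np.int64)
        cur = starts
        alive = np.arange(starts.size)
        while alive.size:
            cont = eq_flat[cur]
            alive = alive[cont]
            cur = cur[cont] + step
            lengths[alive] += 1
        np.add.at(glrlm[ai], (flat[starts] - 1, lengths - 1), 1.0)
        eq_flat[idx] = False

    # ---- GLSZM -----------------------------------------------------
    structure = np.ones((3, 3, 3), dtype=np.int8)
    max_zone = 1
    per_level = []
    # label each level inside its own bounding box (identical zones,
    # much less volume to scan for sparse levels)
    lev_slices = ndimage.find_objects(img)
    for lev0, sl in enumerate(lev_slices):
        if sl is None:
            continue
        lab, _ = ndimage.label(img[sl] == lev0 + 1, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        per_level.append((lev0 + 1, sizes))
        if sizes.size:
            max_zone = max(max_zone, int(sizes.max()))
    glszm = np.zeros((ng, max_zone), dtype=np.float64)
    for lev, sizes in per_level:
        if sizes.size:
            np.add.at(glszm[lev - 1], sizes - 1, 1.0)

    # ---- GLDM + NGTDM neighbor accumulation ------------------------
    steps26 = np.array([_step(off) for off in _ALL_OFFSETS])
    nb26 = flat[idx[:, None] + steps26[None, :]]  # (n_vox, 26)
    in26 = nb26 > 0
    dep = (in26 & (nb26 == vals[:, None])).sum(axis=1)
    nb_sum = np.where(in26, nb26, 0).sum(axis=1).astype(np.float64)
    nb_cnt = in26.sum(axis=1)

    dep_size = dep + 1  # include the center voxel
    max_dep = int(dep_size.max())
    gldm = np.zeros((ng, max_dep), dtype=np.float64)
    np.add.at(gldm, (vals - 1, dep_size - 1), 1.0)

    valid_nb = nb_cnt > 0
    diff = np.abs(vals[valid_nb] - nb_sum[valid_nb] / nb_cnt[valid_nb])
    ngtdm_s = np.zeros(ng, dtype=np.float64)
    ngtdm_n = np.zeros(ng, dtype=np.float64)
    np.add.at(ngtdm_s, vals[valid_nb] - 1, diff)
    np.add.at(ngtdm_n, vals[valid_nb] - 1, 1.0)

    return TextureMatrices(
        glcm=glcm,
        glrlm=glrlm,
        glszm=glszm,
        gldm=gldm,
        ngtdm_s=ngtdm_s,
        ngtdm_n=ngtdm_n,
        n_levels=ng,
        n_voxels=n_vox,
    )


def _slices_for(off: Tuple[int, int, int]):
    sl_c, sl_s = [], []
    for d in off:
        if d == 0:
            sl_c.append(slice(None))
            sl_s.append(slice(None))
        elif d > 0:
            sl_c.append(slice(None, -d))
            sl_s.append(slice(d, None))
        else:
            sl_c.append(slice(-d, None))
            sl_s.append(slice(None, d))
    return tuple(sl_c), tuple(sl_s)


@functools.lru_cache(maxsize=8)
def _index_maps(ng: int):
    """One-hot maps from (i,j) cells onto i+j and |i-j| margins."""
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    ksum = (ii + jj).ravel() - 2  # 0 .. 2ng-2
    kdiff = np.abs(ii - jj).ravel()  # 0 .. ng-1
    s_map = np.zeros((ng * ng, 2 * ng - 1))
    s_map[np.arange(ng * ng), ksum] = 1.0
    d_map = np.zeros((ng * ng, ng))
    d_map[np.arange(ng * ng), kdiff] = 1.0
    return s_map, d_map


def _glcm_features_batch(p: np.ndarray, ng: int) -> Dict[str, np.ndarray]:
    """23 GLCM features of a batch of normalized symmetric matrices.

    ``p`` has shape (A, Ng, Ng); every output is a vector of length A.
    """
    a = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    px = p.sum(axis=2)  # (A, Ng)
    py = p.sum(axis=1)
    mux = (i * px).sum(axis=1)
    muy = (i * py).sum(axis=1)
    sigx = np.sqrt(((i[None, :] - mux[:, None]) ** 2 * px).sum(axis=1))
    sigy = np.sqrt(((i[None, :] - muy[:, None]) ** 2 * py).sum(axis=1))
    s_map, d_map = _index_maps(ng)
    flat = p.reshape(a, ng * ng)
    psum = flat @ s_map  # (A, 2ng-1), k = 2..2ng
    pdiff = flat @ d_map  # (A, ng), k = 0..ng-1
    kdiff = np.arange(0, ng, dtype=np.float64)

    ii, jj = np.meshgrid(i, i, indexing="ij")
    da = (kdiff * pdiff).sum(axis=1)

    hx = -(px * np.log2(px + EPS)).sum(axis=1)
    hy = -(py * np.log2(py + EPS)).sum(axis=1)
    hxy = -(p * np.log2(p + EPS)).sum(axis=(1, 2))
    # HXY1 = -sum p log(px*py) and HXY2 = -sum px*py log(px*py) both
    # reduce to HX + HY exactly (the margins of p are px, py)
    hxy1 = hx + hy
    hxy2 = hx + hy

    autoc = (ii * jj * p).sum(axis=(1, 2))
    sig_ok = (sigx > 0) & (sigy > 0)
    corr = np.zeros(a)
    corr[sig_ok] = (autoc[sig_ok] - mux[sig_ok] * muy[sig_ok]) / (
        sigx[sig_ok] * sigy[sig_ok]
    )

    hmax = np.maximum(hx, hy)
    imc1 = np.where(hmax > 0, (hxy - hxy1) / np.where(hmax > 0, hmax, 1.0), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))

    # MCC: second-largest eigenvalue of Q(i,j) = sum_k p_ik p_jk/(px_i px_k).
    # For the symmetric GLCM, Q is similar to B@B.T with
    # B = D^{-1/2} P D^{-1/2}, D = diag(px), so a symmetric eigensolver
    # applies; absent gray levels contribute zero rows whose zero
    # eigenvalues cannot displace the second-largest (spectrum in [0,1]).
    inv_sqrt = np.where(px > 0, 1.0 / np.sqrt(np.where(px > 0, px, 1.0)), 0.0)
    b = p * inv_sqrt[:, :, None] * inv_sqrt[:, None, :]
    ev = np.sort(np.linalg.eigvalsh(b @ b.transpose(0, 2, 1)), axis=1)
    present = (px > 0).sum(axis=1)
    mcc = np.where(present >= 2, np.sqrt(np.clip(ev[:, -2], 0.0, None)), 0.0)

    cshift = (ii + jj)[None, :, :] - (mux + muy)[:, None, None]
    cshift2 = cshift**2
    inv_var = (
        (pdiff[:, 1:] / kdiff[1:] ** 2).sum(axis=1) if ng > 1 else np.zeros(a)
    )
    return {
        "Autocorrelation": autoc,
        "ClusterProminence": (cshift2**2 * p).sum(axis=(1, 2)),
        "ClusterShade": (cshift2 * cshift * p).sum(axis=(1, 2)),
        "ClusterTendency": (cshift2 * p).sum(axis=(1, 2)),
        "Contrast": ((ii - jj)[None] ** 2 * p).sum(axis=(1, 2)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -(pdiff * np.log2(pdiff + EPS)).sum(axis=1),
        "DifferenceVariance": (
            (kdiff[None, :] - da[:, None]) ** 2 * pdiff
        ).sum(axis=1),
        "Id": (pdiff / (1.0 + kdiff)).sum(axis=1),
        "Idm": (pdiff / (1.0 + kdiff**2)).sum(axis=1),
        "Idmn": (pdiff / (1.0 + kdiff**2 / ng**2)).sum(axis=1),
        "Idn": (pdiff / (1.0 + kdiff / ng)).sum(axis=1),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mux,
        "JointEnergy": (p**2).sum(axis=(1, 2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": p.max(axis=(1, 2)),
        "SumEntropy": -(psum * np.log2(psum + EPS)).sum(axis=1),
        "SumSquares": ((i[None, :] - mux[:, None]) ** 2 * px).sum(axis=1),
    }


def _glrlm_features_batch(r: np.ndarray, n_voxels: int) -> Dict[str, np.ndarray]:
    """16 GLRLM features for a batch (A, Ng, Lmax) of run matrices."""
    _, ng, lmax = r.shape
    nr = r.sum(axis=(1, 2))
    nr_safe = np.where(nr > 0, nr, 1.0)
    i = np.arange(1, ng + 1, dtype=np.float64)[None, :, None]
    l = np.arange(1, lmax + 1, dtype=np.float64)[None, None, :]
    ri = r.sum(axis=2)
    rl = r.sum(axis=1)
    p = r / nr_safe[:, None, None]
    mu_i = (i * p).sum(axis=(1, 2))
    mu_l = (l * p).sum(axis=(1, 2))
    return {
        "GrayLevelNonUniformity": (ri**2).sum(axis=1) / nr_safe,
        "GrayLevelNonUniformityNormalized": (ri**2).sum(axis=1) / nr_safe**2,
        "GrayLevelVariance": ((i - mu_i[:, None, None]) ** 2 * p).sum(axis=(1, 2)),
        "HighGrayLevelRunEmphasis": (r * i**2).sum(axis=(1, 2)) / nr_safe,
        "LongRunEmphasis": (r * l**2).sum(axis=(1, 2)) / nr_safe,
        "LongRunHighGrayLevelEmphasis": (r * i**2 * l**2).sum(axis=(1, 2)) / nr_safe,
        "LongRunLowGrayLevelEmphasis": (r * l**2 / i**2).sum(axis=(1, 2)) / nr_safe,
        "LowGrayLevelRunEmphasis": (r / i**2).sum(axis=(1, 2)) / nr_safe,
        "RunEntropy": -(p * np.log2(p + EPS)).sum(axis=(1, 2)),
        "RunLengthNonUniformity": (rl**2).sum(axis=1) / nr_safe,
        "RunLengthNonUniformityNormalized": (rl**2).sum(axis=1) / nr_safe**2,
        "RunPercentage": nr / n_voxels,
        "RunVariance": ((l - mu_l[:, None, None]) ** 2 * p).sum(axis=(1, 2)),
        "ShortRunEmphasis": (r / l**2).sum(axis=(1, 2)) / nr_safe,
        "ShortRunHighGrayLevelEmphasis": (r * i**2 / l**2).sum(axis=(1, 2)) / nr_safe,
        "ShortRunLowGrayLevelEmphasis": (r / (i**2 * l**2)).sum(axis=(1, 2)) / nr_safe,
    }


def _szm_like_features_batch(z: np.ndarray, n_voxels: np.ndarray) -> Dict[str, np.ndarray]:
    """Shared form of GLSZM/GLDM-style (level x size) matrices, batched.

    ``z`` has shape (R, Ng, Smax); ``n_voxels`` is the per-row region
    size.  Rows are zero-padded along the size axis.
    """
    _, ng, smax = z.shape
    nz = z.sum(axis=(1, 2))
    nz_safe = np.where(nz > 0, nz, 1.0)
    i = np.arange(1, ng + 1, dtype=np.float64)[None, :, None]
    s = np.arange(1, smax + 1, dtype=np.float64)[None, None, :]
    zi = z.sum(axis=2)
    zs = z.sum(axis=1)
    p = z / nz_safe[:, None, None]
    mu_i = (i * p).sum(axis=(1, 2))[:, None, None]
    mu_s = (s * p).sum(axis=(1, 2))[:, None, None]
    return {
        "gln": (zi**2).sum(axis=1) / nz_safe,
        "glnn": (zi**2).sum(axis=1) / nz_safe**2,
        "glv": ((i - mu_i) ** 2 * p).sum(axis=(1, 2)),
        "hgle": (z * i**2).sum(axis=(1, 2)) / nz_safe,
        "large": (z * s**2).sum(axis=(1, 2)) / nz_safe,
        "large_high": (z * i**2 * s**2).sum(axis=(1, 2)) / nz_safe,
        "large_low": (z * s**2 / i**2).sum(axis=(1, 2)) / nz_safe,
        "lgle": (z / i**2).sum(axis=(1, 2)) / nz_safe,
        "szn": (zs**2).sum(axis=1) / nz_safe,
        "sznn": (zs**2).sum(axis=1) / nz_safe**2,
        "small": (z / s**2).sum(axis=(1, 2)) / nz_safe,
        "small_high": (z * i**2 / s**2).sum(axis=(1, 2)) / nz_safe,
        "small_low": (z / (i**2 * s**2)).sum(axis=(1, 2)) / nz_safe,
        "entropy": -(p * np.log2(p + EPS)).sum(axis=(1, 2)),
        "pct": nz / np.asarray(n_voxels, dtype=np.float64),
        "size_var": ((s - mu_s) ** 2 * p).sum(axis=(1, 2)),
    }


def _ngtdm_features(s_i: np.ndarray, n_i: np.ndarray) -> Dict[str, float]:
    nvp = n_i.sum()
    out = dict.fromkeys(NGTDM_NAMES, 0.0)
    if nvp == 0:
        return {f"ngtdm_{k}": v for k, v in out.items()}
    present = n_i > 0
    i = np.arange(1, len(n_i) + 1, dtype=np.float64)[present]
    p = n_i[present] / nvp
    s = s_i[present]
    ngp = present.sum()

    sum_ps = float((p * s).sum())
    out["Coarseness"] = 1.0 / sum_ps if sum_ps > 0 else 1e6
    if ngp > 1:
        di = i[:, None] - i[None, :]
        pipj = p[:, None] * p[None, :]
        out["Contrast"] = float(
            (pipj * di**2).sum() / (ngp * (ngp - 1)) * s.sum() / nvp
        )
        denom = float(np.abs(i[:, None] * p[:, None] - i[None, :] * p[None, :]).sum())
        out["Busyness"] = sum_ps / denom if denom > 0 else 0.0
        out["Complexity"] = float(
            (
                np.abs(di)
                * (p[:, None] * s[:, None] + p[None, :] * s[None, :])
                / (p[:, None] + p[None, :])
            ).sum()
            / nvp
        )
        out["Strength"] = (
            float(((p[:, None] + p[None, :]) * di**2).sum() / s.sum())
            if s.sum() > 0
            else 0.0
        )
    return {f"ngtdm_{k}": v for k, v in out.items()}


_GLSZM_KEYMAP = {
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "GrayLevelVariance": "glv",
    "HighGrayLevelZoneEmphasis": "hgle",
    "LargeAreaEmphasis": "large",
    "LargeAreaHighGrayLevelEmphasis": "large_high",
    "LargeAreaLowGrayLevelEmphasis": "large_low",
    "LowGrayLevelZoneEmphasis": "lgle",
    "SizeZoneNonUniformity": "szn",
    "SizeZoneNonUniformityNormalized": "sznn",
    "SmallAreaEmphasis": "small",
    "SmallAreaHighGrayLevelEmphasis": "small_high",
    "SmallAreaLowGrayLevelEmphasis": "small_low",
    "ZoneEntropy": "entropy",
    "ZonePercentage": "pct",
    "ZoneVariance": "size_var",
}
_GLDM_KEYMAP = {
    "DependenceEntropy": "entropy",
    "DependenceNonUniformity": "szn",
    "DependenceNonUniformityNormalized": "sznn",
    "DependenceVariance": "size_var",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelVariance": "glv",
    "HighGrayLevelEmphasis": "hgle",
    "LargeDependenceEmphasis": "large",
    "LargeDependenceHighGrayLevelEmphasis": "large_high",
    "LargeDependenceLowGrayLevelEmphasis": "large_low",
    "LowGrayLevelEmphasis": "lgle",
    "SmallDependenceEmphasis": "small",
    "SmallDependenceHighGrayLevelEmphasis": "small_high",
    "SmallDependenceLowGrayLevelEmphasis": "small_low",
}


def _pad_stack(mats, widths):
    """Stack (Ng, w_r) matrices into (R, Ng, max_w) with zero padding."""
    wmax = max(widths)
    out = np.zeros((len(mats), mats[0].shape[0], wmax))
    for r, m in enumerate(mats):
        out[r, :, : m.shape[1]] = m
    return out


def texture_features_batch(all_matrices) -> "list[Dict[str, float]]":
    """Compute the 74-feature panel for many regions in one vectorized pass.

    ``all_matrices`` is a sequence of :class:`TextureMatrices` with a
    common ``n_levels``.  GLCM/GLRLM features are evaluated for every
    (region, direction) pair at once and then averaged per region over
    the directions with a nonempty matrix; this amortizes numpy
    dispatch overhead, which dominates on small regions.
    """
    mats = list(all_matrices)
    if not mats:
        return []
    ng = mats[0].n_levels
    if any(m.n_levels != ng for m in mats):
        raise ValueError("all regions must share n_levels")
    n_reg = len(mats)
    n_ang = len(ANGLES)
    results: "list[Dict[str, float]]" = [dict() for _ in range(n_reg)]

    def _per_region_mean(batch_feats, names, prefix, keep):
        # keep: boolean (R*13,) of retained angle rows, ordered by region
        region_of = np.repeat(np.arange(n_reg), n_ang)[keep]
        counts = np.bincount(region_of, minlength=n_reg).astype(float)
        safe = np.where(counts > 0, counts, 1.0)
        for name in names:
            sums = np.bincount(region_of, weights=batch_feats[name], minlength=n_reg)
            vals = np.where(counts > 0, sums / safe, 0.0)
            for r in range(n_reg):
                results[r][f"{prefix}_{name}"] = float(vals[r])

    # ---- GLCM ------------------------------------------------------
    glcm = np.concatenate([m.glcm for m in mats], axis=0)  # (R*13, Ng, Ng)
    tot = glcm.sum(axis=(1, 2))
    keep = tot > 0
    p = glcm[keep] / tot[keep][:, None, None]
    feats = _glcm_features_batch(p, ng) if keep.any() else {}
    if keep.any():
        _per_region_mean(feats, GLCM_NAMES, "glcm", keep)
    else:  # pragma: no cover - at least one angle always pairs for >=2 voxels
        for r in range(n_reg):
            results[r].update({f"glcm_{k}": 0.0 for k in GLCM_NAMES})

    # ---- GLRLM -----------------------------------------------------
    widths = [m.glrlm.shape[2] for m in mats]
    wmax = max(widths)
    rlm = np.zeros((n_reg * n_ang, ng, wmax))
    nv_rows = np.empty(n_reg * n_ang)
    for r, m in enumerate(mats):
        rlm[r * n_ang : (r + 1) * n_ang, :, : widths[r]] = m.glrlm
        nv_rows[r * n_ang : (r + 1) * n_ang] = m.n_voxels
    tot = rlm.sum(axis=(1, 2))
    keep = tot > 0
    feats = _glrlm_features_batch(rlm[keep], nv_rows[keep])
    _per_region_mean(feats, GLRLM_NAMES, "glrlm", keep)

    # ---- GLSZM / GLDM ----------------------------------------------
    nv = np.array([m.n_voxels for m in mats], dtype=float)
    sz = _szm_like_features_batch(
        _pad_stack([m.glszm for m in mats], [m.glszm.shape[1] for m in mats]), nv
    )
    dm = _szm_like_features_batch(
        _pad_stack([m.gldm for m in mats], [m.gldm.shape[1] for m in mats]), nv
    )
    for r in range(n_reg):
        for name, key in _GLSZM_KEYMAP.items():
            results[r][f"glszm_{name}"] = float(sz[key][r])
        for name, key in _GLDM_KEYMAP.items():
            results[r][f"gldm_{name}"] = float(dm[key][r])
        results[r].update(_ngtdm_features(mats[r].ngtdm_s, mats[r].ngtdm_n))
    return results


def texture_features(matrices: TextureMatrices) -> Dict[str, float]:
    """Compute the 74 texture features of one region.

    GLCM and GLRLM features are computed per direction and averaged
    over the directions with a nonempty matrix.
    """
    return texture_features_batch([matrices])[0]
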