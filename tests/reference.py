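"""Independent naive reference implementations used as test oracles.

Everything here is written straight from the textbook definitions with
explicit Python loops and no shared code with the package: texture
matrices by brute-force pair/run/zone enumeration, first-order
statistics formula by formula, and a reference fuzzy-c-means that
follows the update equations literally.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np

OFFSETS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def naive_glcm(img: np.ndarray, ng: int, off: Tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction by enumeration."""
    p = np.zeros((ng, ng))
    nx, ny, nz = img.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = img[x, y, z]
                if a == 0:
                    continue
                xx, yy, zz = x + off[0], y + off[1], z + off[2]
                if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                    b = img[xx, yy, zz]
                    if b > 0:
                        p[a - 1, b - 1] += 1
                        p[b - 1, a - 1] += 1
    return p


def naive_glrlm(img: np.ndarray, ng: int, off: Tuple[int, int, int]) -> np.ndarray:
    """Run-length counts for one direction by walking every line."""
    nx, ny, nz = img.shape
    counted = np.zeros(img.shape, dtype=bool)
    runs: List[Tuple[int, int]] = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                v = img[x, y, z]
                if v == 0:
                    continue
                # only start a run if the previous voxel along -off differs
                px, py, pz = x - off[0], y - off[1], z - off[2]
                if (
                    0 <= px < nx
                    and 0 <= py < ny
                    and 0 <= pz < nz
                    and img[px, py, pz] == v
                ):
                    continue
                length = 1
                cx, cy, cz = x + off[0], y + off[1], z + off[2]
                while 0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz and img[cx, cy, cz] == v:
                    length += 1
                    cx, cy, cz = cx + off[0], cy + off[1], cz + off[2]
                runs.append((v, length))
    lmax = max((l for _, l in runs), default=1)
    r = np.zeros((ng, lmax))
    for v, l in runs:
        r[v - 1, l - 1] += 1
    return r


def naive_glszm(img: np.ndarray, ng: int) -> np.ndarray:
    """Zone-size counts via flood fill with 26-connectivity."""
    nx, ny, nz = img.shape
    seen = np.zeros(img.shape, dtype=bool)
    zones: List[Tuple[int, int]] = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                v = img[x, y, z]
                if v == 0 or seen[x, y, z]:
                    continue
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in OFFSETS_26:
                        xx, yy, zz = cx + dx, cy + dy, cz + dz
                        if (
                            0 <= xx < nx
                            and 0 <= yy < ny
                            and 0 <= zz < nz
                            and not seen[xx, yy, zz]
                            and img[xx, yy, zz] == v
                        ):
                            seen[xx, yy, zz] = True
                            stack.append((xx, yy, zz))
                zones.append((v, size))
    smax = max((s for _, s in zones), default=1)
    zm = np.zeros((ng, smax))
    for v, s in zones:
        zm[v - 1, s - 1] += 1
    return zm


def naive_gldm(img: np.ndarray, ng: int) -> np.ndarray:
    """Dependence counts: 1 + equal-level 26-neighbors per voxel."""
    nx, ny, nz = img.shape
    entries: List[Tuple[int, int]] = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                v = img[x, y, z]
                if v == 0:
                    continue
                d = 1
                for dx, dy, dz in OFFSETS_26:
                    xx, yy, zz = x + dx, y + dy, z + dz
                    if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz and img[xx, yy, zz] == v:
                        d += 1
                entries.append((v, d))
    dmax = max((d for _, d in entries), default=1)
    m = np.zeros((ng, dmax))
    for v, d in entries:
        m[v - 1, d - 1] += 1
    return m


def naive_ngtdm(img: np.ndarray, ng: int) -> Tuple[np.ndarray, np.ndarray]:
    """(s_i, n_i) of the neighborhood gray-tone difference matrix."""
    nx, ny, nz = img.shape
    s = np.zeros(ng)
    n = np.zeros(ng)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                v = img[x, y, z]
                if v == 0:
                    continue
                vals = []
                for dx, dy, dz in OFFSETS_26:
                    xx, yy, zz = x + dx, y + dy, z + dz
                    if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz and img[xx, yy, zz] > 0:
                        vals.append(img[xx, yy, zz])
                if not vals:
                    continue
                s[v - 1] += abs(v - sum(vals) / len(vals))
                n[v - 1] += 1
    return s, n


def naive_first_order(values: np.ndarray, disc: np.ndarray, voxvol: float) -> Dict[str, float]:
    """The 18 first-order statistics, formula by formula."""
    x = sorted(float(v) for v in np.ravel(values))
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)

    def pct(q):
        return float(np.percentile(np.asarray(x), q))

    p10, p25, p75, p90 = pct(10), pct(25), pct(75), pct(90)
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    counts: Dict[int, int] = {}
    for d in np.ravel(disc):
        counts[int(d)] = counts.get(int(d), 0) + 1
    probs = [c / n for c in counts.values()]
    energy = sum(v * v for v in x)
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxvol,
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "Minimum": x[0],
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": x[-1],
        "Mean": mean,
        "Median": pct(50),
        "InterquartileRange": p75 - p25,
        "Range": x[-1] - x[0],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(v - rmean) for v in robust) / len(robust),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": (sum((v - mean) ** 3 for v in x) / n) / sd**3 if sd > 0 else 0.0,
        "Kurtosis": (sum((v - mean) ** 4 for v in x) / n) / var**2 if var > 0 else 0.0,
        "Variance": var,
        "Uniformity": sum(p * p for p in probs),
    }


def reference_fcm(
    X: np.ndarray, init_centers: np.ndarray, m: float, n_iter: int
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Literal FCM update equations from fixed initial centroids."""
    X = np.asarray(X, dtype=float)
    centers = np.array(init_centers, dtype=float)
    c = len(centers)
    n = len(X)
    u = np.zeros((n, c))
    for _ in range(n_iter):
        for k in range(n):
            d = [np.linalg.norm(X[k] - centers[i]) for i in range(c)]
            if min(d) == 0:
                for i in range(c):
                    u[k, i] = 1.0 if d[i] == 0 else 0.0
                continue
            for i in range(c):
                u[k, i] = 1.0 / sum((d[i] / d[j]) ** (2.0 / (m - 1.0)) for j in range(c))
        for i in range(c):
            w = u[:, i] ** m
            centers[i] = (w[:, None] * X).sum(axis=0) / w.sum()
    obj = 0.0
    for k in range(n):
        for i in range(c):
            obj += u[k, i] ** m * np.linalg.norm(X[k] - centers[i]) ** 2
    return u, centers, obj


def naive_auc_and_delong_var(scores: np.ndarray, y: np.ndarray):
    """AUC by exhaustive concordant-pair counting plus the DeLong
    variance from placement values computed by direct counting."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    m, n = len(pos), len(neg)
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    auc = total / (m * n)
    v10 = []
    for p in pos:
        v10.append(sum(1.0 if p > q else (0.5 if p == q else 0.0) for q in neg) / n)
    v01 = []
    for q in neg:
        v01.append(sum(1.0 if p > q else (0.5 if p == q else 0.0) for p in pos) / m)
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return auc, var
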