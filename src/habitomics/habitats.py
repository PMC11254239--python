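"""Adaptive subregion (habitat) label maps.

Stage 1 — fuzzy c-means (FCM) clusters the per-voxel 4-vector of
z-scored intensities into ``n_clusters`` (10) preliminary subregions.
Stage 2 — a 368-column secondary radiomic signature (first-order +
texture, four sequences, no shape) is extracted per preliminary
cluster, standardized, reduced by PCA keeping >= 85% of the variance,
and the preliminary clusters are merged by a variational Bayesian
Gaussian mixture whose effective component count (1..10) adapts per
patient.  The final map is always a coarsening of the preliminary
partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.mixture import BayesianGaussianMixture

from habitomics.core import SEQUENCES, PreprocessedVolumeSet, SubregionLabelMap
from habitomics.features.extract import feature_names_secondary
from habitomics.features.firstorder import FIRSTORDER_NAMES, first_order_features
from habitomics.features.texture import texture_features_batch, texture_matrices
from habitomics.features.extract import TEXTURE_NAMES
from scipy import ndimage


@dataclass
class FcmConfig:
    n_clusters: int = 10
    fuzzifier_m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.fuzzifier_m <= 1:
            raise ValueError("fuzzifier_m must be > 1")


@dataclass
class HabitatConfig:
    fcm: FcmConfig = field(default_factory=FcmConfig)
    pca_retained_fraction: float = 0.85
    max_components: int = 10
    covariance_type: str = "spherical"
    min_voxels_per_cluster: int = 10
    weight_floor: float = 0.01
    n_restarts: int = 10
    seed: int = 0


def _kmeanspp_init(X: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding of the FCM centroids."""
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, c):
        d2 = np.min(
            ((X[:, None, :] - np.asarray(centers)[None, :, :]) ** 2).sum(-1), axis=1
        )
        total = d2.sum()
        if total == 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    return np.asarray(centers)


def fcm_objective(X: np.ndarray, u: np.ndarray, centers: np.ndarray, m: float) -> float:
    """The FCM objective sum_ik u_ik^m ||x_k - v_i||^2."""
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    return float((u**m * d2).sum())


def fcm_cluster(
    X: np.ndarray, config: FcmConfig, return_history: bool = False
) -> Tuple[np.ndarray, np.ndarray]:
    """Fuzzy c-means over a voxel-by-channel matrix.

    Iterates the standard membership / centroid updates until the
    maximum absolute membership change drops below ``tol`` or
    ``max_iter`` is reached.  Returns ``(memberships, hard_labels)``
    with memberships of shape (n, c) summing to 1 per row and hard
    labels in ``0..c'-1`` (empty hard clusters are dropped and the
    labeling compacted).  A voxel coinciding with a centroid receives
    full membership in that centroid's cluster.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (voxels x channels)")
    n = X.shape[0]
    c = config.n_clusters
    if n < c:
        raise ValueError(f"{n} voxels < {c} clusters")
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < c:
        warnings.warn(
            f"only {n_distinct} distinct voxel vectors for {c} clusters; "
            "result will collapse to fewer clusters"
        )
        c = max(n_distinct, 1)

    m = config.fuzzifier_m
    rng = np.random.default_rng(config.seed)
    centers = _kmeanspp_init(X, c, rng)
    u_prev = None
    history = []
    expo = 2.0 / (m - 1.0)
    for _ in range(config.max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-expo / 2.0 * 1.0)  # d^{-2/(m-1)} since d2^(expo/2) = d^expo
            u = inv / inv.sum(axis=1, keepdims=True)
        rows_zero = zero.any(axis=1)
        if rows_zero.any():
            u[rows_zero] = 0.0
            u[rows_zero, d2[rows_zero].argmin(axis=1)] = 1.0
        um = u**m
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        if return_history:
            history.append(fcm_objective(X, u, centers, m))
        if u_prev is not None and np.abs(u - u_prev).max() < config.tol:
            u_prev = u
            break
        u_prev = u
    u = u_prev

    hard = u.argmax(axis=1)
    present = np.unique(hard)
    if len(present) < u.shape[1]:
        remap = {old: new for new, old in enumerate(present)}
        hard = np.vectorize(remap.get)(hard)
        u = u[:, present]
        u = u / u.sum(axis=1, keepdims=True)
    if return_history:
        return u, hard, history
    return u, hard


def extract_secondary_features(
    pvs: PreprocessedVolumeSet,
    prelim_labels: np.ndarray,
    min_voxels: int = 10,
) -> Tuple[np.ndarray, np.ndarray, list]:
    """Per-preliminary-cluster 368-column secondary signature.

    Clusters smaller than ``min_voxels`` are merged into the nearest
    surviving cluster (centroid distance in intensity space) before
    extraction, since texture matrices are unstable on a handful of
    voxels.  Returns ``(features, labels_after_merge, cluster_ids)``
    where ``features[i]`` corresponds to ``cluster_ids[i]``.
    """
    labels = np.asarray(prelim_labels).copy()
    mask = labels > 0
    X = pvs.stacked_tumor_intensities()
    lab_vec = labels[pvs.tumor_mask.astype(bool)]

    ids, counts = np.unique(lab_vec, return_counts=True)
    small = ids[counts < min_voxels]
    big = ids[counts >= min_voxels]
    if len(big) == 0:
        big = np.array([ids[counts.argmax()]])
        small = ids[ids != big[0]]
    if len(small):
        warnings.warn(f"merging {len(small)} clusters below {min_voxels} voxels")
        cents = {i: X[lab_vec == i].mean(axis=0) for i in ids}
        for s in small:
            d = {b: np.linalg.norm(cents[s] - cents[b]) for b in big}
            tgt = min(d, key=d.get)
            lab_vec[lab_vec == s] = tgt
            labels[labels == s] = tgt

    cluster_ids = sorted(np.unique(lab_vec))
    names = feature_names_secondary()
    feats = np.empty((len(cluster_ids), len(names)))
    voxel_volume = float(np.prod(pvs.voxel_spacing_mm))
    mask_b = pvs.tumor_mask.astype(bool)
    sl = ndimage.find_objects(mask_b.astype(np.int8))[0]
    cont_cache = {seq: pvs.sequences[seq][mask_b] for seq in SEQUENCES}
    disc_cache = {seq: pvs.discretized[seq][mask_b] for seq in SEQUENCES}
    mats = []
    for cid in cluster_ids:
        sub_region = (labels == cid)[sl]
        for seq in SEQUENCES:
            region_levels = np.where(sub_region, pvs.discretized[seq][sl], 0)
            mats.append(texture_matrices(region_levels, pvs.n_gray_levels))
    tex_all = texture_features_batch(mats)
    for row, cid in enumerate(cluster_ids):
        col = 0
        region_vec = lab_vec == cid
        for si, seq in enumerate(SEQUENCES):
            fo = first_order_features(
                cont_cache[seq][region_vec], disc_cache[seq][region_vec], voxel_volume
            )
            for nm in FIRSTORDER_NAMES:
                feats[row, col] = fo[nm]
                col += 1
            tex = tex_all[row * len(SEQUENCES) + si]
            for nm in TEXTURE_NAMES:
                feats[row, col] = tex[nm]
                col += 1
    return feats, labels, cluster_ids


def reduce_pca(
    feature_matrix: np.ndarray, retained_fraction: float = 0.85
) -> Tuple[np.ndarray, np.ndarray]:
    """Standardize columns and keep the fewest PCs reaching the
    cumulative explained-variance target.

    Returns ``(scores, explained_variance_ratio)`` of the kept
    components.  Zero-variance columns are dropped (with a warning)
    before the decomposition.
    """
    M = np.asarray(feature_matrix, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need >= 2 rows for PCA")
    sd = M.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance columns before PCA")
    M = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(M)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, retained_fraction - 1e-12) + 1)
    k = min(k, scores.shape[1])
    return scores[:, :k], evr[:k]


def cluster_subregions_bgmm(
    scores: np.ndarray,
    max_components: int = 10,
    seed: int = 0,
    weight_floor: float = 0.01,
    n_restarts: int = 10,
    covariance_type: str = "spherical",
) -> Tuple[np.ndarray, int]:
    """Merge preliminary clusters with a variational Bayesian GMM.

    Fits a Dirichlet-process mixture with ``min(max_components, rows)``
    components over ``n_restarts`` seeded initializations, keeps the
    best evidence lower bound, and reports effective components —
    spherical component covariances by default: with at most ten rows
    a full covariance is rank-deficient and the variational fit
    degenerates to one component per row —
    those with posterior weight >= ``weight_floor`` and at least one
    assigned row.  Returns ``(assignment 1..V per row, V)``.
    """
    S = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    n = S.shape[0]
    if n == 1:
        return np.array([1]), 1
    k = min(max_components, n)
    if np.allclose(S, S[0]):
        return np.ones(n, dtype=int), 1

    best = None
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_restarts):
        bgm = BayesianGaussianMixture(
            n_components=k,
            covariance_type=covariance_type,
            weight_concentration_prior_type="dirichlet_process",
            weight_concentration_prior=1.0 / k,
            reg_covar=1e-4,
            max_iter=500,
            random_state=int(child.generate_state(1)[0] % (2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bgm.fit(S)
        if best is None or bgm.lower_bound_ > best.lower_bound_:
            best = bgm

    raw = best.predict(S)
    weights = best.weights_
    effective = [
        c for c in range(k) if weights[c] >= weight_floor and np.any(raw == c)
    ]
    # rows assigned to sub-floor components join the nearest effective one
    means = best.means_
    assign = np.empty(n, dtype=int)
    for i in range(n):
        if raw[i] in effective:
            assign[i] = effective.index(raw[i])
        else:
            d = [np.linalg.norm(S[i] - means[c]) for c in effective]
            assign[i] = int(np.argmin(d))
    # compact to 1..V in order of first appearance for determinism
    order = []
    for a in assign:
        if a not in order:
            order.append(a)
    relabel = {a: r + 1 for r, a in enumerate(order)}
    final = np.array([relabel[a] for a in assign], dtype=int)
    return final, len(order)


def build_subregion_map(
    pvs: PreprocessedVolumeSet, config: HabitatConfig | None = None
) -> SubregionLabelMap:
    """Full stage-1 + stage-2 subregion map for one patient."""
    config = config or HabitatConfig()
    X = pvs.stacked_tumor_intensities()
    fcm_cfg = config.fcm
    if fcm_cfg.seed != config.seed:
        fcm_cfg = FcmConfig(
            n_clusters=fcm_cfg.n_clusters,
            fuzzifier_m=fcm_cfg.fuzzifier_m,
            tol=fcm_cfg.tol,
            max_iter=fcm_cfg.max_iter,
            seed=config.seed,
        )
    _, hard = fcm_cluster(X, fcm_cfg)

    mask_b = pvs.tumor_mask.astype(bool)
    prelim = np.zeros(pvs.shape, dtype=np.int16)
    prelim[mask_b] = hard + 1

    feats, merged_labels, cluster_ids = extract_secondary_features(
        pvs, prelim, min_voxels=config.min_voxels_per_cluster
    )
    if len(cluster_ids) == 1:
        assign, V = np.array([1]), 1
    else:
        scores, _ = reduce_pca(feats, config.pca_retained_fraction)
        assign, V = cluster_subregions_bgmm(
            scores,
            max_components=min(config.max_components, len(cluster_ids)),
            seed=config.seed,
            weight_floor=config.weight_floor,
            n_restarts=config.n_restarts,
            covariance_type=config.covariance_type,
        )

    provenance = {int(cid): int(a) for cid, a in zip(cluster_ids, assign)}
    final = np.zeros(pvs.shape, dtype=np.int16)
    for cid, a in provenance.items():
        final[merged_labels == cid] = a
    return SubregionLabelMap(labels=final, V=int(V), provenance=provenance)
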