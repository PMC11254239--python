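"""Region-level feature extraction over the four MRI sequences.

Full signature: per sequence 18 first-order + 14 shape + 74 texture
= 106 features, concatenated over the 4 sequences to 424.  Shape is a
property of the region geometry alone; it is computed once and repeated
under each sequence namespace so that every sequence block carries the
complete 106-feature panel.

Secondary signature (used only for habitat clustering): first-order +
texture (92) per sequence = 368, no shape.

Feature ids are ``<sequence>_<family>_<name>``.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np
from scipy import ndimage

from habitomics.core import SEQUENCES, PreprocessedVolumeSet
from habitomics.features.firstorder import FIRSTORDER_NAMES, first_order_features
from habitomics.features.shape import SHAPE_NAMES, shape_features
from habitomics.features.texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    texture_features_batch,
    texture_matrices,
)

TEXTURE_NAMES = tuple(
    [f"glcm_{n}" for n in GLCM_NAMES]
    + [f"glrlm_{n}" for n in GLRLM_NAMES]
    + [f"glszm_{n}" for n in GLSZM_NAMES]
    + [f"gldm_{n}" for n in GLDM_NAMES]
    + [f"ngtdm_{n}" for n in NGTDM_NAMES]
)

assert len(TEXTURE_NAMES) == 74
FIRSTORDER_IDS = tuple(f"firstorder_{n}" for n in FIRSTORDER_NAMES)
SHAPE_IDS = tuple(f"shape_{n}" for n in SHAPE_NAMES)


def feature_names_full() -> List[str]:
    """The 424 feature ids of a full extraction, in canonical order."""
    names = []
    for seq in SEQUENCES:
        names += [f"{seq}_{fid}" for fid in FIRSTORDER_IDS]
        names += [f"{seq}_{fid}" for fid in SHAPE_IDS]
        names += [f"{seq}_{fid}" for fid in TEXTURE_NAMES]
    return names


def feature_names_secondary() -> List[str]:
    """The 368 secondary (clustering) feature ids: no shape family."""
    names = []
    for seq in SEQUENCES:
        names += [f"{seq}_{fid}" for fid in FIRSTORDER_IDS]
        names += [f"{seq}_{fid}" for fid in TEXTURE_NAMES]
    return names


def _region_bbox(region_mask: np.ndarray):
    sl = ndimage.find_objects(region_mask.astype(np.int8))[0]
    return sl


def extract_region_features(
    pvs: PreprocessedVolumeSet,
    labels: np.ndarray,
    region_id: int | str,
    include_shape: bool = True,
) -> Dict[str, float]:
    """Extract the per-region signature from a labeled volume.

    ``region_id`` selects ``labels == region_id`` for an integer id, or
    the whole nonzero label volume for the string ``"tumor"``.  Returns
    424 features (or 368 with ``include_shape=False``).
    """
    labels = np.asarray(labels)
    if region_id == "tumor":
        region_mask = labels > 0
    else:
        region_mask = labels == int(region_id)
    if not region_mask.any():
        raise ValueError(f"region {region_id!r} absent from label volume")

    voxel_volume = float(np.prod(pvs.voxel_spacing_mm))
    out: Dict[str, float] = {}

    shape_vals: Optional[Dict[str, float]] = None
    if include_shape:
        shape_vals = shape_features(region_mask, pvs.voxel_spacing_mm)

    sl = _region_bbox(region_mask)
    sub_mask = region_mask[sl]
    mats = []
    for seq in SEQUENCES:
        region_levels = np.where(sub_mask, pvs.discretized[seq][sl], 0)
        mats.append(texture_matrices(region_levels, pvs.n_gray_levels))
    tex_all = texture_features_batch(mats)
    for si, seq in enumerate(SEQUENCES):
        cont = pvs.sequences[seq][region_mask]
        disc = pvs.discretized[seq][region_mask]
        fo = first_order_features(cont, disc, voxel_volume)
        for name in FIRSTORDER_NAMES:
            out[f"{seq}_firstorder_{name}"] = fo[name]
        if include_shape:
            for name in SHAPE_NAMES:
                out[f"{seq}_shape_{name}"] = shape_vals[name]
        for name in TEXTURE_NAMES:
            out[f"{seq}_{name}"] = tex_all[si][name]
    return out
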