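"""Volume standardization: bias correction, z-scoring, resampling, discretization.

The pipeline order is fixed — bias correction, then intensity
standardization, then isotropic resampling, then gray-level
discretization — and enforced by :func:`preprocess_volumeset`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import SimpleITK as sitk

from habitomics.core import SEQUENCES, PreprocessedVolumeSet, VolumeSet


@dataclass
class PreprocessConfig:
    target_spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_gray_levels: int = 32
    bias_correction: bool = True
    normalization_region: str = "volume"  # "volume" | "mask"

    def __post_init__(self) -> None:
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be >= 2")
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValueError("target spacing must be positive")
        if self.normalization_region not in ("volume", "mask"):
            raise ValueError("normalization_region must be 'volume' or 'mask'")


def _to_sitk(volume: np.ndarray, spacing) -> sitk.Image:
    # numpy (x, y, z) -> sitk expects z-fastest via GetImageFromArray
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.T).astype(np.float64))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).T


def correct_bias(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing_mm=(1.0, 1.0, 1.0),
    shrink_factor: int = 2,
) -> np.ndarray:
    """N4 bias-field correction of a multiplicative smooth intensity field.

    The correction runs in the log domain, so the volume must be
    strictly positive; non-positive voxels trigger a global
    shift-to-positive with a warning.  The output is rescaled so the
    mean over ``mask`` equals the input mean over ``mask`` (the overall
    gain of the scanner is not identifiable and is fixed by convention).
    """
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask).astype(np.uint8)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    mean_all = volume.mean()
    if mean_all == 0 or volume.std() / abs(mean_all) < 1e-8:
        return volume.copy()  # constant input: nothing to correct
    shift = 0.0
    vmin = volume.min()
    if vmin <= 0:
        shift = -vmin + 1.0
        warnings.warn("non-positive voxels: shifting volume to positive for N4")
    work = volume + shift

    img = _to_sitk(work, spacing_mm)
    msk = sitk.GetImageFromArray(np.ascontiguousarray(np.ones_like(mask).T))
    msk.CopyInformation(img)
    if shrink_factor > 1:
        small = sitk.Shrink(img, [shrink_factor] * 3)
        small_mask = sitk.Shrink(msk, [shrink_factor] * 3)
    else:
        small, small_mask = img, msk
    corrector = sitk.N4BiasFieldCorrectionImageFilter()
    corrector.SetMaximumNumberOfIterations([30, 30, 30])
    corrector.Execute(small, sitk.Cast(small_mask, sitk.sitkUInt8))
    log_field = corrector.GetLogBiasFieldAsImage(img)
    field = np.exp(_from_sitk(log_field))
    corrected = work / field - shift

    m = mask.astype(bool)
    gain = volume[m].mean() / corrected[m].mean()
    return corrected * gain


def zscore_normalize(
    volume: np.ndarray, mask: np.ndarray | None = None, region: str = "volume"
) -> np.ndarray:
    """Standardize intensities to zero mean, unit variance.

    ``region='volume'`` uses every voxel for the statistics (the
    default); ``region='mask'`` uses in-mask voxels only.  Either way
    the transform is applied to the whole volume.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if region == "mask":
        if mask is None:
            raise ValueError("mask required for region='mask'")
        sel = volume[np.asarray(mask).astype(bool)]
    else:
        sel = volume.ravel()
    if sel.size < 2:
        raise ValueError("normalization region must have >= 2 voxels")
    sd = sel.std()
    if sd == 0:
        raise ValueError("zero variance in normalization region")
    return (volume - sel.mean()) / sd


def resample_isotropic(
    volume: np.ndarray,
    in_spacing,
    out_spacing,
    is_label: bool = False,
) -> np.ndarray:
    """Resample to a new voxel spacing.

    Scalar volumes use cubic B-spline interpolation; label volumes and
    masks use nearest-neighbor.  The output grid covers the input
    physical extent (shape = ceil(extent / out_spacing)) with the same
    world origin.
    """
    in_spacing = tuple(float(s) for s in in_spacing)
    out_spacing = tuple(float(s) for s in out_spacing)
    if any(s <= 0 for s in in_spacing + out_spacing):
        raise ValueError("spacings must be positive")
    volume = np.asarray(volume)
    if is_label and not np.issubdtype(volume.dtype, np.integer):
        if not np.all(np.equal(np.mod(volume, 1), 0)):
            raise ValueError("label volume must be integer-valued")
    img = _to_sitk(volume.astype(np.float64), in_spacing)
    out_size = [
        int(np.ceil(volume.shape[i] * in_spacing[i] / out_spacing[i])) for i in range(3)
    ]
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing(out_spacing)
    res.SetSize(out_size)
    res.SetOutputOrigin(img.GetOrigin())
    res.SetOutputDirection(img.GetDirection())
    res.SetInterpolator(sitk.sitkNearestNeighbor if is_label else sitk.sitkBSpline)
    # output samples beyond the last input sample center take the edge value
    res.SetUseNearestNeighborExtrapolator(True)
    out = _from_sitk(res.Execute(img))
    if is_label:
        out = np.rint(out).astype(np.int32)
    return out


def discretize_gray_levels(
    volume: np.ndarray, mask: np.ndarray, n_levels: int
) -> np.ndarray:
    """Fixed-bin-count discretization over the in-mask intensity range.

    Levels are ``floor(n_levels * (x - min) / (max - min)) + 1`` capped
    at ``n_levels``; voxels outside the mask are 0.  A constant region
    maps everything to level 1 with a warning.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    volume = np.asarray(volume, dtype=np.float64)
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    vals = volume[m]
    vmin, vmax = vals.min(), vals.max()
    out = np.zeros(volume.shape, dtype=np.int32)
    if vmax == vmin:
        warnings.warn("constant region: all voxels map to level 1")
        out[m] = 1
        return out
    lev = np.floor(n_levels * (vals - vmin) / (vmax - vmin)).astype(np.int32) + 1
    out[m] = np.minimum(lev, n_levels)
    return out


def preprocess_volumeset(
    vs: VolumeSet, config: PreprocessConfig | None = None
) -> PreprocessedVolumeSet:
    """Run the fixed standardization sequence on one patient.

    Order: (optional) N4 bias correction -> z-score -> isotropic
    resampling (skipped when the grid is already at target spacing) ->
    32-level discretization over the tumor mask.
    """
    config = config or PreprocessConfig()
    spacing = vs.voxel_spacing_mm
    needs_resample = not np.allclose(spacing, config.target_spacing_mm)

    sequences = {}
    mask = vs.tumor_mask
    for name in SEQUENCES:
        vol = vs.sequences[name]
        if config.bias_correction:
            vol = correct_bias(vol, mask, spacing)
        vol = zscore_normalize(vol, mask, region=config.normalization_region)
        if needs_resample:
            vol = resample_isotropic(vol, spacing, config.target_spacing_mm)
        sequences[name] = vol
    if needs_resample:
        mask = resample_isotropic(
            mask, spacing, config.target_spacing_mm, is_label=True
        ).astype(np.uint8)
        spacing = config.target_spacing_mm

    discretized = {
        name: discretize_gray_levels(sequences[name], mask, config.n_gray_levels)
        for name in SEQUENCES
    }
    return PreprocessedVolumeSet(
        sequences=sequences,
        discretized=discretized,
        tumor_mask=mask,
        voxel_spacing_mm=tuple(float(s) for s in spacing),
        n_gray_levels=config.n_gray_levels,
        patient_id=vs.patient_id,
    )
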