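"""Core containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

#: Canonical sequence order used everywhere (feature naming, channel stacking).
SEQUENCES: Tuple[str, ...] = ("T2WI", "T1WI", "DWI", "CE-T1WI")


def _as_spacing(spacing) -> Tuple[float, float, float]:
    s = tuple(float(v) for v in spacing)
    if len(s) != 3 or any(v <= 0 for v in s):
        raise ValueError(f"voxel spacing must be three positive numbers, got {spacing!r}")
    return s


@dataclass
class VolumeSet:
    """Four co-registered scalar volumes plus a binary tumor mask for one patient.

    All arrays share one grid; ``voxel_spacing_mm`` is the (x, y, z) voxel
    size.  Sequences are keyed by the names in :data:`SEQUENCES`.
    """

    sequences: Dict[str, np.ndarray]
    tumor_mask: np.ndarray
    voxel_spacing_mm: Tuple[float, float, float]
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.voxel_spacing_mm = _as_spacing(self.voxel_spacing_mm)
        missing = [s for s in SEQUENCES if s not in self.sequences]
        if missing:
            raise ValueError(f"missing sequences: {missing}")
        self.tumor_mask = np.asarray(self.tumor_mask)
        shape = self.tumor_mask.shape
        if self.tumor_mask.ndim != 3:
            raise ValueError("tumor mask must be 3-D")
        uniq = np.unique(self.tumor_mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("tumor mask must be binary (0/1)")
        if not self.tumor_mask.any():
            raise ValueError("tumor mask is empty")
        for name in SEQUENCES:
            vol = np.asarray(self.sequences[name], dtype=np.float64)
            if vol.shape != shape:
                raise ValueError(
                    f"sequence {name} shape {vol.shape} != mask shape {shape}"
                )
            self.sequences[name] = vol

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.tumor_mask.shape

    @property
    def n_tumor_voxels(self) -> int:
        return int(self.tumor_mask.sum())

    def stacked_tumor_intensities(self) -> np.ndarray:
        """(n_tumor_voxels, 4) matrix of intensities, sequence order fixed."""
        m = self.tumor_mask.astype(bool)
        return np.column_stack([self.sequences[s][m] for s in SEQUENCES])


@dataclass
class PreprocessedVolumeSet:
    """A :class:`VolumeSet` after standardization.

    ``sequences`` hold z-scored continuous intensities; ``discretized``
    hold integer gray levels in ``1..n_gray_levels`` inside the tumor
    mask and 0 outside.
    """

    sequences: Dict[str, np.ndarray]
    discretized: Dict[str, np.ndarray]
    tumor_mask: np.ndarray
    voxel_spacing_mm: Tuple[float, float, float]
    n_gray_levels: int
    patient_id: Optional[str] = None

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.tumor_mask.shape

    def stacked_tumor_intensities(self) -> np.ndarray:
        m = self.tumor_mask.astype(bool)
        return np.column_stack([self.sequences[s][m] for s in SEQUENCES])


@dataclass
class SubregionLabelMap:
    """Final adaptive subregion labeling of one tumor.

    ``labels`` is 0 outside the tumor and ``1..V`` inside; ``provenance``
    maps each preliminary fuzzy-c-means cluster to its final subregion,
    so the final map is by construction a coarsening of the preliminary
    partition.
    """

    labels: np.ndarray
    V: int
    provenance: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = np.unique(self.labels[self.labels > 0])
        if self.V < 1 or self.V > 10:
            raise ValueError(f"V={self.V} outside 1..10")
        if len(present) and (present.min() < 1 or present.max() > self.V):
            raise ValueError("labels must be within 1..V")

    def region_ids(self):
        return list(range(1, self.V + 1))
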