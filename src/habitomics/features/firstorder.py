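"""First-order intensity statistics.

The 18-feature set follows the IBSI / pyradiomics default first-order
panel.  Histogram-based statistics (entropy, uniformity) operate on the
discretized gray levels; all others operate on the continuous (z-scored)
intensities.  Moment-based statistics use population (biased) moments;
kurtosis is the raw fourth standardized moment (3 for a Gaussian), not
excess kurtosis.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(
    values: np.ndarray,
    discretized: np.ndarray,
    voxel_volume_mm3: float = 1.0,
) -> Dict[str, float]:
    """Compute the 18 first-order features of one region.

    Parameters
    ----------
    values
        Continuous intensities of the in-region voxels (1-D).
    discretized
        Integer gray levels of the same voxels (used for entropy and
        uniformity).
    voxel_volume_mm3
        Physical voxel volume; scales ``TotalEnergy``.

    Degenerate statistics of a constant region (skewness, kurtosis)
    return 0 by convention.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty region")
    d = np.asarray(discretized).ravel()
    if d.size != x.size:
        raise ValueError("values and discretized must align")

    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if robust.size:
        rmad = float(np.abs(robust - robust.mean()).mean())
    else:  # pragma: no cover - percentile bounds always keep >=1 value
        rmad = 0.0

    if var > 0:
        sd = np.sqrt(var)
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2)
    else:
        skew = 0.0
        kurt = 0.0

    _, counts = np.unique(d, return_counts=True)
    p = counts / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * float(voxel_volume_mm3),
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(energy / n)),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }
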