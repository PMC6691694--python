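"""First-order (intensity-distribution) features of the in-ROI voxels.

All moments use the population convention (divide by n).  Skewness is the
Fisher moment coefficient g1 = m3 / m2^{3/2} without bias correction;
kurtosis is the (non-excess) Pearson coefficient m4 / m2^2.  Both are
defined as 0 for zero-variance input so that a constant ROI still yields a
complete feature vector.  Histogram-based features (entropy, uniformity)
use an equal-width histogram with ``n_bins`` bins between the in-ROI min
and max; entropy is in bits.
"""

from __future__ import annotations

import numpy as np

FIRST_ORDER_NAMES = [
    "fos_mean",
    "fos_median",
    "fos_min",
    "fos_max",
    "fos_range",
    "fos_variance",
    "fos_standard_deviation",
    "fos_skewness",
    "fos_kurtosis",
    "fos_energy",
    "fos_entropy",
    "fos_rms",
    "fos_mean_absolute_deviation",
    "fos_uniformity",
    "fos_p10",
    "fos_p25",
    "fos_p75",
    "fos_p90",
    "fos_iqr",
    "fos_coefficient_of_variation",
]


def first_order_features(values: np.ndarray, n_bins: int = 32) -> dict:
    """Compute the 20 first-order features of a 1D array of ROI intensities."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("first-order features require at least one voxel")
    n = x.size
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev**2)
    m3 = np.mean(dev**3)
    m4 = np.mean(dev**4)
    sd = np.sqrt(m2)
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 if m2 > 0 else 0.0

    lo, hi = x.min(), x.max()
    if hi > lo:
        hist, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    else:
        hist = np.array([n])
    p = hist[hist > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    cv = sd / mean if mean != 0 else 0.0
    return {
        "fos_mean": float(mean),
        "fos_median": float(p50),
        "fos_min": float(lo),
        "fos_max": float(hi),
        "fos_range": float(hi - lo),
        "fos_variance": float(m2),
        "fos_standard_deviation": float(sd),
        "fos_skewness": float(skew),
        "fos_kurtosis": float(kurt),
        "fos_energy": float((x**2).sum()),
        "fos_entropy": entropy,
        "fos_rms": float(np.sqrt((x**2).mean())),
        "fos_mean_absolute_deviation": float(np.abs(dev).mean()),
        "fos_uniformity": uniformity,
        "fos_p10": float(p10),
        "fos_p25": float(p25),
        "fos_p75": float(p75),
        "fos_p90": float(p90),
        "fos_iqr": float(p75 - p25),
        "fos_coefficient_of_variation": float(cv),
    }
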