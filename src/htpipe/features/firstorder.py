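"""The 18 first-order (intensity histogram) features.

Conventions: Energy is the raw sum of squares and TotalEnergy scales it by
the voxel volume; Entropy (bits) and Uniformity are computed on the
discretized in-ROI histogram; Variance, Skewness and Kurtosis use population
(biased) moments, with Kurtosis in the Pearson (non-excess) convention;
percentiles use linear interpolation.
"""

from __future__ import annotations

import numpy as np

from htpipe.features.discretize import DiscretizationSpec, discretize

FIRST_ORDER_NAMES: tuple[str, ...] = (
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "MeanAbsoluteDeviation",
    "Mean",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
)


def first_order(
    intensities: np.ndarray,
    voxel_volume: float = 1.0,
    disc_spec: DiscretizationSpec | None = None,
) -> dict[str, float]:
    """Compute the 18 first-order features of one ROI's intensity sample."""
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("first_order requires at least one intensity sample")

    n = x.size
    mean = x.mean()
    dev = x - mean
    m2 = float(np.mean(dev**2))
    m3 = float(np.mean(dev**3))
    m4 = float(np.mean(dev**4))

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    energy = float(np.sum(x**2))

    levels = discretize(x, disc_spec)
    p = np.bincount(levels)[1:].astype(float) / n
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p**2).sum())

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": entropy,
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Maximum": float(x.max()),
        "MeanAbsoluteDeviation": float(np.abs(dev).mean()),
        "Mean": float(mean),
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(energy / n)),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "TotalEnergy": float(voxel_volume) * energy,
        "Uniformity": uniformity,
        "Variance": m2,
    }
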