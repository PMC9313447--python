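"""Gray-level discretization for histogram and texture features."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscretizationSpec:
    """How ROI intensities are binned into discrete gray levels.

    ``fixed-bin-count`` computes ``value`` equal-width bins between the
    in-ROI minimum and maximum (a per-ROI, scale-free choice — the default,
    with 32 bins).  ``fixed-bin-width`` uses bins of width ``value`` anchored
    at 0, preserving absolute intensity meaning across ROIs.
    """

    mode: str = "fixed-bin-count"
    value: float = 32

    def __post_init__(self) -> None:
        if self.mode not in ("fixed-bin-count", "fixed-bin-width"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.value <= 0:
            raise ValueError("discretization value must be > 0")
        if self.mode == "fixed-bin-count" and int(self.value) != self.value:
            raise ValueError("fixed-bin-count requires an integer bin count")


def discretize(values: np.ndarray, spec: DiscretizationSpec | None = None) -> np.ndarray:
    """Map intensities to integer gray levels starting at 1.

    A constant input maps entirely to level 1.  With fixed bin count the
    maximum value lands in the top bin.
    """
    spec = spec or DiscretizationSpec()
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty array")
    lo, hi = values.min(), values.max()
    if spec.mode == "fixed-bin-count":
        n = int(spec.value)
        if hi == lo:
            return np.ones(values.shape, dtype=np.int64)
        edges = np.linspace(lo, hi, n + 1)
        return np.digitize(values, edges[1:-1], right=False) + 1
    # fixed-bin-width, anchored at 0
    w = float(spec.value)
    base = np.floor(lo / w)
    return (np.floor(values / w) - base).astype(np.int64) + 1
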