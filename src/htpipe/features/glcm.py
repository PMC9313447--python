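"""Gray-level co-occurrence matrix (GLCM) texture features.

Co-occurrences of discretized gray levels are accumulated over in-mask
voxel pairs at a fixed offset for each of the 13 unique 3-D neighbour
directions, symmetrized, normalized to a joint probability matrix per
direction, and each of the 22 features is computed per direction and then
averaged.  Logarithms are base 2 with 0·log 0 ≡ 0.

The matrix is indexed by the gray-level *values* actually present in the
ROI (empty levels are dropped, values retained), and ``Ng`` in the
normalized inverse-difference features is the number of present levels.
Degenerate single-level ROIs yield the constant-image limit (Contrast 0,
JointEnergy 1, Correlation 1) rather than an error; a mask too thin to form
a single voxel pair in any direction is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GLCM_NAMES: tuple[str, ...] = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
)

#: the 13 unique (non-antiparallel) 3-D neighbour offsets
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
    and ((dx > 0) or (dx == 0 and dy > 0) or (dx == 0 and dy == 0 and dz > 0))
)


@dataclass
class GLCMSpec:
    distance: int = 1
    directions: tuple[tuple[int, int, int], ...] = field(default=DIRECTIONS_13)
    symmetric: bool = True
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.aggregation != "mean":
            raise ValueError("only mean-over-directions aggregation is supported")
        if self.symmetric:
            seen = set(self.directions)
            anti = {tuple(-c for c in d) for d in self.directions}
            if seen & anti:
                raise ValueError("directions must be pairwise non-antiparallel when symmetric")


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_matrices(
    levels: np.ndarray,
    mask: np.ndarray,
    spec: GLCMSpec | None = None,
    roi_name: str = "<roi>",
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate normalized GLCMs for every direction with at least one pair.

    Returns ``(P, level_values)`` where ``P`` has shape
    ``(n_directions_kept, L, L)`` and ``level_values`` are the ``L`` distinct
    in-mask gray-level values (ascending).
    """
    spec = spec or GLCMSpec()
    levels = np.asarray(levels)
    mask = np.asarray(mask).astype(bool)
    if levels.shape != mask.shape:
        raise ValueError("levels and mask must share one grid")
    if not mask.any():
        raise ValueError(f"empty mask for ROI {roi_name}")

    values = np.unique(levels[mask])
    L = len(values)
    rank = np.zeros(levels.shape, dtype=np.int64)
    rank[mask] = np.searchsorted(values, levels[mask])

    mats = []
    for d in spec.directions:
        off = tuple(int(c) * spec.distance for c in d)
        src = tuple(
            slice(max(0, -o), levels.shape[a] - max(0, o)) for a, o in enumerate(off)
        )
        dst = tuple(
            slice(max(0, o), levels.shape[a] - max(0, -o)) for a, o in enumerate(off)
        )
        valid = mask[src] & mask[dst]
        if not valid.any():
            continue
        a = rank[src][valid]
        b = rank[dst][valid]
        counts = np.bincount(a * L + b, minlength=L * L).reshape(L, L).astype(float)
        if spec.symmetric:
            counts = counts + counts.T
        mats.append(counts / counts.sum())
    if not mats:
        raise ValueError(f"no in-mask voxel pair in any direction for ROI {roi_name}")
    return np.stack(mats), values.astype(float)


def _level_weights(lv: np.ndarray) -> dict:
    """Level-value-dependent weight matrices, cached across ROIs.

    Every feature that is a linear functional of the joint probabilities is
    evaluated as one matrix product against this stacked weight matrix.
    """
    key = lv.tobytes()
    cached = _WEIGHT_CACHE.get(key)
    if cached is not None:
        return cached
    L = len(lv)
    Ng = L
    i = lv[:, None]
    j = lv[None, :]
    diff = np.abs(i - j)
    summ = i + j
    with np.errstate(divide="ignore"):
        inv_d2 = np.where(diff > 0, 1.0 / np.where(diff > 0, diff**2, 1.0), 0.0)
    stack = np.stack(
        [
            diff**2,                      # contrast
            i * j,                        # autocorrelation
            1.0 / (1.0 + diff**2),        # idm
            1.0 / (1.0 + (diff / Ng) ** 2),  # idmn
            1.0 / (1.0 + diff),           # id
            1.0 / (1.0 + diff / Ng),      # idn
            inv_d2,                       # inverse variance
            summ,                         # E[s]
            summ**2,                      # E[s^2]
            summ**3,                      # E[s^3]
            summ**4,                      # E[s^4]
        ]
    ).reshape(11, -1)
    dvals, dinv = np.unique(diff, return_inverse=True)
    svals, sinv = np.unique(summ, return_inverse=True)
    onehot_d = np.zeros((L * L, len(dvals)))
    onehot_d[np.arange(L * L), dinv.ravel()] = 1.0
    onehot_s = np.zeros((L * L, len(svals)))
    onehot_s[np.arange(L * L), sinv.ravel()] = 1.0
    cached = {"stack": stack.T, "dvals": dvals, "svals": svals,
              "onehot_d": onehot_d, "onehot_s": onehot_s}
    if len(_WEIGHT_CACHE) > 256:
        _WEIGHT_CACHE.clear()
    _WEIGHT_CACHE[key] = cached
    return cached


_WEIGHT_CACHE: dict = {}


def glcm_features(P: np.ndarray, level_values: np.ndarray) -> dict[str, float]:
    """The 22 texture features, computed per direction then averaged."""
    P = np.asarray(P, dtype=float)
    if P.ndim == 2:
        P = P[None]
    lv = np.asarray(level_values, dtype=float)
    D, L, _ = P.shape

    W = _level_weights(lv)
    Pf = P.reshape(D, L * L)
    lin = Pf @ W["stack"]  # (D, 11) linear functionals of the joint matrix
    contrast, autocorr, idm, idmn, id_, idn, inverse_var = lin[:, :7].T
    s1, s2, s3, s4 = lin[:, 7:].T  # raw moments of the sum distribution

    px = P.sum(axis=2)  # (D, L) row marginal; symmetric => px == py
    mu = px @ lv  # (D,)
    var = px @ lv**2 - mu**2
    joint_avg = mu

    # central moments of s = i + j give the cluster features (E[s] = 2 mu)
    m = 2.0 * mu
    cluster_t = s2 - m**2
    cluster_s = s3 - 3.0 * m * s2 + 2.0 * m**3
    cluster_p = s4 - 4.0 * m * s3 + 6.0 * m**2 * s2 - 3.0 * m**4

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (autocorr - mu**2) / var
    corr = np.where(var > 0, corr, 1.0)  # constant level: perfectly correlated

    joint_energy = (Pf**2).sum(axis=1)
    HXY = -_xlog2(Pf).sum(axis=1)
    max_prob = Pf.max(axis=1)

    # difference and sum distributions over the distinct |i-j| and i+j values
    pdiff = Pf @ W["onehot_d"]
    psum = Pf @ W["onehot_s"]
    dvals, svals = W["dvals"], W["svals"]
    diff_avg = pdiff @ dvals
    diff_ent = -_xlog2(pdiff).sum(axis=1)
    diff_var = pdiff @ dvals**2 - diff_avg**2
    sum_ent = -_xlog2(psum).sum(axis=1)

    # information measures of correlation; for a joint with marginals px, py
    # the textbook HXY1 and HXY2 terms both reduce to HX + HY analytically
    HX = -_xlog2(px).sum(axis=1)
    HXY1 = HXY2 = 2.0 * HX  # symmetric matrix: HY == HX
    with np.errstate(invalid="ignore", divide="ignore"):
        imc1 = (HXY - HXY1) / HX
    imc1 = np.where(HX > 0, imc1, 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (HXY2 - HXY)), 0.0, 1.0))

    per_direction = {
        "Autocorrelation": autocorr,
        "JointAverage": joint_avg,
        "ClusterProminence": cluster_p,
        "ClusterShade": cluster_s,
        "ClusterTendency": cluster_t,
        "Contrast": contrast,
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": diff_ent,
        "DifferenceVariance": diff_var,
        "JointEnergy": joint_energy,
        "JointEntropy": HXY,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": idm,
        "Idmn": idmn,
        "Id": id_,
        "Idn": idn,
        "InverseVariance": inverse_var,
        "MaximumProbability": max_prob,
        "SumEntropy": sum_ent,
        "SumSquares": var,
    }
    return {k: float(v.mean()) for k, v in per_direction.items()}


def glcm(
    levels: np.ndarray,
    mask: np.ndarray,
    spec: GLCMSpec | None = None,
    roi_name: str = "<roi>",
) -> dict[str, float]:
    """Convenience wrapper: matrices + direction-averaged features."""
    P, values = glcm_matrices(levels, mask, spec, roi_name)
    return glcm_features(P, values)
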