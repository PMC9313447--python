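"""Naive reference implementations of the 54 radiomics features.

Deliberately slow and literal: plain Python loops over voxels, pairs and
gray levels, following the textbook definitions.  These serve as the
independent oracle the fast vectorized implementations are checked against.
"""

from __future__ import annotations

import math

import numpy as np
from skimage.measure import marching_cubes


def naive_percentile(xs: list[float], q: float) -> float:
    """Linear-interpolation percentile, computed by hand."""
    s = sorted(xs)
    if len(s) == 1:
        return s[0]
    pos = q / 100.0 * (len(s) - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(s) - 1)
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def naive_discretize(xs: list[float], nbins: int = 32) -> list[int]:
    lo, hi = min(xs), max(xs)
    if hi == lo:
        return [1 for _ in xs]
    width = (hi - lo) / nbins
    out = []
    for x in xs:
        level = int((x - lo) / width) + 1
        out.append(min(level, nbins))
    return out


def naive_first_order(xs: list[float], voxel_volume: float = 1.0, nbins: int = 32) -> dict:
    n = len(xs)
    mean = sum(xs) / n
    m2 = sum((x - mean) ** 2 for x in xs) / n
    m3 = sum((x - mean) ** 3 for x in xs) / n
    m4 = sum((x - mean) ** 4 for x in xs) / n
    p10 = naive_percentile(xs, 10)
    p90 = naive_percentile(xs, 90)
    energy = sum(x * x for x in xs)

    levels = naive_discretize(xs, nbins)
    probs = []
    for lvl in sorted(set(levels)):
        probs.append(levels.count(lvl) / n)
    entropy = -sum(p * math.log2(p) for p in probs if p > 0)
    uniformity = sum(p * p for p in probs)

    robust = [x for x in xs if p10 <= x <= p90]
    rmean = sum(robust) / len(robust)
    rmad = sum(abs(x - rmean) for x in robust) / len(robust)

    return {
        "10Percentile": p10,
        "90Percentile": p90,
        "Energy": energy,
        "Entropy": entropy,
        "InterquartileRange": naive_percentile(xs, 75) - naive_percentile(xs, 25),
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Maximum": max(xs),
        "MeanAbsoluteDeviation": sum(abs(x - mean) for x in xs) / n,
        "Mean": mean,
        "Median": naive_percentile(xs, 50),
        "Minimum": min(xs),
        "Range": max(xs) - min(xs),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "TotalEnergy": voxel_volume * energy,
        "Uniformity": uniformity,
        "Variance": m2,
    }


def naive_shape(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict:
    """Shape oracle: same mesh as the implementation (marching cubes of the
    padded bounding box), but every derived quantity is accumulated with
    explicit loops; diameters are brute-force over all vertex pairs."""
    mask = np.asarray(mask).astype(bool)
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    padded = np.pad(sub, 3).astype(float)
    from scipy.ndimage import gaussian_filter

    field = gaussian_filter(padded, 0.6)
    if field.max() <= 0.5:
        field = padded
    verts, faces, _, _ = marching_cubes(field, level=0.5, spacing=tuple(spacing))

    area = 0.0
    vol6 = 0.0
    for f in faces:
        a, b, c = verts[f[0]], verts[f[1]], verts[f[2]]
        ab = [b[k] - a[k] for k in range(3)]
        ac = [c[k] - a[k] for k in range(3)]
        cx = [ab[1] * ac[2] - ab[2] * ac[1],
              ab[2] * ac[0] - ab[0] * ac[2],
              ab[0] * ac[1] - ab[1] * ac[0]]
        area += 0.5 * math.sqrt(sum(v * v for v in cx))
        vol6 += a[0] * cx[0] + a[1] * cx[1] + a[2] * cx[2]
    mesh_volume = abs(vol6) / 6.0

    n = len(idx)
    coords = [[idx[i][k] * spacing[k] for k in range(3)] for i in range(n)]
    center = [sum(c[k] for c in coords) / n for k in range(3)]
    cov = [[sum((c[a] - center[a]) * (c[b] - center[b]) for c in coords) / n
            for b in range(3)] for a in range(3)]
    eig = sorted(np.linalg.eigvalsh(np.array(cov)), reverse=True)
    eig = [max(e, 0.0) for e in eig]

    def max_dist(points) -> float:
        best = 0.0
        for i in range(len(points)):
            for j in range(i + 1, len(points)):
                d = math.sqrt(sum((points[i][k] - points[j][k]) ** 2
                                  for k in range(len(points[i]))))
                best = max(best, d)
        return best

    vlist = [tuple(v) for v in verts]
    return {
        "Elongation": math.sqrt(eig[1] / eig[0]) if eig[0] > 0 else 0.0,
        "Flatness": math.sqrt(eig[2] / eig[0]) if eig[0] > 0 else 0.0,
        "LeastAxisLength": 4 * math.sqrt(eig[2]),
        "MajorAxisLength": 4 * math.sqrt(eig[0]),
        "Maximum2DDiameterColumn": max_dist([(v[1], v[2]) for v in vlist]),
        "Maximum2DDiameterRow": max_dist([(v[0], v[2]) for v in vlist]),
        "Maximum2DDiameterSlice": max_dist([(v[0], v[1]) for v in vlist]),
        "Maximum3DDiameter": max_dist(vlist),
        "MeshVolume": mesh_volume,
        "MinorAxisLength": 4 * math.sqrt(eig[1]),
        "Sphericity": (36 * math.pi * mesh_volume**2) ** (1 / 3) / area,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / mesh_volume,
        "VoxelVolume": float(n) * spacing[0] * spacing[1] * spacing[2],
    }


NAIVE_DIRECTIONS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
    and ((dx > 0) or (dx == 0 and dy > 0) or (dx == 0 and dy == 0 and dz > 0))
]


def naive_glcm(levels: np.ndarray, mask: np.ndarray, distance: int = 1,
               directions=None) -> dict:
    """GLCM oracle: dictionaries of pair counts per direction, textbook
    feature formulas per direction (including explicit HXY1/HXY2 double
    sums), then the plain average over directions with at least one pair."""
    levels = np.asarray(levels)
    mask = np.asarray(mask).astype(bool)
    directions = directions or NAIVE_DIRECTIONS
    values = sorted({int(levels[tuple(v)]) for v in np.argwhere(mask)})
    Ng = len(values)
    shape = mask.shape

    per_direction = []
    for d in directions:
        counts: dict[tuple[int, int], float] = {}
        total = 0
        for v in np.argwhere(mask):
            w = (v[0] + d[0] * distance, v[1] + d[1] * distance, v[2] + d[2] * distance)
            if not all(0 <= w[k] < shape[k] for k in range(3)):
                continue
            if not mask[w]:
                continue
            a, b = int(levels[tuple(v)]), int(levels[w])
            counts[(a, b)] = counts.get((a, b), 0) + 1  # forward
            counts[(b, a)] = counts.get((b, a), 0) + 1  # symmetrize
            total += 2
        if total == 0:
            continue
        P = {k: c / total for k, c in counts.items()}

        px = {i: sum(P.get((i, j), 0.0) for j in values) for i in values}
        mu = sum(i * px[i] for i in values)
        var = sum((i - mu) ** 2 * px[i] for i in values)

        feats = {}
        feats["Autocorrelation"] = sum(P[(i, j)] * i * j for (i, j) in P)
        feats["JointAverage"] = mu
        feats["ClusterProminence"] = sum(P[(i, j)] * (i + j - 2 * mu) ** 4 for (i, j) in P)
        feats["ClusterShade"] = sum(P[(i, j)] * (i + j - 2 * mu) ** 3 for (i, j) in P)
        feats["ClusterTendency"] = sum(P[(i, j)] * (i + j - 2 * mu) ** 2 for (i, j) in P)
        feats["Contrast"] = sum(P[(i, j)] * (i - j) ** 2 for (i, j) in P)
        if var > 0:
            feats["Correlation"] = (feats["Autocorrelation"] - mu * mu) / var
        else:
            feats["Correlation"] = 1.0

        pdiff: dict[int, float] = {}
        psum: dict[int, float] = {}
        for (i, j), p in P.items():
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p
            psum[i + j] = psum.get(i + j, 0.0) + p
        da = sum(k * p for k, p in pdiff.items())
        feats["DifferenceAverage"] = da
        feats["DifferenceEntropy"] = -sum(p * math.log2(p) for p in pdiff.values() if p > 0)
        feats["DifferenceVariance"] = sum((k - da) ** 2 * p for k, p in pdiff.items())
        feats["JointEnergy"] = sum(p * p for p in P.values())
        hxy = -sum(p * math.log2(p) for p in P.values() if p > 0)
        feats["JointEntropy"] = hxy

        hx = -sum(p * math.log2(p) for p in px.values() if p > 0)
        hxy1 = -sum(P[(i, j)] * math.log2(px[i] * px[j])
                    for (i, j) in P if px[i] * px[j] > 0)
        hxy2 = -sum(px[i] * px[j] * math.log2(px[i] * px[j])
                    for i in values for j in values if px[i] * px[j] > 0)
        feats["Imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
        inner = 1.0 - math.exp(-2.0 * (hxy2 - hxy))
        feats["Imc2"] = math.sqrt(min(max(inner, 0.0), 1.0))

        feats["Idm"] = sum(p / (1 + (i - j) ** 2) for (i, j), p in P.items())
        feats["Idmn"] = sum(p / (1 + ((i - j) / Ng) ** 2) for (i, j), p in P.items())
        feats["Id"] = sum(p / (1 + abs(i - j)) for (i, j), p in P.items())
        feats["Idn"] = sum(p / (1 + abs(i - j) / Ng) for (i, j), p in P.items())
        feats["InverseVariance"] = sum(p / (i - j) ** 2 for (i, j), p in P.items() if i != j)
        feats["MaximumProbability"] = max(P.values())
        feats["SumEntropy"] = -sum(p * math.log2(p) for p in psum.values() if p > 0)
        feats["SumSquares"] = var
        per_direction.append(feats)

    keys = per_direction[0].keys()
    return {k: sum(f[k] for f in per_direction) / len(per_direction) for k in keys}
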