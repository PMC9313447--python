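"""Vascular-territory label atlas.

The brain is partitioned into ten arterial supply areas per hemisphere:
anterior cerebral (``a``), the five middle-cerebral-artery subterritories
(``m1``–``m5``), posterior cerebral (``p``), lenticular nucleus (``l``),
caudate nucleus (``c``) and insula (``i``).  Labels encode (territory, side):
territory ``t`` with 0-based index ``k`` gets right label ``k + 1`` and left
label ``k + 11``; 0 is background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from htpipe.volume import ImageVolume, SYMMETRY_AXIS

#: canonical territory ordering, used everywhere a deterministic order matters
TERRITORIES: tuple[str, ...] = ("a", "m1", "m2", "m3", "m4", "m5", "p", "l", "c", "i")

SIDES = ("left", "right")


def default_code_map() -> dict[str, tuple[int, int]]:
    """territory name -> (left label, right label)."""
    return {t: (k + 11, k + 1) for k, t in enumerate(TERRITORIES)}


@dataclass
class TerritoryAtlas:
    """Integer label volume plus the territory-name/label correspondence."""

    labels: ImageVolume
    code_map: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if set(self.code_map) != set(TERRITORIES):
            missing = set(TERRITORIES) - set(self.code_map)
            extra = set(self.code_map) - set(TERRITORIES)
            raise ValueError(
                f"code_map must cover exactly the 10 territories; missing={sorted(missing)}, "
                f"unexpected={sorted(extra)}"
            )
        known = {lab for pair in self.code_map.values() for lab in pair}
        present = set(np.unique(self.labels.data)) - {0}
        orphans = present - known
        if orphans:
            raise ValueError(f"label volume contains codes absent from code_map: {sorted(orphans)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def brain_mask(self) -> np.ndarray:
        return self.labels.data > 0

    def hemisphere_mask(self, side: str) -> np.ndarray:
        """Boolean mask of one full hemisphere (index space, axis 0 split)."""
        if side not in SIDES:
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        w = self.shape[SYMMETRY_AXIS]
        idx = np.arange(w).reshape([-1 if a == SYMMETRY_AXIS else 1 for a in range(3)])
        half = idx < w // 2 if side == "left" else idx >= w // 2
        return np.broadcast_to(half, self.shape).copy()

    def territory_mask(self, territory: str, side: str) -> np.ndarray:
        if territory not in self.code_map:
            raise KeyError(f"unknown territory code {territory!r}")
        left, right = self.code_map[territory]
        label = left if side == "left" else right
        if side not in SIDES:
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        return self.labels.data == label


# relative seed positions (fraction of grid extent) for the ten territories in
# the RIGHT hemisphere: x in (0.5, 1], y anterior (0) to posterior (1)
_SEED_FRACTIONS: dict[str, tuple[float, float, float]] = {
    "a": (0.60, 0.15, 0.60),
    "m1": (0.80, 0.20, 0.55),
    "m2": (0.85, 0.35, 0.55),
    "m3": (0.88, 0.50, 0.55),
    "m4": (0.85, 0.65, 0.55),
    "m5": (0.80, 0.80, 0.55),
    "p": (0.62, 0.85, 0.50),
    "l": (0.66, 0.45, 0.42),
    "c": (0.62, 0.33, 0.62),
    "i": (0.74, 0.45, 0.50),
}


def generate_atlas(
    grid_shape: tuple[int, int, int] = (32, 32, 16),
    spacing_mm: tuple[float, float, float] = (1.8, 1.8, 4.0),
    seed: int = 0,
) -> TerritoryAtlas:
    """Build a bilaterally symmetric 10-territory atlas on an ellipsoidal brain.

    The right hemisphere is partitioned by nearest-seed (Voronoi) assignment
    from ten anatomically arranged seed points, then mirrored to the left, so
    the label field is exactly mirror-symmetric about the mid-sagittal plane.
    The left–right dimension must be even (otherwise there is no unique
    mid-plane to mirror about).
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if grid_shape[SYMMETRY_AXIS] % 2 != 0:
        raise ValueError(
            f"grid must be even along the left-right axis, got {grid_shape[SYMMETRY_AXIS]}"
        )
    rng = np.random.default_rng(seed)
    w, h, d = grid_shape
    x, y, z = np.meshgrid(np.arange(w), np.arange(h), np.arange(d), indexing="ij")
    center = ((w - 1) / 2, (h - 1) / 2, (d - 1) / 2)
    semi = (0.46 * w, 0.46 * h, 0.46 * d)
    brain = (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0
    right = brain & (x >= w // 2)
    if not right.any():
        raise ValueError("grid too small: empty right hemisphere")

    coords = np.argwhere(right)  # (n, 3) voxel indices
    seeds = []
    for t in TERRITORIES:
        frac = np.array(_SEED_FRACTIONS[t])
        pos = frac * (np.array(grid_shape) - 1) + rng.normal(0.0, 0.01, 3) * np.array(grid_shape)
        # clamp the seed onto the nearest in-brain voxel so every territory
        # is guaranteed nonempty (the seed voxel assigns to itself)
        nearest = coords[np.argmin(((coords - pos) ** 2).sum(axis=1))]
        seeds.append(nearest)
    seeds = np.array(seeds, dtype=float)

    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1)  # 0..9, ties -> lowest territory index

    labels = np.zeros(grid_shape, dtype=np.int16)
    labels[tuple(coords.T)] = assign + 1  # right labels 1..10
    left_labels = np.flip(labels, axis=SYMMETRY_AXIS)
    labels = labels + np.where(left_labels > 0, left_labels + 10, 0)

    return TerritoryAtlas(ImageVolume(labels, spacing_mm), default_code_map())
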