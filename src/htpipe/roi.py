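"""Construction of the 20 per-patient ROIs.

For each of the 10 vascular territories on the lesioned ("abnormal")
hemisphere, the abnormal ROI is the territory intersected with the lesion
(infarct ∪ hypoperfusion); where that intersection is empty the full
abnormal-side territory is used instead, so that every patient always yields
20 nonempty ROIs.  The matching "normal" ROI is the abnormal ROI reflected
about the mid-sagittal grid plane onto the healthy hemisphere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from htpipe.atlas import TERRITORIES, TerritoryAtlas, default_code_map
from htpipe.volume import ImageVolume, SYMMETRY_AXIS

SIDE_CLASSES = ("abnormal", "normal")

#: ROIs smaller than this are padded by one morphological dilation inside
#: their territory — texture and mesh features degenerate on near-empty masks
MIN_ROI_VOXELS = 8


def mirror_mask(mask: np.ndarray, symmetry_axis: int = SYMMETRY_AXIS) -> np.ndarray:
    """Reflect a mask about the mid-plane of ``symmetry_axis``.

    Pure index reflection: a voxel at index ``x`` maps to ``W - 1 - x``.
    Requires an even dimension so the mid-plane falls between two slices;
    the operation is an involution and preserves voxel count.
    """
    mask = np.asarray(mask)
    if mask.shape[symmetry_axis] % 2 != 0:
        raise ValueError(
            f"axis {symmetry_axis} has odd size {mask.shape[symmetry_axis]}; "
            "no unique mid-plane to mirror about"
        )
    return np.flip(mask, axis=symmetry_axis)


def merge_labels(
    fine_atlas: ImageVolume, merge_map: dict[int, str | None]
) -> TerritoryAtlas:
    """Merge a fine-grained label volume into the 10 supply territories.

    ``merge_map`` sends every fine label to a territory code (or ``None`` /
    ``""`` for background).  Side is assigned per voxel from its hemisphere
    (axis-0 split).  Fine labels present in the volume but absent from the
    map are reported as orphans.
    """
    data = np.asarray(fine_atlas.data)
    present = set(int(v) for v in np.unique(data)) - {0}
    orphans = sorted(present - set(merge_map))
    if orphans:
        raise ValueError(f"fine labels missing from merge_map: {orphans}")
    for fine, terr in merge_map.items():
        if terr not in (None, "") and terr not in TERRITORIES:
            raise ValueError(f"merge_map sends label {fine} to unknown territory {terr!r}")

    code_map = default_code_map()
    w = data.shape[SYMMETRY_AXIS]
    idx = np.arange(w).reshape([-1 if a == SYMMETRY_AXIS else 1 for a in range(3)])
    is_right = np.broadcast_to(idx >= w // 2, data.shape)

    out = np.zeros(data.shape, dtype=np.int16)
    for fine, terr in merge_map.items():
        if terr in (None, ""):
            continue
        left, right = code_map[terr]
        sel = data == fine
        out[sel & is_right] = right
        out[sel & ~is_right] = left
    return TerritoryAtlas(ImageVolume(out, fine_atlas.spacing), code_map)


@dataclass
class ROISet:
    """The 20 named binary masks of one patient, in canonical order.

    Order: the 10 abnormal-side ROIs (territory order a, m1–m5, p, l, c, i)
    followed by their 10 normal-side mirrors in the same territory order.
    Names are ``"<territory>_<sideclass>"``.
    """

    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    abnormal_side: str

    def __post_init__(self) -> None:
        expected = self.canonical_names()
        if list(self.masks) != expected:
            raise ValueError("ROISet masks must follow the canonical 20-name ordering")

    @staticmethod
    def canonical_names() -> list[str]:
        return [f"{t}_{sc}" for sc in SIDE_CLASSES for t in TERRITORIES]

    def __len__(self) -> int:
        return len(self.masks)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def to_labelmap(self) -> tuple[ImageVolume, dict[str, int]]:
        """Serialize as a single label volume (codes 1–20) + name table.

        Abnormal and normal ROIs never overlap (they live in opposite
        hemispheres) but abnormal ROIs of different territories can, when a
        fallback full territory overlaps a lesion ROI; later codes win.
        """
        labels = np.zeros(next(iter(self.masks.values())).shape, dtype=np.int16)
        table = {}
        for k, (name, m) in enumerate(self.masks.items(), start=1):
            labels[m.astype(bool)] = k
            table[name] = k
        return ImageVolume(labels, self.spacing), table

    def save(self, path_prefix: str | Path) -> None:
        vol, table = self.to_labelmap()
        vol.to_nifti(f"{path_prefix}.nii.gz")
        Path(f"{path_prefix}.json").write_text(
            json.dumps({"abnormal_side": self.abnormal_side, "names": table}, indent=2)
        )


def build_roi_set(
    atlas: TerritoryAtlas,
    infarct_mask: ImageVolume | np.ndarray,
    hypoperfusion_mask: ImageVolume | np.ndarray,
    abnormal_side: str,
    min_voxels: int = MIN_ROI_VOXELS,
) -> ROISet:
    """Build the 20 ROIs for one patient (see module docstring for the rule)."""
    infarct = np.asarray(getattr(infarct_mask, "data", infarct_mask)).astype(bool)
    hypo = np.asarray(getattr(hypoperfusion_mask, "data", hypoperfusion_mask)).astype(bool)
    if infarct.shape != atlas.shape or hypo.shape != atlas.shape:
        raise ValueError("atlas and lesion masks must be co-registered on one grid")

    hemi = atlas.hemisphere_mask(abnormal_side)
    if not (hemi & atlas.brain_mask()).any():
        raise ValueError(f"empty {abnormal_side} (abnormal) hemisphere")
    lesion = infarct | hypo
    if lesion.any() and not (lesion & hemi).any():
        raise ValueError(
            f"lesion lies entirely outside the declared abnormal side {abnormal_side!r}"
        )

    abnormal: dict[str, np.ndarray] = {}
    for t in TERRITORIES:
        territory = atlas.territory_mask(t, abnormal_side)
        roi = territory & lesion
        if not roi.any():
            roi = territory  # lesion-free territory: use its full extent
        if 0 < roi.sum() < min_voxels:
            roi = ndimage.binary_dilation(roi) & territory
        abnormal[t] = roi

    masks: dict[str, np.ndarray] = {}
    for t in TERRITORIES:
        masks[f"{t}_abnormal"] = abnormal[t]
    for t in TERRITORIES:
        masks[f"{t}_normal"] = mirror_mask(abnormal[t])
    return ROISet(masks=masks, spacing=atlas.labels.spacing, abnormal_side=abnormal_side)
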