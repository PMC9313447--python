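"""Patient- and cohort-level feature extraction.

Per patient the vector is ordered sequence-major, then ROI (canonical
20-name order), then category (first-order, shape, GLCM), giving
``n_sequences x 20 x 54`` named values — 5400 for the five-sequence run,
1080 for a single sequence.  Shape features depend only on the mask, so they
are computed once per ROI and repeated across sequences; this redundancy is
kept deliberately so the per-sequence block is always 20 x 54.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from htpipe.cohort import SEQUENCES, SyntheticPatient
from htpipe.features.discretize import DiscretizationSpec, discretize
from htpipe.features.firstorder import FIRST_ORDER_NAMES, first_order
from htpipe.features.glcm import GLCM_NAMES, GLCMSpec, glcm_matrices, glcm_features
from htpipe.features.shape import SHAPE_NAMES, shape_features
from htpipe.roi import ROISet, build_roi_set

CATEGORY_NAMES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRST_ORDER_NAMES,
    "shape": SHAPE_NAMES,
    "glcm": GLCM_NAMES,
}

FEATURES_PER_ROI = sum(len(v) for v in CATEGORY_NAMES.values())  # 54


def feature_names(sequences: tuple[str, ...] = SEQUENCES) -> list[str]:
    """The canonical ordered feature-name list for a set of sequences."""
    names = []
    for seq in sequences:
        for roi_name in ROISet.canonical_names():
            territory, side_class = roi_name.rsplit("_", 1)
            for cat, feats in CATEGORY_NAMES.items():
                names.extend(f"{seq}_{territory}_{side_class}_{cat}_{f}" for f in feats)
    return names


def _bounding_box(mask: np.ndarray) -> tuple[slice, slice, slice]:
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def extract_patient(
    maps: dict[str, np.ndarray],
    roi_set: ROISet,
    disc_spec: DiscretizationSpec | None = None,
    glcm_spec: GLCMSpec | None = None,
    sequences: tuple[str, ...] = SEQUENCES,
) -> pd.Series:
    """Extract the full named feature vector of one patient.

    ``maps`` holds one 3-D array (or ImageVolume) per requested sequence on
    the ROI grid.  Output order is deterministic and independent of the
    mapping/mask insertion order.
    """
    disc_spec = disc_spec or DiscretizationSpec()
    glcm_spec = glcm_spec or GLCMSpec()
    missing = [s for s in sequences if s not in maps]
    if missing:
        raise KeyError(f"missing sequence maps: {missing}")

    spacing = roi_set.spacing
    voxvol = float(np.prod(spacing))
    arrays = {s: np.asarray(getattr(maps[s], "data", maps[s]), dtype=float) for s in sequences}
    for s, arr in arrays.items():
        if arr.shape != next(iter(roi_set.masks.values())).shape:
            raise ValueError(f"map {s} not on the ROI grid")

    # per-ROI mask preparation + shape features (sequence-independent)
    rois = {}
    for roi_name, mask in roi_set.masks.items():
        box = _bounding_box(mask)
        rois[roi_name] = (box, mask[box].astype(bool), shape_features(mask, spacing))

    values: list[float] = []
    for seq in sequences:
        arr = arrays[seq]
        for roi_name in ROISet.canonical_names():
            box, sub_mask, shp = rois[roi_name]
            sub = arr[box]
            inten = sub[sub_mask]
            fo = first_order(inten, voxvol, disc_spec)
            levels = np.zeros(sub.shape, dtype=np.int64)
            levels[sub_mask] = discretize(inten, disc_spec)
            P, lv = glcm_matrices(levels, sub_mask, glcm_spec, roi_name=f"{seq}_{roi_name}")
            tex = glcm_features(P, lv)
            values.extend(fo[f] for f in FIRST_ORDER_NAMES)
            values.extend(shp[f] for f in SHAPE_NAMES)
            values.extend(tex[f] for f in GLCM_NAMES)

    series = pd.Series(values, index=feature_names(tuple(sequences)), dtype=float)
    if series.isna().any():
        bad = series.index[series.isna()].tolist()[:5]
        raise ValueError(f"NaN features produced, e.g. {bad}")
    return series


def extract_cohort(
    patients: list[SyntheticPatient],
    disc_spec: DiscretizationSpec | None = None,
    glcm_spec: GLCMSpec | None = None,
    sequences: tuple[str, ...] = SEQUENCES,
) -> pd.DataFrame:
    """Patients x features table with an ``HT`` label column appended."""
    if not patients:
        raise ValueError("extract_cohort requires at least one patient")
    rows, ids = [], []
    for p in patients:
        roi_set = build_roi_set(p.atlas, p.infarct_mask, p.hypoperfusion_mask, p.abnormal_side)
        vec = extract_patient(p.maps, roi_set, disc_spec, glcm_spec, sequences)
        if rows and len(vec) != len(rows[0]):
            raise ValueError(f"inconsistent feature vector length for {p.patient_id}")
        rows.append(vec)
        ids.append(p.patient_id)
    table = pd.DataFrame(rows, index=pd.Index(ids, name="patient_id"))
    table["HT"] = [p.ht_label for p in patients]
    return table
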