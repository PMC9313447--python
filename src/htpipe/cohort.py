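"""Synthetic stroke cohort generator.

Produces fully synthetic patients — a shared symmetric territory atlas,
unilateral infarct-core and hypoperfusion lesions, five co-registered
parametric maps (ADC, CBF, CBV, MTT, TTP), an HT (hemorrhagic
transformation) outcome label, and 16 clinical factors — so that every
downstream stage can be exercised and tested without any real data.

Intensity model (per sequence ``s`` with baseline ``b_s`` and noise scale
``sigma_s = noise_sd * b_s``):

    I(v) = b_s + patient offset + territory offset (bilaterally symmetric)
           + sign_s * effect_size_abnormal * sigma_s     [v in lesion]
           + HT * sign_s * effect_size_ht_abnormal * sigma_s   [v in abnormal-hemisphere brain tissue]
           + HT * sign_s * effect_size_ht_normal * sigma_s     [v in normal-hemisphere brain tissue]
           + N(0, sigma_s^2)

``sign_s`` is the pathophysiological direction of the lesion contrast: ADC,
CBF and CBV fall in the abnormal region while MTT and TTP rise.  All effect
sizes are standardized (units of ``sigma_s``).  The HT-dependent shift is a
diffuse hemispheric derangement: it applies to the brain tissue of each
hemisphere (two thirds of it ipsilateral to the lesion, one third
contralateral by default), which is what makes contralateral
("normal-side") ROIs informative for HT prediction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from htpipe.atlas import TERRITORIES, TerritoryAtlas, generate_atlas
from htpipe.volume import ImageVolume, SYMMETRY_AXIS

SEQUENCES: tuple[str, ...] = ("ADC", "CBF", "CBV", "MTT", "TTP")

#: plausible map baselines (ADC in 1e-6 mm^2/s, CBF in mL/100 g/min, CBV in
#: mL/100 g, MTT and TTP in s) — only their relative scale matters downstream
SEQUENCE_BASELINES: dict[str, float] = {"ADC": 800.0, "CBF": 50.0, "CBV": 4.0, "MTT": 6.0, "TTP": 25.0}

#: direction of the lesion intensity contrast relative to healthy tissue
LESION_SIGNS: dict[str, int] = {"ADC": -1, "CBF": -1, "CBV": -1, "MTT": 1, "TTP": 1}

#: the 15 binary clinical factors; age is the 16th (continuous) factor
BINARY_FACTORS: tuple[str, ...] = (
    "gender",
    "hypertension",
    "hyperlipidemia",
    "diabetes",
    "atrial_fibrillation",
    "leukoaraiosis",
    "coronary",
    "location_A",
    "location_M1",
    "location_M2",
    "location_P",
    "svs_1",
    "svs_2",
    "mtici_2",
    "recanalization",
)

CLINICAL_FACTORS: tuple[str, ...] = ("age",) + BINARY_FACTORS

#: per-group prevalence (P(factor=1 | HT), P(factor=1 | no HT)) of each binary
#: factor, taken as count/group-size in an HT=11 / no-HT=60 reference cohort;
#: gender is coded male=1.  SVS at initial examination (svs_1) and an M2
#: infarct location are the two factors whose prevalence separates the groups.
DEFAULT_PREVALENCES: dict[str, tuple[float, float]] = {
    "gender": (7 / 11, 44 / 60),
    "hypertension": (7 / 11, 47 / 60),
    "hyperlipidemia": (2 / 11, 9 / 60),
    "diabetes": (4 / 11, 13 / 60),
    "atrial_fibrillation": (2 / 11, 3 / 60),
    "leukoaraiosis": (7 / 11, 40 / 60),
    "coronary": (2 / 11, 3 / 60),
    "location_A": (1 / 11, 6 / 60),
    "location_M1": (6 / 11, 32 / 60),
    "location_M2": (4 / 11, 35 / 60),
    "location_P": (1 / 11, 6 / 60),
    "svs_1": (11 / 11, 37 / 60),
    "svs_2": (3 / 11, 22 / 60),
    "mtici_2": (5 / 11, 28 / 60),
    "recanalization": (5 / 11, 26 / 60),
}

AGE_RANGE = (18.0, 85.0)
AGE_CENTER = 64.0
AGE_SD = 12.0


def null_prevalences() -> dict[str, tuple[float, float]]:
    """Prevalence table with zero group contrast (no-HT column for both groups).

    Used by the null-calibration experiments, where *all* effect sizes —
    imaging and clinical — must vanish so that no model can beat chance.
    """
    return {k: (p0, p0) for k, (_, p0) in DEFAULT_PREVALENCES.items()}


@dataclass
class CohortConfig:
    """Everything that determines a synthetic cohort, including the seed."""

    n_patients: int = 71
    ht_fraction: float = 11 / 71
    grid_shape: tuple[int, int, int] = (32, 32, 16)
    spacing_mm: tuple[float, float, float] = (1.8, 1.8, 4.0)
    lesion_territories: tuple[str, ...] = ("m1", "m2", "m3", "m4", "m5")
    effect_size_abnormal: float = 2.0
    effect_size_ht_abnormal: float = 1.0
    effect_size_ht_normal: float = 0.5
    noise_sd: float = 0.05           # fraction of the per-sequence baseline
    core_fraction: float = 0.4       # infarct volume / hypoperfusion volume
    lesion_effect_rel_sd: float = 0.25  # relative per-patient lesion-severity spread
    oligemia_frac: float = 0.25      # hemispheric hypoperfusion spill, fraction of lesion effect
    oligemia_frac_sd: float = 0.25   # per-patient spread of the spill fraction
    patient_offset_sd: float = 0.3   # standardized, per patient per sequence
    territory_offset_sd: float = 0.2  # standardized, per patient per territory
    prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.lesion_territories = tuple(self.lesion_territories)
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.ht_fraction < 1.0:
            raise ValueError("ht_fraction must lie strictly between 0 and 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("all voxel spacings must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.lesion_territories:
            raise ValueError("lesion_territories must be non-empty")
        if not 0.0 < self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in (0, 1]")
        for name, (p1, p0) in self.prevalences.items():
            if not (0.0 <= p1 <= 1.0 and 0.0 <= p0 <= 1.0):
                raise ValueError(f"prevalence for {name!r} outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ClinicalRecord:
    """The 16 pretreatment clinical factors of one patient."""

    age: float
    gender: int
    hypertension: int
    hyperlipidemia: int
    diabetes: int
    atrial_fibrillation: int
    leukoaraiosis: int
    coronary: int
    location_A: int
    location_M1: int
    location_M2: int
    location_P: int
    svs_1: int
    svs_2: int
    mtici_2: int
    recanalization: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticPatient:
    patient_id: str
    atlas: TerritoryAtlas
    maps: dict[str, ImageVolume]
    infarct_mask: ImageVolume
    hypoperfusion_mask: ImageVolume
    abnormal_side: str
    ht_label: int
    clinical: ClinicalRecord


# --------------------------------------------------------------------- lesions
def simulate_lesion(
    atlas: TerritoryAtlas,
    abnormal_side: str,
    lesion_territories: tuple[str, ...],
    rng: np.random.Generator,
    core_fraction: float = 0.4,
) -> tuple[ImageVolume, ImageVolume]:
    """Draw one unilateral lesion: hypoperfusion envelope + infarct core.

    The hypoperfusion region is a random ellipsoid seeded inside one of the
    requested territories (abnormal side), clipped to brain and hemisphere.
    The infarct core is the innermost ``core_fraction`` (jittered ±15 %) of
    the envelope by ellipsoid depth, so infarct ⊆ hypoperfusion by
    construction.
    """
    if not lesion_territories:
        raise ValueError("lesion_territories must be non-empty")
    for t in lesion_territories:
        if t not in atlas.code_map:
            raise KeyError(f"requested lesion territory {t!r} absent from atlas")
    shape = np.array(atlas.shape)
    hemi = atlas.hemisphere_mask(abnormal_side) & atlas.brain_mask()

    territory = lesion_territories[rng.integers(len(lesion_territories))]
    tmask = atlas.territory_mask(territory, abnormal_side)
    cand = np.argwhere(tmask)
    if cand.size == 0:
        raise ValueError(f"territory {territory!r} empty on the {abnormal_side} side")
    center = cand[rng.integers(len(cand))]

    radii = rng.uniform(0.12, 0.25, size=3) * shape
    x, y, z = np.meshgrid(*(np.arange(s) for s in atlas.shape), indexing="ij")
    depth = (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    )
    hypo = (depth <= 1.0) & hemi
    if not hypo.any():  # degenerate draw: keep at least the seed voxel
        hypo = np.zeros(atlas.shape, dtype=bool)
        hypo[tuple(center)] = True

    n_hypo = int(hypo.sum())
    n_core = int(np.clip(round(core_fraction * n_hypo * rng.uniform(0.85, 1.15)), 1, n_hypo))
    flat = np.argwhere(hypo)
    order = np.argsort(depth[hypo], kind="stable")
    infarct = np.zeros(atlas.shape, dtype=bool)
    infarct[tuple(flat[order[:n_core]].T)] = True

    spacing = atlas.labels.spacing
    return (
        ImageVolume(infarct.astype(np.uint8), spacing),
        ImageVolume(hypo.astype(np.uint8), spacing),
    )


# ------------------------------------------------------------------------ maps
def simulate_parametric_maps(
    atlas: TerritoryAtlas,
    infarct_mask: ImageVolume,
    hypoperfusion_mask: ImageVolume,
    ht_label: int,
    config: CohortConfig,
    rng: np.random.Generator,
) -> dict[str, ImageVolume]:
    """Render the five parametric maps for one patient (model in module docstring)."""
    if infarct_mask.shape != atlas.shape or hypoperfusion_mask.shape != atlas.shape:
        raise ValueError("atlas and lesion masks must share one grid")
    lesion = (infarct_mask.data > 0) | (hypoperfusion_mask.data > 0)

    # hemisphere-wide HT masks, inferred from the lesion's side
    brain = atlas.brain_mask()
    left = atlas.hemisphere_mask("left")
    on_left = (lesion & left).sum() >= (lesion & ~left).sum()
    abnormal_tissue = brain & (left if on_left else ~left)
    normal_tissue = brain & ~abnormal_tissue

    # lesion severity varies per patient (drawn once, shared by all sequences),
    # and a severity-dependent oligemia pervades the whole lesioned hemisphere
    # (penumbral hypoperfusion beyond the core).  Both are outcome-independent
    # nuisance on the abnormal side only; the contralateral hemisphere is free
    # of them, which is what makes normal-side ROIs complementary rather than
    # redundant copies of the abnormal-side ones.
    severity = config.effect_size_abnormal * max(0.0, rng.normal(1.0, config.lesion_effect_rel_sd))
    oligemia = config.effect_size_abnormal * max(
        0.0, rng.normal(config.oligemia_frac, config.oligemia_frac_sd)
    )

    maps: dict[str, ImageVolume] = {}
    for seq in SEQUENCES:
        base = SEQUENCE_BASELINES[seq]
        sigma = config.noise_sd * base
        sign = LESION_SIGNS[seq]

        img = np.full(atlas.shape, base, dtype=np.float64)
        img += rng.normal(0.0, config.patient_offset_sd * sigma)
        for t in TERRITORIES:  # symmetric anatomical variation
            off = rng.normal(0.0, config.territory_offset_sd * sigma)
            both = atlas.territory_mask(t, "left") | atlas.territory_mask(t, "right")
            img[both] += off
        img[abnormal_tissue] += sign * oligemia * sigma
        img[lesion] += sign * severity * sigma
        if ht_label:
            img[abnormal_tissue] += sign * config.effect_size_ht_abnormal * sigma
            img[normal_tissue] += sign * config.effect_size_ht_normal * sigma
        img += rng.normal(0.0, sigma, size=atlas.shape)
        maps[seq] = ImageVolume(img, config.spacing_mm)
    return maps


# -------------------------------------------------------------------- clinical
def simulate_clinical(
    n: int,
    ht_labels: np.ndarray,
    rng: np.random.Generator,
    prevalence_table: dict[str, tuple[float, float]] | None = None,
) -> list[ClinicalRecord]:
    """Draw the 16 clinical factors per patient, conditionally on HT group.

    Binary factors are independent Bernoulli draws at their per-group
    prevalence; age is truncated-normal on [18, 85] centred at 64 (median
    ~64 by symmetry of the truncation).
    """
    table = dict(prevalence_table or DEFAULT_PREVALENCES)
    missing = set(BINARY_FACTORS) - set(table)
    if missing:
        raise ValueError(f"prevalence table missing factors: {sorted(missing)}")
    for name, (p1, p0) in table.items():
        if not (0.0 <= p1 <= 1.0 and 0.0 <= p0 <= 1.0):
            raise ValueError(f"prevalence for {name!r} outside [0, 1]")
    ht_labels = np.asarray(ht_labels, dtype=int)
    if ht_labels.shape != (n,):
        raise ValueError("ht_labels must have length n")

    lo, hi = AGE_RANGE
    a, b = (lo - AGE_CENTER) / AGE_SD, (hi - AGE_CENTER) / AGE_SD
    ages = stats.truncnorm.rvs(a, b, loc=AGE_CENTER, scale=AGE_SD, size=n, random_state=rng)

    records = []
    for i in range(n):
        grp = 0 if ht_labels[i] else 1  # column index into (p_ht, p_noht)
        fields = {f: int(rng.random() < table[f][grp]) for f in BINARY_FACTORS}
        records.append(ClinicalRecord(age=float(ages[i]), **fields))
    return records


def clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a patients x 16-factor DataFrame."""
    return pd.DataFrame([r.to_dict() for r in records], columns=list(CLINICAL_FACTORS))


# ---------------------------------------------------------------------- cohort
def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Generate the full synthetic cohort deterministically from the config."""
    rng = np.random.default_rng(config.seed)
    atlas = generate_atlas(config.grid_shape, config.spacing_mm, seed=config.seed)

    n = config.n_patients
    n_ht = int(np.clip(round(config.ht_fraction * n), 1, n - 1))
    ht = np.zeros(n, dtype=int)
    ht[rng.permutation(n)[:n_ht]] = 1

    clinical = simulate_clinical(n, ht, rng, config.prevalences)

    patients = []
    for i in range(n):
        side = "left" if rng.random() < 0.5 else "right"
        infarct, hypo = simulate_lesion(
            atlas, side, config.lesion_territories, rng, config.core_fraction
        )
        maps = simulate_parametric_maps(atlas, infarct, hypo, int(ht[i]), config, rng)
        patients.append(
            SyntheticPatient(
                patient_id=f"P{i:04d}",
                atlas=atlas,
                maps=maps,
                infarct_mask=infarct,
                hypoperfusion_mask=hypo,
                abnormal_side=side,
                ht_label=int(ht[i]),
                clinical=clinical[i],
            )
        )
    return patients


# ------------------------------------------------------------------------- I/O
def write_cohort(
    patients: list[SyntheticPatient],
    out_dir: str | Path,
    config: CohortConfig | None = None,
    overwrite: bool = False,
) -> dict:
    """Write NIfTI volumes + clinical/label CSVs + a JSON manifest; returns the manifest."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace it")
    out.mkdir(parents=True, exist_ok=True)

    entries = []
    for p in patients:
        pdir = out / p.patient_id
        pdir.mkdir(exist_ok=True)
        paths = {"atlas": str(pdir / "atlas.nii.gz")}
        p.atlas.labels.to_nifti(paths["atlas"])
        for seq, vol in p.maps.items():
            paths[seq] = str(pdir / f"{seq}.nii.gz")
            vol.to_nifti(paths[seq])
        paths["infarct"] = str(pdir / "infarct.nii.gz")
        paths["hypoperfusion"] = str(pdir / "hypoperfusion.nii.gz")
        p.infarct_mask.to_nifti(paths["infarct"])
        p.hypoperfusion_mask.to_nifti(paths["hypoperfusion"])
        entries.append(
            {"patient_id": p.patient_id, "abnormal_side": p.abnormal_side, "paths": paths}
        )

    clin = clinical_frame([p.clinical for p in patients])
    clin.insert(0, "patient_id", [p.patient_id for p in patients])
    clin["HT"] = [p.ht_label for p in patients]
    clin.to_csv(out / "clinical.csv", index=False)

    labels = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "abnormal_side": [p.abnormal_side for p in patients],
            "HT": [p.ht_label for p in patients],
        }
    )
    labels.to_csv(out / "labels.csv", index=False)

    manifest = {
        "n_patients": len(patients),
        "patients": entries,
        "clinical_csv": str(out / "clinical.csv"),
        "labels_csv": str(out / "labels.csv"),
        "seed": None if config is None else config.seed,
        "config": None if config is None else config.to_dict(),
        "config_hash": None if config is None else config.config_hash(),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=list))
    return manifest


def read_cohort(in_dir: str | Path) -> list[SyntheticPatient]:
    """Re-read a written cohort (bit-exact voxel arrays)."""
    out = Path(in_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    clin = pd.read_csv(out / "clinical.csv").set_index("patient_id")
    from htpipe.atlas import default_code_map

    patients = []
    for entry in manifest["patients"]:
        pid = entry["patient_id"]
        atlas = TerritoryAtlas(ImageVolume.from_nifti(entry["paths"]["atlas"]), default_code_map())
        maps = {seq: ImageVolume.from_nifti(entry["paths"][seq]) for seq in SEQUENCES}
        row = clin.loc[pid]
        record = ClinicalRecord(**{f: row[f] for f in CLINICAL_FACTORS})
        patients.append(
            SyntheticPatient(
                patient_id=pid,
                atlas=atlas,
                maps=maps,
                infarct_mask=ImageVolume.from_nifti(entry["paths"]["infarct"]),
                hypoperfusion_mask=ImageVolume.from_nifti(entry["paths"]["hypoperfusion"]),
                abnormal_side=entry["abnormal_side"],
                ht_label=int(row["HT"]),
                clinical=record,
            )
        )
    return patients
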