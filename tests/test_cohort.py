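"""Synthetic cohort generator: atlas symmetry, lesion geometry, map effect
signs, clinical sampling, and round-trip I/O."""

import numpy as np
import pandas as pd
import pytest

from htpipe.atlas import TERRITORIES, generate_atlas
from htpipe.cohort import (
    CohortConfig,
    SEQUENCES,
    generate_cohort,
    null_prevalences,
    read_cohort,
    simulate_clinical,
    simulate_lesion,
    simulate_parametric_maps,
    write_cohort,
)
from htpipe.volume import SYMMETRY_AXIS


class TestAtlas:
    def test_twenty_labels_and_mirror_symmetry(self):
        atlas = generate_atlas((32, 32, 16), seed=0)
        labels = atlas.labels.data
        assert set(np.unique(labels)) == set(range(21))
        for t in TERRITORIES:
            left = atlas.territory_mask(t, "left")
            right = atlas.territory_mask(t, "right")
            assert left.sum() == right.sum() > 0
            assert np.array_equal(left, np.flip(right, axis=SYMMETRY_AXIS))

    def test_determinism(self):
        a = generate_atlas((24, 24, 12), seed=5)
        b = generate_atlas((24, 24, 12), seed=5)
        assert np.array_equal(a.labels.data, b.labels.data)

    def test_odd_left_right_dimension_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_atlas((31, 32, 16))


@pytest.fixture(scope="module")
def lesion_atlas():
    return generate_atlas((24, 24, 12), seed=1)


@pytest.fixture(scope="module")
def map_atlas():
    return generate_atlas((24, 24, 12), seed=2)


class TestLesion:
    def test_unilateral_and_intersects_requested_territory(self, lesion_atlas):
        rng = np.random.default_rng(0)
        infarct, hypo = simulate_lesion(lesion_atlas, "left", ("m2",), rng)
        normal_hemi = lesion_atlas.hemisphere_mask("right")
        assert not (hypo.data.astype(bool) & normal_hemi).any()
        assert (hypo.data.astype(bool) & lesion_atlas.territory_mask("m2", "left")).any()
        assert infarct.data.sum() > 0
        # infarct core contained in the hypoperfusion envelope
        assert not (infarct.data.astype(bool) & ~hypo.data.astype(bool)).any()

    def test_unknown_territory_named_in_error(self, lesion_atlas):
        with pytest.raises(KeyError, match="m9"):
            simulate_lesion(lesion_atlas, "left", ("m9",), np.random.default_rng(0))

    def test_core_fraction_matches_configuration(self, lesion_atlas):
        rng = np.random.default_rng(42)
        fractions = []
        for _ in range(100):
            infarct, hypo = simulate_lesion(lesion_atlas, "right", ("m1", "m3"), rng, core_fraction=0.4)
            fractions.append(infarct.data.sum() / hypo.data.sum())
        assert abs(np.mean(fractions) - 0.4) < 0.1


class TestParametricMaps:
    def _gap(self, map_atlas, config, seq, n, rng, ht=0):
        """Lesion-mask mean minus mirrored-mask mean, per patient."""
        gaps = []
        for _ in range(n):
            infarct, hypo = simulate_lesion(map_atlas, "left", ("m2", "m3"), rng)
            maps = simulate_parametric_maps(map_atlas, infarct, hypo, ht, config, rng)
            lesion = (infarct.data > 0) | (hypo.data > 0)
            mirror = np.flip(lesion, axis=SYMMETRY_AXIS)
            img = maps[seq].data
            gaps.append(img[lesion].mean() - img[mirror].mean())
        return np.array(gaps)

    def test_null_effect_gap_is_centred(self, map_atlas):
        config = CohortConfig(
            effect_size_abnormal=0.0, effect_size_ht_abnormal=0.0, effect_size_ht_normal=0.0,
            grid_shape=(24, 24, 12),
        )
        rng = np.random.default_rng(3)
        gaps = self._gap(map_atlas, config, "CBF", 50, rng)
        z = gaps.mean() / (gaps.std(ddof=1) / np.sqrt(len(gaps)))
        assert abs(z) < 4

    def test_cbf_decreases_and_mtt_increases_in_lesion(self, map_atlas):
        config = CohortConfig(grid_shape=(24, 24, 12), effect_size_abnormal=2.0)
        rng = np.random.default_rng(4)
        cbf_gaps = self._gap(map_atlas, config, "CBF", 100, rng)
        assert (cbf_gaps < 0).sum() >= 95
        mtt_gaps = self._gap(map_atlas, config, "MTT", 20, rng)
        assert (mtt_gaps > 0).all()

    def test_gap_grows_monotonically_with_effect_size(self, map_atlas):
        rng_seed = 5
        means = []
        for effect in (0.5, 1.5, 3.0):
            config = CohortConfig(grid_shape=(24, 24, 12), effect_size_abnormal=effect)
            gaps = self._gap(map_atlas, config, "TTP", 25, np.random.default_rng(rng_seed))
            means.append(gaps.mean())
        assert means[0] < means[1] < means[2]

    def test_unknown_grid_rejected(self, map_atlas):
        config = CohortConfig(grid_shape=(24, 24, 12))
        rng = np.random.default_rng(0)
        infarct, hypo = simulate_lesion(map_atlas, "left", ("m2",), rng)
        bad = generate_atlas((16, 16, 8))
        with pytest.raises(ValueError, match="grid"):
            simulate_parametric_maps(bad, infarct, hypo, 0, config, rng)


class TestClinical:
    def test_ht_group_svs1_always_positive(self):
        rng = np.random.default_rng(0)
        labels = np.ones(50, dtype=int)
        records = simulate_clinical(50, labels, rng)
        assert all(r.svs_1 == 1 for r in records)

    def test_no_ht_svs1_frequency(self):
        rng = np.random.default_rng(1)
        n = 10_000
        records = simulate_clinical(n, np.zeros(n, dtype=int), rng)
        freq = np.mean([r.svs_1 for r in records])
        assert abs(freq - 0.617) < 0.015

    def test_age_bounds_and_centre(self):
        rng = np.random.default_rng(2)
        n = 2000
        records = simulate_clinical(n, np.zeros(n, dtype=int), rng)
        ages = np.array([r.age for r in records])
        assert ages.min() >= 18 and ages.max() <= 85
        assert abs(np.median(ages) - 64) < 1.5

    def test_invalid_probability_rejected(self):
        table = null_prevalences()
        table["svs_1"] = (1.2, 0.5)
        with pytest.raises(ValueError, match="svs_1"):
            simulate_clinical(5, np.zeros(5, dtype=int), np.random.default_rng(0), table)

    def test_null_table_removes_group_contrast(self):
        rng = np.random.default_rng(3)
        n = 4000
        labels = np.array([1, 0] * (n // 2))
        records = simulate_clinical(n, labels, rng, null_prevalences())
        svs = np.array([r.svs_1 for r in records])
        assert abs(svs[labels == 1].mean() - svs[labels == 0].mean()) < 0.05


class TestCohort:
    def test_determinism_bit_identical(self):
        cfg = dict(n_patients=4, grid_shape=(16, 16, 8), seed=11)
        a = generate_cohort(CohortConfig(**cfg))
        b = generate_cohort(CohortConfig(**cfg))
        for pa, pb in zip(a, b):
            assert pa.ht_label == pb.ht_label and pa.abnormal_side == pb.abnormal_side
            for seq in SEQUENCES:
                assert np.array_equal(pa.maps[seq].data, pb.maps[seq].data)

    def test_ht_count_and_lesion_side(self, small_cohort):
        assert sum(p.ht_label for p in small_cohort) == round(12 * 11 / 71)
        for p in small_cohort:
            hemi = p.atlas.hemisphere_mask(p.abnormal_side)
            assert not (p.hypoperfusion_mask.data.astype(bool) & ~hemi).any()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=1)
        with pytest.raises(ValueError):
            CohortConfig(ht_fraction=0.0)
        with pytest.raises(ValueError):
            CohortConfig(noise_sd=-1.0)
        with pytest.raises(ValueError):
            CohortConfig(spacing_mm=(1.8, 0.0, 4.0))


class TestIO:
    def test_round_trip(self, tmp_path, small_cohort):
        cfg = CohortConfig(n_patients=12, grid_shape=(16, 16, 8), seed=7)
        manifest = write_cohort(small_cohort[:3], tmp_path / "cohort", cfg)
        assert manifest["n_patients"] == 3
        back = read_cohort(tmp_path / "cohort")
        for orig, rt in zip(small_cohort[:3], back):
            assert rt.ht_label == orig.ht_label
            for seq in SEQUENCES:
                assert np.array_equal(orig.maps[seq].data, rt.maps[seq].data)
            assert np.array_equal(orig.infarct_mask.data, rt.infarct_mask.data)

    def test_clinical_csv_has_16_factors_plus_id_and_label(self, tmp_path, small_cohort):
        write_cohort(small_cohort[:2], tmp_path / "c", None)
        clin = pd.read_csv(tmp_path / "c" / "clinical.csv")
        assert clin.shape[1] == 16 + 2  # patient_id + 16 factors + HT
        assert {"patient_id", "HT", "age", "svs_1"} <= set(clin.columns)

    def test_existing_manifest_refused(self, tmp_path, small_cohort):
        write_cohort(small_cohort[:2], tmp_path / "c", None)
        with pytest.raises(FileExistsError):
            write_cohort(small_cohort[:2], tmp_path / "c", None)
        write_cohort(small_cohort[:2], tmp_path / "c", None, overwrite=True)
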