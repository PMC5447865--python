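"""Knowledge-based hierarchical workflow: step rules and composition."""

import warnings

import numpy as np
import pandas as pd
import pytest

from medusahead_obia.errors import ParameterError
from medusahead_obia.hierarchy import (
    ASSOC_CB,
    ASSOC_OAT,
    GOATGRASS,
    LABEL_CANARY,
    LABEL_OTHER,
    LABEL_STORKSBILL,
    HierarchyConfig,
    classify_associations,
    coarse_exclude,
    final_invasive_split,
    greenness_tiers,
    isolate_vetch_mosaic,
    run_hierarchy,
)
from medusahead_obia.scene import MEDUSAHEAD
from medusahead_obia.segmentation import SegmentationLevel
from medusahead_obia.stack import BandStack


def _coarse_fixture():
    """A 2 x 4 raster of four 2 x 1 coarse objects with controlled NDVI."""
    lab = np.array([[0, 1, 2, 3], [0, 1, 2, 3]], dtype=np.int32)
    level = SegmentationLevel(
        label_raster=lab, scale=390.0, shape_weight=0.1, compactness_weight=0.1,
        layer_weights={}, n_objects=4,
    )
    z = np.zeros((2, 4))
    stack = BandStack(
        layers={"blue": z, "green": z, "red": z, "nir": z}, pixel_size_m=1.0
    )
    table = pd.DataFrame(
        {
            "object_id": [0, 1, 2, 3],
            "mean_ndvi": [0.6, 0.05, 0.05, 0.05],
            "glcm_entropy_nir": [3.0, 3.0, 3.0, 3.0],
        }
    )
    return table, level, stack


class TestCoarseExclude:
    def test_green_object_is_candidate_regardless_of_distance(self):
        table, level, stack = _coarse_fixture()
        cfg = HierarchyConfig(ndvi_exclusion_threshold=0.15, distance_exclusion_m=1.0)
        excl, cand = coarse_exclude(table, level, stack, [(0.5, 0.5)], cfg)
        assert 0 in cand  # NDVI 0.6: conjunction cannot exclude it

    def test_low_ndvi_far_object_excluded(self):
        table, level, stack = _coarse_fixture()
        cfg = HierarchyConfig(ndvi_exclusion_threshold=0.15, distance_exclusion_m=1.0)
        excl, cand = coarse_exclude(table, level, stack, [(0.5, 0.5)], cfg)
        assert 3 in excl  # 3 px away from the only sample

    def test_low_ndvi_object_containing_sample_is_candidate(self):
        table, level, stack = _coarse_fixture()
        cfg = HierarchyConfig(ndvi_exclusion_threshold=0.15, distance_exclusion_m=1.0)
        excl, cand = coarse_exclude(table, level, stack, [(1.5, 0.5)], cfg)
        assert 1 in cand  # distance 0

    def test_no_samples_disables_distance_with_warning(self):
        table, level, stack = _coarse_fixture()
        cfg = HierarchyConfig(ndvi_exclusion_threshold=0.15)
        with pytest.warns(UserWarning, match="distance criterion disabled"):
            excl, cand = coarse_exclude(table, level, stack, [], cfg)
        assert excl == {1, 2, 3} and cand == {0}


class TestIsolateVetchMosaic:
    def _table(self):
        return pd.DataFrame(
            {"object_id": [0, 1, 2], "glcm_entropy_nir": [5.5, 3.0, 4.64]}
        )

    def test_high_entropy_object_isolated(self):
        vetch, rest = isolate_vetch_mosaic(self._table(), {0, 1, 2}, HierarchyConfig())
        assert vetch == {0} and rest == {1, 2}

    def test_uniform_object_remains(self):
        vetch, rest = isolate_vetch_mosaic(self._table(), {1}, HierarchyConfig())
        assert vetch == set() and rest == {1}

    def test_infinite_threshold_isolates_nothing(self):
        cfg = HierarchyConfig(entropy_nir_threshold=np.inf)
        vetch, rest = isolate_vetch_mosaic(self._table(), {0, 1, 2}, cfg)
        assert vetch == set()


def _mid_table():
    cols = {
        "object_id": np.arange(6),
        "glcm_entropy_green": [5.5, 3.0, 3.2, 3.1, 2.9, 3.3],
        "mean_red": [0.2, 0.30, 0.31, 0.10, 0.11, 0.29],
        "mean_green": [0.2, 0.25, 0.26, 0.15, 0.16, 0.24],
        "mean_blue": [0.1, 0.17, 0.18, 0.06, 0.07, 0.16],
        "mean_nir": [0.4, 0.40, 0.41, 0.44, 0.45, 0.39],
        "sd_blue": [0.02] * 6,
        "sd_green": [0.02] * 6,
    }
    return pd.DataFrame(cols)


def _assoc_training():
    rows = []
    for i, (cls, red, green, blue, nir) in enumerate(
        [
            ("wild_oat", 0.31, 0.25, 0.17, 0.40),
            ("wild_oat", 0.30, 0.26, 0.18, 0.41),
            ("clover_brome", 0.11, 0.16, 0.06, 0.45),
            ("ryegrass_brome", 0.10, 0.15, 0.07, 0.44),
        ]
    ):
        rows.append(
            {
                "object_id": 100 + i,
                "training_class": cls,
                "mean_red": red,
                "mean_green": green,
                "mean_blue": blue,
                "mean_nir": nir,
                "sd_blue": 0.02,
                "sd_green": 0.02,
            }
        )
    return pd.DataFrame(rows)


class TestClassifyAssociations:
    def test_clumped_texture_object_goes_to_canarygrass(self):
        out = classify_associations(
            _mid_table(), set(range(6)), _assoc_training(), HierarchyConfig()
        )
        assert out[0] == LABEL_CANARY

    def test_storksbill_mask_precedes_features(self):
        out = classify_associations(
            _mid_table(), set(range(6)), _assoc_training(), HierarchyConfig(),
            storksbill_ids={0, 3},
        )
        assert out[0] == LABEL_STORKSBILL and out[3] == LABEL_STORKSBILL

    def test_supervised_split_into_the_two_associations(self):
        out = classify_associations(
            _mid_table(), set(range(6)), _assoc_training(), HierarchyConfig()
        )
        # oat-like spectra (objects 1, 2, 5) vs clover-brome-like (3, 4)
        assert out[1] == out[2] == out[5] == ASSOC_OAT
        assert out[3] == out[4] == ASSOC_CB
        assert LABEL_CANARY not in (out[1], out[3])

    def test_missing_association_training_falls_back_with_warning(self):
        tr = _assoc_training().iloc[:2]  # wild oat only
        with pytest.warns(UserWarning, match="association training"):
            out = classify_associations(
                _mid_table(), {1, 3}, tr, HierarchyConfig()
            )
        assert set(out.values()) == {ASSOC_CB}


class TestGreennessTiers:
    def test_trimodal_association_splits_into_three_tiers(self):
        ndvi = [0.1] * 20 + [0.45] * 20 + [0.8] * 20
        table = pd.DataFrame({"object_id": np.arange(60), "mean_ndvi": ndvi})
        tiers, flagged = greenness_tiers(table, {ASSOC_CB: list(range(60))})
        assert not flagged
        got = [tiers[i] for i in (0, 25, 55)]
        assert got == ["low", "mid", "high"]

    def test_degenerate_association_passes_through_flagged(self):
        table = pd.DataFrame({"object_id": [0, 1], "mean_ndvi": [0.5, 0.5]})
        tiers, flagged = greenness_tiers(table, {ASSOC_OAT: [0, 1]})
        assert flagged == [ASSOC_OAT]
        assert set(tiers.values()) == {"mid"}

    def test_per_association_thresholds_are_independent(self):
        table = pd.DataFrame(
            {
                "object_id": np.arange(12),
                "mean_ndvi": [0.1, 0.2, 0.3, 0.1, 0.2, 0.3, 0.6, 0.7, 0.8, 0.6, 0.7, 0.8],
            }
        )
        tiers, _ = greenness_tiers(
            table, {ASSOC_OAT: list(range(6)), ASSOC_CB: list(range(6, 12))}
        )
        # each association gets its own three tiers despite disjoint ranges
        assert {tiers[i] for i in range(6)} == {"low", "mid", "high"}
        assert {tiers[i] for i in range(6, 12)} == {"low", "mid", "high"}


class TestFinalInvasiveSplit:
    def _table(self):
        return pd.DataFrame(
            {
                "object_id": [0, 1, 2],
                "mean_red": [0.09, 0.095, 0.3],
                "mean_ndvi": [0.65, 0.6, 0.1],
                "glcm_entropy_nir": [3.0, 3.1, 3.0],
            }
        )

    def _training(self, with_goatgrass=True):
        rows = [
            {"object_id": 10, "training_class": MEDUSAHEAD,
             "mean_red": 0.09, "mean_ndvi": 0.66, "glcm_entropy_nir": 3.0},
            {"object_id": 11, "training_class": "clover_brome",
             "mean_red": 0.3, "mean_ndvi": 0.12, "glcm_entropy_nir": 3.0},
        ]
        if with_goatgrass:
            rows.append(
                {"object_id": 12, "training_class": GOATGRASS,
                 "mean_red": 0.096, "mean_ndvi": 0.58, "glcm_entropy_nir": 3.2}
            )
        return pd.DataFrame(rows)

    def test_goatgrass_free_training_warns_binary_fallback(self):
        with pytest.warns(UserWarning, match="goatgrass"):
            out = final_invasive_split(
                self._table(), [0, 1, 2], self._training(False), HierarchyConfig()
            )
        assert GOATGRASS not in out.values()
        assert out[0] == MEDUSAHEAD

    def test_both_invasives_recovered_when_separable(self):
        out = final_invasive_split(
            self._table(), [0, 1, 2], self._training(True), HierarchyConfig(),
        )
        assert out[0] == MEDUSAHEAD and out[1] == GOATGRASS and out[2] == LABEL_OTHER

    def test_empty_member_list(self):
        assert final_invasive_split(self._table(), [], self._training(), HierarchyConfig()) == {}


@pytest.fixture(scope="module")
def hierarchy_run(scene, samples):
    from medusahead_obia.features import segmentation_layers
    from medusahead_obia.objects import build_object_table
    from medusahead_obia.segmentation import segment_hierarchy

    stack, truth = scene
    training, _ = samples
    layers = segmentation_layers(stack)
    levels = segment_hierarchy(layers)
    tables = [build_object_table(lvl, stack) for lvl in levels]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = run_hierarchy(stack, levels, tables, training, seed=1)
    return out, levels, tables


class TestRunHierarchy:
    def test_provenance_total_and_unique(self, hierarchy_run):
        out, levels, _ = hierarchy_run
        prov = out.provenance
        assert len(prov) == levels[-1].n_objects
        assert prov["object_id"].is_unique
        assert prov["label"].notna().all()
        assert set(prov["step"]) <= {
            "coarse_exclude", "isolate_vetch_mosaic", "classify_associations",
            "greenness_tiers", "final_invasive_split",
        }

    def test_isolated_regions_contain_no_medusahead(self, hierarchy_run):
        out, levels, _ = hierarchy_run
        prov = out.provenance
        iso = prov[prov["label"].isin(["vetch_mosaic", "excluded_nonmedusahead"])]
        lab = levels[-1].label_raster
        region = np.isin(lab, iso["object_id"].to_numpy())
        assert not (out.result.medusahead_mask() & region).any()

    def test_result_is_full_coverage(self, hierarchy_run):
        out, levels, _ = hierarchy_run
        assert (out.result.class_index_raster >= 0).all()

    def test_wrong_level_count_errors(self, scene, samples):
        stack, _ = scene
        training, _ = samples
        with pytest.raises(ParameterError):
            run_hierarchy(stack, [], [], training)

    def test_storksbill_mask_never_classified_medusahead(self, scene, samples):
        from shapely.geometry import box

        from medusahead_obia.features import segmentation_layers
        from medusahead_obia.objects import build_object_table
        from medusahead_obia.segmentation import segment_hierarchy

        stack, _ = scene
        training, _ = samples
        layers = segmentation_layers(stack)
        levels = segment_hierarchy(layers)
        tables = [build_object_table(lvl, stack) for lvl in levels]
        mask_geom = box(5.0, 5.0, 20.0, 20.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_hierarchy(
                stack, levels, tables, training, storksbill_mask=mask_geom, seed=1
            )
        prov = out.provenance
        stork = prov[prov["label"] == "storksbill"]["object_id"].to_numpy()
        lab = levels[-1].label_raster
        region = np.isin(lab, stork)
        assert not (out.result.medusahead_mask() & region).any()


def test_invalid_config_rejected():
    with pytest.raises(ParameterError):
        HierarchyConfig(supervised_algorithm="forest")
    with pytest.raises(ParameterError):
        HierarchyConfig(ndvi_exclusion_threshold=np.nan)
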