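"""Supervised single-run classifiers and the unsupervised k-means path."""

import warnings

import numpy as np
import pandas as pd
import pytest

from medusahead_obia.classify import (
    SEVEN_CLASS,
    SPECTRAL,
    SPECTRAL_TEXTURE,
    THREE_CLASS,
    TO_THREE,
    collapse_to_three,
    kmeans_classify,
    kmeans_scan,
    train_predict,
)
from medusahead_obia.errors import ParameterError, TrainingError
from medusahead_obia.scene import MEDUSAHEAD


def _toy_table(n=60, seed=0, n_features=4):
    rng = np.random.default_rng(seed)
    cols = {"object_id": np.arange(n)}
    for i, name in enumerate(SPECTRAL.columns[:n_features]):
        cols[name] = rng.normal(0, 1, n)
    return pd.DataFrame(cols)


class TestFeatureSets:
    def test_spectral_is_subset_of_spectral_texture(self):
        assert set(SPECTRAL.columns) < set(SPECTRAL_TEXTURE.columns)

    def test_schemes(self):
        assert THREE_CLASS.classes == ("medusahead", "other_green", "other_nongreen")
        assert len(SEVEN_CLASS.classes) == 7


class TestTrainPredict:
    def test_one_nn_reproduces_training_labels(self, scene, fine_level, object_table,
                                               training_objects):
        stack, _ = scene
        pred = train_predict(
            object_table, training_objects, "knn", SEVEN_CLASS, SPECTRAL_TEXTURE, seed=0
        )
        for _, row in training_objects.iterrows():
            assert pred.loc[row["object_id"]] == row["training_class"]

    def test_gaussian_boundary_at_midpoint_of_means(self):
        """Equal-variance 1-D two-class case: the decision flips at the
        midpoint of the class means (closed-form Gaussian discriminant)."""
        col = SPECTRAL.columns[0]
        train = pd.DataFrame(
            {
                "object_id": np.arange(8),
                col: [0.0, 0.1, -0.1, 0.05, 1.0, 1.1, 0.9, 0.95],
                "training_class": ["medusahead"] * 4 + ["barbed_goatgrass"] * 4,
            }
        )
        for c in SPECTRAL.columns[1:]:
            train[c] = 0.0
        table = _toy_table(n=41, seed=1)
        for c in SPECTRAL.columns[1:]:
            table[c] = 0.0
        table[col] = np.linspace(-0.5, 1.6, 41)
        from medusahead_obia.classify import ClassScheme

        scheme = ClassScheme("pair", ("medusahead", "barbed_goatgrass"))
        pred = train_predict(table, train, "bayes", scheme, SPECTRAL, seed=0)
        mid = (np.mean([0.0, 0.1, -0.1, 0.05]) + np.mean([1.0, 1.1, 0.9, 0.95])) / 2
        x = table[col].to_numpy()
        assert (pred.to_numpy()[x < mid - 0.03] == "medusahead").all()
        assert (pred.to_numpy()[x > mid + 0.03] == "barbed_goatgrass").all()

    def test_svm_separable_zero_training_error(self):
        rng = np.random.default_rng(2)
        n = 40
        table = _toy_table(n=n, seed=3)
        col = SPECTRAL.columns[0]
        table[col] = np.r_[rng.normal(-2, 0.3, n // 2), rng.normal(2, 0.3, n // 2)]
        train = table.copy()
        train["training_class"] = ["medusahead"] * (n // 2) + ["barbed_goatgrass"] * (n // 2)
        from medusahead_obia.classify import ClassScheme

        scheme = ClassScheme("pair", ("medusahead", "barbed_goatgrass"))
        pred = train_predict(table, train, "svm_linear", scheme, SPECTRAL, seed=0)
        assert (pred.to_numpy() == train["training_class"].to_numpy()).all()

    def test_missing_class_raises_training_error(self, object_table, training_objects):
        sub = training_objects[training_objects["training_class"] == MEDUSAHEAD]
        with pytest.raises(TrainingError) as err:
            train_predict(object_table, sub, "knn", SEVEN_CLASS, SPECTRAL, seed=0)
        assert err.value.missing_class in SEVEN_CLASS.classes

    def test_unknown_algorithm_errors(self, object_table, training_objects):
        with pytest.raises(ParameterError):
            train_predict(object_table, training_objects, "forest", SEVEN_CLASS, SPECTRAL)

    def test_scheme_collapse_consistency(self, scene, fine_level, object_table,
                                         training_objects):
        """Mapping a seven-class result through the green/non-green collapse
        yields a valid three-class result covering every object."""
        stack, _ = scene
        res7 = train_predict(
            object_table, training_objects, "knn", SEVEN_CLASS, SPECTRAL,
            seed=0, level=fine_level, stack=stack,
        )
        res3 = collapse_to_three(res7)
        assert set(res3.assignments.unique()) <= set(THREE_CLASS.classes)
        assert len(res3.assignments) == fine_level.n_objects
        # medusahead objects unchanged by the collapse
        mh7 = set(res7.assignments[res7.assignments == MEDUSAHEAD].index)
        mh3 = set(res3.assignments[res3.assignments == MEDUSAHEAD].index)
        assert mh7 == mh3
        assert set(TO_THREE.values()) == set(THREE_CLASS.classes)


class TestKmeans:
    def test_variance_zero_when_k_equals_n(self):
        table = _toy_table(n=12, seed=4)
        scan = kmeans_scan(table, SPECTRAL, k_range=[11, 12], seed=0)
        assert scan.within_cluster_variance[-1] == pytest.approx(0.0, abs=1e-9)

    def test_variance_non_increasing_in_k(self):
        table = _toy_table(n=80, seed=5)
        scan = kmeans_scan(table, SPECTRAL, k_range=range(2, 12), seed=0)
        v = scan.within_cluster_variance
        assert all(b <= a + 1e-6 for a, b in zip(v, v[1:]))

    def test_two_blob_elbow(self):
        rng = np.random.default_rng(6)
        table = _toy_table(n=60, seed=7)
        # two well-separated blobs expressed in every feature (standardization
        # would otherwise re-inflate pure-noise features to unit variance)
        for col in SPECTRAL.columns:
            table[col] = np.r_[rng.normal(-5, 0.2, 30), rng.normal(5, 0.2, 30)]
        scan = kmeans_scan(table, SPECTRAL, k_range=[1, 2, 3], seed=0)
        v = scan.within_cluster_variance
        assert (v[0] - v[1]) > 10 * (v[1] - v[2])

    def test_k_larger_than_objects_errors(self):
        with pytest.raises(ParameterError):
            kmeans_scan(_toy_table(n=5), SPECTRAL, k_range=[10], seed=0)

    def test_cluster_labelling_theta_rules(self, scene, fine_level, object_table):
        stack, _ = scene
        # objects carrying medusahead samples: pick a handful of object ids
        mh_objects = object_table["object_id"].iloc[:8].tolist()
        res = kmeans_classify(
            object_table, SPECTRAL, 5, 0, mh_objects, fine_level, stack, theta=0.05
        )
        diag = res.metadata["clusters"]
        assert diag["labelled_medusahead"].any()
        assert (diag["mh_sample_fraction"][diag["labelled_medusahead"]] >= 0.05).all()
        # theta = 1.0 with samples split across clusters -> nothing labelled
        if diag["labelled_medusahead"].sum() > 1 or diag["mh_sample_fraction"].max() < 1.0:
            with pytest.warns(UserWarning, match="theta"):
                res2 = kmeans_classify(
                    object_table, SPECTRAL, 5, 0, mh_objects, fine_level, stack, theta=1.0
                )
            assert not res2.medusahead_mask().any()

    def test_no_samples_warns_empty_extent(self, scene, fine_level, object_table):
        stack, _ = scene
        with pytest.warns(UserWarning, match="no medusahead"):
            res = kmeans_classify(
                object_table, SPECTRAL, 4, 0, [], fine_level, stack
            )
        assert not res.medusahead_mask().any()


class TestClassificationResult:
    def test_raster_agrees_with_assignments(self, scene, fine_level, object_table,
                                            training_objects):
        stack, _ = scene
        res = train_predict(
            object_table, training_objects, "knn", SEVEN_CLASS, SPECTRAL,
            seed=0, level=fine_level, stack=stack,
        )
        lab = fine_level.label_raster
        rng = np.random.default_rng(1)
        for oid in rng.choice(fine_level.n_objects, 25, replace=False):
            sel = lab == oid
            codes = np.unique(res.class_index_raster[sel])
            assert len(codes) == 1
            assert res.classes[codes[0]] == res.assignments.loc[oid]

    def test_medusahead_polygons_cover_mask_area(self, scene, fine_level, object_table,
                                                 training_objects):
        stack, _ = scene
        res = train_predict(
            object_table, training_objects, "bayes", SEVEN_CLASS, SPECTRAL,
            seed=0, level=fine_level, stack=stack,
        )
        mask_area = res.medusahead_mask().sum() * stack.pixel_size_m**2
        poly_area = sum(p.area for p in res.medusahead_polygons())
        if mask_area > 0:
            assert poly_area == pytest.approx(mask_area, rel=0.25)
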