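"""End-to-end experiment driver: simulate -> segment -> classify -> validate.

One call builds a seeded synthetic scene, simulates the transect survey and
sample designation, segments the image (fine scale for single-run methods,
three nested scales for the hierarchy), runs a roster of classification
methods, and evaluates each with fuzzy accuracy metrics and transect-based
patch validation.  Every artifact is regenerable from the config and master
seed alone; per-method child seeds derive deterministically from the master
seed by method index, so adding a method never perturbs the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import classify as cls
from .classify import (
    SEVEN_CLASS,
    SPECTRAL,
    SPECTRAL_TEXTURE,
    THREE_CLASS,
    ClassificationResult,
    kmeans_classify,
    train_predict,
)
from .evaluation import FuzzyAccuracyReport, evaluate_combined, evaluate_fuzzy, tabulate_methods
from .features import derive_layers, segmentation_layers
from .hierarchy import GOATGRASS, HierarchyConfig, HierarchyResult, run_hierarchy
from .objects import attach_training, build_object_table
from .scene import MEDUSAHEAD, SceneConfig, default_scene_config, generate_scene
from .segmentation import multiresolution_segment, segment_hierarchy
from .survey import (
    SurveyLayout,
    designate_sample_sets,
    simulate_field_survey,
    survey_reference_candidates,
)
from .transects import transect_validation


@dataclass(frozen=True)
class MethodSpec:
    """One roster entry: a method plus its scheme/feature choices."""

    kind: str  # unsupervised | supervised | hierarchical
    algorithm: str | None = None  # knn | bayes | svm_linear (supervised, hierarchical)
    k: int | None = None  # cluster count (unsupervised)
    scheme: str | None = None  # three_class | seven_class (supervised)
    with_texture: bool = True

    @property
    def method_id(self) -> str:
        if self.kind == "unsupervised":
            return f"unsupervised_k{self.k}_{'texture' if self.with_texture else 'spectral'}"
        if self.kind == "supervised":
            t = "texture" if self.with_texture else "spectral"
            return f"supervised_{self.algorithm}_{self.scheme}_{t}"
        return f"hierarchical_{self.algorithm}"


def default_roster() -> list[MethodSpec]:
    """The 19-method comparison grid: four unsupervised runs (12/18 clusters,
    with and without texture), twelve single-run supervised combinations and
    three hierarchical variants."""
    roster: list[MethodSpec] = []
    for k in (12, 18):
        for tex in (False, True):
            roster.append(MethodSpec(kind="unsupervised", k=k, with_texture=tex))
    for algo in ("knn", "svm_linear", "bayes"):
        for scheme in ("three_class", "seven_class"):
            for tex in (False, True):
                roster.append(
                    MethodSpec(kind="supervised", algorithm=algo, scheme=scheme, with_texture=tex)
                )
    for algo in ("knn", "svm_linear", "bayes"):
        roster.append(MethodSpec(kind="hierarchical", algorithm=algo))
    return roster


@dataclass
class ExperimentConfig:
    scene: SceneConfig | None = None
    scene_extent_m: tuple[float, float] = (96.0, 48.0)
    scene_preset: str = "realistic"
    layout: SurveyLayout = dc_field(default_factory=SurveyLayout)
    fine_scale: float = 10.0
    hierarchy_scales: tuple[float, float, float] = (390.0, 176.0, 10.0)
    shape_weight: float = 0.1
    compactness_weight: float = 0.1
    roster: list[MethodSpec] = dc_field(default_factory=default_roster)
    training_counts: dict[str, int] | None = None
    test_strata: tuple[int, int, int] = (50, 50, 50)
    n_candidate_samples: int = 6000
    candidates_per_patch: int = 10
    kmeans_theta: float = 0.05
    hierarchy_config: HierarchyConfig = dc_field(default_factory=HierarchyConfig)
    master_seed: int = 0

    def child_seed(self, index: int) -> int:
        # counter-based derivation: reproducible per method, independent of
        # roster order, always below 2**31
        return int((self.master_seed * 1_000_003 + 97 * (index + 1)) % (2**31 - 1))


@dataclass
class MethodOutcome:
    spec: MethodSpec
    result: ClassificationResult
    fuzzy: FuzzyAccuracyReport
    combined: FuzzyAccuracyReport | None
    transect_stats: tuple | None
    hierarchy: HierarchyResult | None = None


@dataclass
class ExperimentOutputs:
    config: ExperimentConfig
    stack: object
    truth: object
    transects: list
    field_segments: list
    training: list
    test: list
    outcomes: list[MethodOutcome]
    comparison: pd.DataFrame
    ranges: dict
    manifest: dict


def _features_for(with_texture: bool):
    return SPECTRAL_TEXTURE if with_texture else SPECTRAL


def run_experiment(config: ExperimentConfig | None = None) -> ExperimentOutputs:
    """Run the full roster experiment; see module docstring."""
    config = config or ExperimentConfig()
    scene_cfg = config.scene or default_scene_config(
        extent_m=config.scene_extent_m,
        preset=config.scene_preset,
        seed=config.master_seed,
    )
    stack, truth = generate_scene(scene_cfg)
    derive_layers(stack)

    transects, field_segments, plot_samples = simulate_field_survey(
        truth, config.layout, seed=config.master_seed + 1
    )
    candidates = plot_samples + survey_reference_candidates(
        truth,
        n_random=config.n_candidate_samples,
        per_patch=config.candidates_per_patch,
        seed=config.master_seed + 2,
    )
    training, test = designate_sample_sets(
        candidates,
        training_counts=config.training_counts,
        test_strata=config.test_strata,
        seed=config.master_seed + 3,
    )

    seg_layers = segmentation_layers(stack)
    fine = multiresolution_segment(
        seg_layers,
        config.fine_scale,
        shape_weight=config.shape_weight,
        compactness_weight=config.compactness_weight,
    )
    fine_table = build_object_table(fine, stack)
    train_objects = attach_training(fine_table, training, fine, stack)

    need_hierarchy = any(m.kind == "hierarchical" for m in config.roster)
    if need_hierarchy:
        levels = segment_hierarchy(
            seg_layers,
            scales=config.hierarchy_scales,
            shape_weight=config.shape_weight,
            compactness_weight=config.compactness_weight,
        )
        tables = [build_object_table(lvl, stack) for lvl in levels]

    mh_sample_objects = train_objects["object_id"][
        train_objects["training_class"] == MEDUSAHEAD
    ].tolist()

    outcomes: list[MethodOutcome] = []
    for i, spec in enumerate(config.roster):
        seed = config.child_seed(i)
        hier = None
        if spec.kind == "unsupervised":
            result = kmeans_classify(
                fine_table,
                _features_for(spec.with_texture),
                spec.k,
                seed,
                mh_sample_objects,
                fine,
                stack,
                theta=config.kmeans_theta,
            )
        elif spec.kind == "supervised":
            scheme = SEVEN_CLASS if spec.scheme == "seven_class" else THREE_CLASS
            result = train_predict(
                fine_table,
                train_objects,
                spec.algorithm,
                scheme,
                _features_for(spec.with_texture),
                seed=seed,
                level=fine,
                stack=stack,
            )
        elif spec.kind == "hierarchical":
            hcfg = HierarchyConfig(
                **{
                    **config.hierarchy_config.__dict__,
                    "supervised_algorithm": spec.algorithm,
                }
            )
            hier = run_hierarchy(stack, levels, tables, training, hcfg, seed=seed)
            result = hier.result
        else:
            raise ValueError(f"unknown method kind {spec.kind!r}")
        result.method_id = spec.method_id

        fuzzy = evaluate_fuzzy(result, test)
        combined = None
        if spec.kind == "hierarchical" or spec.scheme == "seven_class":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                combined = evaluate_combined(result, test, merge=(MEDUSAHEAD, GOATGRASS))
        tstats = transect_validation(result, transects, field_segments)
        outcomes.append(MethodOutcome(spec, result, fuzzy, combined, tstats, hierarchy=hier))

    comparison, ranges = tabulate_methods([o.fuzzy for o in outcomes])
    comparison.insert(1, "with_texture", [o.spec.with_texture for o in outcomes])
    manifest = {
        "master_seed": config.master_seed,
        "scene_extent_m": list(truth.extent_m),
        "scene_preset": config.scene_preset,
        "n_transects": len(transects),
        "n_field_segments": len(field_segments),
        "n_training": len(training),
        "n_test": len(test),
        "fine_scale": config.fine_scale,
        "n_fine_objects": fine.n_objects,
        "methods": [m.method_id for m in config.roster],
        "child_seeds": [config.child_seed(i) for i in range(len(config.roster))],
    }
    return ExperimentOutputs(
        config=config,
        stack=stack,
        truth=truth,
        transects=transects,
        field_segments=field_segments,
        training=training,
        test=test,
        outcomes=outcomes,
        comparison=comparison,
        ranges=ranges,
        manifest=manifest,
    )
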