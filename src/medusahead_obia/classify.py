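"""Unsupervised k-means scan and single-run supervised object classifiers.

Three supervised algorithms are compared under two class schemes (a simple
medusahead / other-green / other-non-green split, and seven vegetation
categories) and two feature sets (spectral means only, or means plus the
standard-deviation and GLCM-entropy texture attributes):

* ``knn`` — majority vote of the k nearest training objects (k = 1 default),
* ``bayes`` — Gaussian class-conditionals with diagonal covariance and
  equal priors (training counts are design-balanced, not prevalences),
* ``svm_linear`` — one-vs-one linear-kernel margins, C = 1.

Features are standardized by the training statistics.  The unsupervised path
clusters all objects with seeded, restarted k-means over a range of cluster
counts, flags local deviations of the within-cluster-variance decline curve,
and labels as medusahead every cluster that captures at least a fraction
``theta`` of the medusahead training samples — an explicit numeric stand-in
for a visual cluster-identification step, and deliberately permissive
(overprediction is allowed and diagnosed, not hidden).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage import measure
from sklearn.cluster import KMeans
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ParameterError, TrainingError
from .objects import SPECTRAL_FEATURES, TEXTURE_FEATURES
from .scene import MEDUSAHEAD
from .segmentation import SegmentationLevel
from .stack import BandStack


@dataclass(frozen=True)
class ClassScheme:
    name: str
    classes: tuple[str, ...]


THREE_CLASS = ClassScheme("three_class", ("medusahead", "other_green", "other_nongreen"))
SEVEN_CLASS = ClassScheme(
    "seven_class",
    (
        "medusahead",
        "clover_brome",
        "ryegrass_brome",
        "canarygrass",
        "vetch",
        "barbed_goatgrass",
        "wild_oat",
    ),
)

#: Collapse of scene/seven-class labels onto the three-class scheme.
TO_THREE = {
    "medusahead": "medusahead",
    "clover_brome": "other_green",
    "ryegrass_brome": "other_green",
    "canarygrass": "other_green",
    "vetch": "other_green",
    "barbed_goatgrass": "other_green",
    "wild_oat": "other_nongreen",
    "senescent_matrix": "other_nongreen",
}


@dataclass(frozen=True)
class FeatureSet:
    name: str
    columns: tuple[str, ...]


SPECTRAL = FeatureSet("spectral", tuple(SPECTRAL_FEATURES))
SPECTRAL_TEXTURE = FeatureSet("spectral_texture", tuple(SPECTRAL_FEATURES + TEXTURE_FEATURES))


def scheme_label(best_class: str, scheme: ClassScheme) -> str:
    """Map a scene class name onto a scheme class."""
    if scheme.name == "three_class":
        return TO_THREE[best_class]
    return best_class


@dataclass
class ClassificationResult:
    """An object -> class assignment realized as a raster."""

    method_id: str
    scheme_name: str
    feature_set_name: str
    assignments: pd.Series  # index: object_id, values: class names
    level: SegmentationLevel
    stack: BandStack
    classes: list[str]
    class_index_raster: np.ndarray  # int16, -1 for masked pixels
    metadata: dict = field(default_factory=dict)

    def class_at(self, x: float, y: float) -> str | None:
        r, c = self.stack.world_to_index(x, y)
        H, W = self.class_index_raster.shape
        if not (0 <= r < H and 0 <= c < W):
            return None
        idx = self.class_index_raster[r, c]
        return None if idx < 0 else self.classes[idx]

    def class_mask(self, name: str) -> np.ndarray:
        if name not in self.classes:
            return np.zeros(self.class_index_raster.shape, dtype=bool)
        return self.class_index_raster == self.classes.index(name)

    def medusahead_mask(self) -> np.ndarray:
        return self.class_mask(MEDUSAHEAD)

    def medusahead_polygons(self) -> list[Polygon]:
        """Extent outlines of the classified medusahead, in scene metres."""
        mask = self.medusahead_mask().astype(float)
        px = self.stack.pixel_size_m
        H = mask.shape[0]
        polys = []
        for contour in measure.find_contours(np.pad(mask, 1), 0.5):
            rr = contour[:, 0] - 1
            cc = contour[:, 1] - 1
            xs = (cc + 0.5) * px + self.stack.origin[0]
            ys = (H - rr - 0.5) * px + self.stack.origin[1]
            if len(xs) >= 4:
                poly = Polygon(zip(xs, ys))
                if poly.is_valid and poly.area > 0:
                    polys.append(poly)
        return polys

    def relabeled(self, mapping: dict[str, str], method_suffix: str = "") -> "ClassificationResult":
        """A new result with classes renamed through ``mapping``."""
        new_assign = self.assignments.map(lambda c: mapping.get(c, c))
        return build_result(
            self.method_id + method_suffix,
            self.scheme_name,
            self.feature_set_name,
            new_assign,
            self.level,
            self.stack,
            metadata=dict(self.metadata),
        )


def build_result(
    method_id, scheme_name, feature_set_name, assignments, level, stack, metadata=None
) -> ClassificationResult:
    classes = sorted(set(assignments.values))
    code = {c: i for i, c in enumerate(classes)}
    lut = np.full(level.n_objects, -1, dtype=np.int16)
    for oid, cls in assignments.items():
        lut[int(oid)] = code[cls]
    lab = level.label_raster
    raster = np.where(lab >= 0, lut[np.clip(lab, 0, None)], np.int16(-1))
    return ClassificationResult(
        method_id=method_id,
        scheme_name=scheme_name,
        feature_set_name=feature_set_name,
        assignments=assignments,
        level=level,
        stack=stack,
        classes=classes,
        class_index_raster=raster.astype(np.int16),
        metadata=metadata or {},
    )


# ---------------------------------------------------------------------------
# supervised single-run
# ---------------------------------------------------------------------------

_ALGORITHMS = ("knn", "bayes", "svm_linear")


def _make_estimator(algorithm: str, n_classes: int, knn_k: int, seed: int):
    if algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=knn_k)
    if algorithm == "bayes":
        return GaussianNB(priors=np.full(n_classes, 1.0 / n_classes))
    if algorithm == "svm_linear":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    raise ParameterError(f"unknown algorithm {algorithm!r}; choose from {_ALGORITHMS}")


def train_predict(
    table: pd.DataFrame,
    training: pd.DataFrame,
    algorithm: str,
    scheme: ClassScheme,
    features: FeatureSet,
    seed: int = 0,
    knn_k: int = 1,
    level: SegmentationLevel | None = None,
    stack: BandStack | None = None,
) -> ClassificationResult | pd.Series:
    """Fit one supervised algorithm on the training objects and classify all.

    ``training`` is the labelled subset from :func:`objects.attach_training`
    (must carry ``training_class``).  Labels are mapped onto the scheme; every
    scheme class must have at least one training object.  When ``level`` and
    ``stack`` are given a full :class:`ClassificationResult` is returned,
    otherwise just the object -> class Series.
    """
    y = training["training_class"].map(lambda c: scheme_label(c, scheme))
    missing = [c for c in scheme.classes if c not in set(y)]
    if missing:
        raise TrainingError(
            f"scheme class(es) {missing} have no training objects", missing_class=missing[0]
        )
    cols = list(features.columns)
    scaler = StandardScaler().fit(training[cols].to_numpy(float))
    Xtr = scaler.transform(training[cols].to_numpy(float))
    est = _make_estimator(algorithm, len(scheme.classes), knn_k, seed)
    est.fit(Xtr, y.to_numpy())
    X = scaler.transform(table[cols].to_numpy(float))
    pred = pd.Series(est.predict(X), index=table["object_id"].to_numpy())
    if level is None or stack is None:
        return pred
    method_id = f"supervised_{algorithm}_{scheme.name}_{features.name}"
    return build_result(
        method_id,
        scheme.name,
        features.name,
        pred,
        level,
        stack,
        metadata={"algorithm": algorithm, "knn_k": knn_k, "seed": seed},
    )


def collapse_to_three(result: ClassificationResult) -> ClassificationResult:
    """Map a seven-class result onto the three-class scheme."""
    out = result.relabeled(TO_THREE, method_suffix="_as3")
    out.scheme_name = "three_class"
    return out


# ---------------------------------------------------------------------------
# unsupervised
# ---------------------------------------------------------------------------


@dataclass
class KMeansScanResult:
    ks: list[int]
    within_cluster_variance: list[float]
    flagged_ks: list[int]


def _standardize(table: pd.DataFrame, features: FeatureSet) -> np.ndarray:
    X = table[list(features.columns)].to_numpy(float)
    return StandardScaler().fit_transform(X)


def kmeans_scan(
    table: pd.DataFrame,
    features: FeatureSet,
    k_range=range(10, 31),
    seed: int = 0,
    restarts: int = 10,
) -> KMeansScanResult:
    """Within-cluster variance over a range of cluster counts.

    Best-of-``restarts`` seeded k-means per k on standardized features; the
    total within-cluster variance (inertia) is recorded, and ks where the
    decline curve shows a local deviation (a sign change of the discrete
    second difference) are flagged as candidate cluster counts.
    """
    ks = list(k_range)
    if max(ks) > len(table):
        raise ParameterError(f"k = {max(ks)} exceeds the {len(table)} objects")
    X = _standardize(table, features)
    inertia = []
    for i, k in enumerate(ks):
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed + i)
        km.fit(X)
        inertia.append(float(km.inertia_))
    d2 = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        d2[i] = inertia[i + 1] - 2 * inertia[i] + inertia[i - 1]
    flagged = [
        ks[i]
        for i in range(2, len(ks) - 1)
        if np.isfinite(d2[i]) and np.isfinite(d2[i - 1]) and np.sign(d2[i]) != np.sign(d2[i - 1])
    ]
    return KMeansScanResult(ks=ks, within_cluster_variance=inertia, flagged_ks=flagged)


def kmeans_classify(
    table: pd.DataFrame,
    features: FeatureSet,
    k: int,
    seed: int,
    mh_sample_objects,
    level: SegmentationLevel,
    stack: BandStack,
    theta: float = 0.05,
    restarts: int = 10,
) -> ClassificationResult:
    """Cluster all objects and label medusahead-bearing clusters.

    ``mh_sample_objects`` is the collection of object ids containing
    medusahead training samples.  A cluster is labelled medusahead when it
    captures at least a fraction ``theta`` of those samples; every other
    cluster keeps a ``cluster_<j>`` label so the output stays a complete
    partition with overlap diagnostics in ``metadata['clusters']``.
    """
    if k > len(table):
        raise ParameterError(f"k = {k} exceeds the {len(table)} objects")
    X = _standardize(table, features)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    cluster = km.fit_predict(X)
    obj_ids = table["object_id"].to_numpy()
    cl_of_obj = dict(zip(obj_ids, cluster))
    mh_objs = [o for o in mh_sample_objects if o in cl_of_obj]
    total = len(mh_objs)
    counts = np.zeros(k)
    for o in mh_objs:
        counts[cl_of_obj[o]] += 1
    if total == 0:
        warnings.warn("no medusahead training samples fall in any cluster", stacklevel=2)
        frac = np.zeros(k)
    else:
        frac = counts / total
    labelled = frac >= theta if total else np.zeros(k, dtype=bool)
    if total and not labelled.any():
        warnings.warn(
            f"no cluster reaches the theta = {theta} medusahead-sample fraction; "
            "empty medusahead extent",
            stacklevel=2,
        )
    names = [MEDUSAHEAD if labelled[j] else f"cluster_{j}" for j in range(k)]
    assignments = pd.Series([names[cl_of_obj[o]] for o in obj_ids], index=obj_ids)
    diagnostics = pd.DataFrame(
        {
            "cluster": np.arange(k),
            "n_objects": np.bincount(cluster, minlength=k),
            "mh_sample_fraction": frac,
            "labelled_medusahead": labelled,
        }
    )
    return build_result(
        f"unsupervised_k{k}_{features.name}",
        "unsupervised",
        features.name,
        assignments,
        level,
        stack,
        metadata={"k": k, "theta": theta, "seed": seed, "clusters": diagnostics},
    )
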