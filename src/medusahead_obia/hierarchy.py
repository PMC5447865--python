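"""Knowledge-based hierarchical classification of medusahead.

The workflow walks a nested segmentation from broad landscape units down to
primitive objects, narrowing the medusahead candidate set at each step:

1. **Coarse exclusion** — broad objects with low NDVI that also lie far from
   every known medusahead training location are removed outright.
2. **Vetch-mosaic isolation** — broad objects whose NIR GLCM entropy marks
   the high-heterogeneity vetch / clover-brome / ryegrass mosaics are set
   aside; those communities do not host medusahead.
3. **Association classing** — mid-scale objects inside the remaining area
   are split into canarygrass (green-band GLCM entropy rule), manually
   delineated storksbill (mask taken verbatim), and the two medusahead
   associations (with wild oat, with clover-brome) by a supervised
   classifier on band means and blue/green standard deviations.
4. **Greenness tiers** — within each association, fine objects are split
   into three NDVI tiers by two-threshold Otsu; the least green tier is
   non-medusahead.
5. **Final invasive split** — the remaining greener objects are classified
   into medusahead, barbed goatgrass and other, on exactly mean red, mean
   NDVI and NIR GLCM entropy.

Every fine object receives a terminal label and a provenance record naming
the single step that fixed it, so exclusions are auditable: classified
medusahead can never appear inside excluded or vetch-mosaic regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .classify import ClassificationResult, build_result, _make_estimator
from .errors import ParameterError
from .features import otsu_thresholds
from .objects import attach_training
from .scene import MEDUSAHEAD
from .segmentation import SegmentationLevel
from .stack import BandStack
from sklearn.preprocessing import StandardScaler

GOATGRASS = "barbed_goatgrass"

# step names, also used as provenance tags
STEP_EXCLUDE = "coarse_exclude"
STEP_VETCH = "isolate_vetch_mosaic"
STEP_ASSOC = "classify_associations"
STEP_TIERS = "greenness_tiers"
STEP_FINAL = "final_invasive_split"

LABEL_EXCLUDED = "excluded_nonmedusahead"
LABEL_VETCH = "vetch_mosaic"
LABEL_CANARY = "canarygrass"
LABEL_STORKSBILL = "storksbill"
LABEL_LOW_TIER = "non_medusahead_low_greenness"
LABEL_OTHER = "other_nonmedusahead"

ASSOC_OAT = "mh_wild_oat_assoc"
ASSOC_CB = "mh_clover_brome_assoc"


@dataclass
class HierarchyConfig:
    """Thresholds and choices for the hierarchical workflow.

    Defaults were calibrated once on the packaged synthetic fixture scene
    (see docs); all are explicit so site-specific recalibration is a config
    edit, not a code change.
    """

    ndvi_exclusion_threshold: float = 0.15
    distance_exclusion_m: float = 30.0
    entropy_nir_threshold: float = 4.65
    entropy_green_threshold: float = 4.85
    supervised_algorithm: str = "bayes"
    association_features: tuple[str, ...] = (
        "mean_red",
        "mean_green",
        "mean_blue",
        "mean_nir",
        "sd_blue",
        "sd_green",
    )
    final_split_features: tuple[str, ...] = ("mean_red", "mean_ndvi", "glcm_entropy_nir")
    knn_k: int = 1

    def __post_init__(self) -> None:
        for name in (
            "ndvi_exclusion_threshold",
            "distance_exclusion_m",
            "entropy_green_threshold",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")
        if self.supervised_algorithm not in ("knn", "bayes", "svm_linear"):
            raise ParameterError(f"invalid algorithm {self.supervised_algorithm!r}")


@dataclass
class HierarchyResult:
    result: ClassificationResult
    provenance: pd.DataFrame  # object_id, step, label (fine level)
    step_log: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# individual steps
# ---------------------------------------------------------------------------


def coarse_exclude(
    table: pd.DataFrame,
    level: SegmentationLevel,
    stack: BandStack,
    mh_training_points: list[tuple[float, float]],
    config: HierarchyConfig,
) -> tuple[set[int], set[int]]:
    """Partition coarse objects into (excluded, candidate).

    An object is excluded iff its mean NDVI is below the threshold AND its
    nearest medusahead training sample is farther than the distance cut
    (conjunction: a green object is always a candidate, and an object
    containing a sample is at distance 0).  Without training samples the
    distance criterion is disabled with a warning and NDVI alone decides.
    """
    low_ndvi = table["mean_ndvi"].to_numpy() < config.ndvi_exclusion_threshold
    if mh_training_points:
        seeds = np.zeros(stack.shape, dtype=bool)
        for x, y in mh_training_points:
            r, c = stack.world_to_index(x, y)
            H, W = stack.shape
            if 0 <= r < H and 0 <= c < W:
                seeds[r, c] = True
        dist_px = ndimage.distance_transform_edt(~seeds)
        lab = level.label_raster
        sel = lab >= 0
        mind = np.full(level.n_objects, np.inf)
        np.minimum.at(mind, lab[sel], dist_px[sel])
        far = mind[table["object_id"].to_numpy()] * stack.pixel_size_m > config.distance_exclusion_m
    else:
        warnings.warn(
            "no medusahead training samples: distance criterion disabled, "
            "excluding on NDVI alone",
            stacklevel=2,
        )
        far = np.ones(len(table), dtype=bool)
    excl = set(table["object_id"].to_numpy()[low_ndvi & far].tolist())
    cand = set(table["object_id"].tolist()) - excl
    return excl, cand


def isolate_vetch_mosaic(
    table: pd.DataFrame,
    candidate_ids: set[int],
    config: HierarchyConfig,
) -> tuple[set[int], set[int]]:
    """Set aside high-NIR-entropy mosaic objects; they never re-enter."""
    sub = table[table["object_id"].isin(candidate_ids)]
    vetch = set(
        sub["object_id"][sub["glcm_entropy_nir"] >= config.entropy_nir_threshold].tolist()
    )
    return vetch, candidate_ids - vetch


def _fit_predict(train_X, train_y, X, algorithm, knn_k, seed):
    scaler = StandardScaler().fit(train_X)
    est = _make_estimator(algorithm, len(set(train_y)), knn_k, seed)
    est.fit(scaler.transform(train_X), train_y)
    return est.predict(scaler.transform(X))


def classify_associations(
    table: pd.DataFrame,
    member_ids: set[int],
    training: pd.DataFrame,
    config: HierarchyConfig,
    storksbill_ids: set[int] | None = None,
    seed: int = 0,
) -> dict[int, str]:
    """Assign mid-scale objects to {canarygrass, storksbill, mh associations}.

    The green-band entropy rule fires first; storksbill objects come from the
    input mask verbatim; everything else is split into the wild-oat and
    clover-brome medusahead associations by the configured supervised
    algorithm.  Association training labels derive from sample best classes
    (wild oat -> oat association; clover-brome / ryegrass -> clover-brome
    association; other classes are uninformative for this split).
    """
    storksbill_ids = storksbill_ids or set()
    out: dict[int, str] = {}
    sub = table[table["object_id"].isin(member_ids)].set_index("object_id")
    rest = []
    for oid in sorted(member_ids):
        if oid in storksbill_ids:
            out[oid] = LABEL_STORKSBILL
        elif sub.loc[oid, "glcm_entropy_green"] >= config.entropy_green_threshold:
            out[oid] = LABEL_CANARY
        else:
            rest.append(oid)
    if not rest:
        return out
    assoc_of = {"wild_oat": ASSOC_OAT, "clover_brome": ASSOC_CB, "ryegrass_brome": ASSOC_CB}
    tr = training[training["training_class"].isin(assoc_of)]
    cols = list(config.association_features)
    if tr.empty or len(set(tr["training_class"].map(assoc_of))) < 2:
        warnings.warn(
            "insufficient association training; assigning all remaining mid-scale "
            "objects to the clover-brome association",
            stacklevel=2,
        )
        for oid in rest:
            out[oid] = ASSOC_CB
        return out
    pred = _fit_predict(
        tr[cols].to_numpy(float),
        tr["training_class"].map(assoc_of).to_numpy(),
        sub.loc[rest, cols].to_numpy(float),
        config.supervised_algorithm,
        config.knn_k,
        seed,
    )
    out.update(dict(zip(rest, pred)))
    return out


def greenness_tiers(
    table: pd.DataFrame,
    ids_by_association: dict[str, list[int]],
) -> tuple[dict[int, str], list[str]]:
    """Three NDVI tiers per association by two-threshold Otsu.

    Returns a tier per object (``low`` / ``mid`` / ``high``) and the list of
    associations that were flagged as degenerate and passed through un-tiered
    (all their objects treated as mid).
    """
    sub = table.set_index("object_id")
    tiers: dict[int, str] = {}
    flagged: list[str] = []
    for assoc, ids in ids_by_association.items():
        ndvi = sub.loc[ids, "mean_ndvi"].to_numpy(float)
        if np.unique(ndvi).size < 3:
            flagged.append(assoc)
            for oid in ids:
                tiers[oid] = "mid"
            continue
        t1, t2 = otsu_thresholds(ndvi, n_classes=3)
        for oid, v in zip(ids, ndvi):
            tiers[oid] = "low" if v <= t1 else ("mid" if v <= t2 else "high")
    return tiers, flagged


def final_invasive_split(
    table: pd.DataFrame,
    member_ids: list[int],
    training: pd.DataFrame,
    config: HierarchyConfig,
    seed: int = 0,
) -> dict[int, str]:
    """Split the surviving fine objects into medusahead / goatgrass / other.

    Supervised on exactly the configured three features.  Without goatgrass
    training objects a binary medusahead / other fallback runs with a
    warning; in a goatgrass-free scene all invasives come out medusahead.
    """
    if not member_ids:
        return {}
    label_of = lambda c: c if c in (MEDUSAHEAD, GOATGRASS) else LABEL_OTHER
    tr = training.copy()
    tr["split_label"] = tr["training_class"].map(label_of)
    have = set(tr["split_label"])
    if MEDUSAHEAD not in have:
        warnings.warn("no medusahead training objects; final split labels all as other",
                      stacklevel=2)
        return {oid: LABEL_OTHER for oid in member_ids}
    if GOATGRASS not in have:
        warnings.warn(
            "no barbed goatgrass training objects; falling back to a binary "
            "medusahead/other split",
            stacklevel=2,
        )
        tr = tr[tr["split_label"].isin((MEDUSAHEAD, LABEL_OTHER))]
    if len(set(tr["split_label"])) == 1:
        only = next(iter(set(tr["split_label"])))
        return {oid: only for oid in member_ids}
    cols = list(config.final_split_features)
    sub = table.set_index("object_id")
    pred = _fit_predict(
        tr[cols].to_numpy(float),
        tr["split_label"].to_numpy(),
        sub.loc[member_ids, cols].to_numpy(float),
        config.supervised_algorithm,
        config.knn_k,
        seed,
    )
    return dict(zip(member_ids, pred))


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def _ids_of_parent(table: pd.DataFrame, parents: set[int]) -> list[int]:
    return table["object_id"][table["parent_id"].isin(list(parents))].tolist()


def storksbill_ids_from_mask(
    table: pd.DataFrame, level: SegmentationLevel, stack: BandStack, geometry
) -> set[int]:
    """Mid-scale objects whose pixel-majority lies inside the mask polygon."""
    H, W = stack.shape
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    x, y = stack.index_to_world(rr.ravel(), cc.ravel())
    inside = shapely.contains_xy(geometry, x, y).reshape(H, W)
    lab = level.label_raster
    sel = lab >= 0
    n_in = np.bincount(lab[sel], weights=inside[sel], minlength=level.n_objects)
    n_all = np.bincount(lab[sel], minlength=level.n_objects)
    frac = np.divide(n_in, n_all, out=np.zeros_like(n_in), where=n_all > 0)
    return set(np.flatnonzero(frac > 0.5).tolist())


def run_hierarchy(
    stack: BandStack,
    levels: list[SegmentationLevel],
    tables: list[pd.DataFrame],
    training_samples,
    config: HierarchyConfig | None = None,
    storksbill_mask=None,
    seed: int = 0,
) -> HierarchyResult:
    """Compose the five steps over a nested (coarse, mid, fine) segmentation.

    ``levels``/``tables`` are coarsest-first as returned by
    :func:`segmentation.segment_hierarchy` / :func:`objects.build_object_table`.
    Every fine object receives exactly one terminal label with provenance.
    """
    config = config or HierarchyConfig()
    if len(levels) != 3:
        raise ParameterError("hierarchy expects exactly three nested levels")
    lvl_coarse, lvl_mid, lvl_fine = levels
    tab_coarse, tab_mid, tab_fine = tables
    log: list[str] = []

    train_fine = attach_training(tab_fine, training_samples, lvl_fine, stack)
    mh_points = [s.location for s in training_samples if s.best_class == MEDUSAHEAD]

    excluded, candidates = coarse_exclude(tab_coarse, lvl_coarse, stack, mh_points, config)
    log.append(f"{STEP_EXCLUDE}: {len(excluded)} excluded, {len(candidates)} candidates")

    vetch, remaining = isolate_vetch_mosaic(tab_coarse, candidates, config)
    log.append(f"{STEP_VETCH}: {len(vetch)} mosaic objects isolated")

    if storksbill_mask is not None:
        stork_ids = storksbill_ids_from_mask(tab_mid, lvl_mid, stack, storksbill_mask)
    else:
        stork_ids = set()
        log.append(f"{STEP_ASSOC}: no storksbill mask provided; step skipped")
    mid_members = set(_ids_of_parent(tab_mid, remaining))
    assoc = classify_associations(
        tab_mid, mid_members, attach_training(tab_mid, training_samples, lvl_mid, stack),
        config, storksbill_ids=stork_ids & mid_members, seed=seed,
    )
    log.append(f"{STEP_ASSOC}: {len(mid_members)} mid-scale objects classed")

    ids_by_assoc: dict[str, list[int]] = {ASSOC_OAT: [], ASSOC_CB: []}
    fine_parent = tab_fine.set_index("object_id")["parent_id"]
    assoc_of_fine: dict[int, str] = {}
    for oid, parent in fine_parent.items():
        a = assoc.get(parent)
        if a in ids_by_assoc:
            ids_by_assoc[a].append(int(oid))
            assoc_of_fine[int(oid)] = a
    ids_by_assoc = {a: ids for a, ids in ids_by_assoc.items() if ids}
    tiers, flagged = greenness_tiers(tab_fine, ids_by_assoc)
    if flagged:
        log.append(f"{STEP_TIERS}: degenerate NDVI in {flagged}; passed through un-tiered")

    surviving = [oid for oid, t in tiers.items() if t in ("mid", "high")]
    split = final_invasive_split(tab_fine, surviving, train_fine, config, seed=seed)
    log.append(f"{STEP_FINAL}: {len(surviving)} objects split")

    # compose terminal labels on the fine level
    mid_parent = tab_mid.set_index("object_id")["parent_id"]
    rows = []
    for oid in tab_fine["object_id"]:
        oid = int(oid)
        parent_mid = fine_parent.loc[oid]
        parent_coarse = mid_parent.get(parent_mid)
        if parent_coarse in excluded:
            rows.append((oid, STEP_EXCLUDE, LABEL_EXCLUDED))
        elif parent_coarse in vetch:
            rows.append((oid, STEP_VETCH, LABEL_VETCH))
        elif assoc.get(parent_mid) == LABEL_CANARY:
            rows.append((oid, STEP_ASSOC, LABEL_CANARY))
        elif assoc.get(parent_mid) == LABEL_STORKSBILL:
            rows.append((oid, STEP_ASSOC, LABEL_STORKSBILL))
        elif tiers.get(oid) == "low":
            rows.append((oid, STEP_TIERS, LABEL_LOW_TIER))
        elif oid in split:
            rows.append((oid, STEP_FINAL, split[oid]))
        else:  # mid-scale object outside any association (should not happen)
            rows.append((oid, STEP_ASSOC, LABEL_OTHER))
    provenance = pd.DataFrame(rows, columns=["object_id", "step", "label"])
    assignments = pd.Series(
        provenance["label"].to_numpy(), index=provenance["object_id"].to_numpy()
    )
    result = build_result(
        f"hierarchical_{config.supervised_algorithm}",
        "hierarchical",
        "spectral_texture",
        assignments,
        lvl_fine,
        stack,
        metadata={"config": config, "seed": seed, "steps": log},
    )
    return HierarchyResult(result=result, provenance=provenance, step_log=log)
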