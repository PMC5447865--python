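"""Fuzzy thematic accuracy assessment against mixed-composition test plots.

Test plots in heterogeneous grassland rarely hold a single vegetation type,
so each reference sample carries a "best" class (maximal cover) and possibly
"acceptable" classes (>= 5 % cover).  Samples are evaluated as
1 m x 1 m squares centred on the surveyed point:

* **MAX** — of the test samples classified as the target, the proportion
  whose best reference class is the target (a fuzzy user's accuracy, i.e.
  commission);
* **RIGHT** — the proportion whose best *or* acceptable classes include the
  target; ``diff = RIGHT - MAX`` measures how much apparent commission error
  is really sub-dominant presence;
* **producer's accuracy** — of the samples whose best class is the target,
  the proportion whose square contains at least one classified-target pixel
  (omission).

"Classified as target" for MAX/RIGHT uses the class at the sample's centre
pixel; producer's accuracy uses any pixel in the square, matching the
asymmetry of the two questions (what did we call this spot? / did we find
this known spot at all?).  Both supports are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassificationResult
from .errors import SchemeError
from .scene import MEDUSAHEAD


@dataclass
class FuzzyAccuracyReport:
    method_id: str
    max_metric: float  # NaN when no sample classified as target
    right_metric: float
    diff: float  # right - max
    producer: float
    n_predicted_target: int
    n_reference_target: int
    target: str = MEDUSAHEAD
    audit: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def __post_init__(self) -> None:
        # structural guarantees of the counting rule, asserted on every report
        if np.isfinite(self.max_metric) and np.isfinite(self.right_metric):
            assert self.right_metric >= self.max_metric - 1e-12, "RIGHT < MAX"
            assert abs(self.diff - (self.right_metric - self.max_metric)) < 1e-12
        for m in (self.max_metric, self.right_metric, self.producer):
            assert np.isnan(m) or 0.0 <= m <= 1.0


def _square_has_target(result: ClassificationResult, x, y, half_m, target) -> bool:
    stack = result.stack
    r0, c0 = stack.world_to_index(x - half_m, y + half_m)
    r1, c1 = stack.world_to_index(x + half_m, y - half_m)
    H, W = result.class_index_raster.shape
    r0, r1 = max(0, min(r0, r1)), min(H - 1, max(r0, r1))
    c0, c1 = max(0, min(c0, c1)), min(W - 1, max(c0, c1))
    if r0 > r1 or c0 > c1:
        return False
    if target not in result.classes:
        return False
    code = result.classes.index(target)
    return bool((result.class_index_raster[r0 : r1 + 1, c0 : c1 + 1] == code).any())


def evaluate_fuzzy(
    result: ClassificationResult,
    test_samples,
    square_size_m: float = 1.0,
    target: str = MEDUSAHEAD,
    predicted_support: str = "center",
) -> FuzzyAccuracyReport:
    """Fuzzy accuracy of one classification against the test samples.

    When no test sample is classified as the target, MAX and RIGHT are
    undefined and reported as NaN with ``n_predicted_target = 0`` — absence
    of prediction is distinguished from failure.
    """
    half = square_size_m / 2
    rows = []
    for i, s in enumerate(test_samples):
        x, y = s.location
        if predicted_support == "center":
            predicted = result.class_at(x, y) == target
        elif predicted_support == "square":
            predicted = _square_has_target(result, x, y, half, target)
        else:
            raise SchemeError(f"unknown predicted_support {predicted_support!r}")
        best_is_target = s.best_class == target
        target_ok = best_is_target or target in s.acceptable_classes
        square_hit = _square_has_target(result, x, y, half, target)
        rows.append(
            {
                "sample": i,
                "best_class": s.best_class,
                "acceptable": ",".join(s.acceptable_classes),
                "classified_as_target": predicted,
                "best_is_target": best_is_target,
                "target_acceptable_or_best": target_ok,
                "square_contains_target": square_hit,
            }
        )
    audit = pd.DataFrame(rows)
    pred = audit[audit["classified_as_target"]]
    n_pred = len(pred)
    if n_pred == 0:
        mx = right = diff = float("nan")
    else:
        mx = pred["best_is_target"].mean()
        right = pred["target_acceptable_or_best"].mean()
        diff = right - mx
    ref = audit[audit["best_is_target"]]
    n_ref = len(ref)
    producer = ref["square_contains_target"].mean() if n_ref else float("nan")
    return FuzzyAccuracyReport(
        method_id=result.method_id,
        max_metric=float(mx),
        right_metric=float(right),
        diff=float(diff),
        producer=float(producer),
        n_predicted_target=n_pred,
        n_reference_target=n_ref,
        target=target,
        audit=audit,
    )


@dataclass
class _MergedSample:
    location: tuple[float, float]
    best_class: str
    acceptable_classes: tuple[str, ...]


def evaluate_combined(
    result: ClassificationResult,
    test_samples,
    merge: tuple[str, ...] = (MEDUSAHEAD, "barbed_goatgrass"),
    square_size_m: float = 1.0,
    **kwargs,
) -> FuzzyAccuracyReport:
    """Accuracy after merging two mutually confused classes.

    Both classes are relabelled to one merged class in the predictions and in
    the reference (best and acceptable), then the fuzzy evaluation is re-run
    with the merged class as target.  Merging a class with itself leaves the
    report unchanged.
    """
    merge = tuple(dict.fromkeys(merge))  # dedupe, keep order
    if result.scheme_name == "three_class" and len(merge) > 1:
        raise SchemeError(f"merge classes {merge} absent from scheme {result.scheme_name!r}")
    target = "+".join(merge)
    mapping = {c: target for c in merge}
    merged_result = result.relabeled(mapping, method_suffix="_combined")
    merged_samples = [
        _MergedSample(
            location=s.location,
            best_class=mapping.get(s.best_class, s.best_class),
            acceptable_classes=tuple(
                dict.fromkeys(mapping.get(a, a) for a in s.acceptable_classes)
            ),
        )
        for s in test_samples
    ]
    # acceptable never repeats the best class after merging
    merged_samples = [
        _MergedSample(
            s.location,
            s.best_class,
            tuple(a for a in s.acceptable_classes if a != s.best_class),
        )
        for s in merged_samples
    ]
    report = evaluate_fuzzy(
        merged_result, merged_samples, square_size_m=square_size_m, target=target, **kwargs
    )
    report.method_id = result.method_id + "_combined"
    return report


def tabulate_methods(reports: list[FuzzyAccuracyReport]) -> tuple[pd.DataFrame, dict]:
    """Comparison grid over methods plus min/max ranges of each metric."""
    rows = [
        {
            "method": r.method_id,
            "MAX": r.max_metric,
            "RIGHT": r.right_metric,
            "diff": r.diff,
            "producer": r.producer,
            "n_predicted": r.n_predicted_target,
        }
        for r in reports
    ]
    table = pd.DataFrame(rows)
    ranges = {}
    if len(table):
        for col in ("MAX", "RIGHT", "diff", "producer"):
            vals = table[col].dropna()
            if len(vals):
                ranges[col] = (float(vals.min()), float(vals.max()))
    return table, ranges
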