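"""Patch-level validation along transects, by segment-length category.

Classified medusahead extents are compared with the field patch segments in
two complementary ways: intersecting the classified runs with the *field
segments* probes under-prediction (did we recover what the surveyors saw?),
while intersecting them with the *full transect lines* probes over-prediction
(what else did we call medusahead along the walked lines?).  Both are
summarized per segment-length category — <= 0.5 m, (0.5, 2], (2, 7] and
> 7 m, closed on the upper bound — as counts and mean lengths, with paired
differences against the field statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassificationResult
from .scene import MEDUSAHEAD
from .survey import PATCH_GAP_M, FieldSegment, Transect, runs_along_line

#: Category upper bounds (m); lengths equal to a bound fall in that category.
CATEGORY_BOUNDS = (0.5, 2.0, 7.0)
CATEGORY_LABELS = ("<=0.5", "0.5-2", "2-7", ">7")


def length_category(length_m: float) -> str:
    for bound, label in zip(CATEGORY_BOUNDS, CATEGORY_LABELS):
        if length_m <= bound:
            return label
    return CATEGORY_LABELS[-1]


@dataclass
class LengthCategoryStats:
    mode: str  # vs_field_segments | vs_full_transects
    table: pd.DataFrame  # category, count, mean_length_m, field_count, field_mean_length_m
    intervals: list[tuple[int, float, float]] = field(default_factory=list)

    def count(self, category: str) -> int:
        row = self.table[self.table["category"] == category]
        return int(row["count"].iloc[0]) if len(row) else 0

    def mean_length(self, category: str) -> float:
        row = self.table[self.table["category"] == category]
        return float(row["mean_length_m"].iloc[0]) if len(row) else float("nan")


def _categorize(lengths: list[float]) -> pd.DataFrame:
    rows = []
    lengths = np.asarray(lengths, float)
    cats = [length_category(v) for v in lengths]
    for label in CATEGORY_LABELS:
        sel = lengths[[c == label for c in cats]]
        rows.append(
            {
                "category": label,
                "count": int(sel.size),
                "mean_length_m": float(sel.mean()) if sel.size else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def field_segment_stats(segments: list[FieldSegment]) -> pd.DataFrame:
    return _categorize([s.length_m for s in segments])


def classified_runs_along(
    result: ClassificationResult,
    transect: Transect,
    merge_gap_m: float = PATCH_GAP_M,
    target: str = MEDUSAHEAD,
) -> list[tuple[float, float]]:
    """Maximal classified-target runs along one transect.

    The class raster is sampled at half-pixel steps along the polyline; runs
    separated by gaps <= ``merge_gap_m`` are merged, reusing the field 20 cm
    patch-separation convention for comparability.
    """
    if target not in result.classes:
        return []
    code = result.classes.index(target)
    px = result.stack.pixel_size_m
    H = result.class_index_raster.shape[0]
    return runs_along_line(
        result.class_index_raster,
        code,
        transect.line,
        px,
        H * px,
        origin=result.stack.origin,
        merge_gap_m=merge_gap_m,
    )


def _attach_field(table: pd.DataFrame, field_stats: pd.DataFrame) -> pd.DataFrame:
    out = table.merge(
        field_stats.rename(
            columns={"count": "field_count", "mean_length_m": "field_mean_length_m"}
        ),
        on="category",
    )
    out["count_diff"] = out["count"] - out["field_count"]
    out["mean_length_diff_m"] = out["mean_length_m"] - out["field_mean_length_m"]
    return out


def intersect_with_segments(
    runs_by_transect: dict[int, list[tuple[float, float]]],
    segments: list[FieldSegment],
) -> LengthCategoryStats:
    """Intersect classified runs with the field segments (under-prediction).

    Each resulting piece is categorized by its *own* length; counts and mean
    lengths per category are reported against the field-segment statistics.
    """
    pieces: list[tuple[int, float, float]] = []
    for seg in segments:
        for s, e in runs_by_transect.get(seg.transect_id, []):
            lo, hi = max(s, seg.start_m), min(e, seg.end_m)
            if hi > lo:
                pieces.append((seg.transect_id, lo, hi))
    table = _attach_field(
        _categorize([hi - lo for _, lo, hi in pieces]), field_segment_stats(segments)
    )
    return LengthCategoryStats(mode="vs_field_segments", table=table, intervals=pieces)


def intersect_with_transects(
    runs_by_transect: dict[int, list[tuple[float, float]]],
    transects: list[Transect],
    segments: list[FieldSegment],
) -> LengthCategoryStats:
    """Categorize classified runs along the full transects (over-prediction)."""
    ids = {t.id for t in transects}
    pieces = [
        (tid, s, e)
        for tid, runs in runs_by_transect.items()
        if tid in ids
        for s, e in runs
    ]
    table = _attach_field(
        _categorize([e - s for _, s, e in pieces]), field_segment_stats(segments)
    )
    return LengthCategoryStats(mode="vs_full_transects", table=table, intervals=pieces)


def transect_validation(
    result: ClassificationResult,
    transects: list[Transect],
    segments: list[FieldSegment],
    merge_gap_m: float = PATCH_GAP_M,
) -> tuple[LengthCategoryStats, LengthCategoryStats]:
    """Both metric sets for one classification result."""
    runs = {t.id: classified_runs_along(result, t, merge_gap_m=merge_gap_m) for t in transects}
    return (
        intersect_with_segments(runs, segments),
        intersect_with_transects(runs, transects, segments),
    )
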