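"""Simulated field survey: transects, patch segments and reference samples.

The survey design mirrors a comprehensive grassland protocol: 20 transects
laid out as five groups of three, one group of four and one single transect,
each with ten 50 cm x 50 cm plots at 10 m intervals.  Where a transect
crosses medusahead, the start/end of the crossing is recorded; crossings
separated by gaps of more than 20 cm count as separate patches.  Plot
locations carry GPS noise of at most 0.3 m.

Reference samples record the plot's cover composition: the best (maximal
cover) class plus any other class at >= 5 % cover as "acceptable" — the rule
fuzzy accuracy assessment is built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point

from .errors import GeometryError, SamplingError
from .scene import CLASS_NAMES, MEDUSAHEAD, SceneTruth

#: Training design: per-class sample counts (total 300).
DEFAULT_TRAINING_COUNTS = {
    "medusahead": 50,
    "ryegrass_brome": 50,
    "vetch": 50,
    "clover_brome": 50,
    "wild_oat": 40,
    "barbed_goatgrass": 30,
    "canarygrass": 30,
}

#: Test design: (best-medusahead, non-medusahead, non-medusahead-with-
#: medusahead-acceptable) stratum sizes (total 150).
DEFAULT_TEST_STRATA = (50, 50, 50)

ACCEPTABLE_COVER = 0.05
PATCH_GAP_M = 0.2


@dataclass
class Transect:
    id: int
    line: LineString
    plot_points: list[tuple[float, float]]
    group_id: int

    @property
    def length_m(self) -> float:
        return self.line.length


@dataclass
class FieldSegment:
    transect_id: int
    start_m: float
    end_m: float

    @property
    def length_m(self) -> float:
        return self.end_m - self.start_m


@dataclass
class ReferenceSample:
    location: tuple[float, float]
    best_class: str
    acceptable_classes: tuple[str, ...]
    cover_fractions: dict[str, float]
    positional_noise_applied: float
    role: str | None = None  # training | test
    source: str = "plot"  # plot | walkabout
    transect_id: int | None = None


@dataclass
class SurveyLayout:
    group_sizes: tuple[int, ...] = (3, 3, 3, 3, 3, 4, 1)
    n_plots: int = 10
    plot_spacing_m: float = 10.0
    transect_spacing_m: float = 12.0
    gps_noise_m: float = 0.3
    plot_window_m: float = 0.5
    margin_m: float = 1.0

    @property
    def n_transects(self) -> int:
        return sum(self.group_sizes)

    @property
    def transect_length_m(self) -> float:
        return (self.n_plots - 1) * self.plot_spacing_m


def _window_cover(truth: SceneTruth, x: float, y: float, window_m: float) -> dict[str, float]:
    """Mean cover fractions in a square window centred on (x, y)."""
    px = truth.pixel_size_m
    half = window_m / 2
    r0, c0 = truth.world_to_index(x - half, y + half)
    r1, c1 = truth.world_to_index(x + half, y - half)
    H, W = truth.dominant_label.shape
    r0, r1 = max(0, min(r0, r1)), min(H, max(r0, r1) + 1)
    c0, c1 = max(0, min(c0, c1)), min(W, max(c0, c1) + 1)
    block = truth.cover_fractions[:, r0:r1, c0:c1]
    means = block.mean(axis=(1, 2))
    return {name: float(m) for name, m in zip(truth.class_names, means)}


def _make_sample(truth, x, y, rng, noise_m, window_m, source, transect_id=None):
    cover = _window_cover(truth, x, y, window_m)
    best = max(cover, key=lambda c: (cover[c], -CLASS_NAMES.index(c)))
    acceptable = tuple(
        c for c in truth.class_names if c != best and cover[c] >= ACCEPTABLE_COVER
    )
    # isotropic jitter uniform within the GPS error radius, clamped so the
    # recorded location stays inside the surveyed site
    r = noise_m * np.sqrt(rng.random())
    th = rng.uniform(0, 2 * np.pi)
    px = truth.pixel_size_m
    w_m, h_m = truth.extent_m
    jx = float(np.clip(x + r * np.cos(th), px / 2, w_m - px / 2))
    jy = float(np.clip(y + r * np.sin(th), px / 2, h_m - px / 2))
    return ReferenceSample(
        location=(jx, jy),
        best_class=best,
        acceptable_classes=acceptable,
        cover_fractions=cover,
        positional_noise_applied=float(r),
        source=source,
        transect_id=transect_id,
    )


def _merge_runs(intervals: list[tuple[float, float]], gap_m: float) -> list[tuple[float, float]]:
    """Merge intervals separated by gaps <= gap_m (patches are separate only
    when the gap *exceeds* it)."""
    if not intervals:
        return []
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s - merged[-1][1] <= gap_m:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def runs_along_line(
    label_raster: np.ndarray,
    target_value: int,
    line: LineString,
    pixel_size_m: float,
    height_m: float,
    origin=(0.0, 0.0),
    merge_gap_m: float = PATCH_GAP_M,
    step_m: float | None = None,
) -> list[tuple[float, float]]:
    """Maximal target-class runs (start, end distances) along a polyline.

    Samples the raster at ``step_m`` (default: half a pixel) along the line,
    extracts maximal runs of the target value and merges runs separated by
    gaps <= ``merge_gap_m``.
    """
    if step_m is None:
        step_m = pixel_size_m / 2
    n = max(2, int(np.ceil(line.length / step_m)) + 1)
    d = np.linspace(0.0, line.length, n)
    pts = [line.interpolate(t) for t in d]
    x = np.array([p.x for p in pts])
    y = np.array([p.y for p in pts])
    H, W = label_raster.shape
    col = np.floor((x - origin[0]) / pixel_size_m).astype(int)
    row = np.floor((origin[1] + height_m - y) / pixel_size_m).astype(int)
    if (row < 0).any() or (row >= H).any() or (col < 0).any() or (col >= W).any():
        raise GeometryError("line exits the raster extent")
    hit = label_raster[row, col] == target_value
    if not hit.any():
        return []
    edges = np.flatnonzero(np.diff(hit.astype(np.int8)))
    starts = [0] if hit[0] else []
    ends = []
    for e in edges:
        if hit[e]:  # 1 -> 0 transition after index e
            ends.append(e)
        else:
            starts.append(e + 1)
    if hit[-1]:
        ends.append(len(hit) - 1)
    # extend to the half-step cell boundaries: run extent is the support of
    # the hit samples, not the span between their centres (a centre-to-centre
    # estimate biases every gap upward by one step)
    step = d[1] - d[0]
    intervals = [
        (max(0.0, d[s] - step / 2), min(line.length, d[e] + step / 2))
        for s, e in zip(starts, ends)
    ]
    return _merge_runs(intervals, merge_gap_m)


def _place_group(rng, layout, extent, n_lines, max_tries=2000):
    """Random heading + base point such that all parallel transects fit.

    The heading is drawn uniformly; given the heading, the feasible box for
    the group's base point is computed exactly (the corner offsets of every
    transect are linear in it) and the base point drawn uniformly inside.
    Headings whose feasible box is empty are resampled.
    """
    L = layout.transect_length_m
    S = layout.transect_spacing_m
    w, h = extent
    m = layout.margin_m
    for _ in range(max_tries):
        theta = rng.uniform(0, 2 * np.pi)
        dx, dy = np.cos(theta), np.sin(theta)
        ox, oy = -dy, dx  # perpendicular offset direction
        tx = [i * S * ox + j * dx for i in range(n_lines) for j in (0.0, L)]
        ty = [i * S * oy + j * dy for i in range(n_lines) for j in (0.0, L)]
        x_lo, x_hi = m - min(tx), (w - m) - max(tx)
        y_lo, y_hi = m - min(ty), (h - m) - max(ty)
        if x_lo > x_hi or y_lo > y_hi:
            continue
        x0 = rng.uniform(x_lo, x_hi)
        y0 = rng.uniform(y_lo, y_hi)
        return [
            LineString(
                [
                    (x0 + i * S * ox, y0 + i * S * oy),
                    (x0 + i * S * ox + L * dx, y0 + i * S * oy + L * dy),
                ]
            )
            for i in range(n_lines)
        ]
    raise GeometryError(
        f"cannot place a group of {n_lines} transects of {L:.0f} m inside extent {extent}"
    )


def simulate_field_survey(
    truth: SceneTruth,
    layout: SurveyLayout | None = None,
    seed: int = 0,
) -> tuple[list[Transect], list[FieldSegment], list[ReferenceSample]]:
    """Lay out the transect survey on the truth raster.

    Returns the transects, the medusahead patch segments crossed by each
    transect (gaps <= 20 cm merged), and the plot reference samples with
    cover fractions read from a 50 cm window and GPS jitter applied.
    """
    layout = layout or SurveyLayout()
    rng = np.random.default_rng(seed)
    extent = truth.extent_m
    mh = truth.class_index(MEDUSAHEAD)
    H = truth.dominant_label.shape[0]
    height_m = H * truth.pixel_size_m

    transects: list[Transect] = []
    tid = 0
    for gid, size in enumerate(layout.group_sizes):
        for line in _place_group(rng, layout, extent, size):
            pts = [
                (p.x, p.y)
                for p in (
                    line.interpolate(i * layout.plot_spacing_m) for i in range(layout.n_plots)
                )
            ]
            transects.append(Transect(id=tid, line=line, plot_points=pts, group_id=gid))
            tid += 1

    segments: list[FieldSegment] = []
    for t in transects:
        for s, e in runs_along_line(
            truth.dominant_label, mh, t.line, truth.pixel_size_m, height_m, truth.origin
        ):
            segments.append(FieldSegment(transect_id=t.id, start_m=s, end_m=e))

    samples: list[ReferenceSample] = []
    for t in transects:
        for x, y in t.plot_points:
            samples.append(
                _make_sample(
                    truth,
                    x,
                    y,
                    rng,
                    layout.gps_noise_m,
                    layout.plot_window_m,
                    "plot",
                    transect_id=t.id,
                )
            )
    return transects, segments, samples


def _is_representative(truth: SceneTruth, sample: ReferenceSample, x: float, y: float) -> bool:
    """A plot is representative when the dominant class at its (true) centre
    agrees with the windowed best class — surveyors centre reference plots
    inside a stand rather than across its boundary."""
    r, c = truth.world_to_index(x, y)
    H, W = truth.dominant_label.shape
    if not (0 <= r < H and 0 <= c < W):
        return False
    centre = truth.class_names[truth.dominant_label[r, c]]
    return centre == sample.best_class


def survey_reference_candidates(
    truth: SceneTruth,
    n_random: int = 2000,
    per_patch: int = 2,
    seed: int = 0,
    gps_noise_m: float = 0.3,
    window_m: float = 0.5,
    representative: bool = True,
) -> list[ReferenceSample]:
    """Off-transect reference candidates ("walkabout" surveys).

    Draws ``n_random`` uniform points plus ``per_patch`` points inside each
    ground-truth patch (surveyors deliberately visit known examples of every
    type), each recorded with windowed cover fractions and GPS jitter.  With
    ``representative=True`` (default) candidate plots that straddle a stand
    boundary — centre-pixel dominant class differing from the windowed best
    class — are discarded, emulating deliberate plot placement.
    """
    rng = np.random.default_rng(seed)
    w, h = truth.extent_m
    out: list[ReferenceSample] = []
    for _ in range(n_random):
        x, y = rng.uniform(0, w), rng.uniform(0, h)
        s = _make_sample(truth, x, y, rng, gps_noise_m, window_m, "walkabout")
        if not representative or _is_representative(truth, s, x, y):
            out.append(s)
    for patch in truth.patch_polygons:
        minx, miny, maxx, maxy = patch.polygon.bounds
        got = 0
        for _ in range(20 * per_patch):
            if got >= per_patch:
                break
            x, y = rng.uniform(minx, maxx), rng.uniform(miny, maxy)
            if 0 <= x < w and 0 <= y < h and patch.polygon.contains(Point(x, y)):
                s = _make_sample(truth, x, y, rng, gps_noise_m, window_m, "walkabout")
                if not representative or _is_representative(truth, s, x, y):
                    out.append(s)
                    got += 1
    return out


def designate_sample_sets(
    samples: list[ReferenceSample],
    training_counts: dict[str, int] | None = None,
    test_strata: tuple[int, int, int] = DEFAULT_TEST_STRATA,
    seed: int = 0,
) -> tuple[list[ReferenceSample], list[ReferenceSample]]:
    """Split candidate samples into disjoint training and test sets.

    Training samples are the highest-cover examples of each class, at the
    per-class counts of the survey design (default 50/50/50/50/40/30/30,
    total 300).  The test set is stratified into best-medusahead,
    non-medusahead, and non-medusahead-with-medusahead-acceptable strata
    (default 50 each, total 150), drawn from the remaining candidates.

    Raises
    ------
    SamplingError
        Naming the deficient class or stratum when candidates run short.
    """
    training_counts = dict(training_counts or DEFAULT_TRAINING_COUNTS)
    rng = np.random.default_rng(seed)
    training: list[ReferenceSample] = []
    used = set()
    for cls, count in training_counts.items():
        cands = [
            (i, s)
            for i, s in enumerate(samples)
            if i not in used and s.best_class == cls
        ]
        cands.sort(key=lambda t: (-t[1].cover_fractions.get(cls, 0.0), t[0]))
        if len(cands) < count:
            raise SamplingError(
                f"only {len(cands)} candidates with best class {cls!r}, need {count}",
                deficient_class=cls,
            )
        for i, s in cands[:count]:
            s.role = "training"
            training.append(s)
            used.add(i)

    def stratum(pred):
        return [i for i, s in enumerate(samples) if i not in used and pred(s)]

    strata_defs = [
        ("medusahead-best", lambda s: s.best_class == MEDUSAHEAD),
        (
            "non-medusahead",
            lambda s: s.best_class != MEDUSAHEAD and MEDUSAHEAD not in s.acceptable_classes,
        ),
        (
            "non-medusahead-with-medusahead-acceptable",
            lambda s: s.best_class != MEDUSAHEAD and MEDUSAHEAD in s.acceptable_classes,
        ),
    ]
    test: list[ReferenceSample] = []
    for (name, pred), count in zip(strata_defs, test_strata):
        idxs = stratum(pred)
        if len(idxs) < count:
            raise SamplingError(
                f"only {len(idxs)} candidates in test stratum {name!r}, need {count}",
                deficient_class=name,
            )
        pick = rng.choice(len(idxs), size=count, replace=False)
        for j in sorted(pick):
            i = idxs[j]
            samples[i].role = "test"
            test.append(samples[i])
            used.add(i)
    return training, test
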