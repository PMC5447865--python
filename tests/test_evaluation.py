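"""Fuzzy accuracy metrics: counting rules, combined classes, tabulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medusahead_obia.classify import build_result
from medusahead_obia.errors import SchemeError
from medusahead_obia.evaluation import (
    evaluate_combined,
    evaluate_fuzzy,
    tabulate_methods,
)
from medusahead_obia.scene import MEDUSAHEAD
from medusahead_obia.segmentation import SegmentationLevel
from medusahead_obia.stack import BandStack
from medusahead_obia.survey import ReferenceSample


def _result_from_classes(class_grid, pixel=1.0, scheme="seven_class"):
    """A ClassificationResult from a small 2-D grid of class-name strings."""
    grid = np.asarray(class_grid, dtype=object)
    names = sorted({c for c in grid.ravel()})
    lab = np.empty(grid.shape, dtype=np.int32)
    assignments = {}
    for i, _ in enumerate(grid.ravel()):
        lab.ravel()[i] = i
        assignments[i] = grid.ravel()[i]
    level = SegmentationLevel(
        label_raster=lab, scale=1.0, shape_weight=0.0, compactness_weight=0.0,
        layer_weights={}, n_objects=lab.size,
    )
    z = np.zeros(grid.shape)
    stack = BandStack(
        layers={"blue": z, "green": z, "red": z, "nir": z}, pixel_size_m=pixel
    )
    return build_result("fixture", scheme, "spectral", pd.Series(assignments), level, stack)


def _sample(x, y, best, acceptable=()):
    return ReferenceSample((x, y), best, tuple(acceptable), {best: 1.0}, 0.0)


MH = MEDUSAHEAD
CB = "clover_brome"
VE = "vetch"


class TestEvaluateFuzzy:
    def test_perfect_classification_all_ones(self):
        res = _result_from_classes([[MH, MH], [MH, MH]])
        samples = [_sample(0.5, 0.5, MH), _sample(1.5, 1.5, MH)]
        rep = evaluate_fuzzy(res, samples)
        assert rep.max_metric == rep.right_metric == rep.producer == 1.0
        assert rep.diff == 0.0

    def test_three_sample_hand_count(self):
        """Predicted-target samples with bests {target, vetch, clover}, only
        the vetch one listing the target acceptable: MAX 1/3, RIGHT 2/3."""
        res = _result_from_classes([[MH, MH, MH]])
        samples = [
            _sample(0.5, 0.5, MH),
            _sample(1.5, 0.5, VE, acceptable=(MH,)),
            _sample(2.5, 0.5, CB),
        ]
        rep = evaluate_fuzzy(res, samples)
        assert rep.max_metric == pytest.approx(1 / 3)
        assert rep.right_metric == pytest.approx(2 / 3)
        assert rep.diff == pytest.approx(1 / 3)
        assert rep.n_predicted_target == 3

    def test_printed_row_arithmetic(self):
        """MAX 0.23 with RIGHT 0.67 gives a fuzzy-composition gain of 0.44 —
        the largest gap in the published method comparison."""
        assert 0.67 - 0.23 == pytest.approx(0.44)

    def test_no_predicted_target_reports_nan_with_zero_count(self):
        res = _result_from_classes([[CB, CB], [CB, CB]])
        rep = evaluate_fuzzy(res, [_sample(0.5, 0.5, MH)])
        assert np.isnan(rep.max_metric) and np.isnan(rep.right_metric)
        assert rep.n_predicted_target == 0
        assert rep.producer == 0.0  # best-mh sample present but missed

    def test_producer_uses_square_support(self):
        # centre pixel is clover, but the 1 m square clips a medusahead pixel
        res = _result_from_classes([[CB, MH], [CB, CB]], pixel=0.6)
        s = _sample(0.55, 0.55, MH)  # centre in the clover pixel
        rep = evaluate_fuzzy(res, [s], square_size_m=1.0)
        assert rep.producer == 1.0
        assert rep.n_predicted_target == 0  # centre-pixel rule for MAX/RIGHT

    def test_order_invariance(self):
        res = _result_from_classes([[MH, CB, MH, CB]])
        samples = [
            _sample(0.5, 0.5, MH),
            _sample(1.5, 0.5, CB),
            _sample(2.5, 0.5, VE, acceptable=(MH,)),
            _sample(3.5, 0.5, CB, acceptable=(VE,)),
        ]
        a = evaluate_fuzzy(res, samples)
        b = evaluate_fuzzy(res, samples[::-1])
        assert (a.max_metric, a.right_metric, a.producer) == (
            b.max_metric, b.right_metric, b.producer,
        )

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans()),
                    min_size=1, max_size=12))
    def test_right_never_below_max(self, flags):
        """For any sample composition the acceptable-inclusive count dominates
        the best-only count."""
        grid = [[MH] * len(flags)]
        res = _result_from_classes(grid)
        samples = []
        for i, (best_is_mh, accept_mh, _) in enumerate(flags):
            if best_is_mh:
                samples.append(_sample(i + 0.5, 0.5, MH))
            else:
                samples.append(
                    _sample(i + 0.5, 0.5, CB, acceptable=(MH,) if accept_mh else ())
                )
        rep = evaluate_fuzzy(res, samples)
        assert rep.right_metric >= rep.max_metric
        assert rep.diff == pytest.approx(rep.right_metric - rep.max_metric)

    def test_adding_correct_prediction_never_decreases_metrics(self):
        res = _result_from_classes([[MH, MH, CB]])
        base = [_sample(0.5, 0.5, MH), _sample(2.5, 0.5, CB)]
        rep0 = evaluate_fuzzy(res, base)
        rep1 = evaluate_fuzzy(res, base + [_sample(1.5, 0.5, MH)])
        assert rep1.max_metric >= rep0.max_metric
        assert rep1.right_metric >= rep0.right_metric


class TestEvaluateCombined:
    GG = "barbed_goatgrass"

    def test_confusion_fixture_combined_dominates_separate(self):
        """All medusahead truth predicted goatgrass: merging the two invasives
        recovers the confusions, so combined MAX/producer exceed separate."""
        res = _result_from_classes([[self.GG, self.GG, CB, MH]])
        samples = [
            _sample(0.5, 0.5, MH),
            _sample(1.5, 0.5, MH),
            _sample(2.5, 0.5, CB),
            _sample(3.5, 0.5, self.GG, acceptable=(MH,)),
        ]
        sep = evaluate_fuzzy(res, samples)
        comb = evaluate_combined(res, samples)
        assert comb.producer >= sep.producer
        assert comb.max_metric >= sep.max_metric

    def test_merge_with_itself_is_identity(self):
        res = _result_from_classes([[MH, CB, MH]])
        samples = [_sample(0.5, 0.5, MH), _sample(1.5, 0.5, CB, acceptable=(MH,))]
        sep = evaluate_fuzzy(res, samples)
        comb = evaluate_combined(res, samples, merge=(MH, MH))
        assert comb.max_metric == sep.max_metric
        assert comb.right_metric == sep.right_metric
        assert comb.producer == sep.producer

    def test_disjoint_confusions_unchanged(self):
        """Confusions only with non-merged classes leave the metrics equal."""
        res = _result_from_classes([[MH, VE, CB]])
        samples = [
            _sample(0.5, 0.5, MH),
            _sample(1.5, 0.5, VE),
            _sample(2.5, 0.5, CB),
        ]
        sep = evaluate_fuzzy(res, samples)
        comb = evaluate_combined(res, samples)
        assert comb.max_metric == sep.max_metric
        assert comb.producer == sep.producer

    def test_three_class_scheme_rejects_merge(self):
        res = _result_from_classes([[MH]], scheme="three_class")
        with pytest.raises(SchemeError):
            evaluate_combined(res, [_sample(0.5, 0.5, MH)])


class TestTabulateMethods:
    def test_diff_ranges(self):
        res = _result_from_classes([[MH]])
        reports = []
        for d, (mx, rt) in enumerate([(0.36, 0.62), (0.40, 0.73), (0.23, 0.67)]):
            r = evaluate_fuzzy(res, [_sample(0.5, 0.5, MH)])
            r.max_metric, r.right_metric = mx, rt
            r.diff = rt - mx
            r.method_id = f"m{d}"
            reports.append(r)
        table, ranges = tabulate_methods(reports)
        assert len(table) == 3
        assert ranges["diff"] == (pytest.approx(0.26), pytest.approx(0.44))

    def test_single_report_collapses_range(self):
        res = _result_from_classes([[MH]])
        rep = evaluate_fuzzy(res, [_sample(0.5, 0.5, MH)])
        _, ranges = tabulate_methods([rep])
        assert ranges["MAX"] == (1.0, 1.0)

    def test_empty_list_gives_empty_table(self):
        table, ranges = tabulate_methods([])
        assert len(table) == 0 and ranges == {}
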