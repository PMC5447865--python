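"""NDVI, local Moran's I and multi-level Otsu thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medusahead_obia.errors import BandError, DegenerateInputError, ParameterError
from medusahead_obia.features import local_morans_i, ndvi, otsu_thresholds
from medusahead_obia.stack import BandStack


def _stack(nir, red):
    z = np.zeros_like(np.asarray(nir, float))
    return BandStack(
        layers={"blue": z, "green": z, "red": np.asarray(red, float), "nir": np.asarray(nir, float)}
    )


class TestNdvi:
    def test_equal_bands_give_zero(self):
        s = _stack(np.full((4, 4), 0.3), np.full((4, 4), 0.3))
        assert np.allclose(ndvi(s), 0.0)

    def test_hand_value(self):
        s = _stack([[0.6]], [[0.2]])
        assert ndvi(s)[0, 0] == pytest.approx(0.5)

    def test_zero_sum_is_nodata(self):
        s = _stack([[0.0, 0.6]], [[0.0, 0.2]])
        out = ndvi(s)
        assert np.isnan(out[0, 0]) and s.nodata_masks["ndvi"][0, 0]
        assert out[0, 1] == pytest.approx(0.5)

    def test_antisymmetric_under_band_swap(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0.05, 1, (2, 8, 8))
        assert np.allclose(ndvi(_stack(a, b)), -ndvi(_stack(b, a)))

    def test_bounded(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 1, (2, 16, 16))
        out = ndvi(_stack(a, b))
        ok = ~np.isnan(out)
        assert (out[ok] >= -1).all() and (out[ok] <= 1).all()

    def test_missing_band_errors(self):
        s = BandStack(layers={"nir": np.ones((2, 2))})
        with pytest.raises(BandError):
            ndvi(s)


def _morans_naive(x, window=3, row_standardized=False):
    """Double-loop reference implementation of the local statistic."""
    x = np.asarray(x, float)
    xbar, s2 = x.mean(), x.var()
    h = window // 2
    out = np.zeros_like(x)
    H, W = x.shape
    for i in range(H):
        for j in range(W):
            acc, cnt = 0.0, 0
            for di in range(-h, h + 1):
                for dj in range(-h, h + 1):
                    if di == 0 and dj == 0:
                        continue
                    if 0 <= i + di < H and 0 <= j + dj < W:
                        acc += x[i + di, j + dj] - xbar
                        cnt += 1
            if row_standardized:
                acc /= cnt
            out[i, j] = (x[i, j] - xbar) / s2 * acc
    return out


class TestLocalMoransI:
    def test_constant_layer_errors(self):
        with pytest.raises(DegenerateInputError):
            local_morans_i(np.full((5, 5), 2.0))

    def test_even_window_errors(self):
        with pytest.raises(ParameterError):
            local_morans_i(np.eye(5), window=4)

    def test_single_bright_pixel_negative_at_neighbours(self):
        x = np.zeros((5, 5))
        x[2, 2] = 10.0
        out = local_morans_i(x)
        neigh = [out[i, j] for i in (1, 2, 3) for j in (1, 2, 3) if (i, j) != (2, 2)]
        assert all(v < 0 for v in neigh)

    def test_checkerboard_interior(self):
        """With 8-neighbour binary weights a 2-colour checkerboard cancels
        exactly (4 like diagonal vs 4 unlike axial neighbours): interior I
        is 0; the anti-correlation shows up at edge pixels, where the
        neighbour count is odd, as negative values."""
        x = np.indices((6, 6)).sum(axis=0) % 2 * 1.0
        out = local_morans_i(x)
        np.testing.assert_allclose(out[1:-1, 1:-1], 0.0, atol=1e-12)
        assert (out[0, 1:-1] < 0).all() and (out[1:-1, 0] < 0).all()

    @pytest.mark.parametrize("row_standardized", [False, True])
    @pytest.mark.parametrize("window", [3, 5])
    def test_matches_double_loop_oracle(self, window, row_standardized):
        rng = np.random.default_rng(3)
        for shape in [(4, 7), (12, 12), (20, 20)]:
            x = rng.normal(size=shape)
            got = local_morans_i(x, window=window, row_standardized=row_standardized)
            want = _morans_naive(x, window=window, row_standardized=row_standardized)
            np.testing.assert_allclose(got, want, atol=1e-10)


def _otsu_brute(values, n_classes, bins):
    """Exhaustive maximizer of the between-class variance on the histogram."""
    v = np.asarray(values, float).ravel()
    hist, edges = np.histogram(v, bins=bins, range=(v.min(), v.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    mu = (p * centers).sum()

    def score(groups):
        tot = 0.0
        for g in groups:
            w = p[g].sum()
            if w > 0:
                m = (p[g] * centers[g]).sum() / w
                tot += w * (m - mu) ** 2
        return tot

    occupied = np.flatnonzero(hist > 0)

    def rep(t):
        below = occupied[occupied <= t]
        above = occupied[occupied > t]
        if below.size and above.size:
            return 0.5 * (centers[below[-1]] + centers[above[0]])
        return centers[t]

    best, best_t = -1.0, None
    if n_classes == 2:
        for t in range(bins - 1):
            s = score([slice(0, t + 1), slice(t + 1, bins)])
            if s > best + 1e-15:
                best, best_t = s, (rep(t),)
    else:
        for t1 in range(bins - 2):
            for t2 in range(t1 + 1, bins - 1):
                s = score([slice(0, t1 + 1), slice(t1 + 1, t2 + 1), slice(t2 + 1, bins)])
                if s > best + 1e-15:
                    best, best_t = s, (rep(t1), rep(t2))
    return best_t


class TestOtsu:
    def test_bimodal_delta_peaks(self):
        v = np.r_[np.full(50, 0.1), np.full(50, 0.9)]
        (t,) = otsu_thresholds(v, 2)
        assert 0.1 < t < 0.9

    def test_trimodal_two_thresholds(self):
        v = np.r_[np.zeros(30), np.full(30, 0.5), np.ones(30)]
        t1, t2 = otsu_thresholds(v, 3)
        assert 0.0 < t1 < 0.5 < t2 < 1.0

    @pytest.mark.parametrize("n_classes", [2, 3])
    @pytest.mark.parametrize("bins", [64, 256])
    def test_matches_exhaustive_search(self, n_classes, bins):
        rng = np.random.default_rng(5)
        for _ in range(4):
            v = np.concatenate(
                [rng.normal(m, 0.05, 60) for m in rng.uniform(0, 1, n_classes + 1)]
            )
            got = otsu_thresholds(v, n_classes, bins=bins)
            want = _otsu_brute(v, n_classes, bins)
            np.testing.assert_allclose(got, want, atol=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=8, max_size=60))
    def test_property_matches_exhaustive_on_random_lists(self, vals):
        v = np.asarray(vals)
        if np.unique(v).size < 2:
            return
        got = otsu_thresholds(v, 2, bins=64)
        want = _otsu_brute(v, 2, 64)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_partition_agrees_with_skimage(self):
        """Any cut in the empty inter-mode gap is optimal, so representative
        values differ between implementations; the induced partitions of the
        data must nevertheless coincide."""
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(6)
        v = np.r_[rng.normal(0.2, 0.02, 300), rng.normal(0.8, 0.02, 300)]
        (t,) = otsu_thresholds(v, 2)
        t_sk = threshold_otsu(v, nbins=256)
        np.testing.assert_array_equal(v <= t, v <= t_sk)

    def test_degenerate_errors(self):
        with pytest.raises(DegenerateInputError):
            otsu_thresholds(np.full(10, 0.5), 2)
        with pytest.raises(DegenerateInputError):
            otsu_thresholds(np.r_[np.zeros(5), np.ones(5)], 3)
        with pytest.raises(ParameterError):
            otsu_thresholds(np.arange(10.0), 4)
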