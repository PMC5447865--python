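"""Per-pixel derived layers and generic thresholding.

Three primitives used throughout the pipeline:

* :func:`ndvi` — the normalized difference vegetation index,
  ``(NIR - red) / (NIR + red)``, the greenness proxy that separates
  still-green medusahead from the senescent annual-grass matrix.
* :func:`local_morans_i` — a per-pixel local spatial-autocorrelation
  statistic computed in a small moving window; strongly negative values
  mark pixels that contrast with their neighbourhood, so the layer acts
  as a local-heterogeneity metric for segmentation.
* :func:`otsu_thresholds` — multi-level Otsu thresholding by exhaustive
  maximization of the between-class variance over a discretized histogram.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve

from .errors import DegenerateInputError, ParameterError
from .stack import BandStack


def ndvi(stack: BandStack) -> np.ndarray:
    """Compute NDVI = (nir - red) / (nir + red).

    Pixels where ``nir + red == 0`` are undefined and returned as NaN; their
    positions are also recorded in ``stack.nodata_masks['ndvi']``.
    """
    stack.require("nir", "red")
    nir = stack["nir"].astype(float)
    red = stack["red"].astype(float)
    denom = nir + red
    out = np.full(nir.shape, np.nan)
    ok = denom != 0
    out[ok] = (nir[ok] - red[ok]) / denom[ok]
    stack.nodata_masks["ndvi"] = ~ok
    return out


def local_morans_i(
    layer: np.ndarray,
    window: int = 3,
    row_standardized: bool = False,
) -> np.ndarray:
    """Local Moran's I with binary weights in a square moving window.

    For pixel *i*,

        I_i = (x_i - xbar) / s^2 * sum_j w_ij (x_j - xbar)

    with ``xbar`` and ``s^2`` the *global* mean and (population) variance and
    ``w_ij = 1`` for every other pixel of the window centred on *i*.  Edge
    pixels simply sum over the neighbours that exist.  With
    ``row_standardized=True`` the neighbour sum is divided by the number of
    available neighbours instead.

    Raises
    ------
    DegenerateInputError
        If the layer is constant (zero variance).
    ParameterError
        If ``window`` is not an odd integer >= 3.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be an odd integer >= 3, got {window}")
    x = np.asarray(layer, dtype=float)
    xbar = x.mean()
    s2 = x.var()
    if s2 == 0:
        raise DegenerateInputError("constant layer: local Moran's I undefined (s^2 = 0)")
    dev = x - xbar
    kernel = np.ones((window, window))
    kernel[window // 2, window // 2] = 0.0
    # Zero-padding makes absent neighbours contribute nothing, i.e. edge
    # pixels use exactly the neighbours available inside the raster.
    neigh_sum = convolve(dev, kernel, mode="constant", cval=0.0)
    if row_standardized:
        counts = convolve(np.ones_like(dev), kernel, mode="constant", cval=0.0)
        neigh_sum = neigh_sum / counts
    return dev / s2 * neigh_sum


def _between_class_variance_2(p: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """sigma_B^2 for every single-threshold split of histogram ``p``."""
    w0 = np.cumsum(p)[:-1]
    m = np.cumsum(p * centers)
    mu = m[-1]
    w1 = 1.0 - w0
    m0 = m[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = np.where(
            (w0 > 0) & (w1 > 0),
            (mu * w0 - m0) ** 2 / (w0 * w1),
            -np.inf,
        )
    return sigma


def otsu_thresholds(
    values: np.ndarray,
    n_classes: int = 2,
    bins: int = 256,
) -> tuple[float, ...]:
    """Multi-level Otsu thresholds over a uniform histogram of the values.

    The data are binned into ``bins`` uniform bins over the observed range and
    every admissible threshold tuple is scored by the between-class variance
    ``sum_k w_k (mu_k - mu)^2``; the maximizing tuple is chosen, ties broken
    by the lexicographically smallest tuple.  Each chosen cut is reported as
    the midpoint between the last occupied bin below it and the first
    occupied bin above it — every cut inside an empty histogram gap is
    equally optimal, and the gap midpoint is the canonical representative —
    so class membership is "value <= threshold".

    Raises
    ------
    ParameterError
        If ``n_classes`` is not 2 or 3.
    DegenerateInputError
        If there are fewer distinct values than classes.
    """
    if n_classes not in (2, 3):
        raise ParameterError("n_classes must be 2 or 3")
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if np.unique(v).size < n_classes:
        raise DegenerateInputError(
            f"need >= {n_classes} distinct values, got {np.unique(v).size}"
        )
    lo, hi = v.min(), v.max()
    hist, edges = np.histogram(v, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()

    occupied = np.flatnonzero(hist > 0)

    def representative(t: int) -> float:
        below = occupied[occupied <= t]
        above = occupied[occupied > t]
        if below.size and above.size:
            return float(0.5 * (centers[below[-1]] + centers[above[0]]))
        return float(centers[t])

    if n_classes == 2:
        sigma = _between_class_variance_2(p, centers)
        t = int(np.argmax(sigma))  # first max = smallest threshold
        return (representative(t),)

    # n_classes == 3: score every (t1 < t2) pair with prefix sums.
    w = np.cumsum(p)
    m = np.cumsum(p * centers)
    mu = m[-1]
    # class sums for split (t1, t2): [0..t1], (t1..t2], (t2..end]
    w1 = w[:, None]  # w up to t1 (column vector)
    w2 = w[None, :] - w[:, None]
    m1 = m[:, None]
    m2 = m[None, :] - m[:, None]
    w3 = 1.0 - w[None, :]
    m3 = mu - m[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = (
            np.where(w1 > 0, (m1 - mu * w1) ** 2 / w1, 0.0)
            + np.where(w2 > 0, (m2 - mu * w2) ** 2 / w2, 0.0)
            + np.where(w3 > 0, (m3 - mu * w3) ** 2 / w3, 0.0)
        )
    valid = np.triu(np.ones((bins, bins), dtype=bool), k=1)
    sigma = np.where(valid, sigma, -np.inf)
    flat = int(np.argmax(sigma))  # row-major first max = smallest (t1, t2)
    t1, t2 = divmod(flat, bins)
    return (representative(t1), representative(t2))


#: Affine maps applied to layers before they enter segmentation, so the
#: published scale parameters (tuned for 8-bit digital numbers) keep their
#: meaning on unitless [0, 1] reflectance.  NDVI is shifted from [-1, 1];
#: Moran's I is clipped to a robust range before scaling.
SEGMENTATION_LAYER_SCALE = 255.0


def segmentation_layers(stack: BandStack, names=None) -> dict[str, np.ndarray]:
    """Return the layers used for segmentation mapped to a 0-255 DN-like range."""
    if names is None:
        names = [n for n in ("blue", "green", "red", "nir", "ndvi", "morans_i") if n in stack]
    out: dict[str, np.ndarray] = {}
    for name in names:
        a = stack[name].astype(float)
        if name == "ndvi":
            a = (np.nan_to_num(a, nan=0.0) + 1.0) / 2.0
        elif name == "morans_i":
            a = np.clip(a, -8.0, 8.0) / 16.0 + 0.5
        out[name] = a * SEGMENTATION_LAYER_SCALE
    return out


def derive_layers(stack: BandStack, morans_source: str = "ndvi") -> BandStack:
    """Attach ``ndvi`` and ``morans_i`` to the stack (in place) and return it.

    ``morans_source`` picks the layer heterogeneity is measured on; the
    default follows the greenness layer, the quantity whose local contrast
    distinguishes patchy green cover from the senescent matrix.
    """
    if "ndvi" not in stack:
        stack.layers["ndvi"] = ndvi(stack)
    src = stack[morans_source]
    src = np.nan_to_num(src, nan=float(np.nanmean(src)))
    stack.layers["morans_i"] = local_morans_i(src, window=3)
    return stack
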