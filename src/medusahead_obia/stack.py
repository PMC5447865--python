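"""Georeferenced multi-band raster container.

The scene frame is metric and north-up: ``x`` runs east from the lower-left
corner of the raster, ``y`` runs north.  Row 0 of every array is the
*northernmost* row, matching the usual image convention, so

    row = (extent_y - y) / pixel_size   (truncated),
    col = x / pixel_size.

Only this affine form (offset + square pixel) is supported; the synthetic
scenes and everything downstream use it exclusively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, BandError

#: Order in which the four spectral bands are stored on disk.
BAND_ORDER = ("blue", "green", "red", "nir")

#: Derived layers the pipeline may attach.
DERIVED_LAYERS = ("ndvi", "morans_i")


@dataclass
class BandStack:
    """A stack of co-registered raster layers plus the grid georeference.

    Parameters
    ----------
    layers
        Mapping from layer name (``blue``/``green``/``red``/``nir`` and
        optionally ``ndvi``/``morans_i``) to a 2-D float array. All layers
        must share one shape.
    pixel_size_m
        Ground sampling distance of the square pixels, metres.
    origin
        ``(x, y)`` scene coordinate of the *lower-left* corner, metres.
    mask
        Boolean validity mask (True = valid data). ``None`` means all valid.
    """

    layers: dict[str, np.ndarray]
    pixel_size_m: float = 0.15
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None
    nodata_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise AlignmentError(f"layers have mismatched shapes: {sorted(shapes)}")
        if self.mask is not None and self.mask.shape != self.shape:
            raise AlignmentError("mask shape does not match layers")

    # -- grid bookkeeping -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def extent_m(self) -> tuple[float, float]:
        """(width, height) of the raster footprint in metres."""
        h, w = self.shape
        return (w * self.pixel_size_m, h * self.pixel_size_m)

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.layers[name]
        except KeyError:
            raise BandError(f"layer {name!r} not in stack (have {sorted(self.layers)})")

    def valid_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.mask

    # -- coordinate transforms --------------------------------------------
    def world_to_index(self, x, y):
        """Scene (x, y) metres -> (row, col) pixel indices (arrays ok)."""
        h, _ = self.shape
        px = self.pixel_size_m
        col = np.floor((np.asarray(x) - self.origin[0]) / px).astype(int)
        row = np.floor((self.origin[1] + h * px - np.asarray(y)) / px).astype(int)
        return row, col

    def index_to_world(self, row, col):
        """Pixel (row, col) -> scene (x, y) of the pixel centre, metres."""
        h, _ = self.shape
        px = self.pixel_size_m
        x = self.origin[0] + (np.asarray(col) + 0.5) * px
        y = self.origin[1] + (h - np.asarray(row) - 0.5) * px
        return x, y

    def in_extent(self, x, y) -> np.ndarray:
        w, h = self.extent_m
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x >= self.origin[0])
            & (x < self.origin[0] + w)
            & (y >= self.origin[1])
            & (y < self.origin[1] + h)
        )

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise BandError(f"missing layer(s) {missing}; have {sorted(self.layers)}")
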