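"""Seeded synthetic 4-band grassland scenes with per-pixel ground truth.

The generator emulates a late-spring Mediterranean annual grassland at the
moment of peak phenological contrast: a senescent-grass matrix in which
medusahead is still green, alongside the confuser types that make its
detection hard —

* **barbed goatgrass**: green patches with near-medusahead spectra,
* **canarygrass**: disaggregated green clumps inside senescent gaps, so its
  object *means* sit between green and dry grass while its texture is
  strongly structured,
* **vetch**: very bright green rendered as a fine high-heterogeneity mosaic,
* **clover-brome** and **ryegrass-brome**: intermediate-greenness mosaics,
  part of which carries low-density (5-35 % cover) subdominant medusahead,
* **wild oat**: tall senescent grass that can hide understory medusahead,
  rendered with its greenness down-weighted.

Patches are random ellipses whose length distribution is weighted so the
smallest category (<= 0.5 m) dominates, with a thin tail above 7 m.  Cover
fractions are maintained per pixel and always sum to one; reflectance is the
cover-weighted mixture of class spectra plus class-specific texture fields
and white noise, on a unitless [0, 1] scale per band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely import affinity
from shapely.geometry import Point, Polygon

from .errors import ConfigurationError
from .stack import BAND_ORDER, BandStack

#: Fixed class order; index 0 is the matrix and wins dominant-label ties.
CLASS_NAMES = (
    "senescent_matrix",
    "medusahead",
    "barbed_goatgrass",
    "clover_brome",
    "ryegrass_brome",
    "canarygrass",
    "vetch",
    "wild_oat",
)
MATRIX = "senescent_matrix"
MEDUSAHEAD = "medusahead"

#: Patch length categories (m): (low, high], smallest first.
LENGTH_CATEGORY_RANGES = ((0.25, 0.5), (0.5, 2.0), (2.0, 7.0), (7.0, 12.0))


@dataclass(frozen=True)
class ClassSpectrum:
    """Per-class reflectance model: band means (B, G, R, NIR), white-noise sd
    and a texture archetype with its parameters."""

    means: tuple[float, float, float, float]
    noise_sd: float = 0.02
    texture: str = "uniform"  # uniform | clumped | fine_mosaic
    #: clumped: binary clump/gap pattern swinging by +-delta around the mean
    #: with spatial coherence ``clump_scale_m``; fine_mosaic: continuous
    #: per-pixel uniform variation of total span ``delta`` (independent
    #: neighbours -> very high GLCM entropy, the mosaic signature).
    delta: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    clump_fill: float = 0.5
    clump_scale_m: float = 0.45
    #: secondary continuous per-pixel variation added on top of any
    #: archetype (e.g. plant-to-plant greenness variation inside clumps).
    mosaic_delta: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PatchModel:
    """Per-class patch population: how many patches and how large."""

    n_patches: int
    category_weights: tuple[float, float, float, float] = (3.0, 1.0, 1.0, 0.5)
    cover_range: tuple[float, float] = (0.7, 0.95)
    aspect_range: tuple[float, float] = (0.4, 1.0)
    #: probability that a patch of this class carries subdominant medusahead
    #: and the cover range it gets (clover-brome mixing, oat understory).
    mixed_mh_prob: float = 0.0
    mixed_mh_cover: tuple[float, float] = (0.05, 0.35)
    #: greenness retained by medusahead rendered under this class's canopy
    #: (1 = fully visible; < 1 emulates understory that does not look green).
    understory_greenness: float = 1.0


@dataclass
class SceneConfig:
    extent_m: tuple[float, float] = (48.0, 48.0)
    pixel_size_m: float = 0.15
    palette: dict[str, ClassSpectrum] = field(default_factory=dict)
    patch_models: dict[str, PatchModel] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_m[0] <= 0 or self.extent_m[1] <= 0:
            raise ConfigurationError("extent must be positive")
        missing = [c for c in self.patch_models if c not in self.palette]
        if MATRIX not in self.palette:
            missing.append(MATRIX)
        if missing:
            raise ConfigurationError(f"palette missing class(es): {missing}")
        unknown = [c for c in self.patch_models if c not in CLASS_NAMES]
        if unknown:
            raise ConfigurationError(f"unknown class(es): {unknown}")


@dataclass
class ScenePatch:
    class_name: str
    patch_id: int
    polygon: Polygon
    length_m: float
    cover: float


@dataclass
class SceneTruth:
    """Ground truth for a generated scene."""

    dominant_label: np.ndarray  # (H, W) int index into class_names
    cover_fractions: np.ndarray  # (C, H, W) float, sums to 1 per pixel
    class_names: tuple[str, ...]
    patch_polygons: list[ScenePatch]
    pixel_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def extent_m(self) -> tuple[float, float]:
        h, w = self.dominant_label.shape
        return (w * self.pixel_size_m, h * self.pixel_size_m)

    def class_index(self, name: str) -> int:
        return self.class_names.index(name)

    def fraction_of(self, name: str) -> np.ndarray:
        return self.cover_fractions[self.class_index(name)]

    def world_to_index(self, x, y):
        h = self.dominant_label.shape[0]
        px = self.pixel_size_m
        col = np.floor((np.asarray(x) - self.origin[0]) / px).astype(int)
        row = np.floor((self.origin[1] + h * px - np.asarray(y)) / px).astype(int)
        return row, col


# ---------------------------------------------------------------------------
# palette presets
# ---------------------------------------------------------------------------

_MATRIX_MEANS = (0.18, 0.26, 0.33, 0.38)
_MH_MEANS = (0.05, 0.14, 0.09, 0.45)
_GREEN_DELTA = tuple(g - m for g, m in zip(_MH_MEANS, _MATRIX_MEANS))


def _base_palette() -> dict[str, ClassSpectrum]:
    """Site-realistic palette: goatgrass nearly matches medusahead, canarygrass
    is green clumps in dry-grass gaps, vetch is a bright fine mosaic."""
    return {
        MATRIX: ClassSpectrum(_MATRIX_MEANS),
        MEDUSAHEAD: ClassSpectrum(_MH_MEANS),
        "barbed_goatgrass": ClassSpectrum((0.055, 0.145, 0.095, 0.43)),
        "clover_brome": ClassSpectrum((0.09, 0.17, 0.15, 0.37)),
        "ryegrass_brome": ClassSpectrum(
            (0.07, 0.16, 0.12, 0.41),
            texture="fine_mosaic",
            delta=(0.05, 0.08, 0.09, 0.22),
        ),
        "canarygrass": ClassSpectrum(
            tuple(0.55 * g + 0.45 * m for g, m in zip((0.05, 0.15, 0.10, 0.44), _MATRIX_MEANS)),
            texture="clumped",
            delta=tuple(g - m for g, m in zip((0.05, 0.15, 0.10, 0.44), _MATRIX_MEANS)),
            clump_fill=0.55,
            mosaic_delta=(0.0, 0.10, 0.0, 0.03),
        ),
        "vetch": ClassSpectrum(
            (0.04, 0.20, 0.07, 0.55),
            texture="fine_mosaic",
            delta=(0.07, 0.12, 0.10, 0.30),
        ),
        "wild_oat": ClassSpectrum((0.17, 0.25, 0.31, 0.40)),
    }


def _separable_palette() -> dict[str, ClassSpectrum]:
    """Well-separated variant: every class pushed apart spectrally and
    understory medusahead fully visible (used to probe the detection ceiling)."""
    pal = _base_palette()
    pal["barbed_goatgrass"] = ClassSpectrum((0.10, 0.22, 0.20, 0.30))
    pal["canarygrass"] = ClassSpectrum((0.03, 0.20, 0.04, 0.60))
    pal["clover_brome"] = ClassSpectrum((0.12, 0.18, 0.20, 0.32))
    pal["ryegrass_brome"] = ClassSpectrum((0.08, 0.30, 0.13, 0.50))
    pal["vetch"] = ClassSpectrum((0.02, 0.24, 0.05, 0.68))
    pal["wild_oat"] = ClassSpectrum((0.24, 0.30, 0.40, 0.34))
    return pal


def _texture_only_palette() -> dict[str, ClassSpectrum]:
    """Canarygrass shares medusahead's band means exactly and differs only in
    clump structure: a zero-mean clumped modulation plus fine per-pixel
    variation, both kept at amplitudes below the region-merging threshold so
    canarygrass objects stay spectrally identical to medusahead at object
    level while their texture attributes (sd, GLCM entropy) separate."""
    pal = _base_palette()
    # modulation lives in the bands with radiometric headroom (green, NIR);
    # blue and red sit near zero where clipping would bias the means.  The
    # clump component is kept fine and weak — coarse clumps scatter *object
    # means* (clump-fraction varies object to object) and would re-create a
    # spectral difference; the per-pixel mosaic component carries the texture
    # signal with an object-mean footprint that vanishes as 1/sqrt(n).
    pal["canarygrass"] = ClassSpectrum(
        _MH_MEANS,
        texture="clumped",
        delta=(0.003, 0.01, 0.005, 0.02),
        clump_fill=0.5,
        clump_scale_m=0.25,
        mosaic_delta=(0.01, 0.06, 0.015, 0.12),
    )
    return pal


#: Patch densities per hectare for the default study conditions.
_DENSITY_PER_HA = {
    MEDUSAHEAD: 60,
    "barbed_goatgrass": 16,
    "clover_brome": 16,
    "ryegrass_brome": 8,
    "canarygrass": 12,
    "vetch": 8,
    "wild_oat": 10,
}

_BROAD = (0.0, 0.8, 1.6, 2.4)  # community-scale classes skew large


def _base_patch_models(area_ha: float) -> dict[str, PatchModel]:
    def n(cls):
        return max(1, round(_DENSITY_PER_HA[cls] * area_ha))

    return {
        MEDUSAHEAD: PatchModel(n_patches=n(MEDUSAHEAD)),
        # goatgrass occurs as monodominant patches large enough to dominate
        # a survey plot, hence the mid-size-weighted distribution
        "barbed_goatgrass": PatchModel(
            n_patches=n("barbed_goatgrass"), category_weights=(1.0, 2.0, 1.0, 0.3)
        ),
        "clover_brome": PatchModel(
            n_patches=n("clover_brome"),
            category_weights=_BROAD,
            cover_range=(0.6, 0.9),
            mixed_mh_prob=0.5,
        ),
        "ryegrass_brome": PatchModel(n_patches=n("ryegrass_brome"), category_weights=_BROAD),
        "canarygrass": PatchModel(
            n_patches=n("canarygrass"), category_weights=(0.0, 1.0, 2.0, 1.0)
        ),
        "vetch": PatchModel(n_patches=n("vetch"), category_weights=_BROAD),
        "wild_oat": PatchModel(
            n_patches=n("wild_oat"),
            category_weights=_BROAD,
            mixed_mh_prob=0.4,
            mixed_mh_cover=(0.2, 0.55),
            understory_greenness=0.45,
        ),
    }


def default_scene_config(
    extent_m: tuple[float, float] = (48.0, 48.0),
    preset: str = "realistic",
    seed: int = 0,
    pixel_size_m: float = 0.15,
) -> SceneConfig:
    """Build a SceneConfig for one of the named study conditions.

    ``realistic`` is the default condition (spectrally similar goatgrass,
    clump-textured canarygrass, subcanopy medusahead); ``separable`` pushes
    all palettes apart; ``texture_only`` gives canarygrass medusahead's exact
    band means so only texture can separate the two.
    """
    area_ha = extent_m[0] * extent_m[1] / 1e4
    models = _base_patch_models(area_ha)
    if preset == "realistic":
        palette = _base_palette()
    elif preset == "separable":
        palette = _separable_palette()
        # the condition isolates *spectral* separability: a 50/50 two-species
        # canopy pixel is a mixture no palette can separate, so layered
        # canopy mixing is off here (low-density medusahead in clover-brome
        # stays: it feeds the acceptable-class test stratum)
        models["wild_oat"] = replace(
            models["wild_oat"], understory_greenness=1.0, mixed_mh_prob=0.0
        )
    elif preset == "texture_only":
        palette = _texture_only_palette()
        # isolate the canarygrass/medusahead contrast: drop other confusers
        # and give both classes the same patch-size distribution so object
        # support is matched and only texture can separate them
        # near-full cover: partial cover adds patch/matrix mixture texture to
        # both classes alike, masking the class-intrinsic pattern contrast
        models = {
            MEDUSAHEAD: PatchModel(
                n_patches=max(4, round(30 * area_ha)),
                category_weights=(0.0, 1.0, 2.0, 1.0),
                cover_range=(0.92, 1.0),
            ),
            "canarygrass": PatchModel(
                n_patches=max(4, round(30 * area_ha)),
                category_weights=(0.0, 1.0, 2.0, 1.0),
                cover_range=(0.92, 1.0),
            ),
        }
    else:
        raise ConfigurationError(f"unknown preset {preset!r}")
    return SceneConfig(
        extent_m=extent_m,
        pixel_size_m=pixel_size_m,
        palette=palette,
        patch_models=models,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _ellipse(cx, cy, half_len, half_wid, angle_deg) -> Polygon:
    e = affinity.scale(Point(0, 0).buffer(1.0, quad_segs=16), half_len, half_wid)
    e = affinity.rotate(e, angle_deg)
    return affinity.translate(e, cx, cy)


def _ellipse_mask(shape, px, cx, cy, half_len, half_wid, angle_deg, origin, height_m):
    """Boolean mask of pixel centres inside the ellipse, on the full grid."""
    H, W = shape
    pad = max(half_len, half_wid)
    r0 = max(0, int((height_m - (cy + pad)) / px) - 1)
    r1 = min(H, int((height_m - (cy - pad)) / px) + 2)
    c0 = max(0, int((cx - pad - origin[0]) / px) - 1)
    c1 = min(W, int((cx + pad - origin[0]) / px) + 2)
    if r0 >= r1 or c0 >= c1:
        return None, None
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    x = origin[0] + (cc + 0.5) * px
    y = origin[1] + height_m - (rr + 0.5) * px
    th = np.deg2rad(angle_deg)
    u = (x - cx) * np.cos(th) + (y - cy) * np.sin(th)
    w = -(x - cx) * np.sin(th) + (y - cy) * np.cos(th)
    inside = (u / half_len) ** 2 + (w / half_wid) ** 2 <= 1.0
    return (slice(r0, r1), slice(c0, c1)), inside


def _deposit(fractions, window, inside, cls_idx, cover):
    sub = fractions[(slice(None),) + window]
    sub[:, inside] *= 1.0 - cover
    sub[cls_idx][inside] += cover


def generate_scene(config: SceneConfig) -> tuple[BandStack, SceneTruth]:
    """Render a scene and its ground truth; bit-identical for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    px = config.pixel_size_m
    width_m, height_m = config.extent_m
    W = int(round(width_m / px))
    H = int(round(height_m / px))
    C = len(CLASS_NAMES)
    mh_idx = CLASS_NAMES.index(MEDUSAHEAD)

    fractions = np.zeros((C, H, W))
    fractions[0] = 1.0
    understory = np.ones((H, W))  # greenness weight applied to medusahead
    patches: list[ScenePatch] = []

    pid = 0
    for cls in CLASS_NAMES:
        model = config.patch_models.get(cls)
        if model is None or model.n_patches == 0:
            continue
        cls_idx = CLASS_NAMES.index(cls)
        weights = np.asarray(model.category_weights, float)
        weights = weights / weights.sum()
        for _ in range(model.n_patches):
            cat = rng.choice(4, p=weights)
            lo, hi = LENGTH_CATEGORY_RANGES[cat]
            length = rng.uniform(lo, hi)
            aspect = rng.uniform(*model.aspect_range)
            angle = rng.uniform(0, 180)
            cx = rng.uniform(0, width_m)
            cy = rng.uniform(0, height_m)
            cover = rng.uniform(*model.cover_range)
            mixed = rng.random() < model.mixed_mh_prob
            mh_cover = rng.uniform(*model.mixed_mh_cover)
            half_len, half_wid = length / 2, length * aspect / 2
            window, inside = _ellipse_mask(
                (H, W), px, cx, cy, half_len, half_wid, angle, (0.0, 0.0), height_m
            )
            if window is None or not inside.any():
                continue
            _deposit(fractions, window, inside, cls_idx, cover)
            if mixed and cls != MEDUSAHEAD:
                _deposit(fractions, window, inside, mh_idx, mh_cover)
                if model.understory_greenness < 1.0:
                    understory[window][inside] = np.minimum(
                        understory[window][inside], model.understory_greenness
                    )
            patches.append(
                ScenePatch(cls, pid, _ellipse(cx, cy, half_len, half_wid, angle), length, cover)
            )
            pid += 1

    # texture fields, one per class needing one (fixed class order)
    pattern = {}  # cls -> (4,) x (H, W) additive field
    for cls in CLASS_NAMES:
        spec = config.palette.get(cls)
        if spec is None:
            continue
        field_ = None
        if spec.texture == "clumped":
            smooth = gaussian_filter(rng.standard_normal((H, W)), spec.clump_scale_m / px)
            cut = np.quantile(smooth, 1.0 - spec.clump_fill)
            base = (smooth >= cut).astype(float) - spec.clump_fill
            field_ = base[None, :, :] * np.asarray(spec.delta, float)[:, None, None]
        elif spec.texture == "fine_mosaic":
            base = rng.random((H, W)) - 0.5
            field_ = base[None, :, :] * np.asarray(spec.delta, float)[:, None, None]
        elif spec.texture != "uniform":
            raise ConfigurationError(f"unknown texture archetype {spec.texture!r}")
        if any(d != 0 for d in spec.mosaic_delta):
            extra = (rng.random((H, W)) - 0.5)[None, :, :] * np.asarray(
                spec.mosaic_delta, float
            )[:, None, None]
            field_ = extra if field_ is None else field_ + extra
        if field_ is not None:
            # centre the field over the class's own cover so the class mean
            # equals the configured spectrum exactly (a raw global field has
            # a nonzero mean over any finite patch footprint)
            w = fractions[CLASS_NAMES.index(cls)]
            if w.sum() > 0:
                field_ = field_ - (field_ * w).sum(axis=(1, 2), keepdims=True) / w.sum()
            pattern[cls] = field_

    matrix_means = np.asarray(config.palette[MATRIX].means)
    bands = np.zeros((4, H, W))
    noise_sd = np.zeros((H, W))
    for ci, cls in enumerate(CLASS_NAMES):
        frac = fractions[ci]
        if not frac.any():
            continue
        spec = config.palette.get(cls)
        if spec is None:
            raise ConfigurationError(f"palette missing class {cls!r}")
        means = np.asarray(spec.means, float)[:, None, None]
        if cls == MEDUSAHEAD:
            w = understory[None, :, :]
            contrib = w * means + (1.0 - w) * matrix_means[:, None, None]
        else:
            contrib = np.broadcast_to(means, (4, H, W))
        if cls in pattern:
            contrib = contrib + pattern[cls]
        bands += frac[None] * contrib
        noise_sd += frac * spec.noise_sd
    # spatially correlated noise: canopy micro-texture is smooth at 0.15 m,
    # so neighbouring pixels co-vary; mosaics/clumps add structure on top
    white = rng.standard_normal((4, H, W))
    smooth = gaussian_filter(white, sigma=(0, 1.0, 1.0))
    smooth /= smooth.std(axis=(1, 2), keepdims=True)
    bands += smooth * noise_sd[None]
    np.clip(bands, 0.0, 1.0, out=bands)

    stack = BandStack(
        layers={name: bands[i] for i, name in enumerate(BAND_ORDER)},
        pixel_size_m=px,
    )
    truth = SceneTruth(
        dominant_label=np.argmax(fractions, axis=0).astype(np.int16),
        cover_fractions=fractions,
        class_names=CLASS_NAMES,
        patch_polygons=patches,
        pixel_size_m=px,
    )
    return stack, truth
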