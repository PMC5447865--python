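"""Disk formats: multi-band TIFF rasters, GeoJSON vectors, YAML configs.

Rasters are written as multi-band TIFF with a JSON sidecar carrying the
georeference (origin, pixel size, band order); vectors as GeoJSON
FeatureCollections with class names and other attributes as string/number
properties; configs as YAML.  All formats are plain files a GIS can open.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml
from shapely.geometry import mapping, shape

from .stack import BAND_ORDER, BandStack


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


def write_band_stack(stack: BandStack, path) -> None:
    """Write the stack as multi-band TIFF + ``<path>.meta.json`` sidecar."""
    path = Path(path)
    names = [n for n in BAND_ORDER if n in stack] + [
        n for n in stack.layers if n not in BAND_ORDER
    ]
    data = np.stack([stack[n].astype(np.float32) for n in names])
    tifffile.imwrite(path, data)
    meta = {
        "layers": names,
        "pixel_size_m": stack.pixel_size_m,
        "origin": list(stack.origin),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_band_stack(path) -> BandStack:
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    layers = {n: data[i].astype(float) for i, n in enumerate(meta["layers"])}
    return BandStack(
        layers=layers,
        pixel_size_m=float(meta["pixel_size_m"]),
        origin=tuple(meta["origin"]),
    )


def write_label_raster(labels: np.ndarray, pixel_size_m: float, path, origin=(0.0, 0.0)) -> None:
    path = Path(path)
    tifffile.imwrite(path, labels.astype(np.int32))
    meta = {"pixel_size_m": pixel_size_m, "origin": list(origin)}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_label_raster(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    labels = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    return labels, meta


# ---------------------------------------------------------------------------
# GeoJSON vectors
# ---------------------------------------------------------------------------


def _feature(geom, properties) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": properties}


def write_geojson(features: list[dict], path) -> None:
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_geojson(path) -> list[tuple]:
    """Read a FeatureCollection as (shapely geometry, properties) pairs."""
    fc = json.loads(Path(path).read_text())
    return [(shape(f["geometry"]), f.get("properties", {})) for f in fc["features"]]


def samples_to_geojson(samples, path) -> None:
    from shapely.geometry import Point

    feats = [
        _feature(
            Point(*s.location),
            {
                "best_class": s.best_class,
                "acceptable_classes": list(s.acceptable_classes),
                "role": s.role,
                "source": s.source,
                "positional_noise_m": round(s.positional_noise_applied, 4),
                "cover_fractions": {k: round(v, 4) for k, v in s.cover_fractions.items()},
            },
        )
        for s in samples
    ]
    write_geojson(feats, path)


def transects_to_geojson(transects, path) -> None:
    feats = [
        _feature(t.line, {"id": t.id, "group_id": t.group_id, "n_plots": len(t.plot_points)})
        for t in transects
    ]
    write_geojson(feats, path)


def segments_to_geojson(segments, transects, path) -> None:
    """Field segments as line fragments along their transect geometry."""
    from shapely.ops import substring

    by_id = {t.id: t for t in transects}
    feats = []
    for s in segments:
        line = substring(by_id[s.transect_id].line, s.start_m, s.end_m)
        feats.append(
            _feature(
                line,
                {
                    "transect_id": s.transect_id,
                    "start_m": round(s.start_m, 3),
                    "end_m": round(s.end_m, 3),
                    "length_m": round(s.length_m, 3),
                },
            )
        )
    write_geojson(feats, path)


def patches_to_geojson(truth, path) -> None:
    feats = [
        _feature(
            p.polygon,
            {
                "class": p.class_name,
                "patch_id": p.patch_id,
                "length_m": round(p.length_m, 3),
                "cover": round(p.cover, 3),
            },
        )
        for p in truth.patch_polygons
    ]
    write_geojson(feats, path)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_yaml_config(config, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
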