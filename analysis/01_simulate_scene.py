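"""Generate the default synthetic grassland scene and its field survey.

Writes the 4-band scene (TIFF + georeference sidecar), the truth label
raster and patch polygons, the 20-transect survey with its medusahead
segments and plot samples, and prints a composition summary.
"""

from pathlib import Path

import numpy as np

from medusahead_obia.features import derive_layers
from medusahead_obia.io import (
    patches_to_geojson,
    samples_to_geojson,
    segments_to_geojson,
    transects_to_geojson,
    write_band_stack,
    write_label_raster,
)
from medusahead_obia.scene import CLASS_NAMES, default_scene_config, generate_scene
from medusahead_obia.survey import simulate_field_survey
from medusahead_obia.transects import field_segment_stats

OUT = Path(__file__).resolve().parents[1] / "results" / "scene"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_scene_config(extent_m=(96.0, 48.0), preset="realistic", seed=SEED)
    stack, truth = generate_scene(cfg)
    derive_layers(stack)
    write_band_stack(stack, OUT / "scene.tif")
    write_label_raster(truth.dominant_label, truth.pixel_size_m, OUT / "truth_labels.tif")
    patches_to_geojson(truth, OUT / "truth_patches.geojson")

    transects, segments, plots = simulate_field_survey(truth, seed=SEED + 1)
    transects_to_geojson(transects, OUT / "transects.geojson")
    segments_to_geojson(segments, transects, OUT / "field_segments.geojson")
    samples_to_geojson(plots, OUT / "plot_samples.geojson")

    total = truth.dominant_label.size
    print(f"scene {stack.shape[1]}x{stack.shape[0]} px ({cfg.extent_m[0]:g} x "
          f"{cfg.extent_m[1]:g} m), seed {SEED}")
    for i, name in enumerate(CLASS_NAMES):
        frac = float((truth.dominant_label == i).sum()) / total
        if frac > 0:
            print(f"  {name:18s} {100 * frac:5.1f} % of pixels")
    print(f"{len(transects)} transects, {len(plots)} plots, "
          f"{len(segments)} medusahead field segments")
    stats = field_segment_stats(segments)
    print(stats.to_string(index=False))
    print(f"artifacts in {OUT}")


if __name__ == "__main__":
    main()
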