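"""Published fuzzy-accuracy benchmarks for the original field campaign.

The aerial imagery and field data behind the original medusahead-mapping
campaign were never deposited, so its headline numbers cannot be recomputed
from raw data.  What *can* be recomputed is their internal arithmetic: the
printed comparison of 19 classification methods reports MAX, RIGHT, their
difference and producer's accuracy per method, and the combined
medusahead+goatgrass accuracies for the nine methods where both invasives
were classified.  These tables are inputs to the package (ranges, column
arithmetic, combined-vs-separate relations), not outputs of it.

Two printed rows are internally inconsistent: "KNN, 7 classes, with texture"
prints a MAX-RIGHT difference of 0.33 where RIGHT - MAX = 0.32, and
"Bayesian, 7 classes, with texture" prints 0.32 where RIGHT - MAX = 0.28.
The recomputation functions flag them rather than hide them.
"""

from __future__ import annotations

import pandas as pd

# method, with_texture, MAX, RIGHT, printed diff (RIGHT - MAX), producer
_METHOD_TABLE = [
    ("unsupervised_12", False, 0.36, 0.68, 0.32, 0.96),
    ("unsupervised_12", True, 0.34, 0.70, 0.36, 1.00),
    ("unsupervised_18", False, 0.35, 0.68, 0.33, 0.98),
    ("unsupervised_18", True, 0.35, 0.71, 0.36, 1.00),
    ("supervised_knn_3", False, 0.45, 0.81, 0.36, 0.66),
    ("supervised_knn_3", True, 0.44, 0.77, 0.33, 0.64),
    ("supervised_knn_7", False, 0.45, 0.78, 0.33, 0.66),
    ("supervised_knn_7", True, 0.45, 0.77, 0.33, 0.68),
    ("supervised_svm_3", False, 0.23, 0.67, 0.44, 0.44),
    ("supervised_svm_3", True, 0.40, 0.66, 0.26, 0.56),
    ("supervised_svm_7", False, 0.35, 0.66, 0.31, 0.64),
    ("supervised_svm_7", True, 0.45, 0.73, 0.28, 0.90),
    ("supervised_bayes_3", False, 0.44, 0.73, 0.29, 0.82),
    ("supervised_bayes_3", True, 0.44, 0.71, 0.27, 0.88),
    ("supervised_bayes_7", False, 0.52, 0.83, 0.31, 0.60),
    ("supervised_bayes_7", True, 0.48, 0.76, 0.32, 0.76),
    ("hierarchical_knn", True, 0.40, 0.69, 0.29, 0.76),
    ("hierarchical_svm", True, 0.33, 0.63, 0.30, 0.58),
    ("hierarchical_bayes", True, 0.46, 0.76, 0.30, 0.74),
]

# combined medusahead + barbed-goatgrass accuracies (7-class + hierarchical)
_COMBINED_TABLE = [
    ("supervised_knn_7", False, 0.51, 0.83, 0.96),
    ("supervised_knn_7", True, 0.52, 0.82, 0.86),
    ("supervised_svm_7", False, 0.49, 0.77, 0.87),
    ("supervised_svm_7", True, 0.54, 0.85, 0.92),
    ("supervised_bayes_7", False, 0.62, 0.90, 0.73),
    ("supervised_bayes_7", True, 0.57, 0.86, 0.88),
    ("hierarchical_knn", True, 0.51, 0.80, 0.78),
    ("hierarchical_svm", True, 0.53, 0.85, 0.78),
    ("hierarchical_bayes", True, 0.53, 0.85, 0.84),
]


def reference_method_table() -> pd.DataFrame:
    """The 19-row printed method comparison (MAX / RIGHT / diff / producer)."""
    return pd.DataFrame(
        _METHOD_TABLE,
        columns=["method", "with_texture", "MAX", "RIGHT", "printed_diff", "producer"],
    )


def reference_combined_table() -> pd.DataFrame:
    """The printed combined medusahead+goatgrass accuracies (9 methods)."""
    return pd.DataFrame(
        _COMBINED_TABLE, columns=["method", "with_texture", "MAX", "RIGHT", "producer"]
    )


def recompute_reference_arithmetic() -> dict:
    """Recompute the derived columns and ranges of the printed tables.

    Returns the recomputed RIGHT - MAX column, the rows where it disagrees
    with the printed difference beyond printed precision, the across-row
    range of the difference, and the extreme producer / RIGHT values.
    """
    t = reference_method_table()
    t["recomputed_diff"] = (t["RIGHT"] - t["MAX"]).round(10)
    t["discrepancy"] = (t["recomputed_diff"] - t["printed_diff"]).round(10)
    inconsistent = t[t["discrepancy"].abs() > 0.005]
    return {
        "table": t,
        "inconsistent_rows": inconsistent,
        "diff_range": (float(t["recomputed_diff"].min()), float(t["recomputed_diff"].max())),
        "printed_diff_range": (float(t["printed_diff"].min()), float(t["printed_diff"].max())),
        "producer_min": float(t["producer"].min()),
        "producer_max": float(t["producer"].max()),
        "right_max": float(t["RIGHT"].max()),
        "right_min": float(t["RIGHT"].min()),
        "n_methods": int(len(t)),
    }


def combined_vs_separate() -> pd.DataFrame:
    """Join the combined-invasives accuracies against the separate-class rows.

    For every one of the nine methods the combined metrics are at least the
    separate-class metrics — mutual medusahead/goatgrass confusion is the
    dominant error these methods share.
    """
    sep = reference_method_table().set_index(["method", "with_texture"])
    comb = reference_combined_table().set_index(["method", "with_texture"])
    out = comb.join(sep, lsuffix="_combined", rsuffix="_separate")
    for col in ("MAX", "RIGHT", "producer"):
        out[f"{col}_gain"] = out[f"{col}_combined"] - out[f"{col}_separate"]
    return out.reset_index()
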