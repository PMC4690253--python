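"""Subject-level heterogeneity features derived from a 16-segment table.

Given per-segment mean T2 and pixel-SD, a subject is summarised by six
numbers:

* ``globalT2`` / ``globalSD`` — the across-segment means;
* ``maxT2`` / ``maxSD`` — the single highest segmental value, sensitive to a
  focus confined to one segment;
* ``madT2`` — the mean absolute deviation of the 16 segmental T2 means from
  their average, on the raw ms scale;
* ``madSD`` — the mean absolute deviation of the natural-log-transformed
  pixel-SDs from their log-scale average (dimensionless), sensitive to a
  focus split across several segments. The log transform makes madSD
  invariant to a common rescaling of all pixel-SDs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["mad", "compute_features", "features_from_segments", "FEATURE_COLUMNS"]

FEATURE_COLUMNS = ["globalT2", "globalSD", "maxT2", "maxSD", "madT2", "madSD"]


def mad(values, log_transform: bool = False) -> float:
    """Mean absolute deviation around the mean, optionally on the log scale.

    ``y_j = ln(x_j)`` when ``log_transform`` else ``y_j = x_j``; returns
    ``sum_j |y_j - ybar| / k`` with no further rescaling.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector of at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if log_transform:
        if np.any(x <= 0):
            raise ValueError("log transform requires strictly positive values")
        x = np.log(x)
    return float(np.abs(x - x.mean()).mean())


def compute_features(table: pd.DataFrame, allow_partial: bool = False,
                     sd_epsilon: float = 1e-6) -> pd.Series:
    """Six heterogeneity features from one subject's segment table.

    ``table`` must carry the 16 segment rows produced by
    :func:`cardiomad.segmentation.segment_statistics`. Rows flagged
    ``ok=False`` are rejected unless ``allow_partial`` is set, in which case
    the statistics use the k available segments. A zero pixel-SD (possible in
    degenerate noiseless phantoms) is clamped to ``sd_epsilon`` ms with a
    warning so the log transform stays finite.
    """
    t = table
    if "ok" in t.columns and not allow_partial:
        if not t["ok"].all() or len(t) != 16:
            raise ValueError(
                "subject has flagged or missing segments; "
                "pass allow_partial=True to compute on the available ones")
    elif "ok" in t.columns:
        t = t[t["ok"]]
    if len(t) < 2:
        raise ValueError("need at least 2 usable segments")

    means = t["mean_T2_ms"].to_numpy(dtype=float)
    sds = t["pixel_SD_ms"].to_numpy(dtype=float)
    if np.any(sds < sd_epsilon):
        warnings.warn("zero pixel-SD clamped before log transform")
        sds = np.maximum(sds, sd_epsilon)
    return pd.Series({
        "globalT2": means.mean(),
        "globalSD": sds.mean(),
        "maxT2": means.max(),
        "maxSD": sds.max(),
        "madT2": mad(means, log_transform=False),
        "madSD": mad(sds, log_transform=True),
    })


def features_from_segments(segments: pd.DataFrame, label: str | None = None,
                           **kwargs) -> pd.DataFrame:
    """Per-subject feature table from a stacked multi-subject segment table."""
    rows = []
    for sid, sub in segments.groupby("subject_id", sort=False):
        feats = compute_features(sub, **kwargs)
        feats["subject_id"] = sid
        rows.append(feats)
    out = pd.DataFrame(rows).set_index("subject_id").reset_index()
    if label is not None:
        out.insert(1, "label", label)
    return out
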