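"""Per-stride reduction, measurement QC and the study-level table.

Stride mean and range of motion (max - min) are computed on the raw,
unfiltered angle series within each half-open stride interval; the high-pass
filter is used for event detection only.  Measurements with fewer than five
complete strides are discarded, as are per-stride records with more than 20%
missing frames for a variable.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import MarkerTrajectorySet, TrialMeta
from .segmentation import StrideSegmentation

logger = logging.getLogger(__name__)

MIN_STRIDES = 5  # measurements with fewer complete strides are discarded
MAX_MISSING_FRACTION = 0.2  # per stride and variable

#: column schema of the long-format stride table
TABLE_COLUMNS = (
    "horse",
    "day",
    "trial",
    "path",
    "measurement",
    "stride",
    "variable",
    "stride_mean",
    "stride_rom",
    "speed",
)


def summarize_strides(
    angles: Mapping[str, np.ndarray],
    seg: StrideSegmentation,
    meta: TrialMeta | None = None,
) -> pd.DataFrame:
    """Reduce per-frame series to one row per stride and variable.

    ``angles`` maps variable names to per-frame series (the ``speed`` entry,
    if present, becomes the per-stride speed column rather than a variable
    row).  Strides with more than 20% missing frames for a variable yield no
    row for it; empty intervals are excluded with a log entry.
    """
    meta = meta or TrialMeta()
    speed_series = angles.get("speed")
    rows: list[tuple] = []
    for k, (start, end) in enumerate(seg.strides):
        if end <= start:
            logger.warning("%s: empty stride interval %d, excluded", meta.measurement_id, k)
            continue
        if speed_series is not None:
            sp = float(np.nanmean(speed_series[start:end]))
        else:
            sp = np.nan
        for name, series in angles.items():
            if name == "speed":
                continue
            chunk = np.asarray(series[start:end], dtype=float)
            missing = np.isnan(chunk).mean()
            if missing > MAX_MISSING_FRACTION:
                continue
            vals = chunk[~np.isnan(chunk)]
            rows.append(
                (
                    meta.horse,
                    meta.day,
                    meta.trial,
                    meta.path,
                    meta.measurement_id,
                    k,
                    name,
                    float(vals.mean()),
                    float(vals.max() - vals.min()),
                    sp,
                )
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def qc_filter(records: pd.DataFrame, min_strides: int = MIN_STRIDES) -> pd.DataFrame:
    """Drop measurements with fewer than ``min_strides`` complete strides.

    Surviving rows pass through unchanged; discarded measurements are logged.
    """
    if records.empty:
        return records.copy()
    counts = records.groupby("measurement")["stride"].nunique()
    bad = set(counts.index[counts < min_strides])
    for mid in sorted(bad):
        logger.info(
            "discarding measurement %s: %d strides < %d", mid, counts[mid], min_strides
        )
    return records[~records["measurement"].isin(bad)].reset_index(drop=True)


def aggregate_measurements(table: pd.DataFrame) -> pd.DataFrame:
    """Per-measurement means of stride means and stride ROMs.

    One row per measurement x variable, carrying the horse / day / trial /
    path keys (the descriptive scatterplot level of the analysis).
    """
    if table.empty:
        raise ValueError("cannot aggregate an empty table")
    grouped = (
        table.groupby(["horse", "day", "trial", "path", "measurement", "variable"])
        .agg(
            mean=("stride_mean", "mean"),
            rom=("stride_rom", "mean"),
            speed=("speed", "mean"),
            n_strides=("stride", "nunique"),
        )
        .reset_index()
    )
    return grouped
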