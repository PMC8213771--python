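"""End-to-end orchestration: trajectories -> stride table -> models."""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .io import MarkerTrajectorySet
from .kinematics import compute_all_variables
from .segmentation import StrideDetectionError, segment_strides
from .summaries import MIN_STRIDES, qc_filter, summarize_strides
from .synthetic import SyntheticStudyConfig, generate_study

logger = logging.getLogger(__name__)


def process_trial(t: MarkerTrajectorySet, max_gap: int = 10) -> pd.DataFrame:
    """Per-stride records for one measurement (no study-level QC).

    Gaps of at most ``max_gap`` frames are linearly interpolated first; an
    unrecoverable gap in a required marker marks the whole measurement as
    poor tracking and yields an empty table.
    """
    try:
        t = t.interpolate_gaps(max_gap)
    except ValueError as exc:
        logger.info("discarding %s: %s", t.meta.measurement_id, exc)
        return pd.DataFrame()
    try:
        seg = segment_strides(t)
    except StrideDetectionError as exc:
        logger.info("discarding %s: %s", t.meta.measurement_id, exc)
        return pd.DataFrame()
    angles = compute_all_variables(t, seg)
    return summarize_strides(angles, seg, t.meta)


def process_study(
    trials: Iterable[MarkerTrajectorySet], min_strides: int = MIN_STRIDES
) -> pd.DataFrame:
    """Run the measurement pipeline over a collection of trials and apply
    the < ``min_strides`` discard rule."""
    frames = [df for df in (process_trial(t) for t in trials) if not df.empty]
    if not frames:
        return pd.DataFrame()
    table = pd.concat(frames, ignore_index=True)
    return qc_filter(table, min_strides)


def run_synthetic_study(config: SyntheticStudyConfig) -> pd.DataFrame:
    """Generate a full synthetic study and reduce it to the stride table."""
    return process_study(generate_study(config))
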