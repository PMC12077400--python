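"""End-to-end convenience: frames -> detections -> tracks -> labels -> stats."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior_stats import (
    StatsParams,
    TakeoffStat,
    classify_table,
    normalized_takeoffs,
    participation,
    spontaneous_rate,
    takeoff_response,
    timeseries,
    transitions,
)
from .config import PipelineConfig
from .detect import detect_sequence
from .iocore import FrameSequence
from .stimulus import StimulusSchedule, response_windows
from .track import finalize_tracks, run_tracker

__all__ = ["run_pipeline", "compute_stats"]


def run_pipeline(frames: FrameSequence, config: PipelineConfig | None = None,
                 schedule: StimulusSchedule | None = None,
                 n_total: int | None = None) -> dict:
    """Run detection, tracking, classification and statistics on a video.

    Returns a dict with the labeled trajectory table, the event log, the
    per-track behavior series, and (when a schedule is given) the takeoff
    statistics per response window.
    """
    config = config or PipelineConfig()
    dets = detect_sequence(frames, config.detector, seed=config.seed)
    tracks = run_tracker(dets, config.tracker)
    table, log = finalize_tracks(tracks, config.tracker.min_track_frames, frames.fps)
    bparams = config.behavior.model_copy(update={"fps": frames.fps})
    if len(table):
        table, series = classify_table(table, log, bparams)
    else:
        series = []
    out = {
        "table": table,
        "events": log,
        "series": series,
        "participation": participation(table, frames.n_frames) if len(table) else 0.0,
    }
    if n_total:
        out["timeseries"] = timeseries(table, frames.n_frames, n_total)
    if schedule is not None and len(table):
        out["takeoff_stats"] = compute_stats(
            table, log, schedule, config.stats, frames.fps, frames.n_frames
        )
    return out


def compute_stats(table: pd.DataFrame, log: pd.DataFrame,
                  schedule: StimulusSchedule, params: StatsParams,
                  fps: float, duration_frames: int) -> list[TakeoffStat]:
    """Per-epoch observed takeoff rate, shared baseline, normalized takeoffs."""
    spont_mean, spont_summary = spontaneous_rate(
        table, log, schedule, params, fps, duration_frames
    )
    stats = []
    for window in response_windows(schedule, params.post_window_s, fps):
        st = takeoff_response(table, log, window, params, fps, duration_frames)
        st.spont_mean = spont_mean
        st.spont_samples = spont_summary
        if not st.excluded and np.isfinite(st.obs_rate):
            st.normalized = normalized_takeoffs(st.obs_rate, spont_mean)
        stats.append(st)
    return stats
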