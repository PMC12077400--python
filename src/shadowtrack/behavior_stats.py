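"""Behavioral classification and summary statistics.

A landed mosquito is *searching* when its 1-s centered moving-median walking
speed lies in the 6-52 px/s band (walking faster than 52 px/s was never
observed; the upper bound keeps takeoff lunges out of the searching class),
otherwise *stationary*.  Searching bouts separated by fewer than 30
stationary frames are merged into one contiguous bout.

Transition probabilities between {stationary, searching, takeoff} are
estimated by resampling 2-s bins (~60 contiguous frames) from the labeled
tracks: a bin is scored takeoff if the track takes off within it, else as
the alternative state if that state occupies more than half the bin, else
as its start state.  Stimulus responses are scored per response window: the
landed population is censused 500 ms before stimulus onset and the observed
takeoff rate is the fraction of that population taking off during the
stimulus or up to 1 s after.  The spontaneous baseline is the same score on
2-s windows placed at random stimulus-free times; normalized takeoffs is
observed minus baseline.  Replicates with fewer than 10 landed mosquitoes at
the census are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .stimulus import StimulusSchedule, response_windows

__all__ = [
    "BehaviorParams",
    "StatsParams",
    "BehaviorSeries",
    "TransitionEstimate",
    "TakeoffStat",
    "frame_speed",
    "classify_search",
    "classify_table",
    "transitions",
    "takeoff_response",
    "spontaneous_rate",
    "normalized_takeoffs",
    "participation",
    "timeseries",
    "aggregate_normalized",
]

STATES = ("stationary", "searching", "takeoff")


class BehaviorParams(BaseModel):
    model_config = {"validate_assignment": True}

    median_window_s: float = Field(1.0, gt=0)
    search_speed_min: float = Field(6.0, gt=0)    # px/s, inclusive
    search_speed_max: float = Field(52.0, gt=0)   # px/s, inclusive
    merge_gap_frames: int = Field(30, ge=1)       # strict <
    fps: float = Field(30.0, gt=0)

    @model_validator(mode="after")
    def _check(self):
        if self.search_speed_min >= self.search_speed_max:
            raise ValueError("search_speed_min must be < search_speed_max")
        if self.window_frames < 3:
            raise ValueError("median window must span >= 3 frames")
        return self

    @property
    def window_frames(self) -> int:
        n = int(round(self.median_window_s * self.fps))
        return n + 1 if n % 2 == 0 else n


class StatsParams(BaseModel):
    model_config = {"validate_assignment": True}

    bin_s: float = Field(2.0, gt=0)
    n_transition_samples: int = Field(50_000, gt=0)
    n_spont_samples: int = Field(20_000, gt=0)
    pre_window_s: float = Field(0.5, gt=0)
    post_window_s: float = Field(1.0, gt=0)
    min_landed: int = Field(10, gt=0)
    switch_fraction: float = Field(0.5, gt=0, lt=1)   # strict >
    spont_window_s: float | None = None     # None: use bin_s for baseline windows
    # baseline windows census only insects tracked at least this long; the
    # minimum-track-length rule conditions a track's first second on survival,
    # so censusing younger tracks would bias the baseline downward
    census_min_age_frames: int = Field(30, ge=0)
    seed: int = 0

    def bin_frames(self, fps: float) -> int:
        return int(round(self.bin_s * fps))


@dataclass
class BehaviorSeries:
    """Per-frame behavior labels of one track."""

    track_id: int
    start_frame: int
    labels: np.ndarray            # 1 = stationary, 2 = searching (per visible frame)
    terminal_takeoff: bool
    takeoff_frame: int | None = None


@dataclass
class TransitionEstimate:
    """2-s bin transition probabilities from each start state."""

    matrix: pd.DataFrame          # index stationary/searching, columns STATES
    n_valid: dict[str, int]

    def __getitem__(self, key: tuple[str, str]) -> float:
        return float(self.matrix.loc[key[0], key[1]])


@dataclass
class TakeoffStat:
    """Observed vs spontaneous takeoff rates for one response window."""

    n_landed_pre: int
    n_takeoff_obs: int
    obs_rate: float
    spont_mean: float | None = None
    spont_samples: dict | None = None
    normalized: float | None = None
    excluded: bool = False


# ---------------------------------------------------------------------------
# Speed and classification
# ---------------------------------------------------------------------------

def frame_speed(xy: np.ndarray, fps: float) -> np.ndarray:
    """Per-frame speed in px/s; speed[0] duplicates speed[1]."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        raise ValueError("need >= 2 frames to compute speed")
    disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    speed = np.empty(len(xy))
    speed[1:] = disp * fps
    speed[0] = speed[1]
    return speed


def _merge_short_gaps(searching: np.ndarray, max_gap: int) -> np.ndarray:
    """Relabel stationary gaps shorter than ``max_gap`` frames that sit
    between two searching bouts."""
    out = searching.copy()
    n = len(out)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], (~out).astype(int), [0]])))
    # runs of stationary frames: pairs (start, stop)
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s < max_gap and s > 0 and e < n:
            out[s:e] = True
    return out


def classify_search(xy: np.ndarray, params: BehaviorParams,
                    track_id: int = 0, start_frame: int = 0,
                    terminal_takeoff: bool = False,
                    takeoff_frame: int | None = None) -> BehaviorSeries:
    """Label each visible frame stationary/searching from the track path."""
    speed = frame_speed(xy, params.fps)
    med = (pd.Series(speed)
           .rolling(params.window_frames, center=True, min_periods=1)
           .median()
           .to_numpy())
    searching = (med >= params.search_speed_min) & (med <= params.search_speed_max)
    searching = _merge_short_gaps(searching, params.merge_gap_frames)
    labels = np.where(searching, 2, 1).astype(np.int8)
    return BehaviorSeries(track_id=track_id, start_frame=start_frame,
                          labels=labels, terminal_takeoff=terminal_takeoff,
                          takeoff_frame=takeoff_frame)


def classify_table(table: pd.DataFrame, log: pd.DataFrame,
                   params: BehaviorParams) -> tuple[pd.DataFrame, list[BehaviorSeries]]:
    """Classify every track in a trajectory table.

    Returns the table with ``speed_px_per_s`` and ``behavior_label`` filled
    in, plus the per-track :class:`BehaviorSeries`.
    """
    table = table.sort_values(["track_id", "frame_idx"]).reset_index(drop=True)
    takeoff_ids = set(log.loc[log.event_type == "takeoff", "track_id"])
    series = []
    speeds = np.full(len(table), np.nan)
    labels = np.empty(len(table), dtype=object)
    pos = 0
    for tid, grp in table.groupby("track_id", sort=True):
        xy = grp[["x_px", "y_px"]].to_numpy()
        sp = frame_speed(xy, params.fps)
        bs = classify_search(
            xy, params, track_id=int(tid),
            start_frame=int(grp.frame_idx.iloc[0]),
            terminal_takeoff=tid in takeoff_ids,
            takeoff_frame=int(grp.frame_idx.iloc[-1]) if tid in takeoff_ids else None,
        )
        k = len(grp)
        speeds[pos:pos + k] = sp
        labels[pos:pos + k] = np.where(bs.labels == 2, "searching", "stationary")
        series.append(bs)
        pos += k
    out = table.copy()
    out["speed_px_per_s"] = speeds
    out["behavior_label"] = labels
    return out, series


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------

def transitions(series_set: list[BehaviorSeries], params: StatsParams,
                fps: float = 30.0, exhaustive: bool = False) -> TransitionEstimate:
    """Estimate 2-s bin transition probabilities from labeled tracks.

    Bins are drawn uniformly over all (track, start-frame) positions; bins
    running past the end of a takeoff track are scored takeoff, while start
    positions within one bin of a non-takeoff track end are not valid (they
    would be censored).  ``exhaustive`` enumerates every valid bin instead
    of sampling; sampling is deterministic under ``params.seed``.
    """
    n = params.bin_frames(fps)
    majority = n // 2 + 1
    valid_per_track = []
    for bs in series_set:
        n_start = len(bs.labels) if bs.terminal_takeoff else len(bs.labels) - n + 1
        valid_per_track.append(max(0, n_start))
    total = int(np.sum(valid_per_track))
    if total == 0:
        raise ValueError("no track offers a full 2-s bin")

    counts = np.zeros((2, 3), dtype=np.int64)     # rows S, R; cols stay/switch/TO

    def tally(bs: BehaviorSeries, starts: np.ndarray):
        labels = bs.labels
        alt_of = {1: 2, 2: 1}
        # vectorized scoring over starts
        starts = np.asarray(starts)
        if len(starts) == 0:
            return
        start_states = labels[starts]
        # the takeoff happens at the track's last labeled frame, so any bin
        # reaching that frame (starts + n >= len) contains it
        truncated = bs.terminal_takeoff & (starts + n >= len(labels))
        pad = np.concatenate([(labels == 2).astype(np.int64), np.zeros(n, dtype=np.int64)])
        csum = np.concatenate([[0], np.cumsum(pad)])
        searching_frames = csum[starts + n] - csum[starts]
        for st in (1, 2):
            sel = start_states == st
            if not sel.any():
                continue
            alt = alt_of[st]
            alt_frames = searching_frames[sel] if alt == 2 else (
                np.minimum(starts[sel] + n, len(labels)) - starts[sel] - searching_frames[sel]
            )
            # note: for truncated windows alt_frames is not used
            trunc = truncated[sel]
            switched = (alt_frames >= majority) & ~trunc
            row = 0 if st == 1 else 1
            counts[row, 2] += int(trunc.sum())
            counts[row, 1] += int(switched.sum())
            counts[row, 0] += int((~trunc & ~switched).sum())

    if exhaustive:
        for bs, nv in zip(series_set, valid_per_track):
            tally(bs, np.arange(nv))
    else:
        rng = np.random.default_rng(params.seed)
        cum = np.concatenate([[0], np.cumsum(valid_per_track)])
        draws = rng.integers(0, total, size=params.n_transition_samples)
        track_of = np.searchsorted(cum, draws, side="right") - 1
        for ti in np.unique(track_of):
            starts = draws[track_of == ti] - cum[ti]
            tally(series_set[ti], starts)

    mat = np.full((2, 3), np.nan)
    n_valid = {}
    for row, name in enumerate(("stationary", "searching")):
        tot = counts[row].sum()
        n_valid[name] = int(tot)
        if tot:
            mat[row] = counts[row] / tot
    # matrix rows are start states, columns end states: row "stationary" is
    # (stay, switch, takeoff) and row "searching" is (switch, stay, takeoff)
    df = pd.DataFrame(
        [[mat[0, 0], mat[0, 1], mat[0, 2]],
         [mat[1, 1], mat[1, 0], mat[1, 2]]],
        index=["stationary", "searching"],
        columns=["stationary", "searching", "takeoff"],
    )
    return TransitionEstimate(matrix=df, n_valid=n_valid)


# ---------------------------------------------------------------------------
# Takeoff statistics
# ---------------------------------------------------------------------------

def _visible_ids_at(table: pd.DataFrame, frame: int) -> np.ndarray:
    return table.loc[table.frame_idx == frame, "track_id"].to_numpy()


def takeoff_response(table: pd.DataFrame, log: pd.DataFrame,
                     window: tuple[int, int], params: StatsParams,
                     fps: float = 30.0, duration_frames: int | None = None) -> TakeoffStat:
    """Observed takeoff rate for one stimulus response window."""
    start, stop = window
    if duration_frames is not None and (start < 0 or stop > duration_frames):
        raise ValueError(f"response window {window} outside the video")
    census_frame = start - int(round(params.pre_window_s * fps))
    if census_frame < 0:
        raise ValueError("response window starts before the census lead time")
    present = _visible_ids_at(table, census_frame)
    n_landed = len(present)
    to = log[(log.event_type == "takeoff")
             & (log.frame_idx >= start) & (log.frame_idx < stop)
             & (log.track_id.isin(present))]
    n_obs = len(to)
    obs_rate = n_obs / n_landed if n_landed else float("nan")
    return TakeoffStat(
        n_landed_pre=n_landed, n_takeoff_obs=n_obs, obs_rate=obs_rate,
        excluded=n_landed < params.min_landed,
    )


def spontaneous_rate(table: pd.DataFrame, log: pd.DataFrame,
                     schedule: StimulusSchedule | None, params: StatsParams,
                     fps: float = 30.0,
                     duration_frames: int | None = None) -> tuple[float, dict]:
    """Baseline takeoff rate from randomly placed stimulus-free windows.

    Windows have duration ``spont_window_s`` (default: the 2-s bin), must
    not overlap any stimulus response window, and are scored like a response
    window censused at the window start.  Deterministic under
    ``params.seed``.
    """
    if duration_frames is None:
        duration_frames = int(table.frame_idx.max()) + 1 if len(table) else 0
    win_s = params.spont_window_s if params.spont_window_s is not None else params.bin_s
    win = int(round(win_s * fps))
    if duration_frames <= win:
        raise ValueError("recording shorter than one baseline window")
    blocked = np.zeros(duration_frames, dtype=bool)
    if schedule is not None:
        for s, e in response_windows(schedule, params.post_window_s, fps):
            blocked[max(0, s - win + 1):min(e, duration_frames)] = True
    candidates = np.nonzero(~blocked[: duration_frames - win + 1])[0]
    if len(candidates) == 0:
        raise ValueError("no stimulus-free time available for baseline windows")

    rng = np.random.default_rng(params.seed)
    starts = rng.choice(candidates, size=params.n_spont_samples, replace=True)

    # per-frame counts of census-eligible tracks (present and older than the
    # minimum age); a takeoff counts toward a window only if its track was
    # census-eligible at the window start
    age = params.census_min_age_frames
    spans = table.groupby("track_id").frame_idx.agg(["min", "max"])
    count_diff = np.zeros(duration_frames + 1, dtype=np.int64)
    for r in spans.itertuples():
        lo, hi = int(r.min) + age, int(r.max)
        if hi >= lo:
            count_diff[lo] += 1
            count_diff[hi + 1] -= 1
    counts = np.cumsum(count_diff[:-1])
    to = log[log.event_type == "takeoff"]
    per_start = np.zeros(duration_frames + 1, dtype=np.int64)
    for r in to.itertuples():
        lo = max(int(spans["min"].get(r.track_id, 0)) + age,
                 int(r.frame_idx) - win + 1)
        hi = int(r.frame_idx)          # valid census frames are [lo, hi]
        if hi >= lo:
            per_start[lo] += 1
            per_start[hi + 1] -= 1
    n_to_at = np.cumsum(per_start[:-1])

    n_landed = counts[starts]
    n_to = n_to_at[starts]
    ok = n_landed > 0
    rates = np.full(len(starts), np.nan)
    rates[ok] = n_to[ok] / n_landed[ok]
    valid = rates[ok]
    if len(valid) == 0:
        raise ValueError("no baseline window had a landed mosquito")
    mean = float(np.mean(valid))
    summary = {
        "mean": mean,
        "sd": float(np.std(valid)),
        "n": int(len(valid)),
        "quantiles": {q: float(np.quantile(valid, q))
                      for q in (0.05, 0.25, 0.5, 0.75, 0.95)},
    }
    return mean, summary


def normalized_takeoffs(obs_rate: float, spont_mean: float) -> float:
    """Observed minus spontaneous takeoff rate (0 = no effect)."""
    for name, v in (("obs_rate", obs_rate), ("spont_mean", spont_mean)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be within [0, 1], got {v}")
    return obs_rate - spont_mean


def participation(table: pd.DataFrame, duration_frames: int) -> float:
    """Mean number of landed mosquitoes per frame over the recording."""
    if duration_frames <= 0:
        raise ValueError("duration_frames must be > 0")
    return float(len(table) / duration_frames)


def timeseries(table: pd.DataFrame, duration_frames: int, n_total: int) -> pd.DataFrame:
    """Per-frame percent landed, percent of landed searching, and mean x."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    frames = np.arange(duration_frames)
    counts = np.bincount(table.frame_idx.to_numpy(), minlength=duration_frames)[:duration_frames]
    pct_landed = counts / n_total * 100.0
    sum_x = np.bincount(table.frame_idx.to_numpy(),
                        weights=table.x_px.to_numpy(), minlength=duration_frames)[:duration_frames]
    mean_x = np.divide(sum_x, counts, out=np.full(duration_frames, np.nan),
                       where=counts > 0)
    if "behavior_label" in table.columns and table.behavior_label.notna().any():
        searching = table.behavior_label.eq("searching").to_numpy().astype(float)
        n_search = np.bincount(table.frame_idx.to_numpy(), weights=searching,
                               minlength=duration_frames)[:duration_frames]
        pct_search = np.divide(n_search, counts,
                               out=np.full(duration_frames, np.nan),
                               where=counts > 0) * 100.0
    else:
        pct_search = np.full(duration_frames, np.nan)
    return pd.DataFrame({
        "frame_idx": frames,
        "percent_landed": pct_landed,
        "percent_searching_of_landed": pct_search,
        "mean_x_of_landed": mean_x,
    })


def aggregate_normalized(stats: list[TakeoffStat]) -> tuple[float, float, int]:
    """Mean +/- SEM of normalized takeoffs over non-excluded replicates."""
    vals = [s.normalized for s in stats if not s.excluded and s.normalized is not None]
    if not vals:
        return float("nan"), float("nan"), 0
    arr = np.asarray(vals, dtype=float)
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return float(arr.mean()), sem, len(arr)
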