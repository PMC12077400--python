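"""Frame-to-frame identity maintenance.

Each landed insect is followed with a 2-D constant-velocity Kalman filter;
per frame, Kalman-predicted positions are matched to detections by solving
the global rectangular assignment problem (Hungarian algorithm) and then
rejecting matched pairs at Euclidean distance >= ``gate_px`` (strict <10 px
by default, which also keeps flying insects — faster than 10 px/frame —
from being matched).  Tracks unseen for more than ``max_invisible`` (6)
consecutive frames are closed and flagged as takeoff candidates; tracks
shorter than ``min_track_frames`` (30 frames, 1 s) are discarded before any
behavioral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.optimize import linear_sum_assignment

from .iocore import EVENT_COLUMNS, TRACK_COLUMNS, validate_events, validate_tracks
from .detect import Detection

__all__ = [
    "TrackerParams",
    "KalmanState",
    "Track",
    "kalman_predict",
    "kalman_update",
    "assign",
    "step_tracker",
    "run_tracker",
    "finalize_tracks",
]


class TrackerParams(BaseModel):
    """Tracking constants; distances in px, velocities in px/frame."""

    model_config = {"validate_assignment": True}

    gate_px: float = Field(10.0, gt=0)          # strict upper bound on match distance
    max_invisible: int = Field(6, ge=0)
    min_track_frames: int = Field(30, ge=1)
    process_noise_pos: float = Field(1.0, gt=0)
    process_noise_vel: float = Field(0.5, gt=0)
    measurement_noise: float = Field(1.0, gt=0)
    initial_pos_var: float = Field(4.0, gt=0)
    initial_vel_var: float = Field(25.0, gt=0)
    pre_gate: bool = False                      # gate the cost matrix before solving


# State transition and observation matrices for the constant-velocity model;
# state is (x, y, vx, vy) in px and px/frame.
_F = np.array([[1.0, 0, 1, 0],
               [0, 1.0, 0, 1],
               [0, 0, 1.0, 0],
               [0, 0, 0, 1.0]])
_H = np.array([[1.0, 0, 0, 0],
               [0, 1.0, 0, 0]])


@dataclass
class KalmanState:
    mean: np.ndarray        # (x, y, vx, vy)
    covariance: np.ndarray  # 4x4 symmetric positive-definite

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.mean.shape != (4,) or self.covariance.shape != (4, 4):
            raise ValueError("KalmanState needs a 4-vector mean and 4x4 covariance")
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.covariance))):
            raise ValueError("non-finite Kalman state")

    @property
    def position(self) -> np.ndarray:
        return self.mean[:2]


def initial_state(x: float, y: float, params: TrackerParams) -> KalmanState:
    """New-track prior: observed position, zero velocity, wide velocity variance."""
    cov = np.diag([params.initial_pos_var, params.initial_pos_var,
                   params.initial_vel_var, params.initial_vel_var])
    return KalmanState(np.array([x, y, 0.0, 0.0]), cov)


def kalman_predict(s: KalmanState, params: TrackerParams) -> KalmanState:
    """Advance one frame under constant velocity; covariance grows by Q."""
    q = np.diag([params.process_noise_pos, params.process_noise_pos,
                 params.process_noise_vel, params.process_noise_vel])
    return KalmanState(_F @ s.mean, _F @ s.covariance @ _F.T + q)


def kalman_update(s: KalmanState, z, params: TrackerParams) -> KalmanState:
    """Standard linear-Gaussian measurement update with measurement z=(x, y)."""
    z = np.asarray(z, dtype=float)
    if z.shape != (2,) or not np.all(np.isfinite(z)):
        raise ValueError("measurement must be a finite (x, y) pair")
    r = params.measurement_noise * np.eye(2)
    innov = z - _H @ s.mean
    s_cov = _H @ s.covariance @ _H.T + r
    gain = s.covariance @ _H.T @ np.linalg.inv(s_cov)
    mean = s.mean + gain @ innov
    # Joseph form keeps the posterior covariance symmetric positive-definite
    a = np.eye(4) - gain @ _H
    cov = a @ s.covariance @ a.T + gain @ r @ gain.T
    return KalmanState(mean, cov)


def assign(predicted, detections, gate_px: float = 10.0, pre_gate: bool = False):
    """Optimal assignment of predicted track positions to detections.

    Parameters
    ----------
    predicted
        Sequence of ``(track_id, x, y)``.
    detections
        Sequence of :class:`Detection` (or ``(x, y)`` pairs).
    gate_px
        Strict upper bound: assigned pairs at distance >= gate are discarded
        and their members returned as unmatched.
    pre_gate
        Solve with gated (infinite) costs instead of gating afterwards.

    Returns
    -------
    matches
        List of ``(track_id, detection_index, distance)``.
    unmatched_tracks, unmatched_detections
        Lists of track ids / detection indices.
    """
    track_ids = [p[0] for p in predicted]
    if not predicted or not detections:
        return [], list(track_ids), list(range(len(detections)))
    ppos = np.array([[p[1], p[2]] for p in predicted], dtype=float)
    dpos = np.array(
        [d.centroid if isinstance(d, Detection) else tuple(d) for d in detections],
        dtype=float,
    )
    cost = np.linalg.norm(ppos[:, None, :] - dpos[None, :, :], axis=2)
    if pre_gate:
        big = 1e9
        solver_cost = np.where(cost < gate_px, cost, big)
    else:
        solver_cost = cost
    rows, cols = linear_sum_assignment(solver_cost)
    matches, mt, md = [], set(), set()
    for r, c in zip(rows, cols):
        if cost[r, c] < gate_px:
            matches.append((track_ids[r], int(c), float(cost[r, c])))
            mt.add(track_ids[r])
            md.add(int(c))
    unmatched_tracks = [t for t in track_ids if t not in mt]
    unmatched_detections = [i for i in range(len(detections)) if i not in md]
    return matches, unmatched_tracks, unmatched_detections


@dataclass
class Track:
    """Identity-resolved trajectory of one landed insect."""

    id: int
    history: list[tuple[int, float, float, bool]] = field(default_factory=list)
    kstate: KalmanState | None = None
    invisible_streak: int = 0
    status: str = "active"          # active | lost
    end_reason: str = "none"        # none | takeoff_candidate | video_end

    @property
    def start_frame(self) -> int:
        return self.history[0][0]

    @property
    def last_frame(self) -> int:
        return self.history[-1][0]

    @property
    def last_observed_frame(self) -> int:
        for frame_idx, _, _, observed in reversed(self.history):
            if observed:
                return frame_idx
        return self.history[0][0]

    def trim_predicted_tail(self) -> None:
        while self.history and not self.history[-1][3]:
            self.history.pop()


def step_tracker(tracks: list[Track], detections: list[Detection], frame_idx: int,
                 params: TrackerParams | None = None) -> list[Track]:
    """Advance the tracker by one frame (mutates and returns ``tracks``).

    Active tracks are predicted and matched; matches are Kalman-updated and
    recorded as observed, unmatched tracks coast on their prediction, and
    tracks invisible for more than ``max_invisible`` frames are closed as
    takeoff candidates (their predicted-only tail is trimmed so the track
    ends at its last observation).  Unmatched detections seed new tracks.
    """
    params = params or TrackerParams()
    for d in detections:
        if d.frame_idx != frame_idx:
            raise ValueError(
                f"detection from frame {d.frame_idx} fed to tracker step {frame_idx}"
            )
    active = [t for t in tracks if t.status == "active"]
    predicted = []
    for t in active:
        t.kstate = kalman_predict(t.kstate, params)
        predicted.append((t.id, t.kstate.position[0], t.kstate.position[1]))
    matches, unmatched_tracks, unmatched_dets = assign(
        predicted, detections, params.gate_px, params.pre_gate
    )
    by_id = {t.id: t for t in active}
    for tid, di, _ in matches:
        t = by_id[tid]
        z = detections[di].centroid
        t.kstate = kalman_update(t.kstate, z, params)
        t.history.append((frame_idx, z[0], z[1], True))
        t.invisible_streak = 0
    for tid in unmatched_tracks:
        t = by_id[tid]
        x, y = t.kstate.position
        t.history.append((frame_idx, float(x), float(y), False))
        t.invisible_streak += 1
        if t.invisible_streak > params.max_invisible:
            t.status = "lost"
            t.end_reason = "takeoff_candidate"
            t.trim_predicted_tail()
    next_id = max((t.id for t in tracks), default=-1) + 1
    for di in unmatched_dets:
        x, y = detections[di].centroid
        t = Track(id=next_id, history=[(frame_idx, x, y, True)],
                  kstate=initial_state(x, y, params))
        tracks.append(t)
        next_id += 1
    return tracks


def run_tracker(detections_per_frame: list[list[Detection]],
                params: TrackerParams | None = None) -> list[Track]:
    """Run the tracker over per-frame detection lists for a whole video."""
    params = params or TrackerParams()
    tracks: list[Track] = []
    for frame_idx, dets in enumerate(detections_per_frame):
        step_tracker(tracks, dets, frame_idx, params)
    for t in tracks:
        if t.status == "active":
            t.end_reason = "video_end"
            t.trim_predicted_tail()
    return tracks


def finalize_tracks(tracks: list[Track], min_track_frames: int = 30,
                    fps: float = 30.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop sub-threshold tracks and emit the trajectory table + event log.

    Tracks spanning fewer than ``min_track_frames`` frames are excluded.
    Every surviving track emits a landing event at its first frame; tracks
    closed as takeoff candidates emit a takeoff at their last observed
    frame, and tracks alive at the video end a ``track_lost_at_video_end``.
    """
    rows, events = [], []
    for t in tracks:
        if not t.history or len(t.history) < min_track_frames:
            continue
        for frame_idx, x, y, observed in t.history:
            rows.append((t.id, frame_idx, frame_idx / fps, x, y, observed))
        f0, x0, y0, _ = t.history[0]
        events.append(("landing", t.id, f0, f0 / fps, x0, y0))
        fl, xl, yl, _ = t.history[-1]
        if t.end_reason == "takeoff_candidate":
            events.append(("takeoff", t.id, fl, fl / fps, xl, yl))
        else:
            events.append(("track_lost_at_video_end", t.id, fl, fl / fps, xl, yl))
    table = pd.DataFrame(rows, columns=TRACK_COLUMNS[:6])
    log = pd.DataFrame(events, columns=EVENT_COLUMNS)
    if len(table):
        table["speed_px_per_s"] = np.nan
        table["behavior_label"] = pd.NA
    else:
        table = pd.DataFrame(columns=TRACK_COLUMNS)
        log = pd.DataFrame(columns=EVENT_COLUMNS)
    return validate_tracks(table), validate_events(log, table)
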