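"""Agent-based cohort simulator and IR frame renderer.

The simulator emulates a cage of ~30 host-seeking mosquitoes on the back
wall: agents land (Poisson), alternate stationary and searching bouts,
take off spontaneously, and respond to shadow epochs with evoked takeoffs
(fast edges) or freezing (slow edges).  The behavioral core is a per-frame
Markov chain over {stationary, searching} with an absorbing takeoff; its
per-frame hazards are calibrated so that the chain's *scored* 2-s transition
probabilities — scored exactly the way the statistics module scores sampled
2-s bins (takeoff if one occurs in the bin, else the alternative state if it
occupies >50% of frames, else the start state) — equal the configured
probabilities.  The forward map from hazards to scored probabilities is an
exact dynamic program (:func:`scored_transition_probs`), which doubles as an
independent oracle in the tests.

The renderer draws each on-wall agent as a dark anisotropic Gaussian spot on
a bright background with additive Gaussian noise, emulating the IR view of
the assay (the visible-light shadow is invisible to the IR camera and is
never rendered).  Every stage is deterministic under its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import least_squares

from .iocore import EVENT_COLUMNS, TRACK_COLUMNS, FrameSequence, validate_tracks
from .stimulus import Polarity, Direction, StimulusEpoch, StimulusSchedule

__all__ = [
    "AgentParams",
    "RenderParams",
    "GroundTruth",
    "scored_transition_probs",
    "calibrate_frame_hazards",
    "simulate_cohort",
    "render_frames",
    "silhouette_areas",
    "write_ground_truth",
    "read_ground_truth",
    "truth_to_tracks",
    "truth_occupancy",
    "match_takeoffs",
]

OFF_WALL, STATIONARY, SEARCHING = 0, 1, 2
_STATE_NAMES = {OFF_WALL: "off_wall", STATIONARY: "stationary", SEARCHING: "searching"}

GT_EVENT_TYPES = {"landing", "spontaneous_takeoff", "evoked_takeoff", "freeze_onset"}


class AgentParams(BaseModel):
    """Behavioral parameters of the simulated cohort.

    The three ``p_*_2s`` transition probabilities are *scored* 2-s bin
    probabilities (see module docstring); per-frame hazards are derived from
    them by exact calibration.  ``p_spont_takeoff_2s`` may be overridden per
    state with ``p_spont_takeoff_stationary_2s`` / ``..._searching_2s``.
    Evoked takeoff probabilities are per encounter (sampled once per agent
    per epoch) and are scaled by a logistic in edge speed and by a polarity
    factor, so fast OFF edges are maximally aversive while slow ON edges
    barely register.
    """

    model_config = {"validate_assignment": True}

    n_agents: int = Field(30, ge=1)
    landing_rate: float = Field(0.04, gt=0)          # landings / agent / s
    relanding_delay_mean: float = Field(12.0, gt=0)  # s; >60% re-land within 20 s
    stationary_bout_mean: float = Field(2.1, gt=0)   # s; implied by the hazards
    searching_bout_mean: float = Field(8.0, gt=0)    # s; implied by the hazards
    walk_speed_range: tuple[float, float] = (10.0, 45.0)   # px/s, within [6, 52]
    p_spont_takeoff_2s: float = Field(0.13, ge=0, le=1)
    p_spont_takeoff_stationary_2s: float | None = None
    p_spont_takeoff_searching_2s: float | None = None
    # scored 2-s switch probabilities; set both to None to parametrize the
    # chain by the exponential bout means instead
    p_stationary_to_search_2s: float | None = Field(0.38, ge=0, le=1)
    p_search_to_stationary_2s: float | None = Field(0.08, ge=0, le=1)
    p_evoked_takeoff_stationary: float = Field(0.87, ge=0, le=1)
    p_evoked_takeoff_searching: float = Field(0.93, ge=0, le=1)
    p_freeze_given_slow_stimulus: float = Field(0.5, ge=0, le=1)
    fast_speed_threshold_cm_s: float = Field(15.0, gt=0)
    evoked_v50_cm_s: float = 8.0      # logistic midpoint of speed-graded aversion
    evoked_width_cm_s: float = 3.0
    on_edge_factor: float = Field(0.4, ge=0, le=1)
    flash_off_factor: float = Field(0.5, ge=0, le=1)
    flash_on_factor: float = Field(0.02, ge=0, le=1)
    takeoff_latency_range_s: tuple[float, float] = (0.05, 0.35)
    turn_rate_rad_sqrt_s: float = Field(1.5, gt=0)
    min_separation_px: float = Field(16.0, ge=0)
    margin_px: float = Field(12.0, ge=0)

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.walk_speed_range
        if not (0 < lo < hi):
            raise ValueError("walk_speed_range must be ordered and positive")
        return self

    @property
    def p_takeoff_stationary_2s(self) -> float:
        p = self.p_spont_takeoff_stationary_2s
        return self.p_spont_takeoff_2s if p is None else p

    @property
    def p_takeoff_searching_2s(self) -> float:
        p = self.p_spont_takeoff_searching_2s
        return self.p_spont_takeoff_2s if p is None else p


class RenderParams(BaseModel):
    """Rendering constants for the synthetic IR view.

    Blob spatial scales and contrasts are drawn per agent from the given
    ranges; the defaults put every half-depth silhouette inside
    ``area_band`` (verified by :func:`silhouette_areas`, and enforced at
    render time when ``enforce_area_band`` is set).
    """

    model_config = {"validate_assignment": True}

    width: int = Field(640, ge=32)
    height: int = Field(480, ge=32)
    fps: float = Field(30.0, gt=0)
    background_level: int = Field(200, ge=1, le=255)
    noise_sd: float = Field(2.0, ge=0)
    contrast_range: tuple[float, float] = (100.0, 130.0)
    sigma_x_range: tuple[float, float] = (2.4, 2.7)
    sigma_y_range: tuple[float, float] = (1.95, 2.1)
    area_band: tuple[int, int] = (20, 60)
    enforce_area_band: bool = True
    illumination_drift: float = Field(0.0, ge=0, le=0.5)  # robustness stressor
    patch_radius: int = Field(14, ge=4)

    @model_validator(mode="after")
    def _check(self):
        if self.contrast_range[0] <= self.noise_sd:
            raise ValueError("blob contrast must exceed noise_sd")
        return self


@dataclass
class GroundTruth:
    """Exact per-frame states, positions and events of a simulated cohort."""

    states: np.ndarray        # (n_frames, n_agents) int8: 0 off_wall, 1 stationary, 2 searching
    positions: np.ndarray     # (n_frames, n_agents, 2) float, NaN while off wall
    events: pd.DataFrame      # event_type, agent_id, frame_idx, time_s, x_px, y_px
    fps: float
    canvas: tuple[int, int]   # (width, height)

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_agents(self) -> int:
        return self.states.shape[1]

    def takeoff_events(self) -> pd.DataFrame:
        return self.events[
            self.events.event_type.isin(["spontaneous_takeoff", "evoked_takeoff"])
        ].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Scored 2-s transition probabilities: exact forward model + calibration
# ---------------------------------------------------------------------------

def scored_transition_probs(a: float, b: float, h_s: float, h_r: float,
                            n_frames: int = 60) -> np.ndarray:
    """Exact scored bin probabilities of the per-frame chain.

    Per frame an agent in state S(tationary) takes off with probability
    ``h_s``, else switches to R (searching) with probability ``a``; from R it
    takes off with ``h_r``, else switches back with ``b``.  A bin of
    ``n_frames`` frames starting in a given state is scored takeoff if the
    agent takes off before the bin ends, else as the alternative state if
    that state occupies more than half the frames, else as the start state.

    Returns a 2x3 array, rows (start stationary, start searching), columns
    (stay, switch, takeoff).  Computed by dynamic programming over
    (state, frames-in-alternative-state); this is exact, not simulated.
    """
    n_steps = n_frames - 1
    majority = n_frames // 2 + 1     # strict > 50% of the bin's frames
    out = np.zeros((2, 3))
    for row, start in enumerate((STATIONARY, SEARCHING)):
        # p[state_idx, c] = P(in state, c frames spent in the alternative state)
        p = np.zeros((2, n_frames + 1))
        p[0 if start == STATIONARY else 1, 0] = 1.0
        absorbed = 0.0
        for _ in range(n_steps):
            absorbed += p[0].sum() * h_s + p[1].sum() * h_r
            s_stay = p[0] * (1 - h_s) * (1 - a)
            s_go = p[0] * (1 - h_s) * a
            r_stay = p[1] * (1 - h_r) * (1 - b)
            r_go = p[1] * (1 - h_r) * b
            new = np.zeros_like(p)
            if start == STATIONARY:       # alternative state is R
                new[0] = s_stay + r_go
                new[1, 1:] = (s_go + r_stay)[:-1]
            else:                         # alternative state is S
                new[1] = r_stay + s_go
                new[0, 1:] = (r_go + s_stay)[:-1]
            p = new
        # the takeoff hazard also applies on the step leaving the last bin frame
        absorbed += p[0].sum() * h_s + p[1].sum() * h_r
        p_alt = p[:, majority:].sum()
        out[row] = (1.0 - absorbed - p_alt, p_alt, absorbed)
    return out


_HAZARD_CACHE: dict[tuple, tuple[float, float, float, float]] = {}


def calibrate_frame_hazards(p_s_switch: float, p_s_takeoff: float,
                            p_r_switch: float, p_r_takeoff: float,
                            n_frames: int = 60) -> tuple[float, float, float, float]:
    """Invert :func:`scored_transition_probs`: per-frame hazards (a, b, h_s, h_r)
    whose scored bin probabilities match the four targets."""
    key = (round(p_s_switch, 6), round(p_s_takeoff, 6),
           round(p_r_switch, 6), round(p_r_takeoff, 6), n_frames)
    if key in _HAZARD_CACHE:
        return _HAZARD_CACHE[key]

    targets = np.array([p_s_switch, p_s_takeoff, p_r_switch, p_r_takeoff])

    def unpack(u):
        return 1.0 / (1.0 + np.exp(-u))     # keep hazards in (0, 1)

    def resid(u):
        a, b, h_s, h_r = unpack(u)
        m = scored_transition_probs(a, b, h_s, h_r, n_frames)
        return np.array([m[0, 1], m[0, 2], m[1, 1], m[1, 2]]) - targets

    # geometric-decay initial guesses: switches act over ~half a bin,
    # takeoff hazard over the whole bin
    eps = 1e-6
    g = np.clip([
        1 - (1 - p_s_switch) ** (2.0 / n_frames),
        1 - (1 - p_s_takeoff) ** (1.0 / n_frames),
        1 - (1 - p_r_switch) ** (2.0 / n_frames),
        1 - (1 - p_r_takeoff) ** (1.0 / n_frames),
    ], eps, 1 - eps)
    u0 = np.log(g / (1 - g))
    sol = least_squares(resid, u0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    a, b, h_s, h_r = (float(v) for v in unpack(sol.x))
    achieved = scored_transition_probs(a, b, h_s, h_r, n_frames)
    err = np.max(np.abs([achieved[0, 1] - p_s_switch, achieved[0, 2] - p_s_takeoff,
                         achieved[1, 1] - p_r_switch, achieved[1, 2] - p_r_takeoff]))
    if err > 1e-6:
        raise RuntimeError(f"hazard calibration did not converge (residual {err:.2e})")
    _HAZARD_CACHE[key] = (a, b, h_s, h_r)
    return a, b, h_s, h_r


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _edge_crossing_time(epoch: StimulusEpoch, x: float, y: float,
                        width: int, height: int) -> float | None:
    """Time at which the sweeping edge passes an agent, or None if the sweep
    stops short of the agent (partial coverage)."""
    if epoch.is_flash:
        return epoch.t_start
    span = width if epoch.direction in (Direction.LEFT, Direction.RIGHT) else height
    px_per_cm = span / epoch.wall_extent_cm
    coord = x if epoch.direction in (Direction.LEFT, Direction.RIGHT) else y
    if epoch.direction in (Direction.LEFT, Direction.UP):
        dist_px = span - coord
    else:
        dist_px = coord
    travel_px = epoch.coverage * span
    if dist_px > travel_px:
        return None
    return epoch.t_start + (dist_px / px_per_cm) / epoch.edge_speed


def _speed_scale(epoch: StimulusEpoch, p: AgentParams) -> float:
    if epoch.is_flash:
        return 1.0
    return 1.0 / (1.0 + math.exp(-(epoch.edge_speed - p.evoked_v50_cm_s)
                                 / p.evoked_width_cm_s))


def _polarity_factor(epoch: StimulusEpoch, p: AgentParams) -> float:
    return {
        Polarity.OFF_EDGE: 1.0,
        Polarity.ON_EDGE: p.on_edge_factor,
        Polarity.FLASH_OFF: p.flash_off_factor,
        Polarity.FLASH_ON: p.flash_on_factor,
        Polarity.NONE: 0.0,
    }[epoch.polarity]


def _place(rng, pos, on_wall, width, height, margin, min_sep):
    """Draw a landing position away from walls and from other landed agents."""
    for _ in range(50):
        cand = rng.uniform([margin, margin], [width - margin, height - margin])
        occupied = pos[on_wall]
        if len(occupied) == 0 or np.min(np.linalg.norm(occupied - cand, axis=1)) >= min_sep + 4:
            return cand
    return cand


def simulate_cohort(params: AgentParams | None = None,
                    schedule: StimulusSchedule | None = None,
                    duration_s: float = 150.0, seed: int = 0,
                    fps: float = 30.0,
                    canvas: tuple[int, int] = (640, 480)) -> GroundTruth:
    """Simulate a caged cohort under a stimulus schedule.

    Returns exact ground truth (per-frame states and positions plus an event
    list).  Identical arguments and seed give bit-identical output.
    """
    params = params or AgentParams()
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if schedule is not None and schedule.recording_duration > duration_s + 1e-9:
        raise ValueError("schedule is longer than the simulated duration")
    width, height = canvas
    n_frames = int(round(duration_s * fps))
    n = params.n_agents
    dt = 1.0 / fps
    rng = np.random.default_rng(seed)
    bin_frames = int(round(2.0 * fps))

    if (params.p_stationary_to_search_2s is None
            or params.p_search_to_stationary_2s is None):
        # bout-mean parametrization: exponential bout durations, geometric
        # conversion of the per-2-s takeoff probability
        a = 1.0 - math.exp(-dt / params.stationary_bout_mean)
        b = 1.0 - math.exp(-dt / params.searching_bout_mean)
        h_s = 1.0 - (1.0 - params.p_takeoff_stationary_2s) ** (1.0 / bin_frames)
        h_r = 1.0 - (1.0 - params.p_takeoff_searching_2s) ** (1.0 / bin_frames)
    else:
        a, b, h_s, h_r = calibrate_frame_hazards(
            params.p_stationary_to_search_2s, params.p_takeoff_stationary_2s,
            params.p_search_to_stationary_2s, params.p_takeoff_searching_2s,
            bin_frames,
        )
    p_land = 1.0 - math.exp(-params.landing_rate * dt)

    state = np.full(n, OFF_WALL, dtype=np.int8)
    pos = np.full((n, 2), np.nan)
    heading = rng.uniform(0, 2 * np.pi, n)
    bout_speed = np.zeros(n)
    reland_at = np.full(n, -1.0)            # next allowed landing time (for relanding)
    pending_takeoff = np.full(n, -1, dtype=int)   # frame of scheduled evoked takeoff
    pending_kind = np.zeros(n, dtype=np.int8)
    frozen_until = np.full(n, -np.inf)

    states = np.zeros((n_frames, n), dtype=np.int8)
    positions = np.full((n_frames, n, 2), np.nan)
    events: list[tuple] = []

    epochs = list(schedule.epochs) if schedule is not None else []
    epoch_start_frame = {int(round(e.t_start * fps)): e for e in epochs}

    def record(kind, agent, frame):
        x, y = pos[agent]
        events.append((kind, agent, frame, frame / fps, x, y))

    def start_search_bout(idx):
        lo, hi = params.walk_speed_range
        bout_speed[idx] = rng.uniform(lo, hi)
        heading[idx] = rng.uniform(0, 2 * np.pi)

    for f in range(n_frames):
        t = f * dt
        # --- landings -----------------------------------------------------
        off = np.nonzero(state == OFF_WALL)[0]
        for i in off:
            lands = (rng.random() < p_land) if reland_at[i] < 0 else (t >= reland_at[i])
            if lands:
                on_wall = state != OFF_WALL
                pos[i] = _place(rng, pos, on_wall, width, height,
                                params.margin_px, params.min_separation_px)
                state[i] = STATIONARY if rng.random() < 0.5 else SEARCHING
                reland_at[i] = -1.0
                if state[i] == SEARCHING:
                    start_search_bout(i)
                record("landing", i, f)

        # --- stimulus epoch onset: sample evoked responses once per agent --
        if f in epoch_start_frame:
            epoch = epoch_start_frame[f]
            scale = _speed_scale(epoch, params) * _polarity_factor(epoch, params)
            slow_edge = (not epoch.is_flash
                         and epoch.edge_speed < params.fast_speed_threshold_cm_s)
            for i in np.nonzero(state != OFF_WALL)[0]:
                p_evoked = (params.p_evoked_takeoff_stationary if state[i] == STATIONARY
                            else params.p_evoked_takeoff_searching) * scale
                if rng.random() < p_evoked:
                    cross = _edge_crossing_time(epoch, pos[i, 0], pos[i, 1],
                                                width, height)
                    if cross is None:
                        continue      # sweep stops short of this agent
                    latency = rng.uniform(*params.takeoff_latency_range_s)
                    tf = int(round((cross + latency) * fps))
                    pending_takeoff[i] = min(max(tf, f + 1), n_frames - 1)
                elif slow_edge and rng.random() < params.p_freeze_given_slow_stimulus:
                    frozen_until[i] = epoch.t_end + 1.0
                    if state[i] == SEARCHING:
                        state[i] = STATIONARY
                    record("freeze_onset", i, f)

        # --- evoked takeoffs ---------------------------------------------
        due = np.nonzero((pending_takeoff == f) & (state != OFF_WALL))[0]
        for i in due:
            record("evoked_takeoff", i, f - 1 if f > 0 else 0)
            state[i] = OFF_WALL
            pos[i] = np.nan
            pending_takeoff[i] = -1
            reland_at[i] = t + rng.exponential(params.relanding_delay_mean)

        # --- spontaneous chain (skipped while frozen or awaiting takeoff) --
        free = (state != OFF_WALL) & (pending_takeoff < 0) & (t >= frozen_until)
        idx = np.nonzero(free)[0]
        if len(idx):
            u = rng.random(len(idx))
            st = state[idx]
            h = np.where(st == STATIONARY, h_s, h_r)
            sw = np.where(st == STATIONARY, a, b)
            takeoff = u < h
            switch = ~takeoff & (u < h + (1 - h) * sw)
            for i in idx[takeoff]:
                record("spontaneous_takeoff", i, f - 1 if f > 0 else 0)
                state[i] = OFF_WALL
                pos[i] = np.nan
                reland_at[i] = t + rng.exponential(params.relanding_delay_mean)
            for i in idx[switch]:
                if state[i] == STATIONARY:
                    state[i] = SEARCHING
                    start_search_bout(i)
                else:
                    state[i] = STATIONARY

        # --- movement of searching agents ---------------------------------
        moving = np.nonzero((state == SEARCHING)
                            & ((t >= frozen_until) | (pending_takeoff >= 0)))[0]
        if len(moving):
            m = len(moving)
            heading[moving] += rng.normal(0, params.turn_rate_rad_sqrt_s
                                          * math.sqrt(dt), m)
            cand = pos[moving] + (bout_speed[moving] * dt)[:, None] * np.column_stack(
                [np.cos(heading[moving]), np.sin(heading[moving])]
            )
            # reflect off the wall margins
            lo = params.margin_px
            out_x = (cand[:, 0] < lo) | (cand[:, 0] > width - lo)
            out_y = (cand[:, 1] < lo) | (cand[:, 1] > height - lo)
            heading[moving[out_x]] = math.pi - heading[moving[out_x]]
            heading[moving[out_y]] = -heading[moving[out_y]]
            cand[:, 0] = np.clip(cand[:, 0], lo, width - lo)
            cand[:, 1] = np.clip(cand[:, 1], lo, height - lo)
            # physical exclusion: do not walk into another landed agent
            onw = np.nonzero(state != OFF_WALL)[0]
            dists = np.linalg.norm(pos[onw][None, :, :] - cand[:, None, :], axis=2)
            dists[moving[:, None] == onw[None, :]] = np.inf
            conflict = dists.min(axis=1) < params.min_separation_px
            heading[moving[conflict]] += math.pi + rng.normal(0, 0.3, conflict.sum())
            pos[moving[~conflict]] = cand[~conflict]

        states[f] = state
        positions[f] = pos

    ev = pd.DataFrame(events, columns=["event_type", "agent_id", "frame_idx",
                                       "time_s", "x_px", "y_px"])
    return GroundTruth(states=states, positions=positions, events=ev,
                       fps=fps, canvas=(width, height))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _agent_appearance(rp: RenderParams, n_agents: int, seed: int):
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA11CE)))
    sx = rng.uniform(*rp.sigma_x_range, n_agents)
    sy = rng.uniform(*rp.sigma_y_range, n_agents)
    theta = rng.uniform(0, np.pi, n_agents)
    contrast = rng.uniform(*rp.contrast_range, n_agents)
    return sx, sy, theta, contrast


def silhouette_areas(rp: RenderParams, n_agents: int, seed: int) -> np.ndarray:
    """Self-check: noiseless half-depth silhouette area (px²) per agent."""
    sx, sy, theta, contrast = _agent_appearance(rp, n_agents, seed)
    r = rp.patch_radius
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    areas = np.empty(n_agents, dtype=int)
    for i in range(n_agents):
        u = np.cos(theta[i]) * xx + np.sin(theta[i]) * yy
        v = -np.sin(theta[i]) * xx + np.cos(theta[i]) * yy
        depth = contrast[i] * np.exp(-0.5 * ((u / sx[i]) ** 2 + (v / sy[i]) ** 2))
        areas[i] = int((depth >= contrast[i] / 2).sum())
    return areas


def render_frames(truth: GroundTruth, rp: RenderParams | None = None,
                  seed: int = 0) -> FrameSequence:
    """Render ground truth into an 8-bit grayscale frame sequence."""
    rp = rp or RenderParams()
    width, height = truth.canvas
    if (width, height) != (rp.width, rp.height):
        raise ValueError("render canvas does not match the simulated canvas")
    if 6 * max(rp.sigma_x_range[1], rp.sigma_y_range[1]) > min(width, height):
        raise ValueError("blob larger than canvas")
    finite = truth.positions[np.isfinite(truth.positions[..., 0])]
    if len(finite) and (
        finite[:, 0].min() < 0 or finite[:, 0].max() > width - 1
        or finite[:, 1].min() < 0 or finite[:, 1].max() > height - 1
    ):
        raise ValueError("ground-truth positions fall outside the canvas")

    sx, sy, theta, contrast = _agent_appearance(rp, truth.n_agents, seed)
    if rp.enforce_area_band:
        areas = silhouette_areas(rp, truth.n_agents, seed)
        lo, hi = rp.area_band
        if ((areas < lo) | (areas > hi)).any():
            raise ValueError(
                f"renderer self-check failed: silhouette areas {sorted(set(areas))} "
                f"outside configured band {rp.area_band}"
            )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF4A3)))
    r = rp.patch_radius
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    frames = np.empty((truth.n_frames, height, width), dtype=np.uint8)
    base = np.full((height, width), float(rp.background_level))
    col = np.arange(width) / width
    for f in range(truth.n_frames):
        if rp.illumination_drift > 0:
            phase = 2 * np.pi * (f / truth.fps) / 30.0
            img = base * (1.0 + rp.illumination_drift
                          * np.sin(2 * np.pi * col + phase))[None, :]
        else:
            img = base.copy()
        for i in np.nonzero(truth.states[f] != OFF_WALL)[0]:
            x, y = truth.positions[f, i]
            cx, cy = int(round(x)), int(round(y))
            dx = xx + (cx - x)
            dy = yy + (cy - y)
            u = cos_t[i] * dx + sin_t[i] * dy
            v = -sin_t[i] * dx + cos_t[i] * dy
            patch = contrast[i] * np.exp(-0.5 * ((u / sx[i]) ** 2 + (v / sy[i]) ** 2))
            y0, y1 = max(cy - r, 0), min(cy + r + 1, height)
            x0, x1 = max(cx - r, 0), min(cx + r + 1, width)
            img[y0:y1, x0:x1] -= patch[y0 - (cy - r):y1 - (cy - r),
                                       x0 - (cx - r):x1 - (cx - r)]
        if rp.noise_sd > 0:
            img += rp.noise_sd * rng.standard_normal(img.shape, dtype=np.float32)
        frames[f] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return FrameSequence(frames, fps=truth.fps)


# ---------------------------------------------------------------------------
# Ground-truth I/O and evaluation helpers
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Write events.csv and states.csv (lossless to 6 decimals)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    truth.events.to_csv(path / "events.csv", index=False, float_format="%.6f")
    f_idx, a_idx = np.nonzero(truth.states >= 0)   # all cells; keeps dense table
    df = pd.DataFrame({
        "frame_idx": f_idx,
        "agent_id": a_idx,
        "state": [ _STATE_NAMES[s] for s in truth.states[f_idx, a_idx] ],
        "x_px": truth.positions[f_idx, a_idx, 0],
        "y_px": truth.positions[f_idx, a_idx, 1],
    })
    df = df[df.state != "off_wall"]
    with open(path / "states.csv", "w") as fh:
        fh.write(f"# fps={truth.fps} n_frames={truth.n_frames} "
                 f"n_agents={truth.n_agents} canvas={truth.canvas[0]}x{truth.canvas[1]}\n")
        df.to_csv(fh, index=False, float_format="%.6f")
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    events = pd.read_csv(path / "events.csv")
    if len(events) == 0:
        events = events.astype({"agent_id": int, "frame_idx": int})
    with open(path / "states.csv") as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        df = pd.read_csv(fh)
    fps = float(meta["fps"])
    n_frames, n_agents = int(meta["n_frames"]), int(meta["n_agents"])
    w, h = (int(v) for v in meta["canvas"].split("x"))
    states = np.zeros((n_frames, n_agents), dtype=np.int8)
    positions = np.full((n_frames, n_agents, 2), np.nan)
    if len(df):
        codes = df.state.map({v: k for k, v in _STATE_NAMES.items()}).to_numpy()
        states[df.frame_idx, df.agent_id] = codes
        positions[df.frame_idx, df.agent_id, 0] = df.x_px
        positions[df.frame_idx, df.agent_id, 1] = df.y_px
    return GroundTruth(states=states, positions=positions, events=events,
                       fps=fps, canvas=(w, h))


def truth_to_series(truth: GroundTruth, min_track_frames: int = 30) -> list:
    """Ground-truth per-frame behavior labels as BehaviorSeries (one per
    wall visit), bypassing detection/tracking/classification."""
    from .behavior_stats import BehaviorSeries

    out = []
    tid = 0
    on = truth.states != OFF_WALL
    for agent in range(truth.n_agents):
        col = on[:, agent].astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate([[0], col, [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s < min_track_frames:
                continue
            labels = truth.states[s:e, agent].copy()
            takeoff = e < truth.n_frames
            out.append(BehaviorSeries(track_id=tid, start_frame=int(s),
                                      labels=labels, terminal_takeoff=takeoff,
                                      takeoff_frame=int(e - 1) if takeoff else None))
            tid += 1
    return out


def truth_occupancy(truth: GroundTruth) -> np.ndarray:
    """Number of landed agents per frame."""
    return (truth.states != OFF_WALL).sum(axis=1)


def truth_to_tracks(truth: GroundTruth,
                    min_track_frames: int = 30) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert ground truth into an idealized trajectory table + event log.

    Each landing...departure span becomes one track (new identity per
    landing, as in the tracker); spans shorter than ``min_track_frames`` are
    dropped, mirroring the tracker's minimum-length rule.
    """
    takeoffs = truth.takeoff_events()
    takeoff_frames = {(int(r.agent_id), int(r.frame_idx)) for r in takeoffs.itertuples()}
    rows, events = [], []
    tid = 0
    fps = truth.fps
    on = truth.states != OFF_WALL
    for agent in range(truth.n_agents):
        col = on[:, agent].astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate([[0], col, [0]])))
        for s, e in zip(edges[::2], edges[1::2]):    # span frames [s, e)
            if e - s < min_track_frames:
                continue
            for f in range(s, e):
                x, y = truth.positions[f, agent]
                rows.append((tid, f, f / fps, x, y, True))
            x0, y0 = truth.positions[s, agent]
            events.append(("landing", tid, s, s / fps, x0, y0))
            xl, yl = truth.positions[e - 1, agent]
            if (agent, e - 1) in takeoff_frames or e < truth.n_frames:
                events.append(("takeoff", tid, e - 1, (e - 1) / fps, xl, yl))
            else:
                events.append(("track_lost_at_video_end", tid, e - 1, (e - 1) / fps,
                               xl, yl))
            tid += 1
    table = pd.DataFrame(rows, columns=TRACK_COLUMNS[:6])
    if len(table) == 0:
        table = pd.DataFrame(columns=TRACK_COLUMNS[:6])
    log = pd.DataFrame(events, columns=EVENT_COLUMNS)
    if len(log) == 0:
        log = pd.DataFrame(columns=EVENT_COLUMNS)
    return validate_tracks(table), log


def _wall_span_ending_at(truth: GroundTruth, agent: int, frame: int) -> int:
    col = truth.states[: frame + 1, agent] != OFF_WALL
    n = 0
    for v in col[::-1]:
        if not v:
            break
        n += 1
    return n


def match_takeoffs(truth: GroundTruth, called_events: pd.DataFrame,
                   tol_frames: int = 2, tol_px: float = 12.0,
                   min_span_frames: int | None = 30) -> dict:
    """One-to-one matching of ground-truth takeoffs to called takeoff events.

    Returns recovered fraction plus counts; a truth event matches a called
    takeoff within ``tol_frames`` frames and ``tol_px`` pixels.  Truth
    takeoffs ending a wall visit shorter than ``min_span_frames`` are not
    counted: the tracker's minimum-track-length rule discards such visits by
    design, so they are unrecoverable for any faithful pipeline.
    """
    truth_to = truth.takeoff_events()
    if min_span_frames:
        keep = [
            _wall_span_ending_at(truth, int(r.agent_id), int(r.frame_idx))
            >= min_span_frames
            for r in truth_to.itertuples()
        ]
        truth_to = truth_to[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    called = called_events[called_events.event_type == "takeoff"]
    used = np.zeros(len(called), dtype=bool)
    cframes = called.frame_idx.to_numpy()
    cx = called.x_px.to_numpy()
    cy = called.y_px.to_numpy()
    n_match = 0
    for r in truth_to.itertuples():
        ok = (np.abs(cframes - r.frame_idx) <= tol_frames) & ~used
        if tol_px is not None and len(called):
            ok &= np.hypot(cx - r.x_px, cy - r.y_px) <= tol_px
        cand = np.nonzero(ok)[0]
        if len(cand):
            best = cand[np.argmin(np.abs(cframes[cand] - r.frame_idx))]
            used[best] = True
            n_match += 1
    n_truth = len(truth_to)
    return {
        "n_truth": n_truth,
        "n_called": int(len(called)),
        "n_matched": n_match,
        "recovered": n_match / n_truth if n_truth else float("nan"),
    }
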