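"""Shadow-stimulus protocols, stage calibration, and response windows.

The behavioral assay projects a moving shadow onto the back wall of a mesh
cage (15 cm edge length by default).  A stimulus epoch is a single edge
sweep: an OFF edge (light-to-dark, a blocker occluding the light source) or
an ON edge (dark-to-light, the blocker retracting), traveling at a fixed
speed in cm/s until it covers a configurable fraction of the wall.  Full-field
flashes are epochs with no spatial edge and zero duration.  The ambient
illuminance is metadata only: the camera sits behind an IR-pass filter and
does not see the visible-light shadow, so stimuli influence behavior but
never the imaging.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Polarity",
    "Direction",
    "StimulusEpoch",
    "StimulusSchedule",
    "StageCalibration",
    "PROTOCOLS",
    "build_protocol",
    "fit_calibration",
    "edge_position",
    "response_windows",
    "write_schedule",
    "read_schedule",
]

#: Physical width of the cage back wall, cm.
DEFAULT_WALL_EXTENT_CM = 15.0


class Polarity(str, enum.Enum):
    OFF_EDGE = "OFF_EDGE"    # light -> dark, blocker advancing
    ON_EDGE = "ON_EDGE"      # dark -> light, blocker retracting
    FLASH_OFF = "FLASH_OFF"  # full-field light off, no spatial edge
    FLASH_ON = "FLASH_ON"    # full-field light on
    NONE = "NONE"


class Direction(str, enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    UP = "UP"
    DOWN = "DOWN"


_FLASHES = {Polarity.FLASH_OFF, Polarity.FLASH_ON}


@dataclass(frozen=True)
class StimulusEpoch:
    """One edge sweep (or flash) of the shadow stimulus."""

    t_start: float
    polarity: Polarity
    edge_speed: float = 0.0          # cm/s; 0 for flashes
    direction: Direction = Direction.LEFT
    coverage: float = 1.0            # fraction of the back wall finally shadowed
    wall_extent_cm: float = DEFAULT_WALL_EXTENT_CM

    def __post_init__(self) -> None:
        if self.t_start < 0:
            raise ValueError("t_start must be >= 0")
        if self.edge_speed < 0:
            raise ValueError("edge_speed must be >= 0")
        if not (0 < self.coverage <= 1):
            raise ValueError("coverage must be in (0, 1]")
        if self.polarity not in _FLASHES and self.edge_speed == 0 and self.polarity != Polarity.NONE:
            raise ValueError("moving-edge epochs need edge_speed > 0")

    @property
    def is_flash(self) -> bool:
        return self.polarity in _FLASHES

    @property
    def duration_s(self) -> float:
        """Edge travel time: wall extent x coverage / speed (0 for flashes)."""
        if self.is_flash or self.edge_speed == 0:
            return 0.0
        return self.wall_extent_cm * self.coverage / self.edge_speed

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration_s


@dataclass(frozen=True)
class StimulusSchedule:
    epochs: tuple[StimulusEpoch, ...]
    recording_duration: float
    ambient_lux: float | None = None   # metadata; invisible to the IR camera

    def __post_init__(self) -> None:
        epochs = tuple(sorted(self.epochs, key=lambda e: e.t_start))
        object.__setattr__(self, "epochs", epochs)
        if self.recording_duration <= 0:
            raise ValueError("recording_duration must be > 0")
        for a, b in zip(epochs, epochs[1:]):
            if b.t_start < a.t_end:
                raise ValueError(
                    f"epochs overlap: one ending {a.t_end:.3f}s, next starting {b.t_start:.3f}s"
                )
        for e in epochs:
            if e.t_end > self.recording_duration:
                raise ValueError("epoch extends past recording_duration")

    def __len__(self) -> int:
        return len(self.epochs)


@dataclass(frozen=True)
class StageCalibration:
    """Linear map from stepper-stage position to shadow-edge pixels."""

    slope: float                 # px per stage unit
    intercept: float             # px
    wall_extent_cm: float = DEFAULT_WALL_EXTENT_CM
    wall_extent_px: float = 640.0
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope) or self.slope == 0:
            raise ValueError("calibration slope must be finite and nonzero")

    @property
    def px_per_cm(self) -> float:
        return self.wall_extent_px / self.wall_extent_cm

    def stage_to_px(self, stage: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(stage, dtype=float) + self.intercept


def default_calibration(width_px: float = 640.0,
                        wall_extent_cm: float = DEFAULT_WALL_EXTENT_CM) -> StageCalibration:
    """Calibration mapping the wall onto the full frame width."""
    return StageCalibration(slope=width_px / 100.0, intercept=0.0,
                            wall_extent_cm=wall_extent_cm, wall_extent_px=width_px)


# ---------------------------------------------------------------------------
# Named protocols
# ---------------------------------------------------------------------------

def _standard_150s(off_speed=60.0, on_speed=4.0, coverage=1.0,
                   wall=DEFAULT_WALL_EXTENT_CM) -> list[StimulusEpoch]:
    off = dict(polarity=Polarity.OFF_EDGE, edge_speed=off_speed,
               direction=Direction.LEFT, coverage=coverage, wall_extent_cm=wall)
    on = dict(polarity=Polarity.ON_EDGE, edge_speed=on_speed,
              direction=Direction.RIGHT, coverage=coverage, wall_extent_cm=wall)
    return [
        StimulusEpoch(30.0, **off),
        StimulusEpoch(60.0, **on),
        StimulusEpoch(90.0, **off),
        StimulusEpoch(120.0, **on),
    ]


def _fast_fast_1s_dark(off_speed=60.0, on_speed=60.0, coverage=1.0,
                       wall=DEFAULT_WALL_EXTENT_CM) -> list[StimulusEpoch]:
    """Four rapid OFF/ON pairs with exactly 1 s of dark between each pair."""
    epochs = []
    for t0 in (30.0, 60.0, 90.0, 120.0):
        off = StimulusEpoch(t0, Polarity.OFF_EDGE, off_speed, Direction.LEFT,
                            coverage, wall)
        epochs.append(off)
        epochs.append(StimulusEpoch(off.t_end + 1.0, Polarity.ON_EDGE, on_speed,
                                    Direction.RIGHT, coverage, wall))
    return epochs


def _flash(**_ignored) -> list[StimulusEpoch]:
    return [
        StimulusEpoch(30.0, Polarity.FLASH_OFF),
        StimulusEpoch(60.0, Polarity.FLASH_ON),
        StimulusEpoch(90.0, Polarity.FLASH_OFF),
        StimulusEpoch(120.0, Polarity.FLASH_ON),
    ]


PROTOCOLS = ("standard_150s", "fast_fast_1s_dark", "flash", "none")


def build_protocol(name: str, *, recording_duration: float = 150.0,
                   off_speed: float = 60.0, on_speed: float | None = None,
                   coverage: float = 1.0,
                   wall_extent_cm: float = DEFAULT_WALL_EXTENT_CM,
                   ambient_lux: float | None = None) -> StimulusSchedule:
    """Return a named stimulus schedule.

    ``standard_150s``: 150 s recording with fast OFF edges (60 cm/s) at 30 and
    90 s and slow ON edges (4 cm/s) at 60 and 120 s.  ``fast_fast_1s_dark``:
    four rapid OFF/ON pairs (60 cm/s) with 1 s of dark between each pair.
    ``flash``: full-field light-off at 30/90 s and light-on at 60/120 s.
    ``none``: no stimulus.
    """
    if name == "standard_150s":
        epochs = _standard_150s(off_speed, 4.0 if on_speed is None else on_speed,
                                coverage, wall_extent_cm)
    elif name == "fast_fast_1s_dark":
        epochs = _fast_fast_1s_dark(off_speed, off_speed if on_speed is None else on_speed,
                                    coverage, wall_extent_cm)
    elif name == "flash":
        epochs = _flash()
    elif name == "none":
        epochs = []
    else:
        raise ValueError(f"unknown protocol {name!r}; choose from {PROTOCOLS}")
    return StimulusSchedule(tuple(epochs), recording_duration, ambient_lux)


# ---------------------------------------------------------------------------
# Stage -> shadow calibration
# ---------------------------------------------------------------------------

def fit_calibration(pairs, wall_extent_cm: float = DEFAULT_WALL_EXTENT_CM,
                    wall_extent_px: float = 640.0) -> StageCalibration:
    """Least-squares line from (stage_position, observed_edge_px) pairs."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 2:
        raise ValueError("need >= 2 (stage_position, edge_px) pairs")
    stage, px = pairs[:, 0], pairs[:, 1]
    if len(np.unique(stage)) < 2:
        raise ValueError("need >= 2 distinct stage positions")
    if np.ptp(px) == 0:
        raise ValueError("degenerate calibration: all edge pixels identical")
    slope, intercept = np.polyfit(stage, px, 1)
    resid = px - (slope * stage + intercept)
    return StageCalibration(slope=float(slope), intercept=float(intercept),
                            wall_extent_cm=wall_extent_cm,
                            wall_extent_px=wall_extent_px,
                            residual_rms=float(np.sqrt(np.mean(resid ** 2))))


def edge_position(epoch: StimulusEpoch, calib: StageCalibration,
                  t: float) -> float | None:
    """Pixel position of the shadow edge at time ``t`` (None for flashes).

    Before ``t_start`` the edge sits at its start boundary; during the epoch
    it travels linearly at ``edge_speed * px_per_cm``; afterwards it stays at
    its final boundary.  The returned coordinate is along the travel axis
    (x for LEFT/RIGHT, y for UP/DOWN).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if epoch.is_flash or epoch.polarity == Polarity.NONE:
        return None
    span_px = epoch.wall_extent_cm * calib.px_per_cm
    travel_px = epoch.coverage * span_px
    if epoch.direction in (Direction.LEFT, Direction.UP):
        start, sign = span_px, -1.0
    else:
        start, sign = 0.0, 1.0
    progress = np.clip(t - epoch.t_start, 0.0, epoch.duration_s)
    return float(start + sign * min(epoch.edge_speed * calib.px_per_cm * progress,
                                    travel_px))


def response_windows(schedule: StimulusSchedule, post_window_s: float = 1.0,
                     fps: float = 30.0) -> list[tuple[int, int]]:
    """Half-open frame intervals covering each epoch plus the post window.

    One interval ``[floor(t_start*fps), ceil((t_end + post_window_s)*fps))``
    per epoch; flashes contribute just the post window.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    out = []
    for e in schedule.epochs:
        start = math.floor(e.t_start * fps)
        stop = math.ceil((e.t_end + post_window_s) * fps)
        out.append((start, stop))
    return out


# ---------------------------------------------------------------------------
# Schedule CSV I/O
# ---------------------------------------------------------------------------

_SCHED_COLS = ["t_start", "polarity", "edge_speed", "direction", "coverage",
               "wall_extent_cm"]


def write_schedule(schedule: StimulusSchedule, path: str | Path) -> Path:
    rows = [
        {
            "t_start": e.t_start,
            "polarity": e.polarity.value,
            "edge_speed": e.edge_speed,
            "direction": e.direction.value,
            "coverage": e.coverage,
            "wall_extent_cm": e.wall_extent_cm,
        }
        for e in schedule.epochs
    ]
    df = pd.DataFrame(rows, columns=_SCHED_COLS)
    df.attrs["recording_duration"] = schedule.recording_duration
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# recording_duration={schedule.recording_duration}\n")
        df.to_csv(fh, index=False, float_format="%.6f")
    return path


def read_schedule(path: str | Path) -> StimulusSchedule:
    path = Path(path)
    duration = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# recording_duration="):
            duration = float(first.split("=", 1)[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    if duration is None:
        raise ValueError(f"{path}: missing '# recording_duration=' header line")
    epochs = tuple(
        StimulusEpoch(
            t_start=float(r.t_start),
            polarity=Polarity(r.polarity),
            edge_speed=float(r.edge_speed),
            direction=Direction(r.direction),
            coverage=float(r.coverage),
            wall_extent_cm=float(r.wall_extent_cm),
        )
        for r in df.itertuples()
    )
    return StimulusSchedule(epochs, duration)
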