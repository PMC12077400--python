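"""Shared data types, video/table I/O and logging.

Conventions used throughout the package
---------------------------------------
Pixel coordinates have their origin at the top-left corner of the frame,
``x`` increases rightward and ``y`` downward, indices are 0-based, and
centroids are floats.  Frames are single-channel 8-bit grayscale arrays in
row-major order.  Color input is converted with the ITU-R BT.601 luma
weights and quantized to 8 bits.
"""

from __future__ import annotations

import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "FrameSequence",
    "TRACK_COLUMNS",
    "EVENT_COLUMNS",
    "EVENT_TYPES",
    "get_logger",
    "read_video",
    "write_frames",
    "write_tracks",
    "read_tracks",
    "write_events",
    "read_events",
    "validate_tracks",
    "validate_events",
]

_LUMA = np.array([0.299, 0.587, 0.114])

#: Column order of the trajectory table (one row per track per frame).
TRACK_COLUMNS = [
    "track_id",
    "frame_idx",
    "time_s",
    "x_px",
    "y_px",
    "observed_flag",
    "speed_px_per_s",
    "behavior_label",
]

#: Column order of the event log.
EVENT_COLUMNS = ["event_type", "track_id", "frame_idx", "time_s", "x_px", "y_px"]

EVENT_TYPES = {"landing", "takeoff", "track_lost_at_video_end"}

_FLOAT_COLS = {"time_s", "x_px", "y_px", "speed_px_per_s"}


def get_logger(name: str = "shadowtrack", level: int | str = logging.INFO) -> logging.Logger:
    """Return a logger writing timestamped records to stderr."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


# ---------------------------------------------------------------------------
# FrameSequence
# ---------------------------------------------------------------------------

@dataclass
class FrameSequence:
    """Ordered grayscale frames with timestamps.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)`` with dtype ``uint8``.
    fps
        Acquisition rate in Hz; must be positive.
    timestamps
        Seconds from recording start, one per frame, strictly increasing.
        Defaults to ``arange(n) / fps``.
    """

    frames: np.ndarray
    fps: float
    timestamps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) array")
        if self.frames.dtype != np.uint8:
            raise ValueError("frames must be 8-bit grayscale (uint8)")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.frames)) / self.fps
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, idx: int) -> np.ndarray:
        return self.frames[idx]


def _to_gray8(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    if img.dtype != np.uint8:
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img


_NUM = re.compile(r"(\d+)")


def _numeric_sort_key(p: Path):
    return [int(t) if t.isdigit() else t for t in _NUM.split(p.name)]


def read_video(path: str | Path, downsample: int | None = None,
               fps: float | None = None) -> FrameSequence:
    """Read a video container or a directory of numbered image frames.

    ``fps`` overrides (or supplies, for frame directories) the frame rate.
    ``downsample`` keeps every *n*-th frame and divides the effective fps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"video input not found: {path}")
    if downsample is not None and downsample < 1:
        raise ValueError("downsample must be a positive integer stride")

    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir()
             if p.suffix.lower() in {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}),
            key=_numeric_sort_key,
        )
        if not files:
            raise ValueError(f"no frames found in directory: {path}")
        if fps is None:
            fpsfile = path / "fps.txt"
            if fpsfile.exists():
                fps = float(fpsfile.read_text().strip())
            else:
                raise ValueError(
                    f"frame directory {path} has no fps metadata; pass fps explicitly"
                )
        frames = [_to_gray8(iio.imread(f)) for f in files]
    else:
        try:
            props = iio.improps(path, index=...)  # noqa: F841 - probes readability
            meta = iio.immeta(path)
        except Exception as exc:  # pragma: no cover - backend specific
            raise ValueError(f"unreadable video container: {path}") from exc
        if fps is None:
            fps = meta.get("fps")
            if not fps:
                raise ValueError(f"no fps metadata in {path}; pass fps explicitly")
        frames = [_to_gray8(fr) for fr in iio.imiter(path)]
        if not frames:
            raise ValueError(f"zero frames decoded from {path}")

    if downsample:
        frames = frames[::downsample]
        fps = fps / downsample
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frames differ in shape: {shapes}")
    return FrameSequence(np.stack(frames), fps=float(fps))


def write_frames(seq: FrameSequence, path: str | Path) -> Path:
    """Write a sequence as a directory of numbered PNG frames (lossless)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ndigits = max(6, len(str(seq.n_frames)))
    for i, frame in enumerate(seq.frames):
        iio.imwrite(path / f"frame_{i:0{ndigits}d}.png", frame)
    (path / "fps.txt").write_text(f"{seq.fps:.6f}\n")
    return path


# ---------------------------------------------------------------------------
# TrackTable / EventLog CSV round-trip
# ---------------------------------------------------------------------------

def validate_tracks(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a trajectory table against its invariants; returns the table."""
    missing = [c for c in TRACK_COLUMNS[:6] if c not in table.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    if len(table):
        if table.duplicated(["track_id", "frame_idx"]).any():
            raise ValueError("duplicate (track_id, frame_idx) rows in track table")
        for tid, grp in table.groupby("track_id"):
            fi = np.sort(grp["frame_idx"].to_numpy())
            if len(fi) > 1 and not np.all(np.diff(fi) == 1):
                raise ValueError(f"track {tid}: frame indices not contiguous")
    return table


def validate_events(log: pd.DataFrame, table: pd.DataFrame | None = None) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in log.columns]
    if missing:
        raise ValueError(f"event log missing columns: {missing}")
    bad = set(log["event_type"].unique()) - EVENT_TYPES
    if bad:
        raise ValueError(f"unknown event types: {sorted(bad)}")
    if table is not None and len(log):
        known = set(table["track_id"].unique())
        orphans = set(log.loc[log.event_type == "takeoff", "track_id"]) - known
        if orphans:
            raise ValueError(f"takeoff events reference unknown tracks: {sorted(orphans)}")
    return log


def _write_table(df: pd.DataFrame, columns: list[str], path: str | Path) -> Path:
    path = Path(path)
    out = df.copy()
    for c in columns:
        if c not in out.columns:
            out[c] = np.nan
    out = out[columns]
    out.to_csv(path, index=False, float_format="%.6f")
    return path


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: header missing columns {missing} (line 1)")
    return df[columns]


def write_tracks(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a validated trajectory table to CSV (floats to 6 decimals)."""
    validate_tracks(table)
    return _write_table(table, TRACK_COLUMNS, path)


def read_tracks(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, TRACK_COLUMNS)
    if len(df):
        df = df.astype({"track_id": int, "frame_idx": int, "observed_flag": bool})
    else:
        df = df.astype(
            {"track_id": int, "frame_idx": int, "observed_flag": bool,
             "time_s": float, "x_px": float, "y_px": float, "speed_px_per_s": float}
        )
    return validate_tracks(df)


def write_events(log: pd.DataFrame, path: str | Path,
                 table: pd.DataFrame | None = None) -> Path:
    validate_events(log, table)
    return _write_table(log, EVENT_COLUMNS, path)


def read_events(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, EVENT_COLUMNS)
    if len(df):
        df = df.astype({"track_id": int, "frame_idx": int})
    else:
        df = df.astype({"track_id": int, "frame_idx": int, "time_s": float,
                        "x_px": float, "y_px": float})
        df["event_type"] = df["event_type"].astype(str)
    return validate_events(df)
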