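"""Data model and I/O for frame-indexed freezing-bout annotations.

A session is a fixed-layout recording (default: 60 s pre-CS baseline followed
by a 120 s conditioned-stimulus tone, sampled at 4 frames per second).
Freezing is annotated as bouts — intervals of complete immobility lasting at
least one second, i.e. at least ``fps`` consecutive frames.  Internally all
coordinates are 0-based frames and all intervals are half-open ``[start, end)``;
annotator tables that record the *last* frame of a bout (inclusive convention)
are converted on ingest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SessionLayout",
    "FreezingBout",
    "Ethogram",
    "BinaryTrace",
    "BoutTableError",
    "EthogramValidationError",
    "read_bout_table",
    "write_bout_table",
    "read_metadata",
    "bouts_to_trace",
    "cs_trace",
]

BOUT_TABLE_COLUMNS = ("subject_id", "start_frame", "end_frame")
METADATA_COLUMNS = ("subject_id", "dyad_id", "sex", "group", "configuration")


class BoutTableError(ValueError):
    """A bout table row failed to parse."""


class EthogramValidationError(ValueError):
    """A set of bouts violates the ethogram invariants."""


@dataclass(frozen=True)
class SessionLayout:
    """Temporal layout of a fear-testing session.

    Parameters
    ----------
    fps : int
        Video sampling rate in frames per second.
    pre_cs_s : float
        Duration of the tone-free baseline segment, seconds.
    cs_s : float
        Duration of the conditioned-stimulus (tone) segment, seconds.
    """

    fps: int = 4
    pre_cs_s: float = 60.0
    cs_s: float = 120.0

    def __post_init__(self) -> None:
        if int(self.fps) != self.fps or self.fps < 1:
            raise ValueError(f"fps must be a positive integer, got {self.fps}")
        if self.pre_cs_s <= 0 or self.cs_s <= 0:
            raise ValueError("segment durations must be positive")
        for name in ("pre_cs_s", "cs_s"):
            n = getattr(self, name) * self.fps
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name} must span a whole number of frames")

    @property
    def pre_cs_frames(self) -> int:
        return int(round(self.pre_cs_s * self.fps))

    @property
    def cs_frames(self) -> int:
        return int(round(self.cs_s * self.fps))

    @property
    def n_frames(self) -> int:
        return self.pre_cs_frames + self.cs_frames

    @property
    def cs_window(self) -> tuple[int, int]:
        """Half-open frame interval covering the CS segment."""
        return (self.pre_cs_frames, self.n_frames)

    @property
    def min_bout_frames(self) -> int:
        """Minimum annotatable bout length: one second of frames."""
        return self.fps


@dataclass(frozen=True, order=True)
class FreezingBout:
    """One freezing bout as a half-open frame interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"bout start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"bout end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Ethogram:
    """One subject's annotated session: layout plus ordered freezing bouts.

    Invariants enforced on construction: bouts are sorted, pairwise separated
    by at least one non-freezing frame, each at least one second long, and all
    contained in the session frame range.
    """

    subject_id: str
    layout: SessionLayout
    bouts: tuple[FreezingBout, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bouts", tuple(self.bouts))
        problems: list[str] = []
        min_len = self.layout.min_bout_frames
        prev: FreezingBout | None = None
        for b in self.bouts:
            if b.n_frames < min_len:
                problems.append(
                    f"bout [{b.start}, {b.end}) shorter than {min_len} frames (1 s)"
                )
            if b.end > self.layout.n_frames:
                problems.append(
                    f"bout [{b.start}, {b.end}) exceeds session length "
                    f"{self.layout.n_frames}"
                )
            if prev is not None:
                if b.start < prev.start:
                    problems.append(
                        f"bouts not sorted: [{b.start}, {b.end}) after "
                        f"[{prev.start}, {prev.end})"
                    )
                elif b.start < prev.end:
                    problems.append(
                        f"bouts overlap: [{prev.start}, {prev.end}) and "
                        f"[{b.start}, {b.end})"
                    )
                elif b.start == prev.end:
                    problems.append(
                        f"bouts adjacent with no gap: [{prev.start}, {prev.end}) "
                        f"and [{b.start}, {b.end}) — would be a single bout"
                    )
            prev = b
        if problems:
            raise EthogramValidationError(
                f"subject {self.subject_id!r}: " + "; ".join(problems)
            )

    @property
    def n_bouts(self) -> int:
        return len(self.bouts)

    def total_freezing_frames(self, window: tuple[int, int] | None = None) -> int:
        """Frames spent freezing, optionally restricted to ``window``."""
        lo, hi = window if window is not None else (0, self.layout.n_frames)
        return sum(max(0, min(b.end, hi) - max(b.start, lo)) for b in self.bouts)


@dataclass(eq=False)
class BinaryTrace:
    """Per-frame freezing indicator (1 = freezing, 0 = moving) over a window."""

    window_start: int
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.uint8)
        if v.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if v.size and not np.isin(v, (0, 1)).all():
            raise ValueError("trace values must be 0 or 1")
        self.values = v

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryTrace):
            return NotImplemented
        return self.window_start == other.window_start and np.array_equal(
            self.values, other.values
        )

    @property
    def freezing_fraction(self) -> float:
        return float(self.values.mean()) if self.values.size else 0.0


def _coerce_frames(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("start_frame", "end_frame"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() | (parsed != parsed.round()) | (parsed < 0)
        if bad.any():
            pos = int(np.flatnonzero(bad.to_numpy())[0])
            raise BoutTableError(
                f"row {df.index[pos]}: column {col!r} value {df[col].iloc[pos]!r} "
                "is not a non-negative integer frame index"
            )
        df[col] = parsed.astype(int)
    return df


def read_bout_table(
    source,
    layout: SessionLayout | None = None,
    *,
    bout_end_convention: str = "inclusive",
    frame_origin: int = 0,
) -> list[Ethogram]:
    """Read a bout-annotation CSV into validated :class:`Ethogram` objects.

    Parameters
    ----------
    source : path or file-like
        CSV with header ``subject_id,start_frame,end_frame``.
    layout : SessionLayout, optional
        Session layout used for validation; defaults to the standard
        4 fps / 60 s pre-CS / 120 s CS layout.
    bout_end_convention : {"inclusive", "exclusive"}
        ``inclusive`` (default, matching annotator output that records the
        *last* frame of each bout) converts ``end = last + 1`` on ingest;
        ``exclusive`` takes end frames as already half-open.
    frame_origin : int
        Index of the first video frame in the table (0 or 1); subtracted on
        ingest so internal coordinates are always 0-based.

    Returns
    -------
    list of Ethogram, sorted by subject id.
    """
    if bout_end_convention not in ("inclusive", "exclusive"):
        raise ValueError(f"unknown bout_end_convention {bout_end_convention!r}")
    layout = layout or SessionLayout()
    try:
        df = pd.read_csv(source, dtype={"subject_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise BoutTableError(f"could not parse bout table: {exc}") from exc
    missing = [c for c in BOUT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise BoutTableError(f"bout table missing columns: {missing}")
    df = _coerce_frames(df.copy())
    df["start_frame"] -= frame_origin
    df["end_frame"] -= frame_origin
    if (df["start_frame"] < 0).any():
        row = int(df.index[df["start_frame"] < 0][0])
        raise BoutTableError(f"row {row}: start_frame below frame origin")
    if bout_end_convention == "inclusive":
        df["end_frame"] += 1

    ethograms = []
    for subject_id, sub in df.groupby("subject_id", sort=True):
        sub = sub.sort_values(["start_frame", "end_frame"])
        bouts = tuple(
            FreezingBout(int(s), int(e))
            for s, e in zip(sub["start_frame"], sub["end_frame"])
        )
        ethograms.append(Ethogram(str(subject_id), layout, bouts))
    return ethograms


def write_bout_table(
    ethograms: Iterable[Ethogram],
    sink,
    *,
    bout_end_convention: str = "inclusive",
) -> None:
    """Write ethograms as a bout-table CSV (inverse of :func:`read_bout_table`)."""
    if bout_end_convention not in ("inclusive", "exclusive"):
        raise ValueError(f"unknown bout_end_convention {bout_end_convention!r}")
    shift = 1 if bout_end_convention == "inclusive" else 0
    rows = [
        (e.subject_id, b.start, b.end - shift)
        for e in sorted(ethograms, key=lambda e: e.subject_id)
        for b in e.bouts
    ]
    df = pd.DataFrame(rows, columns=list(BOUT_TABLE_COLUMNS))
    df.to_csv(sink, index=False)


def read_metadata(source) -> pd.DataFrame:
    """Read the per-subject metadata CSV.

    Columns: ``subject_id,dyad_id,sex,group,configuration`` with
    configuration in {PAIR, SINGLE}.
    """
    df = pd.read_csv(source, dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise BoutTableError(f"metadata missing columns: {missing}")
    bad = ~df["configuration"].isin(["PAIR", "SINGLE"])
    if bad.any():
        raise BoutTableError(
            f"metadata: configuration must be PAIR or SINGLE, got "
            f"{sorted(df.loc[bad, 'configuration'].unique())}"
        )
    return df


def bouts_to_trace(
    ethogram: Ethogram, window: tuple[int, int] | None = None
) -> BinaryTrace:
    """Rasterize an ethogram's bouts to a per-frame 0/1 trace over a window.

    ``window`` is a half-open frame interval; by default the CS segment.
    """
    lo, hi = window if window is not None else ethogram.layout.cs_window
    if not (0 <= lo < hi <= ethogram.layout.n_frames):
        raise ValueError(
            f"window [{lo}, {hi}) outside session range "
            f"[0, {ethogram.layout.n_frames})"
        )
    values = np.zeros(hi - lo, dtype=np.uint8)
    for b in ethogram.bouts:
        a, z = max(b.start, lo), min(b.end, hi)
        if a < z:
            values[a - lo : z - lo] = 1
    return BinaryTrace(window_start=lo, values=values)


def cs_trace(ethogram: Ethogram) -> BinaryTrace:
    """Convenience: the CS-segment binary trace of an ethogram."""
    return bouts_to_trace(ethogram, ethogram.layout.cs_window)


def trace_from_values(values: Sequence[int], window_start: int = 0) -> BinaryTrace:
    """Build a trace directly from 0/1 values (mostly for tests and demos)."""
    return BinaryTrace(window_start=window_start, values=np.asarray(values))


def ethogram_from_trace(
    subject_id: str, layout: SessionLayout, trace: BinaryTrace
) -> Ethogram:
    """Reconstruct an ethogram from a full-session binary trace."""
    v = np.asarray(trace.values, dtype=np.int8)
    edges = np.flatnonzero(np.diff(np.r_[0, v, 0]))
    bouts = tuple(
        FreezingBout(int(s) + trace.window_start, int(e) + trace.window_start)
        for s, e in zip(edges[::2], edges[1::2])
    )
    return Ethogram(subject_id, layout, bouts)
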