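"""Session schedules for immobilization (IMO), fear conditioning (FC) and extinction (FE).

A schedule describes the temporal layout of a session in frames at a fixed
frame rate: an intra-session habituation block, a sequence of tone (CS)
presentations separated by inter-trial intervals, an optional footshock (US)
co-terminating with each tone during conditioning, and a final tail segment.
All intervals are half-open ``[start, end)`` in 0-based frame indices.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSchedule",
    "make_fc_schedule",
    "make_fe_schedule",
    "make_imo_schedule",
]

Interval = tuple[int, int]


def _check_intervals(name: str, intervals: tuple[Interval, ...], total: int) -> None:
    prev_end = 0
    for start, end in intervals:
        if not (0 <= start < end <= total):
            raise ValueError(
                f"{name} interval [{start}, {end}) outside [0, {total})"
            )
        if start < prev_end:
            raise ValueError(f"{name} intervals overlap or are unsorted at [{start}, {end})")
        prev_end = end


@dataclass(frozen=True)
class StimulusSchedule:
    """Frame-domain layout of one session.

    Parameters
    ----------
    fps : float
        Acquisition frame rate (frames/second); 30 for the Miniscope DAQ.
    session_kind : {"FC", "FE", "IMO"}
    tone_intervals, shock_intervals : tuple of (start, end)
        Half-open frame intervals, sorted and non-overlapping. Shocks occur
        only in FC sessions and each one ends exactly with its paired tone.
    total_frames : int
    segments : tuple of (kind, start, end)
        Named blocks (habituation / tone / iti / tail / early / late) tiling
        the session.
    """

    fps: float
    session_kind: str
    tone_intervals: tuple[Interval, ...]
    shock_intervals: tuple[Interval, ...] = ()
    total_frames: int = 0
    segments: tuple[tuple[str, int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.session_kind not in ("FC", "FE", "IMO"):
            raise ValueError(f"unknown session_kind {self.session_kind!r}")
        if self.total_frames < 1:
            raise ValueError("total_frames must be >= 1")
        _check_intervals("tone", self.tone_intervals, self.total_frames)
        _check_intervals("shock", self.shock_intervals, self.total_frames)
        if self.session_kind in ("FE", "IMO") and self.shock_intervals:
            raise ValueError(f"{self.session_kind} sessions carry no shocks")
        tone_ends = {end for _, end in self.tone_intervals}
        for s_start, s_end in self.shock_intervals:
            if s_end not in tone_ends:
                raise ValueError(
                    f"shock ending at frame {s_end} does not co-terminate with a tone"
                )

    # -- derived views ---------------------------------------------------

    @property
    def duration_s(self) -> float:
        return self.total_frames / self.fps

    def tone_mask(self) -> np.ndarray:
        """Boolean per-frame vector, True during tone presentation."""
        mask = np.zeros(self.total_frames, dtype=bool)
        for start, end in self.tone_intervals:
            mask[start:end] = True
        return mask

    def shock_mask(self) -> np.ndarray:
        mask = np.zeros(self.total_frames, dtype=bool)
        for start, end in self.shock_intervals:
            mask[start:end] = True
        return mask

    def segment_intervals(self, kind: str) -> list[Interval]:
        return [(s, e) for k, s, e in self.segments if k == kind]

    # -- serialization ---------------------------------------------------

    def to_table(self) -> pd.DataFrame:
        rows = [(k, s, e) for k, s, e in self.segments]
        rows += [("shock", s, e) for s, e in self.shock_intervals]
        df = pd.DataFrame(rows, columns=["kind", "start_frame", "end_frame"])
        return df.sort_values(["start_frame", "kind"], kind="stable").reset_index(drop=True)

    def write(self, path: str | Path) -> None:
        header = (
            f"# fps={self.fps}\n"
            f"# session_kind={self.session_kind}\n"
            f"# total_frames={self.total_frames}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.to_table().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "StimulusSchedule":
        meta: dict[str, str] = {}
        body_lines = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            else:
                body_lines.append(line)
        df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t")
        tones = [
            (int(r.start_frame), int(r.end_frame))
            for r in df.itertuples()
            if r.kind == "tone"
        ]
        shocks = [
            (int(r.start_frame), int(r.end_frame))
            for r in df.itertuples()
            if r.kind == "shock"
        ]
        segments = [
            (str(r.kind), int(r.start_frame), int(r.end_frame))
            for r in df.itertuples()
            if r.kind != "shock"
        ]
        return cls(
            fps=float(meta["fps"]),
            session_kind=meta["session_kind"],
            tone_intervals=tuple(tones),
            shock_intervals=tuple(shocks),
            total_frames=int(meta["total_frames"]),
            segments=tuple(segments),
        )


def _frames(seconds: float, fps: float) -> int:
    n = round(seconds * fps)
    if abs(n - seconds * fps) > 1e-9:
        raise ValueError(f"duration {seconds}s is not a whole number of frames at {fps} fps")
    return int(n)


def _tone_block_schedule(
    kind: str,
    fps: float,
    n_tones: int,
    tone_s: float,
    iti_s: float,
    hab_s: float,
    tail_s: float,
    shock_s: float | None,
) -> StimulusSchedule:
    if n_tones < 1:
        raise ValueError("n_tones must be >= 1")
    for name, dur in (("tone_s", tone_s), ("iti_s", iti_s), ("hab_s", hab_s), ("tail_s", tail_s)):
        if dur <= 0:
            raise ValueError(f"{name} must be positive")
    if shock_s is not None and not (0 < shock_s <= tone_s):
        raise ValueError("shock_s must lie in (0, tone_s]")

    tone_f = _frames(tone_s, fps)
    iti_f = _frames(iti_s, fps)
    hab_f = _frames(hab_s, fps)
    tail_f = _frames(tail_s, fps)
    shock_f = _frames(shock_s, fps) if shock_s is not None else 0

    segments: list[tuple[str, int, int]] = [("habituation", 0, hab_f)]
    tones: list[Interval] = []
    shocks: list[Interval] = []
    cursor = hab_f
    for i in range(n_tones):
        tones.append((cursor, cursor + tone_f))
        segments.append(("tone", cursor, cursor + tone_f))
        if shock_s is not None:
            shocks.append((cursor + tone_f - shock_f, cursor + tone_f))
        cursor += tone_f
        if i < n_tones - 1:
            segments.append(("iti", cursor, cursor + iti_f))
            cursor += iti_f
    segments.append(("tail", cursor, cursor + tail_f))
    cursor += tail_f

    return StimulusSchedule(
        fps=fps,
        session_kind=kind,
        tone_intervals=tuple(tones),
        shock_intervals=tuple(shocks),
        total_frames=cursor,
        segments=tuple(segments),
    )


def make_fc_schedule(
    fps: float = 30.0,
    n_tones: int = 5,
    tone_s: float = 30.0,
    iti_s: float = 180.0,
    hab_s: float = 300.0,
    tail_s: float = 180.0,
    shock_s: float = 1.0,
) -> StimulusSchedule:
    """Fear-conditioning session: habituation, ``n_tones`` tones each
    co-terminated by a footshock occupying the last ``shock_s`` seconds,
    ITIs between tones, and a tail after the last pairing.

    Defaults reproduce the standard protocol: 5 min habituation, five 30 s
    tones with a 1 s shock, 180 s ITIs, 180 s tail (1350 s at 30 fps).
    """
    return _tone_block_schedule("FC", fps, n_tones, tone_s, iti_s, hab_s, tail_s, shock_s)


def make_fe_schedule(
    fps: float = 30.0,
    n_tones: int = 15,
    tone_s: float = 30.0,
    iti_s: float = 30.0,
    hab_s: float = 300.0,
    tail_s: float = 30.0,
) -> StimulusSchedule:
    """Fear-extinction session: tones are never paired with a shock.

    Defaults: 5 min habituation, fifteen 30 s tones spaced by 30 s ITIs,
    30 s tail (1200 s at 30 fps).
    """
    return _tone_block_schedule("FE", fps, n_tones, tone_s, iti_s, hab_s, tail_s, None)


def make_imo_schedule(fps: float = 30.0, epoch_s: float = 600.0) -> StimulusSchedule:
    """Immobilization session fixture: two recorded epochs (early / late),
    each ``epoch_s`` seconds, with no tones or shocks.

    The restraint itself lasts two hours; only the first and last 10 minutes
    are recorded, so the fixture holds exactly those two epochs back to back.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    n = _frames(epoch_s, fps)
    return StimulusSchedule(
        fps=fps,
        session_kind="IMO",
        tone_intervals=(),
        shock_intervals=(),
        total_frames=2 * n,
        segments=(("early", 0, n), ("late", n, 2 * n)),
    )
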