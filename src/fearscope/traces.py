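"""Fluorescence trace containers, ΔF/F0 normalization and calcium-event statistics.

The pipeline consumes already-deconvolved (filtered) fluorescence traces,
one row per neuron, sampled at the acquisition frame rate. Normalization is
ΔF/F0 with F0 the median of the complete session trace — the median rather
than the mean because calcium transients are sparse, large and one-sided, so
the median is a far more stable baseline. A calcium event is a local maximum
of the normalized trace; event frequency (events/second) and amplitude
(peak ΔF/F0) are then summarized over named epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "TraceMatrix",
    "EventRaster",
    "DegenerateBaselineError",
    "normalize_dff",
    "global_fluorescence",
    "detect_events",
    "event_stats",
]


class DegenerateBaselineError(ValueError):
    """Raised when a neuron's baseline (median fluorescence) is zero."""


@dataclass(frozen=True)
class TraceMatrix:
    """Neurons x frames fluorescence matrix at a fixed frame rate."""

    values: np.ndarray
    fps: float
    neuron_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be 2-D (neurons x frames)")
        if values.shape[0] < 1 or values.shape[1] < 2:
            raise ValueError("need at least 1 neuron and 2 frames")
        if not np.isfinite(values).all():
            raise ValueError("trace matrix contains non-finite values")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        object.__setattr__(self, "values", values)
        if not self.neuron_ids:
            object.__setattr__(
                self, "neuron_ids", tuple(f"n{i:04d}" for i in range(values.shape[0]))
            )
        elif len(self.neuron_ids) != values.shape[0]:
            raise ValueError("neuron_ids length does not match number of neurons")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    # -- I/O -------------------------------------------------------------

    def to_csv(self, path: str | Path, header_comment: str = "") -> None:
        df = pd.DataFrame(self.values, index=list(self.neuron_ids))
        df.index.name = "neuron_id"
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# fps={self.fps}\n")
            df.to_csv(fh)

    @classmethod
    def from_csv(cls, path: str | Path, fps: float | None = None,
                 neurons_as: str = "rows") -> "TraceMatrix":
        """Read a delimited trace table. ``neurons_as`` declares the layout
        ('rows' or 'columns')."""
        meta_fps = None
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                if "fps=" in line:
                    meta_fps = float(line.split("fps=")[1])
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, index_col=0)
        if neurons_as == "columns":
            df = df.T
        elif neurons_as != "rows":
            raise ValueError("neurons_as must be 'rows' or 'columns'")
        fps = fps if fps is not None else meta_fps
        if fps is None:
            raise ValueError("fps not given and not recorded in the file header")
        return cls(values=df.to_numpy(dtype=float), fps=fps,
                   neuron_ids=tuple(str(i) for i in df.index))

    def save_npz(self, path: str | Path) -> None:
        np.savez(path, values=self.values, fps=self.fps,
                 neuron_ids=np.array(self.neuron_ids))

    @classmethod
    def load_npz(cls, path: str | Path) -> "TraceMatrix":
        with np.load(path, allow_pickle=False) as data:
            return cls(values=data["values"], fps=float(data["fps"]),
                       neuron_ids=tuple(str(s) for s in data["neuron_ids"]))


@dataclass(frozen=True)
class EventRaster:
    """Boolean neurons x frames event matrix with peak ΔF/F0 amplitudes.

    ``amplitudes`` holds the trace value at each event frame and NaN
    elsewhere; plateau maxima are assigned to the first frame of the plateau.
    """

    events: np.ndarray
    amplitudes: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=bool)
        amp = np.asarray(self.amplitudes, dtype=float)
        if ev.shape != amp.shape:
            raise ValueError("events and amplitudes shapes differ")
        if not np.isnan(amp[~ev]).all():
            raise ValueError("amplitude recorded off-event")
        object.__setattr__(self, "events", ev)
        object.__setattr__(self, "amplitudes", amp)

    @property
    def n_neurons(self) -> int:
        return self.events.shape[0]

    @property
    def n_frames(self) -> int:
        return self.events.shape[1]

    def counts(self) -> np.ndarray:
        return self.events.sum(axis=1)

    def to_triplets(self) -> pd.DataFrame:
        """Sparse export: one row per event (neuron, frame, amplitude)."""
        rows, cols = np.nonzero(self.events)
        return pd.DataFrame(
            {"neuron": rows, "frame": cols, "amplitude": self.amplitudes[rows, cols]}
        )


def normalize_dff(traces: TraceMatrix) -> TraceMatrix:
    """ΔF/F0 per neuron: (F - F0) / F0 with F0 = median of the complete trace.

    Raises :class:`DegenerateBaselineError` naming the first neuron whose
    median fluorescence is zero.
    """
    f0 = np.median(traces.values, axis=1)
    bad = np.nonzero(f0 == 0)[0]
    if bad.size:
        raise DegenerateBaselineError(
            f"neuron {traces.neuron_ids[bad[0]]} has zero median fluorescence"
        )
    out = (traces.values - f0[:, None]) / f0[:, None]
    return TraceMatrix(values=out, fps=traces.fps, neuron_ids=traces.neuron_ids)


def global_fluorescence(traces: TraceMatrix) -> np.ndarray:
    """Whole-field trace: arithmetic mean across neurons at each frame.

    Intended to be called on ΔF/F0-normalized traces.
    """
    if traces.n_neurons < 1:
        raise ValueError("need at least one neuron")
    return traces.values.mean(axis=0)


def default_prominence(trace: np.ndarray) -> float:
    """Scale-free event threshold: 2x the median absolute deviation."""
    return 2.0 * float(np.median(np.abs(trace - np.median(trace))))


def detect_events(traces: TraceMatrix, min_prominence: float | None = None) -> EventRaster:
    """Detect calcium events as local maxima of each trace.

    A frame is an event iff it is a (plateau-leading) local maximum whose
    peak prominence is at least ``min_prominence``. When ``min_prominence``
    is None a per-neuron default of twice the trace's median absolute
    deviation is used.
    """
    if traces.n_frames < 3:
        raise ValueError("need at least 3 frames to detect local maxima")
    if min_prominence is not None and min_prominence < 0:
        raise ValueError("min_prominence must be >= 0")
    events = np.zeros(traces.values.shape, dtype=bool)
    amps = np.full(traces.values.shape, np.nan)
    for i in range(traces.n_neurons):
        trace = traces.values[i]
        prom = default_prominence(trace) if min_prominence is None else min_prominence
        _, props = find_peaks(trace, prominence=prom if prom > 0 else None,
                              plateau_size=(1, None))
        frames = props["left_edges"]
        events[i, frames] = True
        amps[i, frames] = trace[frames]
    return EventRaster(events=events, amplitudes=amps, fps=traces.fps)


def event_stats(
    raster: EventRaster,
    epochs: dict[str, tuple[int, int]],
) -> pd.DataFrame:
    """Per-neuron event frequency and amplitude per epoch, with epoch means.

    Frequency is event count / epoch duration (seconds); a neuron with no
    events in an epoch has frequency 0 and NaN amplitude, and is excluded
    from the epoch's mean amplitude. Returns a long table with per-neuron
    rows plus one ``neuron == 'mean'`` row per epoch.
    """
    rows = []
    for name, (start, end) in epochs.items():
        if end <= start:
            raise ValueError(f"epoch {name!r} has non-positive length")
        dur_s = (end - start) / raster.fps
        ev = raster.events[:, start:end]
        amp = raster.amplitudes[:, start:end]
        counts = ev.sum(axis=1)
        freqs = counts / dur_s
        with np.errstate(invalid="ignore"):
            mean_amp = np.where(counts > 0, np.nansum(amp, axis=1) / np.maximum(counts, 1), np.nan)
        for i in range(raster.n_neurons):
            rows.append((name, str(i), freqs[i], mean_amp[i], int(counts[i])))
        amp_pool = mean_amp[counts > 0]
        rows.append(
            (
                name,
                "mean",
                float(freqs.mean()),
                float(amp_pool.mean()) if amp_pool.size else np.nan,
                int(counts.sum()),
            )
        )
    return pd.DataFrame(
        rows, columns=["epoch", "neuron", "frequency_hz", "amplitude_dff", "n_events"]
    )
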