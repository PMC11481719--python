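"""Session assembly, file I/O and the end-to-end pipeline.

A :class:`SessionBundle` ties together the trace matrix, the stimulus
schedule and exactly one behavioral readout — the movement trace for
restraint (IMO) sessions, the 1 Hz freezing trace for conditioning (FC) and
extinction (FE) sessions. :func:`run_pipeline` executes the stage graph for
the session kind and writes CSV/JSON outputs, each stamped with the run
seed and a hash of the configuration so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .correlation import classify_neurons
from .movement import MovementTrace, high_movement_epochs
from .responsiveness import per_block_responsiveness, tone_responsiveness
from .schedules import StimulusSchedule
from .synthetic import FreezingTrace
from .traces import TraceMatrix, detect_events, event_stats, normalize_dff

__all__ = [
    "PipelineConfig",
    "SessionBundle",
    "load_session",
    "save_session",
    "run_pipeline",
    "write_video",
    "read_video",
]

log = logging.getLogger("fearscope")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable analysis parameters; flags override file values at the CLI."""

    seed: int = 0
    fudge: float = 0.5
    edge_high_quantile: float = 0.7
    min_prominence: float | None = None  # None -> per-neuron 2x MAD
    n_shuffles: int = 1000
    alpha: float = 0.05
    z_crit: float = 1.96
    shuffle_method: str = "hypergeometric"
    freezing_binarize_pct: float = 50.0
    duration_tolerance_s: float = 2.0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class SessionBundle:
    traces: TraceMatrix
    schedule: StimulusSchedule
    movement: MovementTrace | None = None
    freezing: FreezingTrace | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        kind = self.schedule.session_kind
        if kind == "IMO":
            if self.movement is None or self.freezing is not None:
                raise ValueError("IMO sessions carry a movement trace, not freezing")
        else:
            if self.freezing is None or self.movement is not None:
                raise ValueError(f"{kind} sessions carry a freezing trace, not movement")

    def validate_durations(self, tolerance_s: float = 2.0) -> None:
        fps = self.schedule.fps
        offsets = {}
        trace_off = (self.traces.n_frames - self.schedule.total_frames) / fps
        if trace_off:
            offsets["traces"] = trace_off
        if self.movement is not None:
            mov_off = (self.movement.raw.size + 1 - self.schedule.total_frames) / fps
            if mov_off:
                offsets["movement"] = mov_off
        if self.freezing is not None:
            frz_off = self.freezing.n_seconds - self.schedule.total_frames / fps
            if frz_off:
                offsets["freezing"] = frz_off
        bad = {k: v for k, v in offsets.items() if abs(v) > tolerance_s}
        if bad:
            raise ValueError(f"component durations off the schedule beyond tolerance: {bad}")
        if offsets:
            log.warning("duration offsets within tolerance: %s", offsets)


def write_video(frames: np.ndarray, path: str | Path) -> None:
    """Write a frame stack losslessly (.npy) or as a multi-page TIFF."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, frames)
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.asarray(frames))
    else:
        raise ValueError(f"unsupported video container {path.suffix!r} (use .npy or .tiff)")


def read_video(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    raise ValueError(f"unsupported video container {path.suffix!r}")


def save_session(bundle: SessionBundle, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"traces": out / "traces.npz", "schedule": out / "schedule.tsv"}
    bundle.traces.save_npz(paths["traces"])
    bundle.schedule.write(paths["schedule"])
    if bundle.movement is not None:
        paths["movement"] = out / "movement.csv"
        pd.DataFrame({"transition": np.arange(bundle.movement.raw.size),
                      "score": bundle.movement.raw}).to_csv(paths["movement"], index=False)
    if bundle.freezing is not None:
        paths["freezing"] = out / "freezing.csv"
        pd.DataFrame({"second": np.arange(bundle.freezing.n_seconds),
                      "percent_immobility": bundle.freezing.percent}
                     ).to_csv(paths["freezing"], index=False)
    (out / "metadata.json").write_text(json.dumps(bundle.metadata, indent=2))
    return paths


def load_session(session_dir: str | Path,
                 config: PipelineConfig | None = None) -> SessionBundle:
    """Load a saved session directory and validate the bundle.

    Missing files raise an error naming the field; duration mismatches
    beyond the configured tolerance raise with the offsets listed.
    """
    config = config or PipelineConfig()
    d = Path(session_dir)
    for name, fname in (("traces", "traces.npz"), ("schedule", "schedule.tsv")):
        if not (d / fname).exists():
            raise FileNotFoundError(f"session field {name!r}: missing {d / fname}")
    traces = TraceMatrix.load_npz(d / "traces.npz")
    schedule = StimulusSchedule.read(d / "schedule.tsv")
    movement = freezing = None
    if (d / "movement.csv").exists():
        raw = pd.read_csv(d / "movement.csv")["score"].to_numpy()
        movement = MovementTrace(raw=raw, fps=schedule.fps)
    if (d / "freezing.csv").exists():
        pct = pd.read_csv(d / "freezing.csv")["percent_immobility"].to_numpy()
        freezing = FreezingTrace(percent=pct,
                                 binarize_threshold=config.freezing_binarize_pct)
    meta = {}
    if (d / "metadata.json").exists():
        meta = json.loads((d / "metadata.json").read_text())
    bundle = SessionBundle(traces=traces, schedule=schedule, movement=movement,
                           freezing=freezing, metadata=meta)
    bundle.validate_durations(config.duration_tolerance_s)
    return bundle


def _stamp(path: Path, df: pd.DataFrame, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def run_pipeline(bundle: SessionBundle, config: PipelineConfig | None = None,
                 out_dir: str | Path = "results") -> dict:
    """Execute the stage graph for the bundle's session kind.

    IMO: movement normalization -> mixture threshold -> high-movement epoch
    metrics per recorded epoch -> ΔF/F0 -> events -> event statistics per
    epoch -> per-neuron correlation against the movement score.

    FC/FE: ΔF/F0 -> events -> tone responsiveness (whole session and per
    tone block) -> per-neuron correlation against binarized freezing.

    Writes stamped CSV tables plus a JSON summary; returns the summary.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kind = bundle.schedule.session_kind

    dff = normalize_dff(bundle.traces)
    raster = detect_events(dff, cfg.min_prominence)
    summary: dict = {
        "session_kind": kind,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_neurons": dff.n_neurons,
        "n_frames": dff.n_frames,
        "metadata": bundle.metadata,
    }

    try:
        if kind == "IMO":
            mov = bundle.movement.with_normalized().with_mixture(seed=cfg.seed)
            epochs = {name: (s, e) for name, s, e in bundle.schedule.segments
                      if name in ("early", "late")}
            mov_metrics = {}
            for name, (s, e) in epochs.items():
                # transition n scores frames n -> n+1; clip to score length
                seg = mov.normalized[max(s - 1, 0):e - 1]
                mov_metrics[name] = {
                    k: v for k, v in high_movement_epochs(
                        seg, mov.mixture.threshold, bundle.schedule.fps).items()
                    if k != "epochs"
                }
            summary["movement"] = mov_metrics
            summary["mixture"] = {
                "mu1": mov.mixture.mu1, "mu2": mov.mixture.mu2,
                "threshold": mov.mixture.threshold,
                "midpoint_fallback": mov.mixture.midpoint_fallback,
            }
            stats_df = event_stats(raster, epochs)
            _stamp(out / "event_stats.csv", stats_df, cfg)
            aligned = TraceMatrix(values=dff.values[:, 1:], fps=dff.fps,
                                  neuron_ids=dff.neuron_ids)
            cls = classify_neurons(aligned, mov.normalized, bundle.schedule.fps,
                                   behavior_kind="movement", alpha=cfg.alpha)
            _stamp(out / "correlation.csv", cls.to_frame(dff.neuron_ids), cfg)
            summary["correlation_pct"] = cls.percentages()
        else:
            stim = bundle.schedule.tone_mask()
            phi = tone_responsiveness(raster, stim, n_shuffles=cfg.n_shuffles,
                                      seed=cfg.seed, method=cfg.shuffle_method,
                                      z_crit=cfg.z_crit)
            _stamp(out / "phi.csv", phi.to_frame(), cfg)
            labels = list(phi.labels)
            summary["responsive_pct"] = {
                "excited": 100.0 * labels.count("excited") / len(labels),
                "inhibited": 100.0 * labels.count("inhibited") / len(labels),
            }
            n_tones = len(bundle.schedule.tone_intervals)
            if n_tones >= 3:
                third = max(n_tones // 3, 1)
                blocks = {"first": list(range(third)),
                          "middle": list(range(third, 2 * third)),
                          "last": list(range(2 * third, n_tones))}
                block_res = per_block_responsiveness(
                    raster, bundle.schedule, blocks, n_shuffles=cfg.n_shuffles,
                    seed=cfg.seed, method=cfg.shuffle_method)
                summary["block_responsive_pct"] = {
                    name: {
                        "excited": 100.0 * list(r.labels).count("excited") / r.n_neurons,
                        "inhibited": 100.0 * list(r.labels).count("inhibited") / r.n_neurons,
                    } for name, r in block_res.items()
                }
            freezing_pct = bundle.freezing.binary.astype(float) * 100.0
            cls = classify_neurons(dff, freezing_pct, bundle.freezing.rate_hz,
                                   behavior_kind="freezing", alpha=cfg.alpha)
            _stamp(out / "correlation.csv", cls.to_frame(dff.neuron_ids), cfg)
            summary["correlation_pct"] = cls.percentages()
            stats_df = event_stats(
                raster, {"session": (0, bundle.schedule.total_frames)})
            _stamp(out / "event_stats.csv", stats_df, cfg)
    except Exception as exc:  # annotate with the failing stage context
        raise RuntimeError(f"pipeline failed for {kind} session: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
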