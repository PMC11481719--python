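"""Synthetic sessions with known ground truth.

Every downstream stage of the pipeline is exercised on data generated here:
GCaMP6f-like fluorescence traces whose event rate can be coupled to tone
epochs or to a behavioral signal, restraint video whose frame-to-frame
jitter follows a hidden two-state (low/high movement) Markov chain, and
1 Hz freezing traces tied to the tone schedule. Each generator returns the
ground truth it drew (neuron classes, spike frames, hidden states) so that
parameter-recovery tests have an exact answer to recover.

Defaults emulate the recorded sessions: 30 fps, a per-neuron baseline event
rate of 0.2 events/s, GCaMP6f rise/decay time constants of 0.05 s / 0.4 s,
and additive Gaussian noise at 5% of the transient peak (deconvolved traces
are fairly clean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .schedules import StimulusSchedule

__all__ = [
    "CouplingSpec",
    "SyntheticGroundTruth",
    "FreezingTrace",
    "simulate_traces",
    "simulate_movement_video",
    "simulate_freezing",
    "calcium_kernel",
]

#: Event-rate multipliers applied on a neuron's designated frames
#: (tone frames for excited/inhibited, high-movement frames for coupled).
DEFAULT_MULTIPLIERS: Mapping[str, float] = {
    "excited": 8.0,
    "inhibited": 0.05,
    "null": 1.0,
    "pos_coupled": 8.0,
    "neg_coupled": 0.05,
    "uncoupled": 1.0,
}

TONE_CLASSES = ("excited", "inhibited", "null")
BEHAVIOR_CLASSES = ("pos_coupled", "neg_coupled", "uncoupled")


@dataclass(frozen=True)
class CouplingSpec:
    """Per-neuron class labels plus the rate multiplier for each class."""

    classes: tuple[str, ...]
    multipliers: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MULTIPLIERS))

    def __post_init__(self) -> None:
        unknown = set(self.classes) - set(self.multipliers)
        if unknown:
            raise ValueError(f"classes without a multiplier: {sorted(unknown)}")

    @classmethod
    def from_fractions(
        cls,
        n_neurons: int,
        fractions: Mapping[str, float],
        multipliers: Mapping[str, float] | None = None,
    ) -> "CouplingSpec":
        """Deterministic class assignment with counts proportional to
        ``fractions`` (largest-remainder rounding), so recovery tests have
        exact target proportions."""
        if abs(sum(fractions.values()) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        items = list(fractions.items())
        raw = [n_neurons * f for _, f in items]
        counts = [int(np.floor(r)) for r in raw]
        remainder = n_neurons - sum(counts)
        order = np.argsort([c - r for r, c in zip(raw, counts)])
        for idx in order[:remainder]:
            counts[idx] += 1
        labels: list[str] = []
        for (name, _), c in zip(items, counts):
            labels.extend([name] * c)
        return cls(classes=tuple(labels),
                   multipliers=dict(multipliers or DEFAULT_MULTIPLIERS))


@dataclass
class SyntheticGroundTruth:
    """What the simulator actually drew, for parameter-recovery testing."""

    neuron_class: tuple[str, ...] = ()
    spike_times: tuple[np.ndarray, ...] = ()
    state_sequence: np.ndarray | None = None
    seed: int | None = None


@dataclass(frozen=True)
class FreezingTrace:
    """1 Hz immobility trace: percent immobility per second plus the
    binarization threshold used to call a second 'freezing'."""

    percent: np.ndarray
    rate_hz: float = 1.0
    binarize_threshold: float = 50.0

    @property
    def binary(self) -> np.ndarray:
        return self.percent > self.binarize_threshold

    @property
    def n_seconds(self) -> int:
        return self.percent.size


def calcium_kernel(fps: float, tau_rise: float = 0.05, tau_decay: float = 0.4,
                   amplitude: float = 1.0) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalized to ``amplitude``.

    Truncated where the decay envelope falls below 1e-3 of its peak.
    """
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("time constants must be positive")
    if tau_rise >= tau_decay:
        raise ValueError("tau_rise must be smaller than tau_decay")
    n = int(np.ceil(tau_decay * np.log(1000.0) * fps)) + 1
    t = np.arange(n) / fps
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel")
    return amplitude * k / peak


def _slow_drift(n_frames: int, sigma_frames: float, sd: float,
                rng: np.random.Generator) -> np.ndarray:
    """Slow Gaussian baseline wander with correlation scale ``sigma_frames``,
    standardized to standard deviation ``sd``.

    Generated on a coarse knot grid and interpolated, so long sessions stay
    cheap.
    """
    spacing = max(sigma_frames / 4.0, 1.0)
    n_knots = int(np.ceil(n_frames / spacing)) + 9
    knots = gaussian_filter(rng.normal(size=n_knots), sigma=4.0, mode="wrap")
    x = np.interp(np.arange(n_frames) / spacing, np.arange(n_knots), knots)
    s = x.std()
    return (x - x.mean()) / s * sd if s > 0 else np.zeros(n_frames)


def _thin_refractory(spike_idx: np.ndarray, min_sep: int) -> np.ndarray:
    if min_sep <= 1 or spike_idx.size == 0:
        return spike_idx
    kept = [int(spike_idx[0])]
    for t in spike_idx[1:]:
        if t - kept[-1] >= min_sep:
            kept.append(int(t))
    return np.array(kept, dtype=int)


def simulate_traces(
    schedule: StimulusSchedule,
    n_neurons: int,
    base_rate: float = 0.2,
    coupling: CouplingSpec | None = None,
    kernel_tau_rise: float = 0.05,
    kernel_tau_decay: float = 0.4,
    noise_sd: float = 0.05,
    noise_tau_s: float = 90.0,
    min_separation_s: float = 0.2,
    baseline: float = 1.0,
    amplitude: float = 1.0,
    behavior_high_mask: np.ndarray | None = None,
    seed: int | None = None,
):
    """Simulate a fluorescence TraceMatrix tied to a schedule.

    Spikes are one Bernoulli draw per frame with probability
    ``rate x (1/fps)`` (valid for rates well below the frame rate), where the
    rate is ``base_rate`` scaled by the neuron's class multiplier on its
    designated frames: tone frames for excited/inhibited classes,
    ``behavior_high_mask`` frames for behavior-coupled classes. Draws closer
    than ``min_separation_s`` to the previous kept spike are discarded:
    separate calcium transients are not resolvable below the indicator rise
    time, so ground-truth events carry that minimum spacing (the returned
    spike times are the kept ones). Spike trains are convolved with a
    difference-of-exponentials transient; the noise term emulates what
    survives deconvolution — slow baseline wander with correlation scale
    ``noise_tau_s`` (bleaching/focus drift; set 0 for white noise) of
    standard deviation ``noise_sd`` — on top of a constant baseline offset.

    Returns ``(TraceMatrix, SyntheticGroundTruth)``.
    """
    from .traces import TraceMatrix  # local import to avoid cycle at module load

    if base_rate < 0:
        raise ValueError("base_rate must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")

    rng = np.random.default_rng(seed)
    n_frames = schedule.total_frames
    fps = schedule.fps
    if coupling is None:
        coupling = CouplingSpec(classes=("null",) * n_neurons)
    if len(coupling.classes) != n_neurons:
        raise ValueError("coupling spec length does not match n_neurons")

    tone = schedule.tone_mask()
    if behavior_high_mask is not None:
        behavior_high_mask = np.asarray(behavior_high_mask, dtype=bool)
        if behavior_high_mask.size != n_frames:
            raise ValueError("behavior_high_mask length does not match schedule")
    elif any(c in ("pos_coupled", "neg_coupled") for c in coupling.classes):
        raise ValueError("behavior-coupled classes need behavior_high_mask")

    kernel = calcium_kernel(fps, kernel_tau_rise, kernel_tau_decay, amplitude)
    base_p = base_rate / fps
    min_sep = int(round(min_separation_s * fps))

    signal = np.empty((n_neurons, n_frames))
    spike_times = []
    for i, cls_name in enumerate(coupling.classes):
        mult = coupling.multipliers[cls_name]
        p = np.full(n_frames, base_p)
        if cls_name in ("excited", "inhibited"):
            p[tone] = base_p * mult
        elif cls_name in ("pos_coupled", "neg_coupled"):
            p[behavior_high_mask] = base_p * mult
        np.clip(p, 0.0, 1.0, out=p)
        drawn = np.nonzero(rng.random(n_frames) < p)[0]
        # a transient peaking after the recording ends is not an observable event
        drawn = drawn[drawn + int(np.argmax(kernel)) < n_frames]
        kept = _thin_refractory(drawn, min_sep)
        spike_times.append(kept)
        row = np.zeros(n_frames + kernel.size)
        for t in kept:  # exact superposition (no FFT round-off on the baseline)
            row[t:t + kernel.size] += kernel
        signal[i] = row[:n_frames]

    if noise_sd > 0:
        sigma_frames = noise_tau_s * fps
        if sigma_frames > 0:
            noise = np.stack([_slow_drift(n_frames, sigma_frames, noise_sd, rng)
                              for _ in range(n_neurons)])
        else:
            noise = rng.normal(0.0, noise_sd, size=signal.shape)
    else:
        noise = 0.0
    values = baseline + signal + noise
    gt = SyntheticGroundTruth(
        neuron_class=tuple(coupling.classes),
        spike_times=tuple(spike_times),
        seed=seed,
    )
    return TraceMatrix(values=values, fps=fps), gt


def _markov_states(n: int, p_enter_high: float, p_exit_high: float,
                   rng: np.random.Generator) -> np.ndarray:
    if not (0 <= p_enter_high < 1) or not (0 <= p_exit_high < 1):
        raise ValueError("transition probabilities must lie in [0, 1)")
    states = np.zeros(n, dtype=np.int8)  # 0 = low, 1 = high; start low
    u = rng.random(n)
    for t in range(1, n):
        if states[t - 1] == 0:
            states[t] = 1 if u[t] < p_enter_high else 0
        else:
            states[t] = 0 if u[t] < p_exit_high else 1
    return states


def simulate_movement_video(
    n_frames: int,
    height: int = 96,
    width: int = 96,
    p_enter_high: float = 0.05,
    p_exit_high: float = 0.15,
    jitter_low_px: int = 0,
    jitter_high_px: int = 4,
    body_size: int = 48,
    texture_sigma: float = 2.0,
    pixel_noise_sd: float = 0.003,
    seed: int | None = None,
):
    """Simulate restraint video with a hidden two-state movement process.

    A smoothly textured square 'body' sits on a static textured background;
    its position performs a bounded integer random walk whose per-frame step
    is drawn uniformly in ``[-j, j]`` per axis with ``j`` set by the hidden
    state (low/high). High-state steps are re-drawn until their Chebyshev
    norm reaches ``ceil(j/2)``, reflecting that struggle bouts are
    large-amplitude; the default low state is integer-still (sub-pixel
    tremor). Per-pixel sensor noise makes edge masks flicker slightly, as in
    real video, so low-movement scores form a smooth distribution rather
    than an atom at zero. Textures are low-pass speckle (Gaussian-smoothed
    noise), so edge masks overlap substantially at small shifts and the
    movement score grows monotonically with jitter until decorrelation.

    Returns ``(frames, SyntheticGroundTruth)`` with float frames in [0, 1]
    and the per-frame hidden state sequence (0 = low, 1 = high).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if not (0 <= jitter_low_px < jitter_high_px):
        raise ValueError("need jitter_high_px > jitter_low_px >= 0")
    margin = 2 * jitter_high_px + 2
    if body_size + 2 * margin > min(height, width):
        raise ValueError("body (plus jitter margin) larger than the frame")

    rng = np.random.default_rng(seed)
    states = _markov_states(n_frames, p_enter_high, p_exit_high, rng)

    def _speckle(shape, lo, hi):
        tex = gaussian_filter(rng.random(shape), texture_sigma)
        tmin, tmax = tex.min(), tex.max()
        return lo + (hi - lo) * (tex - tmin) / (tmax - tmin)

    texture = _speckle((body_size, body_size), 0.2, 1.0)
    background = _speckle((height, width), 0.0, 0.45).astype(np.float32)

    base_r = (height - body_size) // 2
    base_c = (width - body_size) // 2
    max_off = margin - 1

    frames = np.broadcast_to(background, (n_frames, height, width)).copy()
    off = np.zeros(2, dtype=int)
    min_high_step = max(1, int(np.ceil(jitter_high_px / 2)))
    for t in range(n_frames):
        if t > 0:
            j = jitter_high_px if states[t] else jitter_low_px
            step = rng.integers(-j, j + 1, size=2)
            if states[t]:
                while np.max(np.abs(step)) < min_high_step:
                    step = rng.integers(-j, j + 1, size=2)
            off = np.clip(off + step, -max_off, max_off)
        r, c = base_r + off[0], base_c + off[1]
        frames[t, r:r + body_size, c:c + body_size] = texture

    if pixel_noise_sd > 0:  # sensor noise: edge masks flicker, as in real video
        frames += rng.normal(0.0, pixel_noise_sd, size=frames.shape).astype(np.float32)
        np.clip(frames, 0.0, 1.0, out=frames)

    gt = SyntheticGroundTruth(state_sequence=states, seed=seed)
    return frames, gt


def simulate_freezing(
    schedule: StimulusSchedule,
    p_freeze_tone: float = 0.8,
    p_freeze_iti: float = 0.2,
    binarize_threshold: float = 50.0,
    seed: int | None = None,
) -> tuple[FreezingTrace, SyntheticGroundTruth]:
    """Simulate the 1 Hz percent-immobility output of freezing software.

    Each second is drawn frozen with probability ``p_freeze_tone`` if most
    of its frames fall inside a tone and ``p_freeze_iti`` otherwise; frozen
    seconds report an immobility percentage uniform in (70, 100), other
    seconds uniform in (0, 30), so binarization at the default threshold of
    50% recovers the drawn state exactly.
    """
    for name, p in (("p_freeze_tone", p_freeze_tone), ("p_freeze_iti", p_freeze_iti)):
        if not (0 <= p <= 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_seconds = int(schedule.total_frames // schedule.fps)
    tone = schedule.tone_mask()
    fps = int(round(schedule.fps))
    tone_second = np.array(
        [tone[s * fps:(s + 1) * fps].mean() >= 0.5 for s in range(n_seconds)]
    )
    p_vec = np.where(tone_second, p_freeze_tone, p_freeze_iti)
    frozen = rng.random(n_seconds) < p_vec
    percent = np.where(frozen,
                       rng.uniform(70.0, 100.0, n_seconds),
                       rng.uniform(0.0, 30.0, n_seconds))
    trace = FreezingTrace(percent=percent, rate_hz=1.0,
                          binarize_threshold=binarize_threshold)
    gt = SyntheticGroundTruth(state_sequence=frozen.astype(np.int8), seed=seed)
    return trace, gt
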