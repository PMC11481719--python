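"""Tone-responsiveness of single neurons via the phi coefficient.

Each neuron's activity is a Boolean per-frame event vector; the tone
schedule is a second Boolean vector. Their association is the phi
coefficient of the 2x2 contingency table (true positive = event during
tone, false negative = tone frame without an event, and so on). To avoid a
global phi cut-off, each neuron's events are randomized 1000 times and phi
recomputed, building a null matrix R; the observed phi is expressed as a Z
distance from its null and a neuron is called excited (inhibited) when its
observed phi exceeds (falls below) the null's 95% interval.

A uniform permutation of a binary event vector leaves both margins of the
contingency table fixed, so the randomized true-positive count is exactly
hypergeometric and phi is a deterministic function of it. The default null
therefore draws TP ~ Hypergeometric(N, n_tone, k) directly — the identical
distribution at a fraction of the cost; ``method='permute'`` performs the
literal permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .schedules import StimulusSchedule
from .traces import EventRaster

__all__ = [
    "PhiResult",
    "phi_coefficient",
    "phi_from_margins",
    "shuffle_null",
    "tone_responsiveness",
    "classify_responsive",
    "per_block_responsiveness",
    "responsive_fractions",
]


@dataclass(frozen=True)
class PhiResult:
    """Per-neuron phi statistics against a shuffle null."""

    phi_obs: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    n_shuffles: int
    seed: int | None = None
    labels: tuple[str, ...] | None = None
    degenerate: np.ndarray | None = None
    null_matrix: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.phi_obs.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "phi": self.phi_obs,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "z": self.z,
                "ci95_low": self.ci95_low,
                "ci95_high": self.ci95_high,
            }
        )
        if self.labels is not None:
            df["label"] = list(self.labels)
        return df


def _contingency(events: np.ndarray, stimulus: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum(events & stimulus))
    fn = int(np.sum(~events & stimulus))
    fp = int(np.sum(events & ~stimulus))
    tn = int(np.sum(~events & ~stimulus))
    return tp, fp, fn, tn


def _phi_from_cells(tp, fp, fn, tn) -> tuple[float, bool]:
    tp = np.asarray(tp, dtype=float)
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate = denom2 == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(degenerate, 0.0, (tp * tn - fp * fn) / np.sqrt(denom2))
    return phi, degenerate


def phi_coefficient(events: Sequence[bool] | np.ndarray,
                    stimulus: Sequence[bool] | np.ndarray) -> float:
    """Phi coefficient of two Boolean vectors from their contingency table.

    ``phi = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))`` with
    TP = event during stimulus, FN = stimulus frame without an event,
    FP = event outside stimulus, TN = neither. Returns 0 when an event
    margin is degenerate (no events or all events). The stimulus vector must
    contain both values.
    """
    events = np.asarray(events, dtype=bool)
    stimulus = np.asarray(stimulus, dtype=bool)
    if events.shape != stimulus.shape or events.ndim != 1:
        raise ValueError("events and stimulus must be 1-D vectors of equal length")
    if events.size < 2:
        raise ValueError("need at least 2 frames")
    if stimulus.all() or not stimulus.any():
        raise ValueError("stimulus vector must contain both True and False frames")
    phi, _ = _phi_from_cells(*_contingency(events, stimulus))
    return float(phi)


def phi_from_margins(tp: np.ndarray, n: int, n_stim: int, k: int) -> np.ndarray:
    """Phi as a function of the TP cell with both margins fixed
    (N frames, n_stim stimulus frames, k events)."""
    tp = np.asarray(tp, dtype=float)
    fp = k - tp
    fn = n_stim - tp
    tn = n - n_stim - k + tp
    phi, _ = _phi_from_cells(tp, fp, fn, tn)
    return phi


def _null_phis(events: np.ndarray, stimulus: np.ndarray, n_shuffles: int,
               rng: np.random.Generator, method: str) -> np.ndarray:
    n = events.size
    n_stim = int(stimulus.sum())
    k = int(events.sum())
    if method == "hypergeometric":
        tp = rng.hypergeometric(n_stim, n - n_stim, k, size=n_shuffles) if k else np.zeros(n_shuffles)
        return phi_from_margins(tp, n, n_stim, k)
    if method == "permute":
        phis = np.empty(n_shuffles)
        for s in range(n_shuffles):
            perm = rng.permutation(events)
            phis[s] = phi_from_margins(int(np.sum(perm & stimulus)), n, n_stim, k)
        return phis
    if method == "circular":
        # circular shift preserves within-event autocorrelation
        phis = np.empty(n_shuffles)
        shifts = rng.integers(1, n, size=n_shuffles)
        for s in range(n_shuffles):
            rolled = np.roll(events, shifts[s])
            phis[s] = phi_from_margins(int(np.sum(rolled & stimulus)), n, n_stim, k)
        return phis
    raise ValueError(f"unknown shuffle method {method!r}")


def shuffle_null(events: np.ndarray, stimulus: np.ndarray,
                 n_shuffles: int = 1000, seed: int | None = None,
                 method: str = "hypergeometric",
                 keep_null: bool = True) -> PhiResult:
    """Shuffle null for a single neuron: randomize the event vector
    ``n_shuffles`` times (event count preserved), recompute phi each time,
    and summarize the null (mean, SD, central 95% interval, Z distance).

    ``method='hypergeometric'`` (default) draws the equivalent exact null;
    ``'permute'`` performs literal uniform permutations; ``'circular'``
    rolls the vector by a random offset (conservative for multi-frame
    transients).
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    events = np.asarray(events, dtype=bool)
    stimulus = np.asarray(stimulus, dtype=bool)
    phi_obs = phi_coefficient(events, stimulus)
    rng = np.random.default_rng(seed)
    null = _null_phis(events, stimulus, n_shuffles, rng, method)
    null_mean = null.mean()
    null_sd = null.std(ddof=1)
    lo, hi = np.quantile(null, [0.025, 0.975])
    degenerate = null_sd == 0
    z = (phi_obs - null_mean) / null_sd if not degenerate else np.nan
    return PhiResult(
        phi_obs=np.array([phi_obs]),
        null_mean=np.array([null_mean]),
        null_sd=np.array([null_sd]),
        z=np.array([z]),
        ci95_low=np.array([lo]),
        ci95_high=np.array([hi]),
        n_shuffles=n_shuffles,
        seed=seed,
        degenerate=np.array([degenerate]),
        null_matrix=null[None, :] if keep_null else None,
    )


def tone_responsiveness(raster: EventRaster | np.ndarray,
                        stimulus: np.ndarray,
                        n_shuffles: int = 1000,
                        seed: int | None = None,
                        method: str = "hypergeometric",
                        z_crit: float = 1.96,
                        rule: str = "ci",
                        keep_null: bool = False) -> PhiResult:
    """Population version: phi, null and label for every neuron in a raster."""
    events_mat = raster.events if isinstance(raster, EventRaster) else np.asarray(raster, dtype=bool)
    stimulus = np.asarray(stimulus, dtype=bool)
    n_neurons = events_mat.shape[0]
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    rng = np.random.default_rng(seed)
    phi_obs = np.empty(n_neurons)
    null_mean = np.empty(n_neurons)
    null_sd = np.empty(n_neurons)
    lo = np.empty(n_neurons)
    hi = np.empty(n_neurons)
    degenerate = np.zeros(n_neurons, dtype=bool)
    nulls = np.empty((n_neurons, n_shuffles)) if keep_null else None
    for i in range(n_neurons):
        phi_obs[i] = phi_coefficient(events_mat[i], stimulus)
        null = _null_phis(events_mat[i], stimulus, n_shuffles, rng, method)
        if nulls is not None:
            nulls[i] = null
        null_mean[i] = null.mean()
        null_sd[i] = null.std(ddof=1)
        lo[i], hi[i] = np.quantile(null, [0.025, 0.975])
        degenerate[i] = null_sd[i] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(degenerate, np.nan, (phi_obs - null_mean) / null_sd)
    result = PhiResult(phi_obs=phi_obs, null_mean=null_mean, null_sd=null_sd,
                       z=z, ci95_low=lo, ci95_high=hi, n_shuffles=n_shuffles,
                       seed=seed, degenerate=degenerate, null_matrix=nulls)
    return classify_responsive(result, z_crit=z_crit, rule=rule)


def classify_responsive(result: PhiResult, z_crit: float = 1.96,
                        rule: str = "ci") -> PhiResult:
    """Label each neuron excited / inhibited / nonresponsive.

    ``rule='ci'`` (default): excited when observed phi exceeds the null's
    97.5th percentile, inhibited when below the 2.5th. ``rule='z'``: |Z|
    at or above ``z_crit`` with the matching sign. Degenerate nulls are
    forced nonresponsive.
    """
    labels = []
    for i in range(result.n_neurons):
        if result.degenerate is not None and result.degenerate[i]:
            labels.append("nonresponsive")
            continue
        if rule == "ci":
            if result.phi_obs[i] > result.ci95_high[i]:
                labels.append("excited")
            elif result.phi_obs[i] < result.ci95_low[i]:
                labels.append("inhibited")
            else:
                labels.append("nonresponsive")
        elif rule == "z":
            if result.z[i] >= z_crit:
                labels.append("excited")
            elif result.z[i] <= -z_crit:
                labels.append("inhibited")
            else:
                labels.append("nonresponsive")
        else:
            raise ValueError(f"unknown rule {rule!r}")
    return replace(result, labels=tuple(labels))


def _block_frames(schedule: StimulusSchedule, tone_idx: Sequence[int]) -> np.ndarray:
    """Frame indices of a tone block: the block's tones plus, per tone, an
    equal-duration off-tone window immediately after tone offset (keeps the
    stimulus margins comparable across blocks)."""
    idx: list[np.ndarray] = []
    for t in tone_idx:
        start, end = schedule.tone_intervals[t]
        dur = end - start
        off_end = min(end + dur, schedule.total_frames)
        next_start = (schedule.tone_intervals[t + 1][0]
                      if t + 1 < len(schedule.tone_intervals) else schedule.total_frames)
        off_end = min(off_end, next_start)
        idx.append(np.arange(start, end))
        idx.append(np.arange(end, off_end))
    return np.concatenate(idx)


def per_block_responsiveness(raster: EventRaster, schedule: StimulusSchedule,
                             blocks: Mapping[str, Sequence[int]],
                             n_shuffles: int = 1000, seed: int | None = None,
                             **kwargs) -> dict[str, PhiResult]:
    """Classify every neuron within each tone block (e.g. first / middle /
    last five tones of an extinction session).

    ``blocks`` maps a block name to the indices of its tones in the
    schedule. For each block, the stimulus vector is restricted to the
    block's tone frames plus matched-duration off-tone frames.
    """
    out = {}
    for b, (name, tone_idx) in enumerate(blocks.items()):
        frames = _block_frames(schedule, tone_idx)
        stim = schedule.tone_mask()[frames]
        sub = raster.events[:, frames]
        block_seed = None if seed is None else seed + b
        out[name] = tone_responsiveness(sub, stim, n_shuffles=n_shuffles,
                                        seed=block_seed, **kwargs)
    return out


def responsive_fractions(
    block_labels: Mapping[str, Mapping[str, Sequence[str]]],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Percentage of excited and inhibited neurons per group per tone block.

    ``block_labels[block][animal]`` is the per-neuron label sequence for one
    animal in one block; ``groups`` maps animal to its group (e.g. sex).
    Per-animal percentages are averaged within group (mean ± SEM).
    """
    rows = []
    for block, per_animal in block_labels.items():
        if not per_animal:
            raise ValueError(f"block {block!r} has no animals")
        for animal, labels in per_animal.items():
            labels = list(labels)
            n = len(labels)
            if n == 0:
                raise ValueError(f"animal {animal!r} has no neurons in block {block!r}")
            rows.append({
                "block": block,
                "animal": animal,
                "group": groups[animal],
                "pct_excited": 100.0 * labels.count("excited") / n,
                "pct_inhibited": 100.0 * labels.count("inhibited") / n,
            })
    per_animal_df = pd.DataFrame(rows)
    summary = (per_animal_df
               .groupby(["block", "group"], sort=False)[["pct_excited", "pct_inhibited"]]
               .agg(["mean", "sem"]))
    summary.columns = ["_".join(c) for c in summary.columns]
    return summary.reset_index()
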