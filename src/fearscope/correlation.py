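"""Correlation of fluorescence with behavior (movement or freezing).

Single-neuron ΔF/F0 traces (and the whole-field mean) are paired with a
behavioral series — the frame-rate movement score during restraint, or the
1 Hz freezing trace during conditioning/extinction — and tested with
Pearson's correlation. A neuron is positively correlated when p < alpha and
r > 0, negatively correlated when p < alpha and r < 0, and uncorrelated
otherwise. When the behavioral series is slower than the fluorescence (1 Hz
freezing vs 30 fps traces), the fluorescence is averaged within each
behavior sample's interval; averaging the faster series preserves its
information, unlike interpolating the slower one. No multiple-testing
correction is applied across neurons — labels use per-neuron thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traces import TraceMatrix

__all__ = [
    "CorrClassification",
    "align_behavior",
    "pearson_with_p",
    "classify_neurons",
]


@dataclass(frozen=True)
class CorrClassification:
    """Per-neuron Pearson r, two-sided p and correlation class."""

    r: np.ndarray
    p: np.ndarray
    labels: tuple[str, ...]
    behavior_kind: str
    alpha: float = 0.05
    degenerate: np.ndarray | None = None

    def counts(self) -> dict[str, int]:
        return {lab: list(self.labels).count(lab)
                for lab in ("positive", "negative", "uncorrelated")}

    def percentages(self) -> dict[str, float]:
        n = len(self.labels)
        return {lab: 100.0 * c / n for lab, c in self.counts().items()}

    def to_frame(self, neuron_ids: tuple[str, ...] | None = None) -> pd.DataFrame:
        ids = neuron_ids if neuron_ids is not None else [str(i) for i in range(self.r.size)]
        return pd.DataFrame({"neuron_id": list(ids), "r": self.r, "p": self.p,
                             "label": list(self.labels)})


def align_behavior(traces: TraceMatrix, behavior: np.ndarray,
                   behavior_rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Pair the trace matrix with a behavioral series at the behavior's rate.

    When the behavior runs at the frame rate the pairing is 1:1 (truncated
    to the common length). When it is slower by an integer frame factor,
    each behavior sample is paired with the mean fluorescence over the
    frames it spans. Returns ``(aligned_traces, aligned_behavior)``.
    """
    behavior = np.asarray(behavior, dtype=float)
    if behavior.ndim != 1 or behavior.size == 0:
        raise ValueError("behavior must be a non-empty 1-D series")
    if behavior_rate_hz <= 0:
        raise ValueError("behavior_rate_hz must be positive")
    ratio = traces.fps / behavior_rate_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("frame rate must be an integer multiple of the behavior rate")
    step = int(round(ratio))
    if step == 1:
        m = min(traces.n_frames, behavior.size)
        if m == 0:
            raise ValueError("series do not overlap")
        return traces.values[:, :m], behavior[:m]
    m = min(traces.n_frames // step, behavior.size)
    if m == 0:
        raise ValueError("series do not overlap")
    binned = traces.values[:, :m * step].reshape(traces.n_neurons, m, step).mean(axis=2)
    return binned, behavior[:m]


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with the two-sided p-value from the t distribution
    on n − 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length series with at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant series have no defined correlation")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def classify_neurons(traces: TraceMatrix, behavior: np.ndarray,
                     behavior_rate_hz: float, behavior_kind: str,
                     alpha: float = 0.05) -> CorrClassification:
    """Correlate every neuron with the behavioral series and classify it.

    All-constant neurons are flagged degenerate and counted uncorrelated.
    """
    if behavior_kind not in ("movement", "freezing"):
        raise ValueError("behavior_kind must be 'movement' or 'freezing'")
    aligned, beh = align_behavior(traces, behavior, behavior_rate_hz)
    if np.ptp(beh) == 0:
        raise ValueError("behavior series is constant")
    n = aligned.shape[0]
    r = np.full(n, np.nan)
    p = np.full(n, np.nan)
    degenerate = np.zeros(n, dtype=bool)
    labels = []
    for i in range(n):
        if np.ptp(aligned[i]) == 0:
            degenerate[i] = True
            labels.append("uncorrelated")
            continue
        r[i], p[i] = pearson_with_p(aligned[i], beh)
        if p[i] < alpha and r[i] > 0:
            labels.append("positive")
        elif p[i] < alpha and r[i] < 0:
            labels.append("negative")
        else:
            labels.append("uncorrelated")
    return CorrClassification(r=r, p=p, labels=tuple(labels),
                              behavior_kind=behavior_kind, alpha=alpha,
                              degenerate=degenerate)
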