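"""Video-based movement scoring and high-movement state classification.

The movement of a restrained animal is scored frame to frame: each grayscale
frame is reduced to a binary edge mask (Sobel gradient magnitude thresholded
at a fudge factor times an automatic canny-style high threshold), and the
score for frame *n* is the fraction of its edge pixels that were absent from
frame *n−1*. Scores are shifted to median 0 and scaled by the central 95%
interpercentile range, a two-component Gaussian mixture is fitted to the
normalized scores, and the intersection of the two component densities
between their means classifies frames as low or high movement. Epoch metrics
(percent of frames, mean bout length, bout frequency) summarize the result.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from sklearn.mixture import GaussianMixture

__all__ = [
    "EdgeMask",
    "MovementTrace",
    "MixtureFit",
    "EMConvergenceError",
    "edge_mask",
    "movement_score",
    "score_video",
    "normalize_movement",
    "fit_two_gaussian_threshold",
    "gaussian_intersection",
    "high_movement_epochs",
]


class EMConvergenceError(RuntimeError):
    """EM failed to converge; carries the final lower bound and iterations."""

    def __init__(self, n_iter: int, lower_bound: float, max_iter: int):
        self.n_iter = n_iter
        self.lower_bound = lower_bound
        super().__init__(
            f"EM did not converge within {max_iter} iterations "
            f"(final lower bound {lower_bound:.6g} after {n_iter} iterations)"
        )


@dataclass(frozen=True)
class EdgeMask:
    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def n_edge_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class MixtureFit:
    """Two-Gaussian mixture parameters (ordered mu1 < mu2) and the
    intersection threshold between the means."""

    w1: float
    mu1: float
    sigma1: float
    w2: float
    mu2: float
    sigma2: float
    threshold: float
    converged: bool = True
    n_iter: int = 0
    midpoint_fallback: bool = False

    def pdf(self, x: np.ndarray) -> np.ndarray:
        from scipy.stats import norm

        return (self.w1 * norm.pdf(x, self.mu1, self.sigma1)
                + self.w2 * norm.pdf(x, self.mu2, self.sigma2))


@dataclass(frozen=True)
class MovementTrace:
    """Per-frame movement score trace. ``raw[n]`` scores the transition from
    frame n to frame n+1 (length n_frames − 1; there is no score for the
    first frame)."""

    raw: np.ndarray
    fps: float
    normalized: np.ndarray | None = None
    mixture: MixtureFit | None = None

    @property
    def threshold(self) -> float | None:
        return None if self.mixture is None else self.mixture.threshold

    @property
    def high_mask(self) -> np.ndarray | None:
        if self.normalized is None or self.mixture is None:
            return None
        return self.normalized > self.mixture.threshold

    def with_normalized(self) -> "MovementTrace":
        return replace(self, normalized=normalize_movement(self.raw))

    def with_mixture(self, seed: int = 0, **kwargs) -> "MovementTrace":
        if self.normalized is None:
            raise ValueError("normalize before fitting the mixture")
        fit = fit_two_gaussian_threshold(self.normalized, seed=seed, **kwargs)
        return replace(self, mixture=fit)


def _to_grayscale(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3 and frame.shape[-1] in (3, 4):
        from skimage.color import rgb2gray

        return rgb2gray(frame[..., :3])
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D grayscale or RGB(A)")
    return frame


def edge_mask(frame: np.ndarray, fudge: float = 0.5,
              high_quantile: float = 0.7) -> EdgeMask:
    """Binary edge mask: Sobel gradient magnitude above an automatic threshold.

    The automatic threshold is the canny-style high threshold — the
    ``high_quantile`` quantile of the frame's nonzero gradient magnitudes
    (default retains the strongest 30%) — scaled by ``fudge``. A constant
    frame yields an empty mask.
    """
    if fudge <= 0:
        raise ValueError("fudge must be positive")
    gray = _to_grayscale(frame)
    gx = ndimage.sobel(gray, axis=0, mode="reflect")
    gy = ndimage.sobel(gray, axis=1, mode="reflect")
    grad = np.hypot(gx, gy)
    nz = grad[grad > 0]
    if nz.size == 0:
        return EdgeMask(mask=np.zeros(gray.shape, dtype=bool))
    thr = fudge * np.quantile(nz, high_quantile)
    return EdgeMask(mask=grad > thr)


def movement_score(mask_prev: EdgeMask | np.ndarray,
                   mask_curr: EdgeMask | np.ndarray) -> float:
    """Fraction of current edge pixels absent from the previous mask.

    ``|curr AND NOT prev| / |curr|``; 0 when the current mask is empty (a
    frame with no edges carries no motion evidence).
    """
    prev = mask_prev.mask if isinstance(mask_prev, EdgeMask) else np.asarray(mask_prev, dtype=bool)
    curr = mask_curr.mask if isinstance(mask_curr, EdgeMask) else np.asarray(mask_curr, dtype=bool)
    if prev.shape != curr.shape:
        raise ValueError("mask shapes differ")
    n_curr = curr.sum()
    if n_curr == 0:
        return 0.0
    return float((curr & ~prev).sum() / n_curr)


def score_video(frames: np.ndarray, fps: float = 30.0, fudge: float = 0.5,
                high_quantile: float = 0.7) -> MovementTrace:
    """Edge-mask every frame and score each consecutive transition.

    ``raw[n]`` corresponds to the transition from frame n to frame n+1.
    """
    frames = np.asarray(frames)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    masks = [edge_mask(frames[t], fudge=fudge, high_quantile=high_quantile).mask
             for t in range(frames.shape[0])]
    raw = np.array([movement_score(masks[t - 1], masks[t])
                    for t in range(1, len(masks))])
    return MovementTrace(raw=raw, fps=fps)


def normalize_movement(raw: np.ndarray) -> np.ndarray:
    """Shift scores to median 0 and scale by the central 95% interpercentile
    range (q97.5 − q2.5)."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 20:
        raise ValueError("need at least 20 scores to normalize")
    lo, hi = np.quantile(raw, [0.025, 0.975])
    scale = hi - lo
    if scale <= 0:
        raise ValueError("degenerate movement trace: zero interpercentile range")
    return (raw - np.median(raw)) / scale


def gaussian_intersection(w1: float, mu1: float, sigma1: float,
                          w2: float, mu2: float, sigma2: float,
                          ) -> tuple[float, bool]:
    """Root of ``w1 N(x|mu1,s1) = w2 N(x|mu2,s2)`` between the two means.

    Solves the quadratic obtained from the log-density equality. With equal
    variances the equation is linear (and with equal weights too, the root
    is exactly the midpoint of the means). When no root falls strictly
    between the means (e.g. nested components) the midpoint of the means is
    returned with the fallback flag set.
    """
    if mu1 > mu2:
        (w1, mu1, sigma1), (w2, mu2, sigma2) = (w2, mu2, sigma2), (w1, mu1, sigma1)
    a = 0.5 * (1.0 / sigma2**2 - 1.0 / sigma1**2)
    b = mu1 / sigma1**2 - mu2 / sigma2**2
    c = (0.5 * (mu2**2 / sigma2**2 - mu1**2 / sigma1**2)
         + np.log((w1 * sigma2) / (w2 * sigma1)))
    midpoint = 0.5 * (mu1 + mu2)
    if abs(a) < 1e-300 or sigma1 == sigma2:
        # equal variances: linear equation b x + c = 0
        if b == 0:
            return midpoint, True
        x = -c / b
        if mu1 < x < mu2 or mu1 == mu2:
            return float(x), False
        return midpoint, True
    disc = b * b - 4 * a * c
    if disc < 0:
        return midpoint, True
    roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    inside = roots[(roots > mu1) & (roots < mu2)]
    if inside.size == 0:
        return midpoint, True
    return float(inside[0]), False


def fit_two_gaussian_threshold(normalized: np.ndarray, seed: int = 0,
                               max_iter: int = 500, tol: float = 1e-6,
                               n_init: int = 3) -> MixtureFit:
    """EM fit of a two-component univariate Gaussian mixture to the
    normalized movement scores, with the high-movement threshold at the
    intersection of the two weighted component densities.

    Initialization is k-means with the given seed (deterministic). Raises
    :class:`EMConvergenceError` if EM does not converge within ``max_iter``.
    """
    x = np.asarray(normalized, dtype=float).reshape(-1, 1)
    if x.shape[0] < 4:
        raise ValueError("too few scores for a two-component fit")
    gm = GaussianMixture(n_components=2, covariance_type="full",
                         max_iter=max_iter, tol=tol, n_init=n_init,
                         init_params="kmeans", random_state=seed)
    gm.fit(x)
    if not gm.converged_:
        raise EMConvergenceError(gm.n_iter_, float(gm.lower_bound_), max_iter)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    (mu1, mu2) = means[order]
    (s1, s2) = sds[order]
    (w1, w2) = weights[order]
    thr, fallback = gaussian_intersection(w1, mu1, s1, w2, mu2, s2)
    return MixtureFit(w1=float(w1), mu1=float(mu1), sigma1=float(s1),
                      w2=float(w2), mu2=float(mu2), sigma2=float(s2),
                      threshold=thr, converged=True, n_iter=int(gm.n_iter_),
                      midpoint_fallback=fallback)


def high_movement_epochs(normalized: np.ndarray, threshold: float,
                         fps: float) -> dict:
    """Run-length metrics of high-movement frames (normalized > threshold).

    Returns percent_frames, mean_length_s (NaN when there are no epochs),
    frequency_per_s (bouts per second of trace), and the epoch list as
    half-open index intervals into the score trace.
    """
    normalized = np.asarray(normalized, dtype=float)
    high = normalized > threshold
    n = high.size
    padded = np.concatenate([[False], high, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    epochs = list(zip(starts.tolist(), ends.tolist()))
    lengths = ends - starts
    return {
        "percent_frames": 100.0 * high.sum() / n,
        "mean_length_s": float(lengths.mean() / fps) if lengths.size else float("nan"),
        "frequency_per_s": len(epochs) / (n / fps),
        "n_epochs": len(epochs),
        "epochs": epochs,
    }
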