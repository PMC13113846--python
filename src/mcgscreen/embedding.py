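"""Time-delay phase-space reconstruction and parameter selection.

A scalar series x_1..x_N is lifted to trajectory points
s_i = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau}) following Takens' embedding
theorem.  The delay tau is chosen as the first local minimum of the
lagged mutual information, the dimension m by the false-nearest-neighbors
criterion, and the recurrence threshold epsilon by fixing the target
recurrence rate (default 10%), the standard convention that makes
recurrence plots comparable across cycles.  The pipeline ships with
(m=3, tau=4) as fixed defaults for 224-sample cardiac cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .errors import DegenerateInputError, InvalidParameterError

__all__ = [
    "EmbeddingParams",
    "PhaseTrajectory",
    "delay_embed",
    "estimate_delay_mi",
    "estimate_dim_fnn",
    "select_epsilon",
]


@dataclass
class EmbeddingParams:
    """Embedding configuration; defaults are the pipeline-wide values."""

    m: int = 3
    tau: int = 4
    epsilon: float | None = None  # None: choose per image from the recurrence rate
    recurrence_rate: float = 0.10
    mi_bins: int = 16
    fnn_rtol: float = 10.0
    fnn_atol: float = 2.0


@dataclass
class PhaseTrajectory:
    """M = N - (m-1)*tau points of dimension m, row per time index."""

    points: np.ndarray
    m: int
    tau: int


def delay_embed(x: np.ndarray, m: int, tau: int) -> PhaseTrajectory:
    """Point i (0-based) = (x[i], x[i+tau], ..., x[i+(m-1)tau])."""
    x = np.asarray(x, dtype=float)
    if m < 1 or tau < 1:
        raise InvalidParameterError("m and tau must be >= 1")
    n_points = x.size - (m - 1) * tau
    if n_points < 2:
        raise InvalidParameterError(
            f"series of length {x.size} too short for (m={m}, tau={tau})"
        )
    idx = np.arange(n_points)[:, None] + tau * np.arange(m)[None, :]
    return PhaseTrajectory(points=x[idx], m=m, tau=tau)


def _mutual_information(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px[:, None] * py[None, :])[nz])))


def estimate_delay_mi(x: np.ndarray, tau_max: int = 32, mi_bins: int = 16) -> int:
    """Delay = first local minimum of lagged mutual information I(tau).

    A series whose I(1) is already at the chance level of the histogram
    estimator (the Miller-Madow bias (B-1)^2 / 2n for independent data)
    has no lag structure and returns tau = 1 immediately.  If I has no
    local minimum on 1..tau_max, falls back to the smallest tau with
    I(tau) < I(1)/e, and to tau_max if neither rule fires.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= 2 * tau_max:
        raise InvalidParameterError("series too short for the requested tau_max")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant signal has no delay structure")
    mi = np.array(
        [_mutual_information(x[:-t], x[t:], mi_bins) for t in range(1, tau_max + 1)]
    )
    chance = (mi_bins - 1) ** 2 / (2 * (x.size - 1))
    if mi[0] <= 3 * chance:
        return 1
    for t in range(1, len(mi) - 1):
        if mi[t] < mi[t - 1] and mi[t] <= mi[t + 1]:
            return t + 1
    below = np.nonzero(mi < mi[0] / np.e)[0]
    if below.size:
        return int(below[0]) + 1
    return tau_max


def estimate_dim_fnn(
    x: np.ndarray,
    tau: int,
    m_max: int = 8,
    rtol: float = 10.0,
    atol: float = 2.0,
    threshold: float = 0.01,
) -> int:
    """Embedding dimension by the false-nearest-neighbors criterion.

    For each m, every point's nearest neighbor in dimension m is tested:
    it is false if the extra (m+1)-th coordinate jumps by more than
    ``rtol`` times the current neighbor distance, or if the inflated
    distance exceeds ``atol`` times the signal's standard deviation.
    Returns the smallest m with a false fraction below ``threshold``
    (default 1%), or ``m_max`` if the fraction never collapses.
    """
    x = np.asarray(x, dtype=float)
    if x.size - m_max * tau < 2:
        raise InvalidParameterError("series too short for m_max embedding")
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("constant signal")
    for m in range(1, m_max + 1):
        traj = delay_embed(x, m, tau).points
        # only points whose (m+1)-th coordinate exists can be tested
        n_test = x.size - m * tau
        if n_test < 2:
            return m_max
        pts = traj[:n_test]
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        nn = np.argmin(d2, axis=1)
        dist = np.sqrt(d2[np.arange(n_test), nn])
        extra = np.abs(x[np.arange(n_test) + m * tau] - x[nn + m * tau])
        inflated = np.sqrt(dist**2 + extra**2)
        # a neighbor is false when the unfolded coordinate jumps relative to
        # the current distance (Rtol) or blows past the attractor size (Atol);
        # jumps at rounding-noise scale (exactly periodic signals give
        # coincident points) never count as false
        false = ((extra > rtol * dist) | (inflated > atol * sd)) & (extra > 1e-9 * sd)
        if false.mean() < threshold:
            return m
    return m_max


def select_epsilon(traj: PhaseTrajectory, target_recurrence_rate: float = 0.10) -> float:
    """Recurrence threshold = the target-rate quantile of all pairwise
    off-diagonal distances, so the recurrence plot has approximately that
    fraction of recurrences.  Monotone in the target rate.  Returns 0
    (with a warning) for a degenerate all-identical trajectory.
    """
    if not (0 < target_recurrence_rate < 1):
        raise InvalidParameterError("target recurrence rate must lie in (0, 1)")
    pts = np.asarray(traj.points, dtype=float)
    if pts.shape[0] < 2:
        raise InvalidParameterError("trajectory needs at least 2 points")
    dists = pdist(pts)
    if np.all(dists == 0):
        import warnings

        warnings.warn("degenerate trajectory: all points identical, epsilon = 0")
        return 0.0
    return float(np.quantile(dists, target_recurrence_rate))
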