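"""Phase-space image encodings of a normalized cardiac cycle.

Three complementary encodings of a cycle x in [0, 1]^224:

* Recurrence plot (RP): binary matrix R_ij = 1 iff the delay-embedded
  trajectory points s_i, s_j lie within Euclidean distance epsilon
  (Heaviside convention Theta(0) = 1).  Visualizes determinism vs. chaos.
* Gramian angular summation field (GASF): x is mapped to [-1, 1], to
  angles phi = arccos(x̄), and G_ij = cos(phi_i + phi_j)
  = x̄_i x̄_j - sqrt(1 - x̄_i^2) sqrt(1 - x̄_j^2).  Preserves waveform
  morphology (QRS width, ST slope) in a symmetric texture.
* Markov transition field (MTF): samples are quantile-binned into Q
  states (Q = 8 by default), a first-order transition matrix P is
  estimated, and field_ij = P[state(x_i), state(x_j)] projects the
  Markov dynamics onto the time-time plane.

``to_image`` maps each matrix linearly onto a 224x224 float plane in
[0, 1] replicated to 3 channels for the CNN stem; RP matrices of side
M < 224 are enlarged by nearest-neighbor lookup to preserve the binary
texture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .embedding import PhaseTrajectory
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "RecurrenceMatrix",
    "GasfMatrix",
    "MtfMatrix",
    "EncodedImage",
    "IMAGE_SIDE",
    "recurrence_plot",
    "gasf",
    "mtf",
    "to_image",
]

IMAGE_SIDE = 224


@dataclass
class RecurrenceMatrix:
    R: np.ndarray  # binary, square, symmetric
    epsilon: float


@dataclass
class GasfMatrix:
    G: np.ndarray  # square, symmetric, entries in [-1, 1]
    xbar: np.ndarray  # rescaled series in [-1, 1]
    phi: np.ndarray  # angles in [0, pi]


@dataclass
class MtfMatrix:
    field: np.ndarray  # square, entries in [0, 1]
    Q: int
    transition: np.ndarray  # Q x Q row-stochastic on occupied rows
    states: np.ndarray  # per-sample quantile-bin index
    degenerate: bool = False


@dataclass
class EncodedImage:
    modality: str  # "RP" | "GASF" | "MTF"
    pixels: np.ndarray  # 224 x 224 x 3 in [0, 1]


def recurrence_plot(traj: PhaseTrajectory, epsilon: float) -> RecurrenceMatrix:
    """R_ij = Theta(epsilon - ||s_i - s_j||_2) with Theta(0) = 1."""
    if epsilon < 0:
        raise InvalidParameterError("epsilon must be non-negative")
    pts = np.asarray(traj.points, dtype=float)
    if pts.size == 0:
        raise InvalidInputError("empty trajectory")
    dist = squareform(pdist(pts))
    return RecurrenceMatrix(R=(dist <= epsilon).astype(np.uint8), epsilon=epsilon)


def gasf(x: np.ndarray) -> GasfMatrix:
    """Gramian angular summation field of a [0, 1]-normalized cycle."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise InvalidInputError("x must be a non-empty 1-D array")
    if x.min() < -1e-9 or x.max() > 1 + 1e-9:
        raise InvalidInputError("values must lie in [0, 1] (tolerance 1e-9)")
    x = np.clip(x, 0.0, 1.0)
    xbar = 2.0 * x - 1.0
    phi = np.arccos(xbar)
    G = np.cos(phi[:, None] + phi[None, :])
    return GasfMatrix(G=G, xbar=xbar, phi=phi)


def _quantile_states(x: np.ndarray, Q: int) -> np.ndarray:
    # interior quantile edges; ties on an edge go to the lower bin
    edges = np.quantile(x, np.arange(1, Q) / Q)
    return np.searchsorted(edges, x, side="left")


def mtf(x: np.ndarray, Q: int = 8) -> MtfMatrix:
    """Markov transition field with Q quantile bins (default 8)."""
    x = np.asarray(x, dtype=float)
    if Q < 2:
        raise InvalidParameterError("Q must be >= 2")
    if x.size < Q:
        raise InvalidParameterError("need at least Q samples for quantile bins")
    states = _quantile_states(x, Q)
    counts = np.zeros((Q, Q))
    np.add.at(counts, (states[:-1], states[1:]), 1.0)
    row_sums = counts.sum(axis=1)
    transition = np.zeros_like(counts)
    occupied = row_sums > 0
    transition[occupied] = counts[occupied] / row_sums[occupied, None]
    field = transition[states[:, None], states[None, :]]
    degenerate = bool(np.unique(states).size == 1)
    return MtfMatrix(field=field, Q=Q, transition=transition, states=states, degenerate=degenerate)


def _nearest_index_map(side_out: int, side_in: int) -> np.ndarray:
    # pixel centers of the output grid mapped to nearest input index
    centers = (np.arange(side_out) + 0.5) * side_in / side_out - 0.5
    return np.clip(np.round(centers).astype(int), 0, side_in - 1)


def to_image(matrix: RecurrenceMatrix | GasfMatrix | MtfMatrix | np.ndarray, modality: str) -> EncodedImage:
    """Render a matrix as a 224x224x3 float image in [0, 1].

    RP entries pass through {0,1} -> {0,1}; GASF entries map [-1,1] ->
    [0,1] via (g+1)/2; MTF entries are already in [0,1].  Matrices
    smaller than 224 (the RP, whose side is 224 - (m-1)tau) are enlarged
    by nearest-neighbor lookup; the single plane is replicated to 3
    channels.
    """
    modality = modality.upper()
    if modality not in ("RP", "GASF", "MTF"):
        raise InvalidParameterError(f"unknown modality {modality!r}")
    if isinstance(matrix, RecurrenceMatrix):
        plane = matrix.R.astype(float)
    elif isinstance(matrix, GasfMatrix):
        plane = (matrix.G + 1.0) / 2.0
    elif isinstance(matrix, MtfMatrix):
        plane = matrix.field.astype(float)
    else:
        plane = np.asarray(matrix, dtype=float)
        if modality == "GASF":
            plane = (plane + 1.0) / 2.0
    if plane.ndim != 2 or plane.shape[0] != plane.shape[1]:
        raise InvalidInputError("matrix must be square")
    side = plane.shape[0]
    if side != IMAGE_SIDE:
        idx = _nearest_index_map(IMAGE_SIDE, side)
        plane = plane[np.ix_(idx, idx)]
    pixels = np.repeat(plane[:, :, None], 3, axis=2)
    return EncodedImage(modality=modality, pixels=pixels)
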