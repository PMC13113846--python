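"""Decision-level fusion of the RP and GASF classifier probabilities.

The fused ischemia probability is the convex combination
P_final = w * P_RP + (1 - w) * P_GASF with a single global weight w.
The weight is chosen once, by exhaustive grid search over
{0, 0.05, ..., 1.0} on the validation set, maximizing the rank-based
AUC; ties go to the smallest w so the search is deterministic.  Because
the grid contains both endpoints, the fused validation AUC can never
fall below either single-modality AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .metrics import roc_auc

__all__ = ["FusionConfig", "fuse_probabilities", "grid_search_weight"]


@dataclass
class FusionConfig:
    w: float = 0.5
    grid_step: float = 0.05

    def grid(self) -> np.ndarray:
        n = int(round(1.0 / self.grid_step))
        return np.linspace(0.0, 1.0, n + 1)


def fuse_probabilities(p_rp, p_gasf, w: float):
    """w * p_rp + (1 - w) * p_gasf, elementwise; all arguments in [0, 1]."""
    p_rp = np.asarray(p_rp, dtype=float)
    p_gasf = np.asarray(p_gasf, dtype=float)
    if not 0 <= w <= 1:
        raise InvalidInputError("w must lie in [0, 1]")
    for name, arr in (("p_rp", p_rp), ("p_gasf", p_gasf)):
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise InvalidInputError(f"{name} must lie in [0, 1]")
    fused = w * p_rp + (1 - w) * p_gasf
    return float(fused) if fused.ndim == 0 else fused


def grid_search_weight(
    val_p_rp: np.ndarray,
    val_p_gasf: np.ndarray,
    val_labels: np.ndarray,
    grid_step: float = 0.05,
) -> tuple[float, float, list[dict]]:
    """Return (w*, auc*, table): the smallest weight maximizing the
    validation AUC of the fused probabilities, its AUC, and the
    per-candidate AUC table."""
    val_labels = np.asarray(val_labels, dtype=int)
    if np.unique(val_labels).size < 2:
        raise InvalidInputError("validation labels must contain both classes")
    config = FusionConfig(grid_step=grid_step)
    table = []
    best_w, best_auc = 0.0, -np.inf
    for w in config.grid():
        auc = roc_auc(fuse_probabilities(val_p_rp, val_p_gasf, float(w)), val_labels)
        table.append({"w": float(w), "auc": float(auc)})
        if auc > best_auc:  # strict: ties keep the smallest w
            best_w, best_auc = float(w), float(auc)
    return best_w, best_auc, table
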