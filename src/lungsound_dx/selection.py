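"""Backward-elimination feature selection.

Starting from the full descriptor, the feature whose removal yields the
highest cross-validated accuracy is dropped at each step (ties broken by
lowest column index); elimination stops when a removal would push the score
below the best seen so far for more than ``patience`` consecutive steps, or
when ``min_features`` is reached.

The compact 25-feature set that classification defaults to — SD, PP, LE in
the time domain; spectral SD/skewness/kurtosis/flux/roll-off/decrease; MFCC
and GFCC coefficients 3-10 — ships as the named preset ``"table5"`` so the
classifier is runnable without re-running the (expensive) wrapper search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .audio_io import FeatureTable

__all__ = [
    "SelectionResult",
    "backward_eliminate",
    "reduction_percent",
    "PRESETS",
    "TABLE5_FEATURES",
    "preset_features",
]

TABLE5_FEATURES = (
    ["std", "peak_to_peak", "log_energy"]
    + ["s_std", "s_skewness", "s_kurtosis", "s_flux", "s_rolloff", "s_decrease"]
    + [f"mfcc_{i}" for i in range(3, 11)]
    + [f"gfcc_{i}" for i in range(3, 11)]
)

PRESETS = {"table5": TABLE5_FEATURES}


def preset_features(name: str) -> list[str]:
    if name not in PRESETS:
        raise KeyError(f"unknown feature preset {name!r}; available: {sorted(PRESETS)}")
    return list(PRESETS[name])


@dataclass
class SelectionResult:
    retained: list[int]
    history: list[tuple[int, float]] = field(default_factory=list)  # (removed index, score)
    stop_reason: str = "no_improvement"  # {"min_reached", "no_improvement"}


Evaluator = Callable[[np.ndarray, np.ndarray], float]


def backward_eliminate(
    table: FeatureTable,
    evaluator: Evaluator,
    min_features: int = 1,
    patience: int = 0,
) -> SelectionResult:
    """Greedy backward elimination driven by an accuracy evaluator.

    ``evaluator(matrix, labels)`` must return an accuracy in [0, 1] and be
    deterministic (seed its own cross-validation) for reproducible searches.
    ``history`` records only removals that were applied, so
    ``len(retained) + len(history)`` always equals the starting feature
    count.  With infinite patience the search runs down to ``min_features``.
    """
    n = table.n_features
    if n < 1:
        raise ValueError("table has no features")
    if n == 1:
        return SelectionResult(retained=[0], history=[], stop_reason="min_reached")

    retained = list(range(n))
    best_score = float(evaluator(table.matrix, table.labels))
    history: list[tuple[int, float]] = []
    consecutive_drops = 0

    while len(retained) > min_features:
        best_candidate = None
        best_candidate_score = -math.inf
        for pos, feat in enumerate(retained):
            cols = retained[:pos] + retained[pos + 1 :]
            score = float(evaluator(table.matrix[:, cols], table.labels))
            if score > best_candidate_score:  # strict: ties keep lowest index
                best_candidate_score = score
                best_candidate = feat
        if best_candidate_score < best_score:
            consecutive_drops += 1
            if consecutive_drops > patience:
                return SelectionResult(retained, history, "no_improvement")
        else:
            consecutive_drops = 0
            best_score = best_candidate_score
        retained.remove(best_candidate)
        history.append((best_candidate, best_candidate_score))
    return SelectionResult(retained, history, "min_reached")


def reduction_percent(n_start: int, n_end: int) -> float:
    """Feature-reduction percentage, truncated (not rounded) to two decimals.

    116 -> 25 gives 78.44 (100 * 91/116 = 78.4482...).
    """
    if n_start <= 0 or n_end < 0 or n_end > n_start:
        raise ValueError("need 0 <= n_end <= n_start and n_start > 0")
    return math.floor(100.0 * (n_start - n_end) / n_start * 100.0) / 100.0
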