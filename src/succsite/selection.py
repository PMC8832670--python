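"""Chi-MIC-share forward feature selection.

Relevance and redundancy are measured on the same 0..1 scale by ChiMIC, and
each introduced feature's relevance is *shared* across its redundancy with
the other introduced features.  For a feature set E the total score is

    share(E) = sum_{Xi in E}  ChiMIC(Xi; Y) / sum_{Xj in E} ChiMIC(Xi; Xj),

where the denominator includes the self term ChiMIC(Xi; Xi) = 1.  Features
are introduced greedily by maximal share(E); introduction stops when the
score no longer increases, or — under forced termination — when the relative
gain drops to 1% or below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chimic import chimic_score

Measure = Callable[[np.ndarray, np.ndarray], float]

#: Relative-gain floor for forced termination.
FORCED_GAIN = 0.01


def _default_measure(alpha: float) -> Measure:
    return lambda a, b: chimic_score(a, b, alpha=alpha).value


class _PairCache:
    """Lazily computed, symmetric ChiMIC(Xi; Xj) values (self term = 1)."""

    def __init__(self, columns: list[np.ndarray], measure: Measure):
        self._columns = columns
        self._measure = measure
        self._cache: dict[tuple[int, int], float] = {}

    def __call__(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        key = (i, j) if i < j else (j, i)
        if key not in self._cache:
            self._cache[key] = self._measure(self._columns[i], self._columns[j])
        return self._cache[key]


@dataclass
class SelectionState:
    """Bookkeeping for one Chi-MIC-share run."""

    relevance: np.ndarray  # ChiMIC(Xi; Y) per feature
    redundancy: _PairCache
    introduced: list[int] = field(default_factory=list)
    score_history: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class SelectionResult:
    order: tuple[int, ...]  # introduced feature indices, in order
    names: tuple[str, ...]
    score_history: tuple[float, ...]  # share(S) after each introduction


def share_score(state: SelectionState, members: Sequence[int]) -> float:
    """Total redundancy-shared score of a feature set."""
    total = 0.0
    for i in members:
        denom = sum(state.redundancy(i, j) for j in members)
        total += state.relevance[i] / denom
    return total


def select_features(
    features,
    y,
    alpha: float = 0.05,
    forced: bool = False,
    measure: Measure | None = None,
    max_features: int | None = None,
) -> SelectionResult:
    """Greedy Chi-MIC-share selection over a feature matrix.

    ``features`` is a DataFrame or 2-D array (columns = features); ``y`` the
    binary response.  Ties between candidates with equal share score break
    toward the lower column index.  With ``forced=True`` introduction also
    stops once the relative score gain is <= 1%, so the forced list is a
    prefix of the unforced one.
    """
    if isinstance(features, pd.DataFrame):
        names = list(map(str, features.columns))
        matrix = features.to_numpy(dtype=float)
    else:
        matrix = np.asarray(features, dtype=float)
        names = [f"X{i}" for i in range(matrix.shape[1])]
    if matrix.ndim != 2 or matrix.shape[1] < 1:
        raise ValueError("need a 2-D matrix with at least one feature")
    yv = np.asarray(y, dtype=float)
    measure = measure or _default_measure(alpha)

    columns = [np.ascontiguousarray(matrix[:, i]) for i in range(matrix.shape[1])]
    relevance = np.array([measure(col, yv) for col in columns])
    state = SelectionState(relevance, _PairCache(columns, measure))

    remaining = list(range(matrix.shape[1]))
    limit = max_features or matrix.shape[1]

    # first feature: maximal relevance (share of a singleton is its relevance)
    first = min(remaining, key=lambda i: (-relevance[i], i))
    state.introduced.append(first)
    remaining.remove(first)
    state.score_history.append(float(relevance[first]))

    while remaining and len(state.introduced) < limit:
        current = state.score_history[-1]
        best_idx, best_score = None, -np.inf
        for c in remaining:
            s = share_score(state, state.introduced + [c])
            if s > best_score:
                best_idx, best_score = c, s
        if best_score <= current:  # score no longer increases: stop
            break
        if forced and current > 0 and (best_score - current) / current <= FORCED_GAIN:
            break
        state.introduced.append(best_idx)
        remaining.remove(best_idx)
        state.score_history.append(float(best_score))

    return SelectionResult(
        order=tuple(state.introduced),
        names=tuple(names[i] for i in state.introduced),
        score_history=tuple(state.score_history),
    )
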