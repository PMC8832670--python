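"""ChiMIC: a maximal-information-coefficient variant with chi-square-gated
grid growth.

The classical MIC explores grids up to a size cap and, on finite samples of
*independent* variables, inflates the score well above 0.  ChiMIC instead
grows the grid only while each new partition boundary is statistically
justified: a candidate boundary must pass a local chi-square test (the two
sub-bins it creates, cross-tabulated against the other axis's bins) at level
alpha.  The score is the maximum over visited grids of the normalized mutual
information

    I(X; Y) / min(H(X_bins), H(Y_bins)),

which stays in [0, 1], is ~0 for independent variables, reaches 1 for a
noiseless monotone functional relation and equals 1 for chimic(x, x) even
when x is an unbalanced binary variable (the usual log2(min(n_x, n_y))
denominator caps that self-score at H(x) instead).  Partitioning is
rank-based, so the score is invariant under strictly monotone transforms of
either variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as _chi2_dist

#: Distinct-value count at or below which an axis keeps exact value bins.
_MAX_EXACT_BINS = 4


@dataclass(frozen=True)
class DependenceScore:
    value: float
    grid: tuple[int, int]  # (n_x, n_y) at the maximizing grid


def _y_bins(y: np.ndarray) -> np.ndarray | None:
    """Bin indices for the fixed axis; None when constant.

    Few-valued variables (e.g. a binary class label) keep one bin per value;
    continuous ones get two equal-frequency bins split at the median rank
    (ties stay together).
    """
    distinct, counts = np.unique(y, return_counts=True)
    if distinct.size < 2:
        return None
    if distinct.size <= _MAX_EXACT_BINS:
        return np.searchsorted(distinct, y)
    # equal-frequency split: cut after the distinct value whose cumulative
    # count is closest to n/2 (ties never straddle the boundary)
    cum = np.cumsum(counts)[:-1]
    cut_value = distinct[int(np.argmin(np.abs(cum - len(y) / 2)))]
    return (y > cut_value).astype(int)


def _entropy(masses: np.ndarray) -> float:
    masses = masses[masses > 0]
    return float(-(masses * np.log2(masses)).sum())


def _mutual_information(counts: np.ndarray) -> float:
    """I(X;Y) in bits from a joint count table (rows x-bins, cols y-bins)."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def _row_contributions(rows: np.ndarray, n: float, log_py: np.ndarray) -> np.ndarray:
    """Per-x-bin additive share of I(X;Y): sum_b (n_rb/N)(log2(n_rb/n_r) - log_py).

    ``rows`` is (k, ny); MI of a grid is the sum of its rows' contributions,
    which lets candidate boundaries be scored by updating a single bin.
    """
    nr = rows.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = rows / n * (np.log2(rows) - np.log2(nr) - log_py)
    return np.nansum(terms, axis=1)


def _local_split_p(top: np.ndarray, bottom: np.ndarray) -> float:
    """Pearson chi-square p for a 2 x k table of the two sub-bins a new
    boundary creates; zero marginals carry no evidence (p = 1)."""
    table = np.vstack([top, bottom]).astype(float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return 1.0
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    return float(_chi2_dist.sf(stat, table.shape[1] - 1))


def _directional_score(
    x: np.ndarray, yb: np.ndarray, ny: int, alpha: float
) -> tuple[float, tuple[int, int]]:
    """Grow x-axis boundaries greedily; return best normalized MI and grid."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    # prefix[k, b]: count of y-bin b among the k smallest x values
    onehot = np.zeros((len(x), ny))
    onehot[np.arange(len(x)), yb[order]] = 1.0
    prefix = np.vstack([np.zeros((1, ny)), np.cumsum(onehot, axis=0)])
    # candidate boundaries sit between distinct x values
    candidates = [k for k in range(1, len(xs)) if xs[k] != xs[k - 1]]
    if len(candidates) + 1 > _MAX_EXACT_BINS:
        # continuous axis: keep cuts inside the central 80% of mass, which
        # tames the multiple-testing inflation of maximally selected splits
        # on independent data; few-valued axes may cut anywhere
        lo = max(2, int(0.1 * len(xs)))
        central = [k for k in candidates if lo <= k <= len(xs) - lo]
        candidates = central or candidates
    if not candidates:
        return 0.0, (1, ny)

    n = float(len(xs))
    log_py = np.log2(prefix[-1] / n)  # log2 of the y-bin marginal proportions
    cand = np.array(candidates)
    cuts: list[int] = []
    best = 0.0
    best_grid = (1, ny)
    while cand.size:
        edges = np.array([0] + cuts + [len(xs)])
        bin_rows = prefix[edges[1:]] - prefix[edges[:-1]]
        bin_contrib = _row_contributions(bin_rows, n, log_py)
        mi_base = float(bin_contrib.sum())
        # each candidate splits exactly one current bin in two
        k = np.searchsorted(edges, cand, side="right") - 1
        top = prefix[cand] - prefix[edges[k]]
        bottom = prefix[edges[k + 1]] - prefix[cand]
        mi_all = (
            mi_base
            - bin_contrib[k]
            + _row_contributions(top, n, log_py)
            + _row_contributions(bottom, n, log_py)
        )
        i_best = int(np.lexsort((cand, -mi_all))[0])  # ties: smallest cut
        mi, cut = float(mi_all[i_best]), int(cand[i_best])
        p = _local_split_p(top[i_best], bottom[i_best])
        if p >= alpha:
            break  # sub-bins indistinguishable: the boundary is not justified
        cuts = sorted(cuts + [cut])
        cand = cand[cand != cut]
        nx = len(cuts) + 1
        new_edges = np.array([0] + cuts + [len(xs)])
        x_masses = np.diff(new_edges) / n
        y_masses = prefix[-1] / n
        norm = min(_entropy(x_masses), _entropy(y_masses))
        if norm > 0 and mi / norm > best:
            best = min(mi / norm, 1.0)
            best_grid = (nx, ny)
    return best, best_grid


def chimic_score(x, y, alpha: float = 0.05) -> DependenceScore:
    """ChiMIC dependence of two equal-length numeric vectors.

    Symmetric by construction: the grid search is run with each variable as
    the partitioned axis and the better score is kept.  Simultaneously
    constant inputs score 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")

    best = DependenceScore(0.0, (1, 1))
    for a, b, swap in ((x, y, False), (y, x, True)):
        bins = _y_bins(b)
        if bins is None:
            continue
        ny = int(bins.max()) + 1
        value, (nx, nyy) = _directional_score(a, bins, ny, alpha)
        grid = (nyy, nx) if swap else (nx, nyy)
        if value > best.value:
            best = DependenceScore(value, grid)
    return best
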