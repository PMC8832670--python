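"""Class-by-status contingency tables and chi-square compression.

A 2 x m table counts how often each of m status values (residue symbols at a
window position, or discretized feature values) occurs among positive and
negative samples.  Tables are *compressed* by greedily merging the pair of
columns that maximizes the table chi-square, accepting each merge only if a
local 2 x 2 chi-square test says the merged columns are statistically
indistinguishable (p >= alpha).  The result is a coarser table whose columns
are groups of original statuses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist


@dataclass(frozen=True)
class ContingencyTable:
    """A 2 x m class-by-status count table.

    Rows are the positive and negative classes; marginals are derived from
    the cells.  Counts may be non-integer (the balanced decision table holds
    theta-weighted negatives).
    """

    status_labels: tuple[Hashable, ...]
    pos_counts: np.ndarray
    neg_counts: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.pos_counts, dtype=float)
        neg = np.asarray(self.neg_counts, dtype=float)
        object.__setattr__(self, "pos_counts", pos)
        object.__setattr__(self, "neg_counts", neg)
        m = len(self.status_labels)
        if m < 1:
            raise ValueError("table needs at least one column")
        if pos.shape != (m,) or neg.shape != (m,):
            raise ValueError("count rows must match status_labels length")
        if (pos < 0).any() or (neg < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def m(self) -> int:
        return len(self.status_labels)

    @property
    def pos_total(self) -> float:
        return float(self.pos_counts.sum())

    @property
    def neg_total(self) -> float:
        return float(self.neg_counts.sum())

    @property
    def col_totals(self) -> np.ndarray:
        return self.pos_counts + self.neg_counts

    @property
    def n(self) -> float:
        return self.pos_total + self.neg_total

    @classmethod
    def from_observations(
        cls,
        statuses: Sequence[Hashable],
        labels: Sequence[int],
        status_order: Sequence[Hashable] | None = None,
    ) -> "ContingencyTable":
        """Tally a status sequence against binary labels.

        ``status_order`` fixes the column order (and may include statuses
        with zero counts); by default columns are the sorted observed values.
        """
        statuses = list(statuses)
        labels = np.asarray(labels)
        if len(statuses) != len(labels):
            raise ValueError("statuses and labels must have equal length")
        if status_order is None:
            status_order = sorted(set(statuses))
        index = {s: k for k, s in enumerate(status_order)}
        pos = np.zeros(len(status_order))
        neg = np.zeros(len(status_order))
        for s, lab in zip(statuses, labels):
            k = index[s]
            if lab == 1:
                pos[k] += 1
            else:
                neg[k] += 1
        return cls(tuple(status_order), pos, neg)


def chi2_stat(table: ContingencyTable) -> float:
    """Chi-square of a 2 x m table from the positive-row form.

    chi2 = N^2/(f+ * f-) * [sum_j (f+_j)^2 / f_j  -  (f+)^2 / N], with
    zero-total columns contributing nothing.  Algebraically equal to the
    Pearson statistic sum (O-E)^2/E.
    """
    fp, fn = table.pos_total, table.neg_total
    n = fp + fn
    if n <= 0:
        raise ValueError("empty table")
    if fp == 0 or fn == 0:
        raise ValueError("chi-square undefined: a class marginal is zero")
    cols = table.col_totals
    mask = cols > 0
    inner = float((table.pos_counts[mask] ** 2 / cols[mask]).sum()) - fp**2 / n
    return n**2 / (fp * fn) * inner


def local_chi2_test(
    pos_pair: Sequence[float], neg_pair: Sequence[float]
) -> float:
    """Pearson chi-square p-value (1 df, no continuity correction) of a 2x2.

    A table with a zero row or column marginal carries no evidence of
    difference and returns p = 1.
    """
    a, b = float(pos_pair[0]), float(pos_pair[1])
    c, d = float(neg_pair[0]), float(neg_pair[1])
    if min(a, b, c, d) < 0:
        raise ValueError("negative counts")
    n = a + b + c + d
    if n <= 0:
        raise ValueError("empty 2x2 table")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(_chi2_dist.sf(stat, 1))


@dataclass(frozen=True)
class CompressedTable:
    """Result of compressing a table: the coarser table plus provenance."""

    table: ContingencyTable
    groups: tuple[tuple[Hashable, ...], ...]
    merge_log: tuple[tuple[tuple[Hashable, ...], float], ...]

    @property
    def r(self) -> int:
        return self.table.m


def _group_label(group: tuple[Hashable, ...]):
    if all(isinstance(g, str) and len(g) == 1 for g in group):
        return "".join(group)  # residue groups read like "ARDGTV"
    return group if len(group) > 1 else group[0]


def compress_table(
    table: ContingencyTable,
    alpha: float = 0.05,
    mode: str = "unordered",
    min_groups: int = 2,
) -> CompressedTable:
    """Greedy chi-square-guided column merging.

    At each step the candidate pair whose merge maximizes the table
    chi-square is tried (all pairs in ``unordered`` mode, neighbors only in
    ``adjacent`` mode).  The merge is kept iff the local 2 x 2 test on the
    merged pair has p >= alpha; otherwise compression backtracks and stops.
    Zero-total columns are merged first with local p defined as 1, so empty
    statuses never block compression.  ``min_groups`` is the floor (2 for the
    standard procedure; the ChiDT per-leaf recompression uses 1, where the
    final two columns may still merge if the local test allows).
    """
    if mode not in ("unordered", "adjacent"):
        raise ValueError(f"unknown mode {mode!r}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    groups: list[tuple[Hashable, ...]] = [(lab,) for lab in table.status_labels]
    pos = list(map(float, table.pos_counts))
    neg = list(map(float, table.neg_counts))
    log: list[tuple[tuple[Hashable, ...], float]] = []

    def merged_chi2(i: int, j: int) -> float:
        mp = pos[:]; mn = neg[:]
        mp[i] += mp[j]; mn[i] += mn[j]
        del mp[j], mn[j]
        tmp = ContingencyTable(tuple(range(len(mp))), np.array(mp), np.array(mn))
        return chi2_stat(tmp)

    while len(groups) > min_groups:
        r = len(groups)
        if mode == "adjacent":
            pairs = [(i, i + 1) for i in range(r - 1)]
        else:
            pairs = [(i, j) for i in range(r) for j in range(i + 1, r)]

        zero_pairs = [
            (i, j) for i, j in pairs if pos[i] + neg[i] == 0 or pos[j] + neg[j] == 0
        ]
        if zero_pairs:
            candidates = zero_pairs
            forced_p = 1.0
        else:
            candidates = pairs
            forced_p = None

        best = max(candidates, key=lambda ij: (merged_chi2(*ij), (-ij[0], -ij[1])))
        i, j = best
        if forced_p is not None:
            p = forced_p
        else:
            p = local_chi2_test((pos[i], pos[j]), (neg[i], neg[j]))
            if p < alpha:
                break  # merged columns genuinely differ: backtrack, stop
        merged_group = groups[i] + groups[j]
        pos[i] += pos[j]; neg[i] += neg[j]
        del pos[j], neg[j], groups[j]
        groups[i] = merged_group
        log.append((merged_group, p))

    out = ContingencyTable(
        tuple(_group_label(g) for g in groups), np.array(pos), np.array(neg)
    )
    return CompressedTable(table=out, groups=tuple(groups), merge_log=tuple(log))
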