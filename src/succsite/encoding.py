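"""Positional and compositional feature encoding.

Key window positions are those whose compressed class-by-residue table has a
chi-square above the average over all positions.  Each key position is then
characterized by a *chi-square statistical difference table*: for residue j
at position i, the score is the change in the position's chi-square when one
hypothetical new sample carrying residue j is counted as positive versus as
negative,

    delta_chi2[i, j] = chi2(table with pos cell j + 1) - chi2(table with neg cell j + 1),

with all marginals re-derived from the cells.  A fragment's positional
feature at a key position is a lookup of this score for the residue it
carries there.  Compositional features are the 20 single-residue frequencies
(AAC) and the 210 unordered adjacent-pair frequencies (undirected PCAAC)
within the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contingency import CompressedTable, ContingencyTable, chi2_stat, compress_table
from .fragments import AMINO_ACIDS, SiteFragment

#: Unordered residue pairs (a <= b in alphabet order): 20*21/2 = 210.
PAIRS: tuple[tuple[str, str], ...] = tuple(
    (AMINO_ACIDS[i], AMINO_ACIDS[j])
    for i in range(20)
    for j in range(i, 20)
)

_PAIR_INDEX = {p: k for k, p in enumerate(PAIRS)}


def position_table(
    fragments: Sequence[SiteFragment], offset: int
) -> ContingencyTable:
    """2 x 20 class-by-residue table at one window offset."""
    pos = np.zeros(20)
    neg = np.zeros(20)
    idx = {a: k for k, a in enumerate(AMINO_ACIDS)}
    for frag in fragments:
        if frag.label is None:
            raise ValueError("position tables need labeled fragments")
        row = pos if frag.label == 1 else neg
        row[idx[frag.at(offset)]] += 1
    return ContingencyTable(tuple(AMINO_ACIDS), pos, neg)


@dataclass(frozen=True)
class KeyPositionModel:
    """Per-offset chi-square scan and the selected key positions."""

    offsets: tuple[int, ...]
    chi2_values: dict[int, float]
    chi2_ave: float
    key_offsets: tuple[int, ...]
    window: tuple[int, int]
    compressed: dict[int, CompressedTable]


def select_key_positions(
    fragments: Sequence[SiteFragment],
    alpha: float = 0.05,
    flank: int | None = None,
) -> KeyPositionModel:
    """Scan all offsets, compress each 2 x 20 table, threshold at the mean.

    A position is *key* when its compressed-table chi-square strictly exceeds
    the average over all scanned positions; the window spans the outermost
    key offsets.
    """
    labels = {f.label for f in fragments}
    if labels != {0, 1}:
        raise ValueError("both positive and negative fragments are required")
    if flank is None:
        flank = fragments[0].flank
    offsets = tuple(i for i in range(-flank, flank + 1) if i != 0)

    chi2_values: dict[int, float] = {}
    compressed: dict[int, CompressedTable] = {}
    for off in offsets:
        comp = compress_table(position_table(fragments, off), alpha=alpha,
                              mode="unordered")
        compressed[off] = comp
        chi2_values[off] = chi2_stat(comp.table)

    ave = float(np.mean(list(chi2_values.values())))
    key = tuple(off for off in offsets if chi2_values[off] > ave)
    if not key:
        raise ValueError("no position exceeds the average chi-square")
    return KeyPositionModel(
        offsets=offsets,
        chi2_values=chi2_values,
        chi2_ave=ave,
        key_offsets=key,
        window=(min(key), max(key)),
        compressed=compressed,
    )


def _chi2_with_increment(
    pos: np.ndarray, neg: np.ndarray, j: int, into_positive: bool
) -> float:
    pos = pos.copy(); neg = neg.copy()
    if into_positive:
        pos[j] += 1
    else:
        neg[j] += 1
    return chi2_stat(ContingencyTable(tuple(range(len(pos))), pos, neg))


def delta_chi2(table: ContingencyTable, j: int) -> float:
    """Difference-table score for column j of a 2 x m table."""
    return _chi2_with_increment(
        table.pos_counts, table.neg_counts, j, True
    ) - _chi2_with_increment(table.pos_counts, table.neg_counts, j, False)


@dataclass(frozen=True)
class DifferenceTable:
    """20 residues x key positions of delta-chi-square scores."""

    key_offsets: tuple[int, ...]
    scores: pd.DataFrame  # index residues, columns key offsets
    base_tables: dict[int, ContingencyTable]

    def score(self, residue: str, offset: int) -> float:
        return float(self.scores.at[residue, offset])


def build_difference_table(
    fragments: Sequence[SiteFragment], key_offsets: Sequence[int]
) -> DifferenceTable:
    """Difference table from the *uncompressed* 2 x 20 tables per key offset."""
    if not key_offsets:
        raise ValueError("key_offsets must be non-empty")
    base: dict[int, ContingencyTable] = {}
    cols: dict[int, list[float]] = {}
    for off in key_offsets:
        table = position_table(fragments, off)
        if table.pos_total == 0 or table.neg_total == 0:
            raise ValueError(f"offset {off}: a class marginal is zero")
        base[off] = table
        cols[off] = [delta_chi2(table, j) for j in range(20)]
    scores = pd.DataFrame(cols, index=list(AMINO_ACIDS), columns=list(key_offsets))
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("non-finite difference-table score")
    return DifferenceTable(tuple(key_offsets), scores, base)


def encode_positional(
    fragment: SiteFragment, table: DifferenceTable
) -> dict[int, float]:
    """Positional features: score lookup per key offset."""
    return {off: table.score(fragment.at(off), off) for off in table.key_offsets}


def encode_aac(window: str) -> np.ndarray:
    """Amino-acid composition: per-residue frequency in the window."""
    if not window:
        raise ValueError("empty window")
    counts = np.array([window.count(a) for a in AMINO_ACIDS], dtype=float)
    return counts / len(window)


def encode_pcaac(window: str) -> np.ndarray:
    """Undirected pair-coupled composition over adjacent residue pairs.

    f_{ab} counts adjacent occurrences of ab or ba, normalized by the number
    of adjacent pairs (window length - 1); f_AR and f_RA are the same
    feature.
    """
    if len(window) < 2:
        raise ValueError("window must have at least 2 residues")
    counts = np.zeros(len(PAIRS))
    for a, b in zip(window, window[1:]):
        counts[_PAIR_INDEX[(a, b) if a <= b else (b, a)]] += 1
    return counts / (len(window) - 1)


def positional_feature_names(key_offsets: Sequence[int]) -> list[str]:
    return [f"P_{off}" for off in key_offsets]


def feature_names(key_offsets: Sequence[int]) -> list[str]:
    """Ordered names: positional, then AAC, then undirected-PCAAC."""
    return (
        positional_feature_names(key_offsets)
        + [f"f_{a}" for a in AMINO_ACIDS]
        + [f"f_{a}{b}" for a, b in PAIRS]
    )


def encode_features(
    fragments: Sequence[SiteFragment],
    table: DifferenceTable,
    window: tuple[int, int],
) -> pd.DataFrame:
    """Full feature matrix for a set of fragments.

    One row per fragment; columns are the positional scores at the key
    offsets followed by the 230 compositional features computed on the
    window (9 + 20 + 210 = 239 in the standard configuration).
    """
    start, end = window
    rows = []
    for frag in fragments:
        w = frag.window(start, end)
        positional = [table.score(frag.at(off), off) for off in table.key_offsets]
        rows.append(np.concatenate([positional, encode_aac(w), encode_pcaac(w)]))
    return pd.DataFrame(rows, columns=feature_names(table.key_offsets))
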