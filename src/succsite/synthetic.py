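"""Seeded generator of succinylation-like fragment datasets.

Fragments are 51-mers centered on a K, with residues drawn from a background
distribution except at *planted* offsets, where the positive class draws
from a distribution shifted toward a target residue.  The shift is
parameterized by the total-variation distance between the positive and
negative residue distributions at planted offsets, so the planted signal
strength is explicit and every pipeline stage can be exercised without any
external dataset.  The default 1:10 positive:negative imbalance mirrors the
class ratio typical of succinylation site collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Sequence, Union

import numpy as np

from .fragments import AMINO_ACIDS, DEFAULT_FLANK, SiteFragment

#: Target residues assigned to planted offsets, cycled in order.
_TARGETS = "ESDTA"


def uniform_background() -> np.ndarray:
    return np.full(20, 1 / 20)


def skewed_background(rng_seed: int = 7) -> np.ndarray:
    """A lopsided residue distribution; several residues get near-zero mass,
    which exercises zero-count columns in table compression."""
    weights = np.exp(-0.45 * np.arange(20))
    rng = np.random.default_rng(rng_seed)
    return rng.permutation(weights / weights.sum())


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic dataset.

    ``effect_size`` is the total-variation distance between the positive and
    negative (= background) residue distributions at each planted offset.
    """

    n_pos: int = 500
    n_neg: int = 5000  # 1:10 imbalance by default
    flank: int = DEFAULT_FLANK
    planted_offsets: tuple[int, ...] = (-2, 1)
    effect_size: float = 0.5
    background: np.ndarray = field(default_factory=uniform_background)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes need at least one sample")
        if not 0 <= self.effect_size <= 1:
            raise ValueError("effect_size must be in [0, 1]")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (20,) or (bg < 0).any() or abs(bg.sum() - 1) > 1e-9:
            raise ValueError("background must be a distribution over 20 residues")
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "planted_offsets", tuple(self.planted_offsets))
        if 0 in self.planted_offsets:
            raise ValueError("offset 0 is always K; it cannot carry signal")
        if any(abs(o) > self.flank for o in self.planted_offsets):
            raise ValueError("planted offset outside the fragment")


def positive_distribution(background: np.ndarray, effect_size: float,
                          target_index: int) -> np.ndarray:
    """Background shifted toward one residue with exact TV distance.

    Mixing background with a point mass at the target gives
    TV = lam * (1 - bg[target]); lam is solved so TV equals effect_size.
    """
    slack = 1 - background[target_index]
    if effect_size > slack + 1e-12:
        raise ValueError(
            f"effect_size {effect_size} unreachable: background already puts "
            f"{background[target_index]:.3f} on the target residue"
        )
    lam = 0.0 if slack == 0 else effect_size / slack
    point = np.zeros(20)
    point[target_index] = 1.0
    return (1 - lam) * background + lam * point


def planted_targets(spec: GeneratorSpec) -> dict[int, str]:
    """Which residue is enriched in positives at each planted offset."""
    return {
        off: _TARGETS[i % len(_TARGETS)]
        for i, off in enumerate(spec.planted_offsets)
    }


def generate(spec: GeneratorSpec) -> list[SiteFragment]:
    """Draw labeled fragments; deterministic for a fixed spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    targets = planted_targets(spec)
    aa = np.frompyfunc(AMINO_ACIDS.__getitem__, 1, 1)

    pos_dists = {
        off: positive_distribution(
            spec.background, spec.effect_size, AMINO_ACIDS.index(res)
        )
        for off, res in targets.items()
    }
    width = 2 * spec.flank + 1
    frags: list[SiteFragment] = []
    for label, count, tag in ((1, spec.n_pos, "POS"), (0, spec.n_neg, "NEG")):
        block = rng.choice(20, size=(count, width), p=spec.background)
        for off in spec.planted_offsets:
            col = spec.flank + off
            p = pos_dists[off] if label == 1 else spec.background
            block[:, col] = rng.choice(20, size=count, p=p)
        letters = aa(block).astype(str)
        for k in range(count):
            row = letters[k]
            row[spec.flank] = "K"
            frags.append(
                SiteFragment(
                    protein_id=f"{tag}{k:06d}",
                    site_pos=spec.flank + 1,
                    residues="".join(row),
                    label=label,
                )
            )
    return frags


def write_fasta(fragments: Sequence[SiteFragment], sink: Union[str, IO[str]]) -> None:
    """Each fragment becomes its own FASTA record (K at the center)."""
    lines = []
    for f in fragments:
        lines.append(f">{f.protein_id}\n{f.residues}\n")
    text = "".join(lines)
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w") as fh:
            fh.write(text)


def write_site_table(
    fragments: Sequence[SiteFragment], sink: Union[str, IO[str]]
) -> None:
    """Companion TSV (protein_id, position, label) for :func:`write_fasta`."""
    rows = ["protein_id\tposition\tlabel\n"]
    for f in fragments:
        label = "" if f.label is None else str(f.label)
        rows.append(f"{f.protein_id}\t{f.flank + 1}\t{label}\n")
    text = "".join(rows)
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w") as fh:
            fh.write(text)
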