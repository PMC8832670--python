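"""Sequence fragments around candidate lysines.

Every candidate succinylation site is represented by a fixed-length window
of residues centered on the lysine (K), indexed by signed offsets
-flank ... +flank with the K at offset 0.  When the protein does not extend
far enough on one side, the missing positions are filled by *mirror
extension*: the residue at offset -i is copied from offset +i (and vice
versa), i.e. reflection across the central K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acid one-letter symbols, in alphabetical order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)

#: Default number of residues on each side of the candidate K (window 51).
DEFAULT_FLANK = 25

PathOrHandle = Union[str, IO[str]]


class FragmentError(ValueError):
    """Raised when a fragment cannot be constructed from a protein."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 standard residues."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-standard residue(s) "
                f"{''.join(sorted(bad))!r}; only {AMINO_ACIDS} are allowed"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteFragment:
    """A (2*flank+1)-residue window centered on a candidate K.

    ``residues[flank + i]`` is the residue at signed offset ``i``; offset 0
    is the candidate lysine.  ``label`` is 1 (true site), 0 (false site) or
    None (unknown, e.g. de-novo scanning).
    """

    protein_id: str
    site_pos: int  # 1-based position of the K in the protein
    residues: str
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.residues) % 2 == 0:
            raise ValueError("fragment length must be odd")
        if self.residues[self.flank] != "K":
            raise ValueError(
                f"fragment for {self.protein_id!r} at {self.site_pos}: "
                "central residue is not K"
            )
        if self.label not in (0, 1, None):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")

    @property
    def flank(self) -> int:
        return (len(self.residues) - 1) // 2

    def at(self, offset: int) -> str:
        """Residue at a signed offset (offset 0 = the candidate K)."""
        return self.residues[self.flank + offset]

    def window(self, start: int, end: int) -> str:
        """Residues spanning offsets ``start``..``end`` inclusive."""
        f = self.flank
        if start < -f or end > f or start > end:
            raise ValueError(f"window [{start}, {end}] outside fragment")
        return self.residues[f + start : f + end + 1]


def _fold_distance(i: int, limit: int) -> int:
    """Fold a distance i > limit back into 1..limit (sawtooth, ends repeated)."""
    period = 2 * limit
    j = (i - 1) % period
    return j + 1 if j < limit else period - j


def mirror_extend(
    protein: ProteinRecord, site_pos: int, flank: int = DEFAULT_FLANK
) -> SiteFragment:
    """Build the fragment around ``site_pos``, mirroring at sequence ends.

    A missing residue at offset -i is taken from offset +i (and vice versa).
    If both sides are missing at some distance, the distance is folded back
    into the covered range and the same residue is assigned to both offsets,
    so mirrored pairs always satisfy ``residues[-i] == residues[+i]``.
    """
    seq = protein.sequence
    center = site_pos - 1
    if not 0 <= center < len(seq):
        raise FragmentError(
            f"protein {protein.id!r}: position {site_pos} outside sequence "
            f"of length {len(seq)}"
        )
    if seq[center] != "K":
        raise FragmentError(
            f"protein {protein.id!r}: residue at position {site_pos} is "
            f"{seq[center]!r}, not K"
        )

    left: dict[int, str] = {}  # distance -> residue upstream of K
    right: dict[int, str] = {}
    for i in range(1, flank + 1):
        if center - i >= 0:
            left[i] = seq[center - i]
        if center + i < len(seq):
            right[i] = seq[center + i]
    n_left, n_right = len(left), len(right)

    # one reflection across the central K covers one-sided shortage
    for i in range(1, flank + 1):
        if i not in left and i in right:
            left[i] = right[i]
        elif i not in right and i in left:
            right[i] = left[i]

    covered = max(n_left, n_right)
    if covered < flank:
        if n_left + n_right < 2:
            raise FragmentError(
                f"protein {protein.id!r}: fewer than 2 residues besides the "
                f"K at position {site_pos}; mirror extension impossible"
            )
        source = right if n_right >= n_left else left
        for i in range(covered + 1, flank + 1):
            res = source[_fold_distance(i, covered)]
            left[i] = res
            right[i] = res

    residues = (
        "".join(left[i] for i in range(flank, 0, -1))
        + "K"
        + "".join(right[i] for i in range(1, flank + 1))
    )
    return SiteFragment(protein_id=protein.id, site_pos=site_pos, residues=residues)


def read_fasta(source: PathOrHandle) -> list[ProteinRecord]:
    """Read protein records from FASTA (path or open text handle)."""
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(source, "fasta")
    ]
    if not records:
        raise ValueError("no FASTA records found")
    return records


def read_site_table(source: PathOrHandle) -> pd.DataFrame:
    """Read a tab-separated site table (protein_id, position, label).

    A header row is optional; labels, when present, must be 0/1.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("site table needs at least protein_id and position columns")
    first = str(df.iloc[0, 1])
    if not first.lstrip("-").isdigit():  # header row
        df = df.iloc[1:].reset_index(drop=True)
    df = df.iloc[:, :3] if df.shape[1] >= 3 else df.assign(label=None)
    df.columns = ["protein_id", "position", "label"][: df.shape[1]]
    if df.shape[1] == 2:
        df["label"] = None
    df["position"] = df["position"].astype(int)
    df["label"] = df["label"].map(
        lambda v: None if v is None or pd.isna(v) else int(v)
    )
    return df


def load_sites(
    fasta_source: PathOrHandle, site_table: PathOrHandle
) -> list[tuple[ProteinRecord, int, int | None]]:
    """Pair site-table rows with their protein records.

    Rows pointing at a non-K residue are skipped with a warning; a row
    referencing an unknown protein ID, or a protein containing non-standard
    residues, is a hard error.
    """
    proteins = {rec.id: rec for rec in read_fasta(fasta_source)}
    sites = read_site_table(site_table)
    out: list[tuple[ProteinRecord, int, int | None]] = []
    for row in sites.itertuples(index=False):
        rec = proteins.get(row.protein_id)
        if rec is None:
            raise KeyError(f"site table references unknown protein {row.protein_id!r}")
        pos = int(row.position)
        if not 1 <= pos <= len(rec):
            raise ValueError(
                f"protein {rec.id!r}: position {pos} outside sequence of "
                f"length {len(rec)}"
            )
        if rec.sequence[pos - 1] != "K":
            logger.warning(
                "skipping site %s:%d — residue is %s, not K",
                rec.id, pos, rec.sequence[pos - 1],
            )
            continue
        label = None if row.label is None else int(row.label)
        out.append((rec, pos, label))
    return out


def fragment_sites(
    sites: Iterable[tuple[ProteinRecord, int, int | None]],
    flank: int = DEFAULT_FLANK,
) -> list[SiteFragment]:
    """Mirror-extend every (protein, position, label) triple."""
    frags = []
    for rec, pos, label in sites:
        frag = mirror_extend(rec, pos, flank=flank)
        frags.append(
            SiteFragment(rec.id, pos, frag.residues, label=label)
        )
    return frags


def scan_lysines(protein: ProteinRecord) -> list[int]:
    """1-based positions of every K in the protein."""
    return [i + 1 for i, res in enumerate(protein.sequence) if res == "K"]


def write_fragments_tsv(fragments: Iterable[SiteFragment], path: PathOrHandle) -> None:
    """Export fragments as TSV: protein_id, position, residues, label."""
    df = pd.DataFrame(
        [
            (f.protein_id, f.site_pos, f.residues, "" if f.label is None else f.label)
            for f in fragments
        ],
        columns=["protein_id", "position", "fragment", "label"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path: PathOrHandle) -> list[SiteFragment]:
    """Read fragments written by :func:`write_fragments_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "fragment": str})
    frags = []
    for row in df.itertuples(index=False):
        label = None if pd.isna(row.label) else int(row.label)
        frags.append(
            SiteFragment(str(row.protein_id), int(row.position), row.fragment, label)
        )
    return frags
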