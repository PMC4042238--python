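"""Gapped multiple alignments: FASTA I/O, column filtering, concatenation.

The rate-change pipeline consumes two kinds of alignments: the conserved
test element itself and the concatenated exon alignments of the flanking
reference genes.  Both are small (hundreds to a few thousand columns over
four species), so alignments are held as plain per-species strings.

Coordinates are 0-based half-open throughout; species labels are
case-sensitive exact strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"


@dataclass
class MultipleAlignment:
    """A set of equal-length aligned sequences keyed by species label.

    ``meta`` carries audit information produced by the operations below
    (column keep/drop masks from filtering, per-source offsets from
    concatenation); it never affects equality of the alignment itself.
    """

    rows: dict[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.rows = {sp: seq.upper() for sp, seq in self.rows.items()}

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def column(self, i: int) -> str:
        return "".join(seq[i] for seq in self.rows.values())

    def take_columns(self, keep: Sequence[int] | np.ndarray) -> "MultipleAlignment":
        """New alignment containing the given columns, order preserved."""
        idx = np.asarray(keep, dtype=int)
        rows = {
            sp: "".join(np.frombuffer(seq.encode(), dtype="S1")[idx].astype(str))
            for sp, seq in self.rows.items()
        }
        return MultipleAlignment(rows)

    def slice(self, start: int, end: int) -> "MultipleAlignment":
        return MultipleAlignment({sp: seq[start:end] for sp, seq in self.rows.items()})


@dataclass(frozen=True)
class FilterPolicy:
    """Deterministic proxy for manual alignment curation.

    Columns are removed when they contain a gap (if ``drop_gap_columns``)
    or fall in any sliding window of ``window_len`` columns whose mean
    pairwise identity is below ``min_window_identity``.  The window pass
    is iterated to a fixed point so filtering is idempotent.
    """

    drop_gap_columns: bool = True
    window_len: int = 10
    min_window_identity: float = 0.5

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if not 0.0 <= self.min_window_identity <= 1.0:
            raise ValueError("min_window_identity must lie in [0, 1]")


def read_fasta(path: str | Path) -> MultipleAlignment:
    """Read an aligned multi-FASTA file; sequences are upper-cased."""
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ValueError(f"duplicate species header: {rec.id!r}")
        rows[rec.id] = str(rec.seq)
    if not rows:
        raise ValueError(f"no FASTA records in {path}")
    return MultipleAlignment(rows)


def write_fasta(aln: MultipleAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=sp, description="") for sp, seq in aln.rows.items()]
    SeqIO.write(records, str(path), "fasta")


def _char_matrix(aln: MultipleAlignment) -> np.ndarray:
    return np.array([np.frombuffer(seq.encode(), dtype="S1") for seq in aln.rows.values()])


def _column_identities(chars: np.ndarray) -> np.ndarray:
    """Mean pairwise identity per column over an (n_species, n_cols) array.

    A pair of residues counts as identical only when both are non-gap and
    equal; a gap in either sequence counts as a mismatch for that pair.
    """
    n = chars.shape[0]
    pairs = list(combinations(range(n), 2))
    if not pairs:
        return np.ones(chars.shape[1])
    hits = np.zeros(chars.shape[1])
    gap = np.bytes_(GAP)
    for i, j in pairs:
        hits += (chars[i] == chars[j]) & (chars[i] != gap)
    return hits / len(pairs)


def column_identity(aln: MultipleAlignment, i: int) -> float:
    """Mean pairwise identity of column ``i`` (see ``_column_identities``)."""
    return float(_column_identities(_char_matrix(aln)[:, i : i + 1])[0])


def _window_keep_mask(identities: np.ndarray, window_len: int, min_identity: float) -> np.ndarray:
    """Keep mask after one sliding-window pass over per-column identities."""
    n = len(identities)
    keep = np.ones(n, dtype=bool)
    w = min(window_len, n)  # window longer than alignment: one whole-alignment window
    means = np.convolve(identities, np.ones(w) / w, mode="valid")
    for start in np.nonzero(means < min_identity)[0]:
        keep[start : start + w] = False
    return keep


def filter_columns(aln: MultipleAlignment, policy: FilterPolicy) -> MultipleAlignment:
    """Remove gap-containing and low-identity columns.

    Returns a new alignment whose ``meta['column_mask']`` is a boolean
    array over the *input* columns (True = kept), for audit.
    """
    if aln.n_columns == 0:
        raise ValueError("empty alignment")
    chars = _char_matrix(aln)
    mask = np.ones(aln.n_columns, dtype=bool)

    if policy.drop_gap_columns:
        mask &= ~(chars == np.bytes_(GAP)).any(axis=0)

    # Iterate the window criterion to a fixed point: removing a bad patch
    # re-forms windows across the junction, which may expose further
    # low-identity stretches.
    while policy.min_window_identity > 0.0:
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            break
        ids = _column_identities(chars[:, idx])
        keep = _window_keep_mask(ids, policy.window_len, policy.min_window_identity)
        if keep.all():
            break
        mask[idx[~keep]] = False

    out = aln.take_columns(np.nonzero(mask)[0]) if mask.any() else MultipleAlignment(
        {sp: "" for sp in aln.rows}
    )
    out.meta["column_mask"] = mask
    return out


def concat_alignments(alns: Iterable[MultipleAlignment]) -> MultipleAlignment:
    """Concatenate alignments over an identical species set, in order.

    ``meta['offsets']`` records the half-open column span each source
    occupies in the result, so the originals can be recovered by slicing.
    """
    alns = list(alns)
    if not alns:
        raise ValueError("nothing to concatenate")
    species = set(alns[0].rows)
    for a in alns[1:]:
        if set(a.rows) != species:
            raise ValueError(
                f"species-set mismatch: {sorted(species)} vs {sorted(a.rows)}"
            )
    order = alns[0].species
    rows = {sp: "".join(a.rows[sp] for a in alns) for sp in order}
    offsets, pos = [], 0
    for a in alns:
        offsets.append((pos, pos + a.n_columns))
        pos += a.n_columns
    out = MultipleAlignment(rows)
    out.meta["offsets"] = offsets
    return out
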