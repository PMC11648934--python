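"""Alignment coordinate mapping, gap-column trimming with provenance, anchors.

An *anchor* is a residue position stated on a named reference sequence
(e.g. "position 43 of EcCspD") that is projected through the multiple
sequence alignment to interrogate the homologous position in every family
member. Residue numbering is 1-based, matching the field convention
("K43", "K4"); column indices are 0-based internally.

Trimming removes gap-rich columns but records, for every surviving column,
the column index it had in the original alignment (the *provenance* map).
Anchors are resolved against original coordinates via that map, so an
anchor whose column was trimmed away resolves to the :data:`TRIMMED`
marker rather than silently pointing at the wrong residue.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .seqio import GAP, SeqRecord, read_fasta, write_fasta

#: Marker reported for every sequence when an anchor's column was trimmed away.
TRIMMED = "trimmed"


class AlignmentError(ValueError):
    pass


class AnchorError(ValueError):
    pass


@dataclass(frozen=True)
class Anchor:
    """A 1-based residue position on a named reference sequence."""

    name: str
    ref_id: str
    ref_pos: int
    expected: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_pos < 1:
            raise AnchorError(f"anchor {self.name!r}: ref_pos must be >= 1")


class Alignment:
    """Equal-length gapped rows plus a column-provenance map.

    ``provenance[c]`` is the column index, in the original (untrimmed)
    alignment, of current column ``c``. On an untrimmed alignment the
    provenance is the identity. ``parent`` links a trimmed alignment back
    to the alignment it was trimmed from, so anchors can always be located
    in original coordinates.
    """

    def __init__(
        self,
        rows: Sequence[SeqRecord],
        provenance: Optional[Sequence[int]] = None,
        parent: Optional["Alignment"] = None,
    ) -> None:
        rows = list(rows)
        if not rows:
            raise AlignmentError("alignment needs at least one row")
        lengths = {len(r.seq) for r in rows}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [r.id for r in rows]
        if len(ids) != len(set(ids)):
            raise AlignmentError("duplicate row ids in alignment")
        self.rows: list[SeqRecord] = rows
        self.n_cols: int = lengths.pop()
        if provenance is None:
            provenance = range(self.n_cols)
        provenance = tuple(provenance)
        if len(provenance) != self.n_cols:
            raise AlignmentError("provenance length must equal column count")
        if any(b <= a for a, b in zip(provenance, provenance[1:])):
            raise AlignmentError("provenance must be strictly increasing")
        self.provenance: tuple[int, ...] = provenance
        self.parent = parent

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, ref_id: str) -> SeqRecord:
        for r in self.rows:
            if r.id == ref_id:
                return r
        raise AnchorError(f"no row with id {ref_id!r} in alignment")

    @property
    def is_trimmed(self) -> bool:
        return self.parent is not None

    def untrimmed(self) -> "Alignment":
        """Walk back to the root alignment this one was trimmed from."""
        aln: Alignment = self
        while aln.parent is not None:
            aln = aln.parent
        return aln

    @classmethod
    def from_fasta(cls, path: str | Path, moltype: str = "protein") -> "Alignment":
        return cls(read_fasta(path, moltype=moltype))

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        write_fasta(self.rows, path, width=width)


def column_of(aln: Alignment, ref_id: str, ref_pos: int) -> int:
    """0-based column holding the ``ref_pos``-th non-gap residue of ``ref_id``."""
    if ref_pos < 1:
        raise AnchorError("ref_pos is 1-based and must be >= 1")
    seq = aln.row(ref_id).seq
    seen = 0
    for col, ch in enumerate(seq):
        if ch != GAP:
            seen += 1
            if seen == ref_pos:
                return col
    raise AnchorError(
        f"ref_pos {ref_pos} beyond ungapped length {seen} of {ref_id!r}"
    )


def trim_columns(aln: Alignment, max_gap_frac: float = 0.8) -> Alignment:
    """Keep exactly the columns whose gap fraction is <= ``max_gap_frac``.

    Provenance composes with the input's provenance; row order is preserved.
    Raises :class:`AlignmentError` when no column survives.
    """
    if not 0.0 <= max_gap_frac <= 1.0:
        raise ValueError("max_gap_frac must lie in [0, 1]")
    n_rows = len(aln)
    keep = [
        c
        for c in range(aln.n_cols)
        if sum(r.seq[c] == GAP for r in aln.rows) / n_rows <= max_gap_frac
    ]
    if not keep:
        raise AlignmentError("trimming removed every column")
    new_rows = [
        SeqRecord(
            id=r.id,
            seq="".join(r.seq[c] for c in keep),
            description=r.description,
            moltype=r.moltype,
        )
        for r in aln.rows
    ]
    return Alignment(
        new_rows,
        provenance=[aln.provenance[c] for c in keep],
        parent=aln,
    )


def residues_at(aln: Alignment, col: int) -> dict[str, str]:
    """Residue (or ``'-'``) of every row at 0-based column ``col``."""
    if not 0 <= col < aln.n_cols:
        raise AlignmentError(f"column {col} out of range [0, {aln.n_cols})")
    return {r.id: r.seq[col] for r in aln.rows}


def resolve_anchors(
    aln: Alignment, anchors: Iterable[Anchor]
) -> dict[str, tuple[Optional[int], dict[str, str]]]:
    """Locate each anchor's column and read out the residue of every row.

    Anchors are located on the root (untrimmed) alignment and mapped to the
    current alignment through the provenance map; an anchor whose column was
    trimmed away resolves to ``(None, {id: TRIMMED, ...})``.
    """
    root = aln.untrimmed()
    col_of_orig = {orig: cur for cur, orig in enumerate(aln.provenance)}
    out: dict[str, tuple[Optional[int], dict[str, str]]] = {}
    for anchor in anchors:
        orig_col = column_of(root, anchor.ref_id, anchor.ref_pos)
        cur = col_of_orig.get(orig_col)
        if cur is None:
            out[anchor.name] = (None, {rid: TRIMMED for rid in aln.ids})
        else:
            out[anchor.name] = (cur, residues_at(aln, cur))
    return out


def read_anchors_tsv(path: str | Path) -> list[Anchor]:
    """Read anchors from a TSV with columns name, ref_id, ref_pos[, expected]."""
    anchors: list[Anchor] = []
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            anchors.append(
                Anchor(
                    name=row["name"],
                    ref_id=row["ref_id"],
                    ref_pos=int(row["ref_pos"]),
                    expected=row.get("expected") or None,
                )
            )
    return anchors


def write_anchors_tsv(anchors: Iterable[Anchor], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["name", "ref_id", "ref_pos", "expected"])
        for a in anchors:
            writer.writerow([a.name, a.ref_id, a.ref_pos, a.expected or ""])
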