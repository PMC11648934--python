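"""Sequence and tree I/O plus exact-duplicate removal.

FASTA dialect: the record id is the first whitespace-delimited token of the
header, the remainder is kept as the description. ``-`` is the only accepted
gap character; ``.`` is rejected so that only one gap convention circulates
through the pipeline. Newick trees are carried as :class:`dendropy.Tree`
objects (unrooted trees are stored with an arbitrary trifurcating root).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
from Bio import SeqIO as _BioSeqIO

PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
NUCLEOTIDE_LETTERS = set("ACGT") | {"N"}
GAP = "-"


class FastaFormatError(ValueError):
    """Malformed FASTA content (duplicate ids, forbidden characters...)."""


class AlphabetError(FastaFormatError):
    """A sequence contains characters outside its declared alphabet."""


class NewickParseError(ValueError):
    """Malformed Newick text."""


@dataclass(frozen=True)
class SeqRecord:
    """One identified amino-acid or nucleotide sequence (gaps allowed)."""

    id: str
    seq: str
    description: str = ""
    moltype: str = "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("sequence id must be non-empty")
        if not self.seq:
            raise FastaFormatError(f"sequence {self.id!r} is empty")
        if self.moltype not in ("protein", "nucleotide"):
            raise ValueError(f"unknown moltype {self.moltype!r}")
        if "." in self.seq:
            raise AlphabetError(
                f"sequence {self.id!r} uses '.' as gap; only '-' is accepted"
            )
        alphabet = PROTEIN_LETTERS if self.moltype == "protein" else NUCLEOTIDE_LETTERS
        bad = set(self.seq.upper()) - alphabet - {GAP}
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains characters {sorted(bad)} "
                f"outside the {self.moltype} alphabet"
            )

    @property
    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.seq)


def _check_unique_ids(records: Iterable[SeqRecord]) -> list[SeqRecord]:
    out: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaFormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        out.append(rec)
    return out


def read_fasta(path: str | Path, moltype: str = "protein") -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`, in file order.

    An empty file yields an empty list; duplicate ids raise
    :class:`FastaFormatError`.
    """
    records = [
        SeqRecord(
            id=rec.id,
            seq=str(rec.seq).upper(),
            description=rec.description[len(rec.id):].strip(),
            moltype=moltype,
        )
        for rec in _BioSeqIO.parse(str(path), "fasta")
    ]
    return _check_unique_ids(records)


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA. Deterministic: input order, fixed width."""
    if width < 1:
        raise ValueError("width must be positive")
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_newick(text_or_path: str | Path) -> dendropy.Tree:
    """Parse Newick text (or a file path) into a dendropy Tree.

    Leaf labels must be unique; polytomies and optional branch lengths /
    internal labels are preserved.
    """
    text = str(text_or_path)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text(encoding="utf-8")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise NewickParseError("duplicate leaf labels in Newick tree")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree as one-line Newick with branch lengths if present."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def dedup_exact(
    records: Iterable[SeqRecord],
) -> tuple[list[SeqRecord], dict[str, str]]:
    """Collapse records whose ungapped, upper-cased sequences are identical.

    The first occurrence (input order) is the representative. Returns the
    unique records and a mapping from every input id to its representative's
    id. Idempotent and order-stable.
    """
    records = _check_unique_ids(records)
    unique: list[SeqRecord] = []
    rep_by_seq: dict[str, str] = {}
    representative_of: dict[str, str] = {}
    for rec in records:
        key = rec.ungapped.upper()
        if key not in rep_by_seq:
            rep_by_seq[key] = rec.id
            unique.append(rec)
        representative_of[rec.id] = rep_by_seq[key]
    return unique, representative_of
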