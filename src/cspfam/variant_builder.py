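"""In-silico construction of chimeric and point-mutant protein sequences.

Chimeras fuse the N-terminal portion of one parent to the C-terminal
portion of another at an explicit junction: ``left_end`` residues are taken
from the left parent and the first ``right_skip`` residues of the right
parent are dropped. Junctions are explicit pairs because the residue
correspondence across two parents of unequal length is alignment
information, not something the counts alone determine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .seqio import SeqRecord


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class Junction:
    left_id: str
    left_end: int
    right_id: str
    right_skip: int

    def __post_init__(self) -> None:
        if self.left_end < 0 or self.right_skip < 0:
            raise VariantError("junction counts must be >= 0")


# CspA/CspD chimera junctions: the CspA-side residue counts (13, 35, 39, 47,
# 61) are stated directly; the CspD-side skip counts are transcribed from the
# published chimera alignment figure and are editable config, not hard truth.
CSPA_CSPD_JUNCTIONS = {
    "jct1": Junction("CspA", 13, "CspD", 10),
    "jct2": Junction("CspA", 35, "CspD", 32),
    "jct3": Junction("CspA", 39, "CspD", 36),
    "jct4": Junction("CspA", 47, "CspD", 44),
    "jct5": Junction("CspA", 61, "CspD", 58),
}


def fuse(left: SeqRecord, right: SeqRecord, j: Junction) -> SeqRecord:
    """N-terminal ``left_end`` residues of ``left`` + ``right`` after its
    first ``right_skip`` residues. The id records both parents and junction."""
    if j.left_end > len(left.seq):
        raise VariantError(
            f"left_end {j.left_end} exceeds length {len(left.seq)} of {left.id!r}"
        )
    if j.right_skip > len(right.seq):
        raise VariantError(
            f"right_skip {j.right_skip} exceeds length {len(right.seq)} of {right.id!r}"
        )
    seq = left.seq[: j.left_end] + right.seq[j.right_skip :]
    if not seq:
        raise VariantError("fusion produced an empty sequence")
    return SeqRecord(
        id=f"{left.id}[1-{j.left_end}]+{right.id}[{j.right_skip + 1}-{len(right.seq)}]",
        seq=seq,
        description=f"chimera of {left.id} and {right.id}",
        moltype=left.moltype,
    )


def point_mutate(s: SeqRecord, edits: Iterable[tuple[int, str]]) -> SeqRecord:
    """Apply point substitutions at 1-based positions; length is preserved.

    Positions must be distinct and within the sequence.
    """
    edits = list(edits)
    positions = [p for p, _ in edits]
    if len(positions) != len(set(positions)):
        raise VariantError("duplicate edit positions")
    chars = list(s.seq)
    labels = []
    for pos, new in edits:
        if not 1 <= pos <= len(chars):
            raise VariantError(f"position {pos} outside 1..{len(chars)}")
        if len(new) != 1:
            raise VariantError(f"replacement must be one residue, got {new!r}")
        labels.append(f"{chars[pos - 1]}{pos}{new}")
        chars[pos - 1] = new.upper()
    return SeqRecord(
        id=s.id + ("-" + ",".join(labels) if labels else ""),
        seq="".join(chars),
        description=s.description,
        moltype=s.moltype,
    )
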