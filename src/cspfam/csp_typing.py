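"""Residue-anchored classification of cold-shock proteins into loop types.

Csp family members are typed by the residue pair at the internal-loop
positions homologous to EcCspD K43-A44 (equivalently EcCspA D46-E47):
K-A (EcCspD-like), K-E (PfCsp-like), D-E (EcCspA-like), K-other, or
"other". A gap at either loop position means the member is unaligned at
the anchor and is reported as such rather than typed. Two optional extra
anchors are tracked alongside the loop pair: lysine at the position
homologous to EcCspA K4 in the N-terminal extension (the ``k4_flag``),
and the residue at position 2 (alanine there distinguishes PfCsp-like
K-E members).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .anchor_map import TRIMMED

LABELS = ("K-A", "K-E", "K-other", "D-E", "unaligned", "other")
K_FIRST_LABELS = ("K-A", "K-E", "K-other")


class TypingConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TypeCall:
    """Per-protein anchor residues and the loop-type label they induce."""

    seq_id: str
    loop_first: str
    loop_second: str
    label: str
    nterm_k4: Optional[str] = None
    pos2: Optional[str] = None
    k4_flag: bool = False


def _norm(residue: str, what: str) -> str:
    if len(residue) != 1:
        raise TypingConfigError(f"{what} must be a single character, got {residue!r}")
    return residue.upper()


def classify_loop(first: str, second: str) -> str:
    """Loop-type label from the two anchor residues; total and case-insensitive.

    A gap (or a trimmed-away anchor) at either position yields "unaligned";
    the ambiguity code 'X' at either position yields "other".
    """
    if first == TRIMMED or second == TRIMMED:
        return "unaligned"
    first = _norm(first, "first loop residue")
    second = _norm(second, "second loop residue")
    if first == "-" or second == "-":
        return "unaligned"
    if first == "X" or second == "X":
        return "other"
    if first == "K":
        if second == "A":
            return "K-A"
        if second == "E":
            return "K-E"
        return "K-other"
    if first == "D" and second == "E":
        return "D-E"
    return "other"


def classify_family(
    anchored: Mapping[str, tuple[Optional[int], Mapping[str, str]]],
    loop_first: str = "loop_first",
    loop_second: str = "loop_second",
    k4: Optional[str] = "k4",
    pos2: Optional[str] = "pos2",
) -> list[TypeCall]:
    """One :class:`TypeCall` per sequence from resolved anchors.

    ``anchored`` is the output of :func:`cspfam.anchor_map.resolve_anchors`;
    the keyword arguments name the anchors playing each role. The two loop
    anchors are required; the K4 and position-2 anchors are optional (pass
    ``None`` or omit them from ``anchored``).
    """
    for required in (loop_first, loop_second):
        if required not in anchored:
            raise TypingConfigError(f"missing loop anchor {required!r}")
    _, first_res = anchored[loop_first]
    _, second_res = anchored[loop_second]
    k4_res = anchored[k4][1] if k4 is not None and k4 in anchored else None
    pos2_res = anchored[pos2][1] if pos2 is not None and pos2 in anchored else None

    calls: list[TypeCall] = []
    for seq_id in first_res:
        f, s = first_res[seq_id], second_res[seq_id]
        k4_char = k4_res.get(seq_id) if k4_res is not None else None
        calls.append(
            TypeCall(
                seq_id=seq_id,
                loop_first=f,
                loop_second=s,
                label=classify_loop(f, s),
                nterm_k4=k4_char,
                pos2=pos2_res.get(seq_id) if pos2_res is not None else None,
                k4_flag=(k4_char is not None and k4_char.upper() == "K"),
            )
        )
    return calls


def tally_types(calls: Iterable[TypeCall]) -> dict:
    """Counts and percentages per label, plus the two headline statistics.

    ``k_first_ae_share_pct`` is the percentage, among K-first members
    (labels K-A, K-E, K-other; gapped members excluded), whose second loop
    residue is A or E. ``dual_lysine_count`` counts members with lysine at
    both the first loop position and the K4 position. Percentages are
    reported to one decimal place; counts are exact.
    """
    calls = list(calls)
    n = len(calls)
    counts = Counter(c.label for c in calls)
    label_counts = {label: counts.get(label, 0) for label in LABELS}
    label_pct = {
        label: (round(100.0 * cnt / n, 1) if n else None)
        for label, cnt in label_counts.items()
    }
    k_first = sum(label_counts[l] for l in K_FIRST_LABELS)
    k_first_ae = label_counts["K-A"] + label_counts["K-E"]
    return {
        "n": n,
        "counts": label_counts,
        "percentages": label_pct,
        "k_first_count": k_first,
        "k_first_ae_count": k_first_ae,
        "k_first_ae_share_pct": round(100.0 * k_first_ae / k_first, 1) if k_first else None,
        "dual_lysine_count": sum(1 for c in calls if c.loop_first.upper() == "K" and c.k4_flag),
    }


def calls_to_frame(calls: Iterable[TypeCall]) -> pd.DataFrame:
    """Per-protein annotation table (raw anchor residues alongside the label)."""
    return pd.DataFrame(
        [
            {
                "seq_id": c.seq_id,
                "loop_first": c.loop_first,
                "loop_second": c.loop_second,
                "nterm_k4": c.nterm_k4 if c.nterm_k4 is not None else "",
                "pos2": c.pos2 if c.pos2 is not None else "",
                "label": c.label,
                "k4_flag": c.k4_flag,
            }
            for c in calls
        ]
    )
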