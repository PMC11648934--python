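#!/usr/bin/env python
"""Construct chimeric and point-mutant variants and reclassify them.

Takes one CspD-like (K-A) and one CspA-like (D-E) member of the synthetic
family as stand-in parents, builds the five CspA/CspD chimera junctions,
and applies the loop swap K43D/A44E to the K-A parent. The loop swap must
move the classification from K-A to D-E, the behaviour that motivates the
loop anchors.
"""

import json
from pathlib import Path

from cspfam.csp_typing import classify_loop
from cspfam.seqio import read_fasta, write_fasta
from cspfam.variant_builder import CSPA_CSPD_JUNCTIONS, Junction, fuse, point_mutate

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = {r.id: r for r in read_fasta(ROOT / "synthetic" / "family.fasta")}
    truth = json.loads((ROOT / "synthetic" / "truth.json").read_text())
    ka_parent = records[next(s for s, t in truth["planted_type"].items() if t == "K-A")]
    de_parent = records[next(s for s, t in truth["planted_type"].items() if t == "D-E")]

    out = ROOT / "variants"
    out.mkdir(parents=True, exist_ok=True)

    chimeras = []
    for name, j in CSPA_CSPD_JUNCTIONS.items():
        # same junction geometry, synthetic parents (D-E stands in for CspA)
        jj = Junction(de_parent.id, j.left_end, ka_parent.id, j.right_skip)
        chimeras.append(fuse(de_parent, ka_parent, jj))
        print(f"{name}: {chimeras[-1].id} length {len(chimeras[-1].seq)}")

    loop_swap = point_mutate(ka_parent, [(43, "D"), (44, "E")])
    before = classify_loop(ka_parent.seq[42], ka_parent.seq[43])
    after = classify_loop(loop_swap.seq[42], loop_swap.seq[43])
    print(f"loop swap {ka_parent.id}: {before} -> {after}")
    assert (before, after) == ("K-A", "D-E")

    write_fasta(chimeras + [loop_swap], out / "variants.fasta")
    print(f"variants written to {out / 'variants.fasta'}")


if __name__ == "__main__":
    main()
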