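#!/usr/bin/env python
"""Type every family member at the loop anchors and tally the types.

Reads the synthetic alignment and anchors from results/synthetic/ (run
01_simulate_inputs.py first), resolves the anchors on the untrimmed
alignment, classifies each member (K-A / K-E / K-other / D-E / other /
unaligned), and writes the per-protein table and tally. Also reproduces,
as a worked example from printed counts, the headline K-first statistic:
a 320/102/5 partition of K-A/K-E/K-other proteins puts A or E at the
second loop position in 98.8% of the 427 K-first members.
"""

import json
from pathlib import Path

from cspfam.anchor_map import Alignment, read_anchors_tsv, resolve_anchors
from cspfam.csp_typing import TypeCall, calls_to_frame, classify_family, tally_types

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    aln = Alignment.from_fasta(ROOT / "synthetic" / "family_aln.fasta")
    anchors = read_anchors_tsv(ROOT / "synthetic" / "anchors.tsv")
    calls = classify_family(resolve_anchors(aln, anchors))

    out = ROOT / "typing"
    out.mkdir(parents=True, exist_ok=True)
    calls_to_frame(calls).to_csv(out / "type_calls.tsv", sep="\t", index=False)
    tally = tally_types(calls)
    (out / "tally.json").write_text(json.dumps(tally, indent=2, sort_keys=True))

    truth = json.loads((ROOT / "synthetic" / "truth.json").read_text())
    called = {c.seq_id: c.label for c in calls}
    exact = called == truth["planted_type"]
    print(f"typed {tally['n']} members: {tally['counts']}")
    print(f"calls match planted truth exactly: {exact}")
    print(f"dual-lysine members (loop K + K4): {tally['dual_lysine_count']}")

    worked = tally_types(
        [TypeCall(f"ka{i}", "K", "A", "K-A") for i in range(320)]
        + [TypeCall(f"ke{i}", "K", "E", "K-E") for i in range(102)]
        + [TypeCall(f"ko{i}", "K", "Q", "K-other") for i in range(5)]
    )
    (out / "kfirst_worked_example.json").write_text(json.dumps(worked, indent=2, sort_keys=True))
    print(
        f"worked example: {worked['k_first_ae_count']}/{worked['k_first_count']} "
        f"K-first members carry A or E second = {worked['k_first_ae_share_pct']}%"
    )


if __name__ == "__main__":
    main()
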