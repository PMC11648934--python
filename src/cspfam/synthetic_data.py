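"""Seeded generators for synthetic Csp families, genome tables and
quantitation tables with planted, fully known structure.

The family generator emulates the statistical shape of the real Csp
family: ~70-residue cold-shock-domain-like proteins sharing a conserved
core with invariant RNA-binding motif blocks (RNP1, RNP2), evolved along
a Yule tree, with the type-defining anchor residues planted per member.
The residue-defined types are placed on disjoint subtrees (the K-A
members always form a true clade), and divergence between type subtrees
is deeper than within them, reflecting that the types are anciently
separated subfamilies. Core evolution is indel-free; CspA-like (D-E)
members carry a fixed-length unstructured N-terminal extension, so the
true alignment is known exactly by gap-padding and no alignment inference
is ever needed.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .anchor_map import Alignment, Anchor
from .genome_dist import GenomeRecord
from .seqio import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# CSD-like ancestral core (the E. coli CspA sequence, 70 aa): a realistic
# cold-shock domain scaffold whose RNP1/RNP2 blocks are held invariant.
ANCESTRAL_CORE = "MSGKMTGIVKWFNADKGFGFITPDDGSKDVFVHFSAIQNDGYKSLDEGQKVSFTIESGAKGPAAGNVTSL"
RNP1_SPAN = (15, 20)  # 0-based half-open: "KGFGF"
RNP2_SPAN = (29, 34)  # 0-based half-open: "VFVHF"

TYPE_PREFIX = {"K-A": "KA", "K-E": "KE", "D-E": "DE", "other": "OT"}
#: N-terminal extension length per type (D-E / CspA-like members carry the
#: unstructured N-tail; the loop-typed members do not).
EXTENSION_LENGTH = {"K-A": 0, "K-E": 0, "D-E": 3, "other": 0}
#: Loop residues planted per type; "other" cycles through the loop pairs seen
#: in the non-K-A, non-D-E E. coli paralogs (F-E, A-E, T-T, N-E).
OTHER_LOOP_PAIRS = (("F", "E"), ("A", "E"), ("T", "T"), ("N", "E"))
#: Planted (relative efficiency for baxL, relative efficiency for gdx) per
#: type: K-A members behave like the CspD reference, D-E like CspA.
DEFAULT_QUANT_EFFECTS = {
    "K-A": (1.0, 0.2),
    "K-E": (0.5, 1.0),
    "D-E": (0.1, 1.0),
    "other": (0.3, 0.3),
}
#: Csp-count distribution over 1..10 (most genomes carry one or two Csps,
#: roughly two thirds, mirroring the low/high group balance in real data).
DEFAULT_COUNT_DISTRIBUTION = np.array(
    [0.40, 0.27, 0.13, 0.08, 0.05, 0.03, 0.02, 0.01, 0.007, 0.003]
) / 1.0
DEFAULT_COUNT_DISTRIBUTION /= DEFAULT_COUNT_DISTRIBUTION.sum()

#: Between-type backbone edges evolve through this many rounds of the
#: per-edge substitution probability (deep inter-subfamily divergence).
BACKBONE_ROUNDS = 5


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic family simulation."""

    n_per_type: Mapping[str, int] = field(
        default_factory=lambda: {"K-A": 12, "K-E": 8, "D-E": 12, "other": 8}
    )
    core_length: int = 70
    loop_positions: tuple[int, int] = (43, 44)  # 1-based core coordinates
    k4_position: int = 4  # 1-based full-sequence position (D-E members)
    pos2_position: int = 2  # 1-based full-sequence position
    sub_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_per_type.values()):
            raise SimulationError("type counts must be >= 0")
        unknown = set(self.n_per_type) - set(TYPE_PREFIX)
        if unknown:
            raise SimulationError(f"unknown types {sorted(unknown)}")
        if not 0.0 <= self.sub_prob <= 0.3:
            raise SimulationError("sub_prob must lie in [0, 0.3]")
        if not 46 <= self.core_length <= len(ANCESTRAL_CORE):
            raise SimulationError(
                f"core_length must lie in [46, {len(ANCESTRAL_CORE)}]"
            )
        lo, hi = self.loop_positions
        if not (1 <= lo < hi <= self.core_length):
            raise SimulationError("loop positions must be ordered and within the core")

    @property
    def n_total(self) -> int:
        return sum(self.n_per_type.values())


@dataclass
class TruthBundle:
    """Everything needed to predict every downstream stage's output."""

    true_tree: dendropy.Tree
    true_alignment: Alignment
    planted_type: dict[str, str]
    genome_assignment: dict[str, str]
    quant_effects: dict[str, tuple[float, float]]
    anchors: list[Anchor]
    seed: int


def _yule_subtree(n_leaves: int, rng: np.random.Generator) -> dict:
    """Pure-Python Yule topology: nested dict {children: [...]} / leaf None."""
    tree: dict = {"children": None}  # a single leaf
    leaves = [tree]
    while len(leaves) < n_leaves:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        left, right = {"children": None}, {"children": None}
        node["children"] = [left, right]
        leaves.extend([left, right])
    return tree

def _collect_leaves(node: dict, out: list) -> None:
    if node["children"] is None:
        out.append(node)
    else:
        for child in node["children"]:
            _collect_leaves(child, out)


def _mutate(seq: list[str], p: float, protected: set[int], rng: np.random.Generator) -> list[str]:
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    for site in hits:
        if site in protected:
            continue
        alternatives = AMINO_ACIDS.replace(out[site], "")
        out[site] = alternatives[int(rng.integers(len(alternatives)))]
    return out


def simulate_family(spec: FamilySpec) -> tuple[list[SeqRecord], TruthBundle]:
    """Simulate a Csp-like family with planted types on a known tree.

    Returns the ungapped sequences (emission order: K-A, K-E, D-E, other)
    and the truth bundle with the true tree, the exact true alignment, the
    planted type of every member, a genome assignment, the planted
    quantitation effects, and the anchors that recover the types.
    """
    if spec.n_total < 4:
        raise SimulationError("need at least 4 members in total")
    rng = np.random.default_rng(spec.seed)

    types_present = [t for t in ("K-A", "K-E", "D-E", "other") if spec.n_per_type.get(t, 0) > 0]
    core = list(ANCESTRAL_CORE[: spec.core_length])
    loop0 = (spec.loop_positions[0] - 1, spec.loop_positions[1] - 1)
    protected = set(range(*RNP1_SPAN)) | set(range(*RNP2_SPAN)) | set(loop0)
    protected &= set(range(spec.core_length))
    # position-2 and K4 columns are overwritten post hoc; protect them too
    protected |= {0, 1}

    ext_len = {t: EXTENSION_LENGTH[t] for t in types_present}
    e_max = max(ext_len.values(), default=0)

    # --- evolve cores along per-type Yule subtrees hanging off one backbone ---
    p_backbone = 1.0 - (1.0 - spec.sub_prob) ** BACKBONE_ROUNDS
    member_core: dict[str, list[str]] = {}
    member_type: dict[str, str] = {}
    newick_parts: list[str] = []
    other_cycle = 0
    for t in types_present:
        n_t = spec.n_per_type[t]
        subtree = _yule_subtree(n_t, rng)
        # root sequence of this subtree: ancestor evolved through the backbone
        sub_root_seq = _mutate(core, p_backbone, protected, rng)

        counter = [0]

        def emit(node: dict, seq: list[str], prefix: str = t) -> str:
            nonlocal other_cycle
            if node["children"] is None:
                counter[0] += 1
                seq_id = f"{TYPE_PREFIX[prefix]}{counter[0]:03d}"
                planted = list(seq)
                if prefix == "K-A":
                    planted[loop0[0]], planted[loop0[1]] = "K", "A"
                    planted[1] = "E"
                elif prefix == "K-E":
                    planted[loop0[0]], planted[loop0[1]] = "K", "E"
                    planted[1] = "A"
                elif prefix == "D-E":
                    planted[loop0[0]], planted[loop0[1]] = "D", "E"
                else:
                    pair = OTHER_LOOP_PAIRS[other_cycle % len(OTHER_LOOP_PAIRS)]
                    other_cycle += 1
                    planted[loop0[0]], planted[loop0[1]] = pair
                member_core[seq_id] = planted
                member_type[seq_id] = prefix
                return seq_id
            parts = []
            for child in node["children"]:
                child_seq = _mutate(seq, spec.sub_prob, protected, rng)
                parts.append(f"{emit(child, child_seq)}:{spec.sub_prob}")
            return "(" + ",".join(parts) + ")"

        rendered = emit(subtree, sub_root_seq)
        newick_parts.append(f"{rendered}:{p_backbone}")

    if len(newick_parts) == 1:
        newick = newick_parts[0].rsplit(":", 1)[0] + ";"
        if not newick.startswith("("):
            raise SimulationError("a single-member family has no tree")
    else:
        newick = "(" + ",".join(newick_parts) + ");"
    from .seqio import read_newick

    true_tree = read_newick(newick)

    # --- assemble full sequences and the exactly known true alignment ---
    records: list[SeqRecord] = []
    aligned_rows: list[SeqRecord] = []
    for seq_id, core_seq in member_core.items():
        t = member_type[seq_id]
        ext = ext_len[t]
        core_seq = list(core_seq)
        if ext > 0:
            tail = ["M"] + [
                AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))] for _ in range(ext - 1)
            ]
            if t == "D-E":
                if spec.k4_position > ext:
                    core_seq[spec.k4_position - ext - 1] = "K"
                else:
                    tail[spec.k4_position - 1] = "K"
        else:
            tail = []
        full = "".join(tail) + "".join(core_seq)
        row = "-" * (e_max - ext) + full
        records.append(SeqRecord(id=seq_id, seq=full, moltype="protein"))
        aligned_rows.append(SeqRecord(id=seq_id, seq=row, moltype="protein"))
    true_alignment = Alignment(aligned_rows)

    # --- anchors that recover the planted types ---
    def first_of(t: str) -> Optional[str]:
        for sid, typ in member_type.items():
            if typ == t:
                return sid
        return None

    loop_ref = first_of("K-A") or first_of("K-E") or first_of("other") or first_of("D-E")
    loop_ref_ext = ext_len[member_type[loop_ref]]
    anchors = [
        Anchor("loop_first", loop_ref, loop_ref_ext + spec.loop_positions[0], "K"),
        Anchor("loop_second", loop_ref, loop_ref_ext + spec.loop_positions[1], "A"),
    ]
    k4_ref = first_of("D-E")
    if k4_ref is not None:
        anchors.append(Anchor("k4", k4_ref, spec.k4_position, "K"))
    pos2_ref = first_of("K-E") or loop_ref
    anchors.append(Anchor("pos2", pos2_ref, spec.pos2_position, None))

    # --- genome assignment: draw per-genome Csp counts until all assigned ---
    genome_assignment: dict[str, str] = {}
    ids = list(member_core)
    g = 0
    i = 0
    while i < len(ids):
        g += 1
        k = int(rng.choice(np.arange(1, 11), p=DEFAULT_COUNT_DISTRIBUTION))
        for sid in ids[i : i + k]:
            genome_assignment[sid] = f"g{g:03d}"
        i += k

    return records, TruthBundle(
        true_tree=true_tree,
        true_alignment=true_alignment,
        planted_type=dict(member_type),
        genome_assignment=genome_assignment,
        quant_effects={t: DEFAULT_QUANT_EFFECTS[t] for t in types_present},
        anchors=anchors,
        seed=spec.seed,
    )


def simulate_genomes(
    n_genomes: int = 100,
    count_distribution: Optional[Sequence[float]] = None,
    size_shift: float = 0.3,
    gc_shift: float = 0.05,
    seed: int = 0,
    threshold: int = 3,
    base_size: float = 4.0e6,
    size_sigma: float = 0.2,
    base_gc: float = 0.5,
    gc_sigma: float = 0.04,
) -> list[GenomeRecord]:
    """Genome records with Csp counts on 1..10 and a planted size/GC effect.

    Genomes whose count reaches ``threshold`` get their size multiplied by
    ``(1 + size_shift)`` and their GC shifted by ``gc_shift`` before
    multiplicative/additive noise. Zero shifts make the groups exchangeable.
    """
    if n_genomes < 2:
        raise SimulationError("need at least 2 genomes")
    if count_distribution is None:
        dist = DEFAULT_COUNT_DISTRIBUTION
    else:
        dist = np.asarray(count_distribution, dtype=float)
        if dist.shape != (10,) or np.any(dist < 0) or not np.isclose(dist.sum(), 1.0):
            raise SimulationError(
                "count_distribution must be 10 nonnegative probabilities summing to 1"
            )
    rng = np.random.default_rng(seed)
    out: list[GenomeRecord] = []
    for i in range(n_genomes):
        count = int(rng.choice(np.arange(1, 11), p=dist))
        high = count >= threshold
        size = base_size * (1.0 + (size_shift if high else 0.0)) * float(
            np.exp(rng.normal(0.0, size_sigma))
        )
        gc = base_gc + (gc_shift if high else 0.0) + float(rng.normal(0.0, gc_sigma))
        gc = float(np.clip(gc, 0.05, 0.95))
        gid = f"g{i + 1:04d}"
        out.append(
            GenomeRecord(
                genome_id=gid,
                size=int(round(size)),
                gc=gc,
                csp_ids=tuple(f"{gid}_csp{j + 1}" for j in range(count)),
                taxon="synthetic",
            )
        )
    return out


def simulate_quant(
    effects: Mapping[str, tuple[float, float]],
    noise_sigma: float = 0.15,
    n_reps: int = 3,
    seed: int = 0,
    base_intensity: float = 1000.0,
    baxl_reference: str = "CspD",
    gdx_reference: str = "CspA",
) -> pd.DataFrame:
    """Quantitation table with planted relative efficiencies per sample.

    ``effects[sample] = (rel_baxL, rel_gdx)``: band intensity is the base
    intensity times the planted relative efficiency times lognormal
    multiplicative noise, per replicate. The two reference lanes (planted
    efficiencies 1.0 for their own probe) are added automatically when not
    supplied. With ``noise_sigma = 0`` relative levels recover the planted
    effects exactly.
    """
    if n_reps < 1:
        raise SimulationError("n_reps must be >= 1")
    if noise_sigma < 0:
        raise SimulationError("noise_sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    all_effects: dict[str, tuple[float, float]] = {}
    if baxl_reference not in effects:
        all_effects[baxl_reference] = DEFAULT_QUANT_EFFECTS["K-A"]
    if gdx_reference not in effects:
        all_effects[gdx_reference] = DEFAULT_QUANT_EFFECTS["D-E"]
    all_effects.update(effects)

    rows = []
    for sample, (rel_b, rel_g) in all_effects.items():
        for probe, rel in (("baxL", rel_b), ("gdx", rel_g)):
            for rep in range(1, n_reps + 1):
                noise = float(np.exp(rng.normal(0.0, noise_sigma))) if noise_sigma else 1.0
                rows.append(
                    {
                        "sample": sample,
                        "probe": probe,
                        "replicate": rep,
                        "intensity": base_intensity * rel * noise,
                        "fraction": "total",
                    }
                )
    return pd.DataFrame(rows)


def random_binary_tree(
    n_leaves: int,
    rng: np.random.Generator,
    min_branch: float = 0.1,
    max_branch: float = 1.0,
) -> "dendropy.Tree":
    """Random unrooted binary tree with uniform branch lengths, for
    additive-distance and monophyly checks. Leaves are labelled t0..t{n-1}."""
    from .seqio import read_newick

    if n_leaves < 4:
        raise SimulationError("need at least 4 leaves for a nontrivial tree")
    nodes: list[tuple] = [(f"t{i}",) for i in range(n_leaves)]
    rendered = {(f"t{i}",): f"t{i}" for i in range(n_leaves)}
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        for k in (j, i):
            nodes.pop(k)
        la, lb = rng.uniform(min_branch, max_branch, size=2)
        merged = tuple(sorted(a + b))
        rendered[merged] = f"({rendered[a]}:{la:.9f},{rendered[b]}:{lb:.9f})"
        nodes.append(merged)
    lengths = rng.uniform(min_branch, max_branch, size=3)
    newick = (
        "(" + ",".join(f"{rendered[x]}:{l:.9f}" for x, l in zip(nodes, lengths)) + ");"
    )
    return read_newick(newick)


def tree_distance_matrix(tree: "dendropy.Tree"):
    """Additive (path-length) distances between the leaves of a tree."""
    from .phylo import DistanceMatrix, leaf_labels

    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(leaf_labels(tree))
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels=labels, d=d)
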