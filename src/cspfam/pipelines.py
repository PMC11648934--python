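"""End-to-end workflows: family typing + phylogeny, genome distribution,
and quantitation. Each run writes TSV/JSON reports plus a manifest
(config echo, seed, input checksums, package version) sufficient to
reproduce the outputs bit-for-bit."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .anchor_map import Alignment, read_anchors_tsv, resolve_anchors, trim_columns
from .csp_typing import calls_to_frame, classify_family, tally_types
from .genome_dist import compare_groups, read_genomes_tsv
from .phylo import (
    alignment_distance_matrix,
    is_monophyletic,
    nj_tree,
    split_distance_to_monophyly,
)
from .quantitation import read_quant_tsv, specificity_table
from .seqio import read_newick, write_newick


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str
    msa: Optional[str] = None
    anchors: Optional[str] = None
    tree: Optional[str] = None  # externally inferred Newick; else NJ is built
    build_tree: bool = True
    max_gap_frac: float = 0.8
    genomes: Optional[str] = None
    quant: Optional[str] = None
    csp_threshold: int = 3
    seed: int = 0


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_manifest(cfg: RunConfig, out: Path, inputs: Sequence[str]) -> None:
    manifest = {
        "cspfam_version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "input_checksums": {str(p): _sha256(p) for p in inputs if p},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_typing(cfg: RunConfig) -> dict:
    """Type every family member, tally, and assess per-type monophyly.

    Anchors are resolved on the untrimmed alignment (so they are never
    silently lost); tree distances are computed on the trimmed alignment.
    """
    if cfg.msa is None or cfg.anchors is None:
        raise PipelineError("typing needs --msa and --anchors")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    aln = Alignment.from_fasta(cfg.msa)
    anchors = read_anchors_tsv(cfg.anchors)
    resolved = resolve_anchors(aln, anchors)
    calls = classify_family(resolved)
    table = calls_to_frame(calls)
    table.to_csv(out / "type_calls.tsv", sep="\t", index=False)
    tally = tally_types(calls)
    tally["anchor_resolution"] = "untrimmed alignment"
    (out / "tally.json").write_text(json.dumps(tally, indent=2, sort_keys=True))

    if cfg.tree is not None:
        tree = read_newick(Path(cfg.tree).read_text(encoding="utf-8"))
    elif cfg.build_tree:
        trimmed = trim_columns(aln, max_gap_frac=cfg.max_gap_frac)
        tree = nj_tree(alignment_distance_matrix(trimmed))
    else:
        tree = None

    monophyly = {}
    if tree is not None:
        (out / "tree.nwk").write_text(write_newick(tree) + "\n")
        by_label: dict[str, list[str]] = {}
        for call in calls:
            by_label.setdefault(call.label, []).append(call.seq_id)
        for label, members in sorted(by_label.items()):
            monophyly[label] = {
                "n": len(members),
                "monophyletic": is_monophyletic(tree, members),
                "split_distance": split_distance_to_monophyly(tree, members),
            }
        (out / "monophyly.json").write_text(
            json.dumps(monophyly, indent=2, sort_keys=True)
        )

    _write_manifest(cfg, out, [cfg.msa, cfg.anchors, cfg.tree or ""])
    return {"tally": tally, "monophyly": monophyly, "n_calls": len(calls)}


def run_distribution(cfg: RunConfig) -> dict:
    """Per-genome Csp counts and the size/GC group comparison."""
    if cfg.genomes is None:
        raise PipelineError("distribution needs --genomes")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes = read_genomes_tsv(cfg.genomes)
    counts = {g.genome_id: g.csp_count for g in genomes}
    report = {
        "n_genomes": len(genomes),
        "csp_counts": counts,
        "size": compare_groups(genomes, "size", threshold=cfg.csp_threshold),
        "gc": compare_groups(genomes, "gc", threshold=cfg.csp_threshold),
    }
    (out / "distribution.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _write_manifest(cfg, out, [cfg.genomes])
    return report


def run_quant(cfg: RunConfig) -> dict:
    """Specificity scores from a quantitation table."""
    if cfg.quant is None:
        raise PipelineError("quant needs --quant")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    q = read_quant_tsv(cfg.quant)
    results = specificity_table(q)
    report = {
        r.sample: {
            "rel_baxL": list(r.rel_baxL),
            "rel_gdx": list(r.rel_gdx),
            "score": r.score,
            "score_sd": r.score_sd,
        }
        for r in results
    }
    (out / "specificity.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _write_manifest(cfg, out, [cfg.quant])
    return report
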