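import json

import pytest
from click.testing import CliRunner

from cspfam.anchor_map import write_anchors_tsv
from cspfam.cli import main as cli_main
from cspfam.genome_dist import write_genomes_tsv
from cspfam.pipelines import PipelineError, RunConfig, run_distribution, run_quant, run_typing
from cspfam.quantitation import specificity_table
from cspfam.seqio import write_fasta
from cspfam.synthetic_data import (
    FamilySpec,
    simulate_family,
    simulate_genomes,
    simulate_quant,
)


@pytest.fixture
def family_inputs(tmp_path):
    records, truth = simulate_family(FamilySpec(seed=8, sub_prob=0.03))
    msa = tmp_path / "aln.fasta"
    truth.true_alignment.to_fasta(msa)
    anchors = tmp_path / "anchors.tsv"
    write_anchors_tsv(truth.anchors, anchors)
    return msa, anchors, truth


class TestRunTyping:
    def test_end_to_end_matches_truth(self, tmp_path, family_inputs):
        msa, anchors, truth = family_inputs
        cfg = RunConfig(out_dir=str(tmp_path / "out"), msa=str(msa), anchors=str(anchors))
        report = run_typing(cfg)
        counts = report["tally"]["counts"]
        from collections import Counter

        assert counts == {
            **{label: 0 for label in counts},
            **Counter(truth.planted_type.values()),
        }
        assert report["monophyly"]["K-A"]["monophyletic"] is True
        assert report["monophyly"]["K-A"]["split_distance"] == 0
        out = tmp_path / "out"
        for name in ("type_calls.tsv", "tally.json", "tree.nwk", "monophyly.json", "manifest.json"):
            assert (out / name).exists()

    def test_rerun_is_byte_identical(self, tmp_path, family_inputs):
        msa, anchors, _ = family_inputs
        outs = []
        for run in ("a", "b"):
            cfg = RunConfig(out_dir=str(tmp_path / run), msa=str(msa), anchors=str(anchors))
            run_typing(cfg)
            outs.append(tmp_path / run)
        for name in ("type_calls.tsv", "tally.json", "tree.nwk", "monophyly.json"):
            assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()

    def test_missing_inputs_is_error(self, tmp_path):
        with pytest.raises(PipelineError):
            run_typing(RunConfig(out_dir=str(tmp_path)))

    def test_external_tree_is_consumed(self, tmp_path, family_inputs):
        msa, anchors, truth = family_inputs
        from cspfam.seqio import write_newick

        tree_path = tmp_path / "ext.nwk"
        tree_path.write_text(write_newick(truth.true_tree) + "\n")
        cfg = RunConfig(
            out_dir=str(tmp_path / "out"), msa=str(msa), anchors=str(anchors),
            tree=str(tree_path),
        )
        report = run_typing(cfg)
        assert report["monophyly"]["K-A"]["monophyletic"] is True


class TestRunDistribution:
    def test_planted_effect_direction(self, tmp_path):
        genomes = simulate_genomes(n_genomes=120, size_shift=0.3, gc_shift=0.05, seed=5)
        path = tmp_path / "genomes.tsv"
        write_genomes_tsv(genomes, path)
        report = run_distribution(
            RunConfig(out_dir=str(tmp_path / "out"), genomes=str(path))
        )
        assert report["size"]["direction"] == "high_group_larger"
        assert report["gc"]["direction"] == "high_group_larger"

    def test_single_group_not_testable(self, tmp_path):
        genomes = simulate_genomes(
            n_genomes=10, count_distribution=[1.0] + [0.0] * 9, seed=0
        )
        path = tmp_path / "genomes.tsv"
        write_genomes_tsv(genomes, path)
        report = run_distribution(
            RunConfig(out_dir=str(tmp_path / "out"), genomes=str(path))
        )
        assert report["size"]["testable"] is False


class TestRunQuant:
    def test_matches_module_level_composition(self, tmp_path):
        q = simulate_quant({"s1": (5.0, 0.3), "s2": (0.3, 5.0)}, seed=2)
        path = tmp_path / "quant.tsv"
        q.to_csv(path, sep="\t", index=False)
        report = run_quant(RunConfig(out_dir=str(tmp_path / "out"), quant=str(path)))
        direct = {r.sample: r.score for r in specificity_table(q)}
        assert set(report) == set(direct)
        for sample in direct:
            assert report[sample]["score"] == pytest.approx(direct[sample])

    def test_noiseless_scores_exact(self, tmp_path):
        q = simulate_quant({"s": (5.0, 0.3)}, noise_sigma=0.0)
        path = tmp_path / "quant.tsv"
        q.to_csv(path, sep="\t", index=False)
        report = run_quant(RunConfig(out_dir=str(tmp_path / "out"), quant=str(path)))
        assert report["s"]["score"] == pytest.approx(4.7)
        assert report["s"]["score_sd"] == pytest.approx(0.0)


class TestCli:
    def test_simulate_then_type(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        res = runner.invoke(cli_main, ["simulate", "--seed", "3", "--out", str(sim_dir)])
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            cli_main,
            [
                "type",
                "--msa", str(sim_dir / "family_aln.fasta"),
                "--anchors", str(sim_dir / "anchors.tsv"),
                "--out", str(tmp_path / "typed"),
            ],
        )
        assert res.exit_code == 0, res.output
        tally = json.loads((tmp_path / "typed" / "tally.json").read_text())
        truth = json.loads((sim_dir / "truth.json").read_text())
        from collections import Counter

        assert tally["counts"] == {
            **{k: 0 for k in tally["counts"]},
            **Counter(truth["planted_type"].values()),
        }

    def test_bad_input_nonzero_exit(self, tmp_path):
        runner = CliRunner()
        msa = tmp_path / "bad.fasta"
        msa.write_text(">a\nMK\n>b\nMV\n")
        anchors = tmp_path / "anchors.tsv"
        anchors.write_text("name\tref_id\tref_pos\texpected\nloop_first\tmissing\t1\t\n")
        res = runner.invoke(
            cli_main,
            ["type", "--msa", str(msa), "--anchors", str(anchors), "--out", str(tmp_path / "o")],
        )
        assert res.exit_code != 0
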