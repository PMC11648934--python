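import numpy as np
import pytest
from scipy.stats import mannwhitneyu as scipy_mwu

from cspfam.genome_dist import (
    GenomeDataError,
    GenomeRecord,
    SampleSizeError,
    compare_groups,
    gc_content,
    mann_whitney_u,
    read_genomes_tsv,
    split_by_csp_count,
    write_genomes_tsv,
    _u_statistics,
)
from cspfam.synthetic_data import simulate_genomes


def _genome(i, count, size=4_000_000, gc=0.5):
    return GenomeRecord(
        genome_id=f"g{i}", size=size, gc=gc,
        csp_ids=tuple(f"g{i}c{j}" for j in range(count)),
    )


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 1.0), ("ATGC", 0.5), ("ACNT", 1 / 3)])
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_counting_oracle(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGTN"), size=int(rng.integers(1, 200))))
            counted = [b for b in seq if b != "N"]
            if not counted:
                continue
            expected = sum(b in "GC" for b in counted) / len(counted)
            assert gc_content(seq) == pytest.approx(expected)

    def test_degenerate(self):
        with pytest.raises(GenomeDataError):
            gc_content("NNN")


class TestSplitByCspCount:
    def test_example(self):
        genomes = [_genome(i, c) for i, c in enumerate([1, 2, 3, 10])]
        low, high = split_by_csp_count(genomes)
        assert [g.csp_count for g in low] == [1, 2]
        assert [g.csp_count for g in high] == [3, 10]

    def test_all_low(self):
        low, high = split_by_csp_count([_genome(i, 1) for i in range(4)])
        assert len(low) == 4 and high == []

    def test_zero_csp_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            low, high = split_by_csp_count([_genome(0, 0), _genome(1, 2)])
        assert len(low) + len(high) == 1

    def test_partition_exhaustive(self, rng):
        genomes = [_genome(i, int(rng.integers(1, 11))) for i in range(200)]
        low, high = split_by_csp_count(genomes)
        assert len(low) + len(high) == len(genomes)
        assert all(g.csp_count < 3 for g in low)
        assert all(g.csp_count >= 3 for g in high)


class TestMannWhitneyU:
    def test_exact_enumeration_reference(self):
        """Fully separated samples of 3 vs 3 give U = 0 and exact p = 2/20."""
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_all_tied_symmetry(self):
        u, p = mann_whitney_u([5.0] * 4, [5.0] * 4, mode="approx")
        assert u == pytest.approx(8.0)  # nm/2
        assert p == 1.0

    def test_u_complement_identity(self, rng):
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(2, 20)))
            y = rng.normal(size=int(rng.integers(2, 20)))
            ux, uy = _u_statistics(x, y)
            assert ux + uy == pytest.approx(len(x) * len(y))

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=9) + 0.5
        u1, p1 = mann_whitney_u(x, y)
        u2, p2 = mann_whitney_u(np.exp(x), np.exp(y))
        assert u1 == pytest.approx(u2)
        assert p1 == pytest.approx(p2)

    def test_exact_close_to_approx_at_moderate_n(self, rng):
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            _, p_exact = mann_whitney_u(x, y, mode="exact")
            _, p_approx = mann_whitney_u(x, y, mode="approx")
            assert abs(p_exact - p_approx) < 0.02

    def test_exact_matches_scipy(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(3, 8)))
            y = rng.normal(size=int(rng.integers(3, 8)))
            _, p = mann_whitney_u(x, y, mode="exact")
            ref = scipy_mwu(x, y, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_approx_matches_scipy(self, rng):
        for _ in range(20):
            x = rng.normal(size=25)
            y = np.round(rng.normal(size=30), 1)  # induce occasional ties
            _, p = mann_whitney_u(x, y, mode="approx")
            ref = scipy_mwu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert p == pytest.approx(ref, rel=1e-8)

    def test_empty_sample(self):
        with pytest.raises(SampleSizeError):
            mann_whitney_u([], [1.0])

    def test_exact_mode_rejects_ties(self):
        with pytest.raises(ValueError):
            mann_whitney_u([1, 1, 2], [3, 4, 5], mode="exact")


class TestCompareGroups:
    def test_planted_effect_detected(self):
        hits = 0
        for seed in range(20):
            genomes = simulate_genomes(n_genomes=100, size_shift=0.3, seed=seed)
            report = compare_groups(genomes, "size")
            assert report["direction"] == "high_group_larger"
            hits += report["p_two_sided"] < 0.05
        assert hits >= 18

    def test_identical_groups_p_near_one(self):
        genomes = [_genome(i, 1, size=5_000_000) for i in range(10)]
        genomes += [_genome(i + 10, 4, size=5_000_000) for i in range(10)]
        report = compare_groups(genomes, "size")
        assert report["p_two_sided"] == pytest.approx(1.0)

    def test_empty_group_not_testable(self):
        report = compare_groups([_genome(i, 1) for i in range(5)], "gc")
        assert report["testable"] is False
        assert "p_two_sided" not in report


def test_genome_tsv_round_trip(tmp_path):
    genomes = simulate_genomes(n_genomes=20, seed=3)
    p = tmp_path / "genomes.tsv"
    write_genomes_tsv(genomes, p)
    back = read_genomes_tsv(p)
    assert [g.genome_id for g in back] == [g.genome_id for g in genomes]
    assert [g.csp_ids for g in back] == [g.csp_ids for g in genomes]
    assert all(abs(a.gc - b.gc) < 1e-6 for a, b in zip(back, genomes))
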