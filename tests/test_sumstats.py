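"""Summary statistics against hand computations and brute-force oracles."""

import numpy as np
import pytest

import coalabc as ca
from coalabc.sumstats import _phi_st_from_distances

from conftest import random_alignment


def aln_from(seq_pop_pairs):
    seqs = [s for s, _ in seq_pop_pairs]
    pops = [p for _, p in seq_pop_pairs]
    return ca.HaplotypeAlignment.from_sequences(seqs, pops)


# ---------------------------------------------------------------------------
# Brute-force oracles (pure-python, pairwise enumeration)
# ---------------------------------------------------------------------------


def oracle_nhap(seqs):
    return len(set(seqs))


def oracle_segsites(seqs):
    return sum(1 for col in zip(*seqs) if len(set(col)) > 1)


def oracle_mpd(seqs):
    pairs = [(i, j) for i in range(len(seqs)) for j in range(i + 1, len(seqs))]
    return sum(
        sum(a != b for a, b in zip(seqs[i], seqs[j])) for i, j in pairs
    ) / len(pairs)


def oracle_between_mpd(seqs_a, seqs_b):
    total = sum(
        sum(x != y for x, y in zip(a, b)) for a in seqs_a for b in seqs_b
    )
    return total / (len(seqs_a) * len(seqs_b))


def oracle_fst(seqs_a, seqs_b):
    hw = 0.5 * (oracle_mpd(seqs_a) + oracle_mpd(seqs_b))
    hb = oracle_between_mpd(seqs_a, seqs_b)
    return 0.0 if hb == 0 else 1 - hw / hb


def oracle_hapdiv(seqs):
    n = len(seqs)
    from collections import Counter

    p2 = sum((c / n) ** 2 for c in Counter(seqs).values())
    return n * (1 - p2) / (n - 1)


# ---------------------------------------------------------------------------
# Hand-computed examples
# ---------------------------------------------------------------------------


class TestHandExamples:
    def test_haplotype_count(self):
        aln = aln_from([("AAT", "P"), ("AAT", "P"), ("ACT", "P"), ("ACC", "P"),
                        ("AAA", "Q"), ("AAA", "Q")])
        assert ca.n_haplotypes(aln, "P") == 3
        assert ca.n_haplotypes(aln, "Q") == 1

    def test_identical_and_distinct(self):
        aln = aln_from([("AAAA", "P")] * 3 + [("ACGT", "Q"), ("TGCA", "Q"),
                                              ("AAAA", "Q"), ("CCCC", "Q")])
        assert ca.n_haplotypes(aln, "P") == 1
        assert ca.n_haplotypes(aln, "Q") == 4

    def test_segregating_sites(self):
        aln = aln_from([("AAT", "P"), ("ACT", "P"), ("GCT", "P")])
        assert ca.segregating_sites(aln, "P") == 2
        aln2 = aln_from([("AAA", "P"), ("AAT", "P")])
        assert ca.segregating_sites(aln2, "P") == 1
        aln3 = aln_from([("AAA", "P"), ("AAA", "P")])
        assert ca.segregating_sites(aln3, "P") == 0

    def test_mean_pairwise_diff(self):
        aln = aln_from([("AAT", "P"), ("ACT", "P"), ("GCT", "P")])
        assert ca.mean_pairwise_diff(aln, "P") == pytest.approx(4 / 3)
        aln2 = aln_from([("AAATTT", "P"), ("TATTTA", "P")])
        assert ca.mean_pairwise_diff(aln2, "P") == 3.0

    def test_hudson_fst_hand_case(self):
        # A = {AA, AT}, B = {TT, TT}: H_w = 0.5, H_b = 1.5 -> 1 - 1/3 = 2/3
        aln = aln_from([("AA", "A"), ("AT", "A"), ("TT", "B"), ("TT", "B")])
        assert ca.pairwise_fst(aln, "A", "B") == pytest.approx(2 / 3)

    def test_fst_fixed_difference_is_one(self):
        aln = aln_from([("AAA", "A")] * 3 + [("TTT", "B")] * 3)
        assert ca.pairwise_fst(aln, "A", "B") == pytest.approx(1.0)

    def test_fst_identical_populations_near_zero(self):
        # duplicated polymorphic sets: estimate is -1/(n-1), -> 0 for large n
        half = [("AAT", "A"), ("ACT", "A")] * 15
        other = [(s, "B") for s, _ in half]
        aln = aln_from(half + other)
        assert ca.pairwise_fst(aln, "A", "B") == pytest.approx(0.0, abs=0.05)
        mono = aln_from([("AAA", "A")] * 2 + [("AAA", "B")] * 2)
        assert ca.pairwise_fst(mono, "A", "B") == 0.0

    def test_haplotype_diversity(self):
        distinct = aln_from([("AA", "P"), ("AT", "P"), ("TA", "P"), ("TT", "P")])
        assert ca.haplotype_diversity(distinct, "P") == pytest.approx(1.0)
        counts211 = aln_from([("AA", "P"), ("AA", "P"), ("AT", "P"), ("TT", "P")])
        assert ca.haplotype_diversity(counts211, "P") == pytest.approx(0.8333, abs=1e-4)
        mono = aln_from([("AA", "P")] * 5)
        assert ca.haplotype_diversity(mono, "P") == 0.0

    def test_nucleotide_diversity(self):
        aln = aln_from([("AAT", "P"), ("ACT", "P"), ("GCT", "P")])
        assert ca.nucleotide_diversity(aln, "P") == pytest.approx(4 / 9)
        ten = aln_from([("A" * 10, "P"), ("A" * 9 + "T", "P")])
        assert ca.nucleotide_diversity(ten, "P") == pytest.approx(0.1)

    def test_summary_vector_monomorphic(self):
        aln = aln_from(
            [("AAA", "SAG")] * 3 + [("AAA", "NAG")] * 2 + [("AAA", "NC")] * 2
        )
        assert np.array_equal(
            ca.summary_vector(aln), np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        )

    def test_empty_population_errors(self):
        aln = aln_from([("AAA", "P"), ("AAT", "P")])
        with pytest.raises(ValueError):
            ca.n_haplotypes(aln, "Q")
        single = aln_from([("AAA", "P"), ("AAT", "Q"), ("AAT", "Q")])
        with pytest.raises(ValueError):
            ca.mean_pairwise_diff(single, "P")


class TestInvariances:
    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        aln = random_alignment(rng)
        vec = ca.summary_vector(aln)
        perm = rng.permutation(aln.n_individuals)
        shuffled = ca.HaplotypeAlignment(
            [aln.ids[i] for i in perm],
            [aln.populations[i] for i in perm],
            aln.matrix[perm],
        )
        assert np.allclose(ca.summary_vector(shuffled), vec)

    def test_fst_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            aln = random_alignment(rng)
            assert ca.pairwise_fst(aln, "SAG", "NAG") == pytest.approx(
                ca.pairwise_fst(aln, "NAG", "SAG")
            )

    def test_oracle_equivalence_sample(self):
        """Spot oracle check (the full 1000-case sweep runs in acceptance)."""
        rng = np.random.default_rng(2)
        for _ in range(50)[:50]:
            aln = random_alignment(rng)
            for pop in ("SAG", "NAG", "NC"):
                seqs = [aln.sequence(i) for i in aln.rows_for(pop)]
                assert ca.n_haplotypes(aln, pop) == oracle_nhap(seqs)
                assert ca.segregating_sites(aln, pop) == oracle_segsites(seqs)
                assert ca.mean_pairwise_diff(aln, pop) == pytest.approx(oracle_mpd(seqs))
            sa = [aln.sequence(i) for i in aln.rows_for("SAG")]
            na = [aln.sequence(i) for i in aln.rows_for("NAG")]
            assert ca.pairwise_fst(aln, "SAG", "NAG") == pytest.approx(oracle_fst(sa, na))
            assert ca.haplotype_diversity(aln, "SAG") == pytest.approx(oracle_hapdiv(sa))


class TestPhiST:
    def test_identical_populations_phi_near_zero(self):
        aln = aln_from([("AAT", "A"), ("ACT", "A"), ("AAT", "B"), ("ACT", "B")])
        phi, p = ca.phi_st_permutation(aln, "A", "B", n_perm=200, rng=np.random.default_rng(3))
        assert phi < 0.3
        assert p > 0.2

    def test_fixed_difference_phi_near_one(self):
        # large groups: re-hitting the observed partition by chance is rare,
        # so the permutation p-value reaches its floor 1/(n_perm+1)
        aln = aln_from([("AAAA", "A")] * 9 + [("TTTT", "B")] * 9)
        phi, p = ca.phi_st_permutation(aln, "A", "B", n_perm=199, rng=np.random.default_rng(4))
        assert phi > 0.95
        assert p == pytest.approx(1 / 200)

    def test_exhaustive_matches_bruteforce_oracle(self):
        """Exact p-value equals enumeration over all label assignments."""
        from itertools import combinations

        rng = np.random.default_rng(5)
        for _ in range(5):
            n_a, n_b = 4, 3
            mat = rng.integers(0, 4, size=(n_a + n_b, 12)).astype(np.uint8)
            aln = ca.HaplotypeAlignment(
                [f"i{i}" for i in range(n_a + n_b)],
                ["A"] * n_a + ["B"] * n_b,
                mat,
            )
            phi, p = ca.phi_st_permutation(aln, "A", "B", n_perm=None)

            # oracle: recompute phi for every assignment from scratch
            d = (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(float)
            stats = []
            for members in combinations(range(n_a + n_b), n_a):
                lab = np.ones(n_a + n_b, dtype=int)
                lab[list(members)] = 0
                stats.append(_phi_st_from_distances(d, lab))
            stats = np.array(stats)
            obs = _phi_st_from_distances(d, np.array([0] * n_a + [1] * n_b))
            assert phi == pytest.approx(obs)
            assert p == pytest.approx((stats >= obs - 1e-12).mean())

    def test_monte_carlo_approximates_exact(self):
        rng = np.random.default_rng(6)
        mat = rng.integers(0, 3, size=(8, 10)).astype(np.uint8)
        aln = ca.HaplotypeAlignment(
            [f"i{i}" for i in range(8)], ["A"] * 4 + ["B"] * 4, mat
        )
        _, p_exact = ca.phi_st_permutation(aln, "A", "B", n_perm=None)
        _, p_mc = ca.phi_st_permutation(aln, "A", "B", n_perm=2000, rng=rng)
        assert abs(p_mc - p_exact) < 0.06


class TestDiversityReport:
    def test_report_structure_and_ranges(self, sc1_truth_alignment):
        aln, _ = sc1_truth_alignment
        div, phi = ca.diversity_report(aln, n_perm=49, rng=np.random.default_rng(7))
        assert set(div.index) == {"SAG", "NAG", "NC"}
        assert ((div["haplotype_diversity"] >= 0) & (div["haplotype_diversity"] <= 1)).all()
        assert (div["nucleotide_diversity"] >= 0).all()
        assert len(phi) == 3
        assert ((phi["p_value"] > 0) & (phi["p_value"] <= 1)).all()

    def test_study_scale_magnitudes(self, sc1_truth_alignment):
        """Soft calibration: synthetic data at the study's parameter preset
        shows the study's qualitative pattern (high haplotype diversity, low
        per-site nucleotide diversity, strongest divergence involving NC)."""
        aln, _ = sc1_truth_alignment
        assert ca.haplotype_diversity(aln, "SAG") > 0.85
        assert ca.nucleotide_diversity(aln, "SAG") < 0.02
        assert ca.pairwise_fst(aln, "SAG", "NC") > ca.pairwise_fst(aln, "SAG", "NAG")
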