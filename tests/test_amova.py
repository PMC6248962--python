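import itertools

import numpy as np
import pandas as pd
import pytest

from dompop import amova, amova_matrix, amova_table, pairwise_fst, simulate, squared_distances
from dompop.simulate import SimulationConfig

from conftest import make_matrix


class TestSquaredDistances:
    def test_single_mismatch(self):
        m = make_matrix([[1, 0], [1, 1]])
        d = squared_distances(m)
        assert d.iloc[0, 1] == 1.0

    def test_identical_profiles(self):
        m = make_matrix([[1, 0, 1], [1, 0, 1]])
        assert squared_distances(m).iloc[0, 1] == 0.0

    def test_missing_rescaling(self):
        # 1 mismatch over 2 shared loci, rescaled by 3/2
        m = make_matrix([[1, 0, np.nan], [0, 0, 1]])
        assert squared_distances(m).iloc[0, 1] == pytest.approx(1.5)

    def test_no_shared_loci_errors(self):
        m = make_matrix([[1, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="share no scored locus"):
            squared_distances(m)

    def test_symmetric_zero_diagonal_bounded(self, preset_dataset):
        m, _, _ = preset_dataset
        d = squared_distances(m).to_numpy()
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        assert d.max() <= m.n_loci


class TestAmovaDecomposition:
    def test_hand_worked_four_sample_example(self, tiny_two_pop):
        res = amova_matrix(tiny_two_pop, n_perm=0)
        assert res.ss_total == pytest.approx(2.0)
        assert res.ss_within == pytest.approx(1.0)
        assert res.ss_among == pytest.approx(1.0)
        assert (res.df_among, res.df_within) == (1, 2)
        assert res.sigma2_within == pytest.approx(0.5)
        assert res.sigma2_among == pytest.approx(0.25)
        assert res.phi_st == pytest.approx(1 / 3)

    def test_maximal_differentiation(self):
        m = make_matrix([[1, 1], [1, 1], [0, 0], [0, 0]],
                        pops=["A", "A", "B", "B"])
        res = amova_matrix(m, n_perm=1000, seed=0)
        assert res.phi_st == pytest.approx(1.0)
        # only 1/3 of balanced relabelings reach phi = 1
        assert res.p_value <= 0.40

    def test_table_layout(self, tiny_two_pop):
        t = amova_table(amova_matrix(tiny_two_pop, n_perm=0))
        assert t.loc["Total", "SS"] == pytest.approx(2.0)
        assert t.loc["Among Pops", "%"] + t.loc["Within Pops", "%"] == pytest.approx(100)

    def test_negative_variance_reported_and_clampable(self):
        rng = np.random.default_rng(11)
        # no real structure -> sigma2_among often negative
        for seed in range(20):
            bands = np.random.default_rng(seed).integers(0, 2, (8, 30))
            m = make_matrix(bands, pops=["A"] * 4 + ["B"] * 4)
            res = amova_matrix(m, n_perm=0)
            if res.negative_variance:
                assert res.phi_st < 0
                clamped = amova_matrix(m, n_perm=0, clamp_negative=True)
                assert clamped.phi_st == 0.0
                return
        pytest.fail("no negative variance case found in 20 unstructured draws")

    def test_two_pop_amova_equals_pairwise_entry(self, preset_dataset):
        m, _, _ = preset_dataset
        fst, _ = pairwise_fst(m, n_perm=0)
        two = m.subset_samples(np.concatenate([m.pop_indices("Al-Subiya"),
                                               m.pop_indices("Al-Abraq")]))
        res = amova_matrix(two, n_perm=0)
        assert res.phi_st == pytest.approx(fst.loc["Al-Subiya", "Al-Abraq"])


class TestPermutationTest:
    def test_seeded_reproducibility(self, tiny_two_pop):
        d = squared_distances(tiny_two_pop)
        p1 = amova(d, tiny_two_pop.pop_labels, n_perm=500, seed=42).p_value
        p2 = amova(d, tiny_two_pop.pop_labels, n_perm=500, seed=42).p_value
        assert p1 == p2

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        # 6 samples: enumerate all 720 label permutations exactly
        rng = np.random.default_rng(3)
        m = make_matrix(rng.integers(0, 2, (6, 12)),
                        pops=["A", "A", "A", "B", "B", "B"])
        d = squared_distances(m)
        obs = amova(d, m.pop_labels, n_perm=0).phi_st
        dm = d.to_numpy()
        labels = np.array(m.pop_labels)
        hits = total = 0
        for perm in itertools.permutations(range(6)):
            groups = [np.array(perm)[labels == p] for p in ("A", "B")]
            n0 = (6 - (9 + 9) / 6) / 1
            sub_w = sum(dm[np.ix_(g, g)].sum() / (2 * g.size) for g in groups)
            ss_t = dm.sum() / (2 * 6)
            s2w = sub_w / 4
            s2a = ((ss_t - sub_w) / 1 - s2w) / n0
            phi = s2a / (s2a + s2w)
            total += 1
            if phi >= obs - 1e-12:
                hits += 1
        exact_p = hits / total
        mc = amova(d, m.pop_labels, n_perm=4000, seed=7).p_value
        se = np.sqrt(exact_p * (1 - exact_p) / 4000)
        assert abs(mc - exact_p) <= 3 * se + 1e-3

    def test_null_p_values_roughly_uniform(self):
        # no structure: p should not concentrate near 0
        pvals = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            m = make_matrix(rng.integers(0, 2, (10, 20)),
                            pops=["A"] * 5 + ["B"] * 5)
            pvals.append(amova_matrix(m, n_perm=99, seed=seed).p_value)
        pvals = np.array(pvals)
        assert 0.35 <= pvals.mean() <= 0.65
        assert (pvals <= 0.05).mean() <= 0.15


class TestPairwiseFst:
    def test_duplicated_population_near_zero(self):
        rng = np.random.default_rng(8)
        block = rng.integers(0, 2, (10, 40))
        m = make_matrix(np.vstack([block, block]),
                        pops=["A"] * 10 + ["B"] * 10)
        fst, _ = pairwise_fst(m, n_perm=0)
        # same profiles duplicated: phi is slightly negative, never positive
        assert fst.loc["A", "B"] <= 0.0

    def test_ordering_reflects_divergence(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 2, (8, 50))
        c = 1 - a[:8]
        m = make_matrix(np.vstack([a, a, c]),
                        pops=["A"] * 8 + ["B"] * 8 + ["C"] * 8)
        fst, _ = pairwise_fst(m, n_perm=0)
        assert fst.loc["A", "B"] < fst.loc["A", "C"]

    def test_recovery_of_nominal_differentiation(self):
        # light version of the simulation recovery check (3 seeds)
        errs = []
        for seed in range(3):
            cfg = SimulationConfig(
                pop_names=list("ABCDEF"), pop_sizes=[20] * 6, n_loci=200,
                loci_per_primer=[200], F=0.2, seed=seed)
            m, _, truth = simulate(cfg)
            from dompop import realized_differentiation
            res = amova_matrix(m, n_perm=0)
            errs.append(res.phi_st - realized_differentiation(truth))
        assert abs(np.mean(errs)) <= 0.05
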