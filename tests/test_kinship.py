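import numpy as np
import pytest
import scipy.linalg

from snpher.io_formats import GenotypeMatrix, KinshipMatrix, MISSING, SampleInfo, VariantInfo
from snpher.kinship import (
    LDWeights,
    compute_grm_gcta,
    compute_grm_ldak,
    compute_ld_weights,
    compute_pcs,
    prune_related,
)
from snpher.synthetic_data import CohortConfig, simulate_ancestral_freqs, simulate_genotypes

from .oracles import grm_naive, max_independent_set_size


def _gm(dosages):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    return GenotypeMatrix(
        dosages=dosages,
        samples=[SampleInfo(fid=f"F{i}", iid=f"I{i}") for i in range(n)],
        variants=[VariantInfo(chrom="1", pos=j + 1, id=f"v{j}", allele_a1="A",
                              allele_a2="G") for j in range(m)],
    )


def _kin(values):
    n = values.shape[0]
    return KinshipMatrix(values=values,
                         sample_ids=[(f"F{i}", f"I{i}") for i in range(n)],
                         n_variants_used=np.full((n, n), 10.0))


def _hadamard_gm(reps=1):
    """Genotypes whose standardized columns are exactly orthogonal."""
    h = scipy.linalg.hadamard(8)[:, 1:]  # drop the constant column
    d = np.tile((h + 1), (reps, 1)).astype(np.int8)  # -1/+1 -> 0/2, p = 0.5
    return _gm(d)


class TestGrmGcta:
    def test_matches_naive_oracle(self, rng):
        d = rng.integers(0, 3, size=(10, 20)).astype(np.int8)
        for j in range(20):  # guard against monomorphic columns
            if len(np.unique(d[:, j])) == 1:
                d[0, j] = (d[0, j] + 1) % 3
        g = _gm(d)
        grm = compute_grm_gcta(g)
        expected = grm_naive(d.astype(float), g.allele_frequencies())
        np.testing.assert_allclose(grm.values, expected, atol=1e-12)

    def test_hand_example_two_samples(self):
        """At sample frequencies p = (0.5, 0.5) for x1=(2,0), x2=(1,1):
        A12 = ½[(1·−1)/0.5 + 0] = −1, A11 = ½[1²/0.5 + 0] = 1."""
        g = _gm(np.array([[2, 1], [0, 1]]))
        grm = compute_grm_gcta(g)
        assert grm.values[0, 1] == pytest.approx(-1.0, abs=1e-12)
        assert grm.values[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_eq1_arithmetic_with_given_frequencies(self):
        """Hand evaluation of the allele-sharing sum at externally supplied
        frequencies p = (0.5, 0.25): A12 = ½[(1·−1)/0.5 + (0.5·0.5)/0.375]
        = −0.6667, A11 = ½[2 + 0.6667] = 1.3333."""
        from .oracles import grm_entry
        x = np.array([[2.0, 1.0], [0.0, 1.0]])
        p = np.array([0.5, 0.25])
        assert grm_entry(x, p, 0, 1) == pytest.approx(-2.0 / 3.0, abs=1e-9)
        assert grm_entry(x, p, 0, 0) == pytest.approx(4.0 / 3.0, abs=1e-9)

    def test_duplicate_individuals(self, rng):
        d = rng.integers(0, 3, size=(5, 40)).astype(np.int8)
        d[1] = d[0]
        grm = compute_grm_gcta(_gm(d))
        assert grm.values[0, 1] == pytest.approx(grm.values[0, 0], abs=1e-12)
        assert grm.values[0, 1] == pytest.approx(grm.values[1, 1], abs=1e-12)

    def test_diagonal_mean_near_one_unstructured(self):
        cfg = CohortConfig(n_samples=1000, m_variants=2000, fst=0.0, ld_rho=0.0,
                           seed=21)
        g, _ = simulate_genotypes(cfg, simulate_ancestral_freqs(cfg))
        grm = compute_grm_gcta(g)
        assert np.diag(grm.values).mean() == pytest.approx(1.0, abs=0.02)
        np.testing.assert_allclose(grm.values, grm.values.T, atol=1e-12)

    def test_pairwise_missing_mode(self, rng):
        d = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        d[rng.random(d.shape) < 0.1] = MISSING
        d[:4, 0] = [0, 1, 2, 1]  # keep variants polymorphic
        g = _gm(d)
        grm = compute_grm_gcta(g, pairwise_missing=True)
        obs = (d != MISSING)
        np.testing.assert_array_equal(grm.n_variants_used,
                                      obs.astype(float) @ obs.T.astype(float))

    def test_monomorphic_rejected(self):
        d = np.ones((4, 2), dtype=np.int8)
        d[:, 0] = [0, 1, 2, 1]
        d[:, 1] = 2
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm_gcta(_gm(d))


class TestLdWeights:
    def test_uncorrelated_variants_unit_weights(self):
        g = _hadamard_gm(reps=2)
        w = compute_ld_weights(g, window_size=4)
        np.testing.assert_allclose(w.weights, 1.0, atol=1e-4)

    def test_perfect_ld_pair_shares_weight(self):
        g = _hadamard_gm(reps=2)
        d = np.hstack([g.dosages, g.dosages[:, :1]])  # v7 duplicates v0
        w = compute_ld_weights(_gm(d), window_size=8)
        assert w.weights[0] == pytest.approx(0.5, abs=1e-3)
        assert w.weights[7] == pytest.approx(0.5, abs=1e-3)
        np.testing.assert_allclose(w.weights[1:7], 1.0, atol=1e-3)

    def test_high_ld_block_downweighted(self):
        cfg = CohortConfig(n_samples=1200, m_variants=60, ld_block_size=20,
                           ld_rho=0.95, fst=0.0, seed=22)
        g, _ = simulate_genotypes(cfg, simulate_ancestral_freqs(cfg))
        # make the last two blocks LD-free by shuffling each column independently
        rng = np.random.default_rng(0)
        d = g.dosages.copy()
        for j in range(20, 60):
            rng.shuffle(d[:, j])
        w = compute_ld_weights(_gm(d), window_size=20)
        assert w.weights[:20].mean() < w.weights[20:].mean()

    def test_window_size_validation(self):
        with pytest.raises(ValueError, match="window_size"):
            compute_ld_weights(_hadamard_gm(), window_size=1)


class TestGrmLdak:
    def test_unit_weights_alpha_minus_one_equals_gcta(self, small_cohort):
        _, g, _, _, _ = small_cohort
        from snpher.qc import QCConfig, filter_variants
        g, _ = filter_variants(g, QCConfig())
        gcta = compute_grm_gcta(g)
        ldak = compute_grm_ldak(g, LDWeights.unit(g.m_variants, alpha=-1.0))
        np.testing.assert_allclose(ldak.values, gcta.values, atol=1e-10)

    def test_weight_scale_invariance(self, rng):
        d = rng.integers(0, 3, size=(30, 50)).astype(np.int8)
        d[0] = 1  # keep polymorphic
        g = _gm(d)
        w1 = LDWeights(weights=rng.uniform(0.2, 1.0, 50), alpha=-0.25,
                       info_scores=np.ones(50), window_size=10)
        w2 = LDWeights(weights=2.0 * w1.weights, alpha=-0.25,
                       info_scores=np.ones(50), window_size=10)
        np.testing.assert_allclose(compute_grm_ldak(g, w1).values,
                                   compute_grm_ldak(g, w2).values, atol=1e-12)

    def test_zero_info_equals_variant_removal(self, rng):
        d = rng.integers(0, 3, size=(25, 12)).astype(np.int8)
        d[0] = 1
        g = _gm(d)
        info = np.ones(12)
        info[5] = 0.0
        w = LDWeights(weights=np.ones(12), alpha=-1.0, info_scores=info,
                      window_size=4)
        full = compute_grm_ldak(g, w)
        g_wo = g.subset(variant_idx=[j for j in range(12) if j != 5])
        # recompute without the variant, using the same per-variant frequencies
        wo = compute_grm_ldak(g_wo, LDWeights.unit(11, alpha=-1.0))
        np.testing.assert_allclose(full.values, wo.values, atol=1e-12)

    def test_all_zero_weights_rejected(self, rng):
        d = rng.integers(0, 3, size=(10, 5)).astype(np.int8)
        d[0] = 1
        w = LDWeights(weights=np.ones(5), alpha=-1.0,
                      info_scores=np.zeros(5), window_size=2)
        w.info_scores[:] = 0.0
        with pytest.raises(ValueError, match="zero"):
            compute_grm_ldak(_gm(d), w)


class TestPruneRelated:
    def test_no_violations_all_retained(self):
        k = _kin(np.eye(6) + 0.01)
        assert len(prune_related(k, cutoff=0.025)) == 6

    def test_duplicate_pair_loses_one(self):
        v = np.eye(5) * 1.0
        v[1, 3] = v[3, 1] = 0.98
        keep = prune_related(_kin(v))
        assert len(keep) == 4
        assert len({1, 3} & set(keep)) == 1

    def test_star_pattern_removes_hub_only(self):
        v = np.eye(5)
        for j in (1, 2, 3):
            v[0, j] = v[j, 0] = 0.3
        keep = prune_related(_kin(v))
        assert list(keep) == [1, 2, 3, 4]

    def test_exhaustive_feasibility_small_instances(self, rng):
        """On random kinship instances n ≤ 12 the greedy result has no pair
        above the cutoff, and its size is within 2 of the true maximum
        independent set of the violation graph."""
        for trial in range(60):
            n = int(rng.integers(2, 13))
            b = rng.normal(size=(n, n)) * 0.05
            v = (b + b.T) / 2 + np.eye(n)
            k = _kin(v)
            keep = prune_related(k, cutoff=0.025)
            sub = v[np.ix_(keep, keep)]
            off = sub[~np.eye(len(keep), dtype=bool)]
            assert np.all(off <= 0.025)
            adj = (v > 0.025) & ~np.eye(n, dtype=bool)
            assert len(keep) >= max_independent_set_size(adj) - 2

    def test_cutoff_validation(self):
        with pytest.raises(ValueError, match="cutoff"):
            prune_related(_kin(np.eye(3)), cutoff=0.0)


class TestComputePcs:
    def test_two_subpopulations_separate_on_pc1(self, rng):
        cfg = CohortConfig(m_variants=1000, fst=0.1, seed=23)
        p1, p2 = simulate_ancestral_freqs(cfg)
        n_half = 100
        d = np.vstack([
            rng.binomial(2, p1, size=(n_half, 1000)),
            rng.binomial(2, p2, size=(n_half, 1000)),
        ]).astype(np.int8)
        grm = compute_grm_gcta(_gm(d))
        pcs = compute_pcs(grm, n_components=4)
        label = np.r_[np.zeros(n_half), np.ones(n_half)]
        assert abs(np.corrcoef(pcs.components[:, 0], label)[0, 1]) > 0.9

    def test_identity_kinship_degenerate_but_orthogonal(self):
        pcs = compute_pcs(_kin(np.eye(8)), n_components=3)
        c = pcs.components
        gram = c.T @ c
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)
        assert np.all(np.diff(pcs.eigenvalues) <= 1e-12)

    def test_sign_convention_deterministic(self, rng):
        b = rng.normal(size=(12, 12))
        k = _kin(b @ b.T / 12 + np.eye(12))
        a = compute_pcs(k, n_components=4)
        b2 = compute_pcs(k, n_components=4)
        np.testing.assert_array_equal(a.components, b2.components)
        for c in range(4):
            col = a.components[:, c]
            assert col[np.argmax(np.abs(col))] >= 0

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            compute_pcs(_kin(np.eye(3)), n_components=5)
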