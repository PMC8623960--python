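"""LDAK weights, thinning, expected shares and LD tagging."""

import numpy as np
import pytest

from oracles import grid_nnls

from excessh2.heritability import (
    Model,
    ModelSpec,
    build_tagging_table,
    compute_tagging,
    expected_h2,
    ldak_weights,
    thin_weights,
)
from excessh2.panel import LDTable, VariantRecord


def _variants(n, chrom=1, maf=0.3, spacing=1000):
    return [
        VariantRecord(
            id=f"v{j}", chrom=chrom, pos=1 + j * spacing, a1="A", a2="G", maf=maf
        )
        for j in range(n)
    ]


def _ld(n, pairs):
    t = LDTable(n_variants=n, window_kb=1000.0)
    for j, k, r2 in pairs:
        t.set(j, k, r2)
    return t


class TestLdakWeights:
    def test_isolated_variant_gets_unit_weight(self):
        w = ldak_weights(_ld(1, []), _variants(1))
        assert w[0] == pytest.approx(1.0)

    def test_duplicate_pair_splits_evenly(self):
        # minimal-norm point on the solution line w1 + w2 = 1
        w = ldak_weights(_ld(2, [(0, 1, 1.0)]), _variants(2))
        oracle = grid_nnls(np.array([[1.0, 1.0], [1.0, 1.0]]))
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-4)
        np.testing.assert_allclose(w, oracle, atol=1e-3)

    def test_three_variant_chain_matches_grid_oracle(self):
        a = np.array([[1.0, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 1.0]])
        ld = _ld(3, [(0, 1, 0.5), (1, 2, 0.5), (0, 2, 0.25)])
        w = ldak_weights(ld, _variants(3))
        oracle = grid_nnls(a)
        np.testing.assert_allclose(w, oracle, atol=1e-4)
        np.testing.assert_allclose(a @ w, np.ones(3), atol=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_systems_match_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 3
        a = np.eye(n)
        pairs = []
        for j in range(n):
            for k in range(j + 1, n):
                r2 = float(rng.uniform(0, 0.9))
                a[j, k] = a[k, j] = r2
                pairs.append((j, k, r2))
        w = ldak_weights(_ld(n, pairs), _variants(n))
        oracle = grid_nnls(a)
        np.testing.assert_allclose(w, oracle, atol=1e-4)

    def test_residual_near_one_on_synthetic_panel(self, default_ld, ldak_tagging):
        w = ldak_tagging.weights
        adj = default_ld.neighbor_index()
        resid = np.array(
            [w[j] + sum(w[k] * r2 for k, r2 in adj[j]) for j in range(len(w))]
        )
        assert np.mean((resid >= 0.8) & (resid <= 1.2)) >= 0.95

    def test_high_ld_blocks_downweighted(self):
        # a 4-clique of duplicates shares weight ~1/4 each; an isolated
        # variant keeps weight 1
        pairs = [(j, k, 1.0) for j in range(4) for k in range(j + 1, 4)]
        variants = _variants(5, spacing=1000)
        ld = _ld(5, pairs)
        w = ldak_weights(ld, variants)
        np.testing.assert_allclose(w[:4], 0.25, atol=1e-3)
        assert w[4] == pytest.approx(1.0)


class TestThinWeights:
    def test_duplicate_pair_keeps_lower_position(self):
        w = thin_weights(_ld(2, [(0, 1, 1.0)]), _variants(2))
        assert list(w) == [1.0, 0.0]

    def test_all_below_threshold_all_retained(self):
        w = thin_weights(_ld(3, [(0, 1, 0.5), (1, 2, 0.9)]), _variants(3))
        assert list(w) == [1.0, 1.0, 1.0]

    def test_clique_plus_independent_keeps_two(self):
        pairs = [(j, k, 0.99) for j in range(4) for k in range(j + 1, 4)]
        w = thin_weights(_ld(5, pairs), _variants(5))
        assert w.sum() == 2.0
        assert w[4] == 1.0 and w[0] == 1.0

    def test_binary_and_deterministic(self, default_ld, default_panel):
        w1 = thin_weights(default_ld, default_panel.variants)
        w2 = thin_weights(default_ld, default_panel.variants)
        assert set(np.unique(w1)) <= {0.0, 1.0}
        assert np.array_equal(w1, w2)


class TestExpectedH2:
    def test_alpha_minus_one_ignores_maf(self):
        variants = [
            VariantRecord(id="a", chrom=1, pos=1, a1="A", a2="G", maf=0.05),
            VariantRecord(id="b", chrom=1, pos=2, a1="A", a2="G", maf=0.45),
        ]
        spec = ModelSpec(alpha=-1.0)
        u = expected_h2(variants, np.ones(2), spec)
        np.testing.assert_allclose(u, [50.0, 50.0])

    def test_power_law_evaluation(self):
        # f = 0.5, alpha = -0.25: raw = 0.25 ** 0.75
        variants = [
            VariantRecord(id="a", chrom=1, pos=1, a1="A", a2="G", maf=0.5),
            VariantRecord(id="b", chrom=1, pos=2, a1="A", a2="G", maf=0.2),
        ]
        u = expected_h2(variants, np.ones(2), ModelSpec(alpha=-0.25))
        raw = np.array([0.25**0.75, (0.2 * 0.8) ** 0.75])
        np.testing.assert_allclose(u, 100 * raw / raw.sum())

    def test_zero_info_score_zeroes_share(self):
        variants = [
            VariantRecord(id="a", chrom=1, pos=1, a1="A", a2="G", maf=0.3, info=0.0),
            VariantRecord(id="b", chrom=1, pos=2, a1="A", a2="G", maf=0.3),
        ]
        u = expected_h2(variants, np.ones(2), ModelSpec())
        assert u[0] == 0.0 and u[1] == pytest.approx(100.0)

    def test_no_contributing_variants_raises(self):
        with pytest.raises(ValueError, match="no variant contributes"):
            expected_h2(_variants(2), np.zeros(2), ModelSpec())

    def test_shares_sum_to_100(self, thin_tagging, ldak_tagging):
        assert thin_tagging.u.sum() == pytest.approx(100.0, abs=1e-8)
        assert ldak_tagging.u.sum() == pytest.approx(100.0, abs=1e-8)


class TestComputeTagging:
    def test_identity_without_ld(self):
        u = np.array([60.0, 40.0])
        q = compute_tagging(u, _ld(2, []))
        np.testing.assert_allclose(q, u)

    def test_two_variant_hand_example(self):
        # q1 = 60 + 0.5*40 = 80, q2 = 40 + 0.5*60 = 70
        q = compute_tagging(np.array([60.0, 40.0]), _ld(2, [(0, 1, 0.5)]))
        np.testing.assert_allclose(q, [80.0, 70.0])

    def test_duplicate_pair_under_thin_has_equal_q(self):
        ld = _ld(2, [(0, 1, 1.0)])
        variants = _variants(2)
        w = thin_weights(ld, variants)
        u = expected_h2(variants, w, ModelSpec(model=Model.LDAK_THIN))
        q = compute_tagging(u, ld)
        assert u[1] == 0.0
        assert q[0] == pytest.approx(q[1])

    def test_q_dominates_u_and_brute_force_sum(self, thin_tagging, default_ld):
        q, u = thin_tagging.q, thin_tagging.u
        assert (q >= u - 1e-12).all()
        # independent loop oracle on a handful of variants
        for j in [0, 5, 100, 700]:
            expected = u[j] + sum(
                r2 * u[k] for k, r2 in default_ld.neighbors(j)
            )
            assert q[j] == pytest.approx(expected)


class TestModelContrasts:
    def test_normalization_invariance_of_ratios(self, thin_tagging, default_ld):
        # scaling every share by c > 0 leaves q-ratios unchanged
        c = 37.5
        q = thin_tagging.q
        q_scaled = compute_tagging(thin_tagging.u * c, default_ld)
        np.testing.assert_allclose(q_scaled / q, c)

    def test_ldak_downweights_high_ld_thin_inflates_tagging(self):
        # a near-duplicate block of equal-MAF variants: LDAK shares one
        # unit of weight across the block, so per-variant u drops below an
        # isolated variant's
        variants = _variants(8)
        dup_pairs = [(j, k, 0.99) for j in range(4) for k in range(j + 1, 4)]
        ld_dup = _ld(8, dup_pairs)
        w_ldak = ldak_weights(ld_dup, variants)
        u_ldak = expected_h2(variants, w_ldak, ModelSpec())
        assert u_ldak[:4].mean() < u_ldak[4:].mean()

        # moderate LD below the thin threshold: every block member stays
        # retained at full weight, so each member's q grows with block
        # size while LDAK's weight system keeps q roughly flat — the
        # mechanism by which Thin inflates tagging of LD-rich GWAS hits
        def thin_member_q(block_size):
            n = block_size + 1  # plus one isolated variant
            pairs = [
                (j, k, 0.6)
                for j in range(block_size)
                for k in range(j + 1, block_size)
            ]
            ld = _ld(n, pairs)
            vs = _variants(n)
            w = thin_weights(ld, vs)
            assert w.sum() == n  # nothing thinned at r²=0.6
            u = expected_h2(vs, w, ModelSpec(model=Model.LDAK_THIN))
            return compute_tagging(u, ld)

        q3, q6 = thin_member_q(3), thin_member_q(6)
        assert q3[0] > 1.5 * q3[-1]  # block member tags more than isolated
        assert q6[0] > q3[0]  # and grows with block size

        # under LDAK the solved weights flatten q across the same block
        pairs = [(j, k, 0.6) for j in range(6) for k in range(j + 1, 6)]
        ld = _ld(7, pairs)
        vs = _variants(7)
        u = expected_h2(vs, ldak_weights(ld, vs), ModelSpec())
        q = compute_tagging(u, ld)
        assert q[0] == pytest.approx(q[-1], rel=0.25)
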