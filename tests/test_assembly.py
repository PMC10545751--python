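import io as _io
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import braycurtis, pdist, squareform

from seamod import assembly as am
from seamod import synthdata as sd


def bmntd_oracle(pa, pb, d):
    """Independent brute-force loop implementation."""
    ia = [i for i, v in enumerate(pa) if v > 0]
    ib = [j for j, v in enumerate(pb) if v > 0]
    wa = np.array([pa[i] for i in ia]) / sum(pa[i] for i in ia)
    wb = np.array([pb[j] for j in ib]) / sum(pb[j] for j in ib)
    term_a = sum(w * min(d[i][j] for j in ib) for w, i in zip(wa, ia))
    term_b = sum(w * min(d[i][j] for i in ia) for w, j in zip(wb, ib))
    return 0.5 * (term_a + term_b)


@pytest.fixture
def four_leaf_dmat(four_leaf_tree):
    tree = skbio.TreeNode.read(_io.StringIO(four_leaf_tree))
    dm = tree.tip_tip_distances()
    order = ["A", "B", "C", "D"]
    idx = [list(dm.ids).index(o) for o in order]
    return dm.data[np.ix_(idx, idx)]


class TestBmntd:
    def test_identical_communities_zero(self, four_leaf_dmat):
        p = np.array([0.4, 0.3, 0.2, 0.1])
        assert am.bmntd(p, p, four_leaf_dmat) == pytest.approx(0.0)

    def test_disjoint_single_taxon_hand_value(self, four_leaf_dmat):
        pa = np.array([1.0, 0, 0, 0])  # A only
        pb = np.array([0, 0, 1.0, 0])  # C only
        # 0.5 * (d(A,C) + d(C,A)) with d(A,C) = 4 on the unit 4-leaf tree
        assert am.bmntd(pa, pb, four_leaf_dmat) == pytest.approx(4.0)

    def test_matches_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(4)
        d = squareform(pdist(rng.normal(size=(10, 3))))
        for _ in range(10):
            pa = np.where(rng.random(10) < 0.6, rng.random(10), 0.0)
            pb = np.where(rng.random(10) < 0.6, rng.random(10), 0.0)
            if pa.sum() == 0 or pb.sum() == 0:
                continue
            assert am.bmntd(pa, pb, d) == pytest.approx(bmntd_oracle(pa, pb, d))

    def test_empty_community_rejected(self, four_leaf_dmat):
        with pytest.raises(ValueError, match="zero total"):
            am.bmntd(np.zeros(4), np.ones(4), four_leaf_dmat)


class TestBnti:
    def test_phylogeny_independent_assembly_calibrated(self):
        rng = np.random.default_rng(42)
        n = 40
        d = squareform(pdist(rng.normal(size=(n, 4))))
        zs = []
        for _ in range(40):
            pa = np.zeros(n)
            pb = np.zeros(n)
            pa[rng.choice(n, 15, replace=False)] = rng.dirichlet(np.ones(15))
            pb[rng.choice(n, 15, replace=False)] = rng.dirichlet(np.ones(15))
            zs.append(am.bnti(pa, pb, d, n_null=199, seed=rng))
        assert (np.abs(zs) < 2).mean() >= 0.9

    def test_different_clades_heterogeneous(self):
        specs = [sd.NichedModuleSpec(i + 1, 20, (0, 0, 0), (1, 1, 1)) for i in range(10)]
        tree = skbio.TreeNode.read(_io.StringIO(sd.generate_phylogeny(specs, seed=5)))
        dm = tree.tip_tip_distances()
        ids = list(dm.ids)
        # communities restricted to the two most divergent clades
        mod_idx = {s.module_id: [ids.index(a) for a in sd.module_asv_ids(s)]
                   for s in specs}
        pairs = [(i, j) for i in mod_idx for j in mod_idx if i < j]
        i, j = max(pairs, key=lambda p: dm.data[np.ix_(mod_idx[p[0]],
                                                       mod_idx[p[1]])].mean())
        m1, m2 = mod_idx[i], mod_idx[j]
        rng = np.random.default_rng(1)
        zs = []
        for _ in range(8):
            pa = np.zeros(len(ids))
            pb = np.zeros(len(ids))
            pa[rng.choice(m1, 12, replace=False)] = rng.dirichlet(np.ones(12))
            pb[rng.choice(m2, 12, replace=False)] = rng.dirichlet(np.ones(12))
            zs.append(am.bnti(pa, pb, dm.data, n_null=199, seed=rng))
        assert np.median(zs) > 2

    def test_degenerate_null_rejected(self):
        # all between-taxon distances equal -> every shuffle gives the same value
        d = np.ones((6, 6)) - np.eye(6)
        pa = np.array([1.0, 1.0, 0, 0, 0, 0])
        pb = np.array([0, 0, 1.0, 1.0, 0, 0])
        with pytest.raises(ValueError, match="zero spread"):
            am.bnti(pa, pb, d, n_null=50, seed=0)

    def test_invalid_n_null(self, four_leaf_dmat):
        with pytest.raises(ValueError):
            am.bnti(np.array([1.0, 0, 0, 0]), np.array([0, 1.0, 0, 0]),
                    four_leaf_dmat, n_null=1)


def rc_enumeration_oracle(ca, cb, pool_freq, pool_ab):
    """Exact RC expectation and null support by exhaustive enumeration.

    Enumerates every ordered species draw (sequential weighted sampling
    without replacement, matching the implementation) and every
    allocation of the remaining individuals, accumulating exact outcome
    probabilities.
    """

    def assemblies(total, s_count):
        n_sp = len(pool_freq)
        out = {}
        for order in permutations(range(n_sp), s_count):
            prob = 1.0
            w = list(pool_freq)
            for i in order:
                prob *= w[i] / sum(w)
                w[i] = 0.0
            rem = total - s_count
            chosen = list(order)
            ab = np.array([pool_ab[i] for i in chosen], dtype=float)
            p_alloc = ab / ab.sum() if ab.sum() > 0 else np.full(len(chosen), 1 / len(chosen))
            for alloc in _compositions(rem, s_count):
                vec = np.zeros(n_sp)
                for i, extra in zip(chosen, alloc):
                    vec[i] = 1 + extra
                p_multi = _multinomial_pmf(alloc, p_alloc)
                key = tuple(vec)
                out[key] = out.get(key, 0.0) + prob * p_multi
        return out

    obs = braycurtis(np.asarray(ca, float), np.asarray(cb, float))
    asm_a = assemblies(int(sum(ca)), int(sum(1 for v in ca if v > 0)))
    asm_b = assemblies(int(sum(cb)), int(sum(1 for v in cb if v > 0)))
    p_less = p_tie = 0.0
    support = set()
    for va, qa in asm_a.items():
        for vb, qb in asm_b.items():
            bc = braycurtis(np.array(va), np.array(vb))
            support.add(round(bc, 12))
            if np.isclose(bc, obs, atol=1e-12):
                p_tie += qa * qb
            elif bc < obs:
                p_less += qa * qb
    return 2 * (p_less + 0.5 * p_tie) - 1, support


def _compositions(total, parts):
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def _multinomial_pmf(counts, probs):
    from math import factorial

    n = sum(counts)
    coef = factorial(n)
    p = 1.0
    for c, q in zip(counts, probs):
        coef //= factorial(c)
        p *= q**c
    return coef * p


class TestRcBray:
    def test_identical_communities_near_minus_one(self):
        rng = np.random.default_rng(0)
        c = np.array([50, 30, 20, 0, 0], dtype=float)
        freq = np.array([0.8, 0.6, 0.5, 0.3, 0.2])
        ab = np.array([0.4, 0.3, 0.2, 0.07, 0.03])
        rc = am.rc_bray(c, c, freq, ab, n_null=199, seed=rng)
        assert rc <= -0.9

    def test_label_for_high_rc(self):
        assert am.classify(0.5, 0.97) == "dispersal_limitation"

    def test_bounds(self):
        rng = np.random.default_rng(3)
        freq = np.array([0.5, 0.5, 0.5, 0.5])
        ab = np.array([0.25, 0.25, 0.25, 0.25])
        for _ in range(5):
            ca = rng.multinomial(30, [0.4, 0.3, 0.2, 0.1]).astype(float)
            cb = rng.multinomial(25, [0.1, 0.2, 0.3, 0.4]).astype(float)
            rc = am.rc_bray(ca, cb, freq, ab, n_null=99, seed=rng)
            assert -1.0 <= rc <= 1.0

    def test_tiny_pool_matches_enumeration(self):
        # 3 species, richness 2 each: the null space is exhaustively enumerable
        ca = np.array([3.0, 1.0, 0.0])
        cb = np.array([0.0, 2.0, 2.0])
        freq = np.array([0.6, 0.3, 0.1])
        ab = np.array([0.5, 0.3, 0.2])
        exact, support = rc_enumeration_oracle(ca, cb, freq, ab)
        rc = am.rc_bray(ca, cb, freq, ab, n_null=999, seed=7)
        # Monte-Carlo estimate vs exact expectation (3 sigma ~ 0.09)
        assert rc == pytest.approx(exact, abs=0.1)
        # and every sampled null distance must lie in the enumerated support
        rng = np.random.default_rng(11)
        for _ in range(200):
            xa = am._null_assembly(4, 2, freq, ab, rng)
            xb = am._null_assembly(4, 2, freq, ab, rng)
            bc = braycurtis(xa, xb)
            assert round(bc, 12) in support or any(
                np.isclose(bc, s, atol=1e-9) for s in support
            )

    def test_pool_too_small_rejected(self):
        ca = np.array([1.0, 1.0, 1.0])
        freq = np.array([0.5, 0.5, 0.0])
        ab = np.array([0.5, 0.5, 0.0])
        with pytest.raises(ValueError, match="pool"):
            am.rc_bray(ca, ca, freq, ab, n_null=10)

    def test_empty_community_rejected(self):
        freq = np.ones(3)
        with pytest.raises(ValueError, match="empty"):
            am.rc_bray(np.zeros(3), np.ones(3), freq, freq, n_null=10)


class TestClassify:
    @pytest.mark.parametrize(
        "z, rc, label",
        [
            (2.5, None, "heterogeneous_selection"),
            (-2.5, None, "homogeneous_selection"),
            (0.3, 0.97, "dispersal_limitation"),
            (0.3, -0.97, "homogenizing_dispersal"),
            (0.3, 0.1, "drift"),
            (1.99, 0.0, "drift"),
        ],
    )
    def test_decision_rule(self, z, rc, label):
        assert am.classify(z, rc) == label

    def test_missing_rc_rejected(self):
        with pytest.raises(ValueError, match="RC_bray"):
            am.classify(0.5, None)


class TestPairwiseAndFractions:
    @pytest.fixture
    def small_system(self):
        specs = [sd.NichedModuleSpec(i + 1, 8, (0, 0, 0), (1, 1, 1)) for i in range(4)]
        nwk = sd.generate_phylogeny(specs, seed=2)
        tree = skbio.TreeNode.read(_io.StringIO(nwk))
        dm = tree.tip_tip_distances()
        dmat = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
        rng = np.random.default_rng(0)
        taxa = list(dm.ids)
        counts = pd.DataFrame(
            rng.multinomial(500, rng.dirichlet(np.ones(len(taxa)), 1)[0], size=6),
            index=[f"s{i}" for i in range(6)], columns=taxa,
        )
        return counts, dmat

    def test_rows_and_labels(self, small_system):
        counts, dmat = small_system
        pairs = [("s0", "s1"), ("s2", "s3")]
        calls = am.pairwise_mechanisms(counts, dmat, pairs, n_null=49, seed=1)
        assert len(calls) == 2
        assert set(calls["label"]) <= set(am.LABELS)

    def test_pair_order_invariance(self, small_system):
        counts, dmat = small_system
        pairs = [("s0", "s1"), ("s2", "s3"), ("s1", "s4")]
        c1 = am.pairwise_mechanisms(counts, dmat, pairs, n_null=49, seed=1)
        c2 = am.pairwise_mechanisms(counts, dmat, pairs[::-1], n_null=49, seed=1)
        merged = c1.merge(c2, on=["sample_a", "sample_b"], suffixes=("_1", "_2"))
        np.testing.assert_allclose(merged["bnti_1"], merged["bnti_2"])
        assert (merged["label_1"] == merged["label_2"]).all()

    def test_fraction_closure_and_modal(self):
        calls = pd.DataFrame(
            {
                "sample_a": ["a"] * 4,
                "sample_b": ["b"] * 4,
                "group": ["g1", "g1", "g1", "g2"],
                "label": ["drift", "drift", "homogeneous_selection", "drift"],
            }
        )
        frac = am.mechanism_fractions(calls)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0)
        assert frac.loc["g1", "drift"] == pytest.approx(2 / 3)
        assert frac.loc["g2", "drift"] == pytest.approx(1.0)

    def test_delta_t_binning(self):
        calls = pd.DataFrame(
            {
                "sample_a": ["s0", "s0"],
                "sample_b": ["s1", "s2"],
                "label": ["drift", "dispersal_limitation"],
            }
        )
        meta = pd.DataFrame({"temperature": [10.0, 11.0, 19.0]},
                            index=["s0", "s1", "s2"])
        frac = am.mechanism_fractions(calls, meta, delta_t_binwidth=2.0)
        assert set(frac.index) == {0.0, 8.0}

    def test_within_group_pairs(self):
        meta = pd.DataFrame(
            {
                "ocean": ["a", "a", "b"],
                "fraction": ["f", "f", "f"],
                "depth_layer": ["upper"] * 3,
            },
            index=["s1", "s2", "s3"],
        )
        pairs = am.within_group_pairs(meta)
        assert len(pairs) == 1
        assert pairs[0][:2] == ("s1", "s2")
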