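import random

import pytest

from nsslink.fca_enum import Concept, closure_of, enumerate_concepts_bruteforce
from nsslink.network_io import BipartiteNetwork, FormalContext, to_context
from nsslink.overlap_nss import (
    NSSParams,
    OverlapRecord,
    collect_marked_pairs,
    is_nontrivial,
    marked_pairs_for_network,
    overlap_rates,
    select_negatives,
    select_negatives_random,
    structure_hole,
)

from conftest import random_context


def brute_force_marked(ctx: FormalContext, params: NSSParams) -> set[tuple[int, int]]:
    """Oracle: union of holes over all non-trivial comparable concept pairs."""
    concepts = enumerate_concepts_bruteforce(ctx)
    marked: set[tuple[int, int]] = set()
    for c1 in concepts:
        for c2 in concepts:
            if c1 == c2 or not c1.leq(c2):
                continue
            rec = OverlapRecord(c1, c2)
            if is_nontrivial(rec, params):
                marked |= rec.hole
    return marked - set(ctx.incidence)


class TestOverlapRates:
    def test_direct_arithmetic(self):
        c1 = Concept((0, 1, 2, 3), (0, 1))
        c2 = Concept((0, 1), (0, 1, 2))
        assert overlap_rates(c1, c2) == (0.5, 2 / 3)

    def test_identical_concepts(self):
        c = Concept((0, 1), (2,))
        assert overlap_rates(c, c) == (1.0, 1.0)

    def test_zero_sized_component(self, identity_context):
        bottom = closure_of({0}, identity_context)  # ({g0}, {m0})
        top = closure_of(set(), identity_context)  # (G, {})
        assert overlap_rates(bottom, top) == (1 / 3, 0.0)

    def test_symmetric(self):
        c1 = Concept((0, 1, 2), (0,))
        c2 = Concept((0,), (0, 1))
        assert overlap_rates(c1, c2) == overlap_rates(c2, c1)

    def test_incomparable_rejected(self):
        with pytest.raises(ValueError, match="not comparable"):
            overlap_rates(Concept((0,), (0,)), Concept((1,), (1,)))


class TestIsNontrivial:
    def _rec(self):
        return OverlapRecord(
            Concept((0, 1, 2, 3), (4, 5)), Concept((0, 1), (4, 5, 6))
        )

    def test_passes_at_alpha_2(self):
        rec = self._rec()  # sizes (4, 2, 2, 3), sigma (0.5, 2/3)
        assert is_nontrivial(rec, NSSParams(alpha=2, rho=0.5))

    def test_fails_at_alpha_3(self):
        assert not is_nontrivial(self._rec(), NSSParams(alpha=3, rho=0.5))

    def test_rho_one_never_passes_for_distinct(self):
        # distinct comparable concepts force sigma1 < 1
        assert not is_nontrivial(self._rec(), NSSParams(alpha=1, rho=1.0))


class TestStructureHole:
    def test_single_pair(self):
        lower = Concept((0, 1, 2), (0,))
        upper = Concept((0, 1), (0, 1))
        assert structure_hole(lower, upper) == {(2, 1)}

    def test_equal_concepts_empty(self):
        c = Concept((0, 1), (0,))
        assert structure_hole(c, c) == set()

    def test_size_is_product_of_differences(self):
        lower = Concept((0, 1, 2, 3), (0,))
        upper = Concept((0,), (0, 1, 2))
        hole = structure_hole(lower, upper)
        assert len(hole) == (4 - 1) * (3 - 1)

    def test_wrong_order_rejected(self):
        with pytest.raises(ValueError):
            structure_hole(Concept((0,), (0, 1)), Concept((0, 1), (0,)))

    def test_hole_containment_on_chains(self):
        # for c1 <= c2 <= c3 the extreme pair's hole contains both sub-holes
        for seed in range(20):
            ctx = random_context(seed, max_side=6)
            concepts = sorted(enumerate_concepts_bruteforce(ctx), key=lambda c: -len(c.extent))
            for c1 in concepts:
                for c2 in concepts:
                    if c1 == c2 or not c1.leq(c2):
                        continue
                    for c3 in concepts:
                        if c2 == c3 or not c2.leq(c3):
                            continue
                        big = structure_hole(c1, c3)
                        assert structure_hole(c1, c2) <= big
                        assert structure_hole(c2, c3) <= big


class TestCollectMarkedPairs:
    def test_full_context_nothing(self, full_context):
        assert collect_marked_pairs(full_context, NSSParams(alpha=1, rho=0.1)) == set()

    def test_rho_one_nothing(self, two_block_context):
        assert collect_marked_pairs(two_block_context, NSSParams(alpha=1, rho=1.0)) == set()

    def test_two_block_matches_bruteforce(self, two_block_context):
        params = NSSParams(alpha=2, rho=0.4)
        marked = collect_marked_pairs(two_block_context, params)
        assert marked == brute_force_marked(two_block_context, params)
        # the two 2x2 exclusive corners
        assert marked == (
            {(g, m) for g in (0, 1) for m in (4, 5)}
            | {(g, m) for g in (4, 5) for m in (0, 1)}
        )

    def test_never_contains_incidence(self):
        for seed in range(10):
            ctx = random_context(seed, max_side=7)
            marked = collect_marked_pairs(ctx, NSSParams(alpha=2, rho=0.3))
            assert not marked & set(ctx.incidence)

    def test_relabeling_invariance(self, two_block_context):
        params = NSSParams(alpha=2, rho=0.4)
        base = collect_marked_pairs(two_block_context, params)
        rng = random.Random(5)
        for _ in range(5):
            perm_g = list(range(two_block_context.n_objects))
            perm_m = list(range(two_block_context.n_attributes))
            rng.shuffle(perm_g)
            rng.shuffle(perm_m)
            permuted = FormalContext(
                two_block_context.n_objects,
                two_block_context.n_attributes,
                frozenset(
                    (perm_g[g], perm_m[m]) for g, m in two_block_context.incidence
                ),
            )
            marked = collect_marked_pairs(permuted, params)
            assert marked == {(perm_g[g], perm_m[m]) for g, m in base}

    def test_network_wrapper_orientation(self, two_block_context):
        from nsslink.network_io import context_to_network

        net = context_to_network(two_block_context)
        params = NSSParams(alpha=2, rho=0.4)
        marked = marked_pairs_for_network(net, params)
        expected = collect_marked_pairs(two_block_context, params)
        assert marked == {(f"g{g}", f"m{m}") for g, m in expected}


class TestSelectNegatives:
    def _net(self):
        return BipartiteNetwork(
            ["a", "b", "c"],
            ["x", "y", "z"],
            {("a", "x"), ("b", "y"), ("c", "z")},
        )

    def test_pool_arithmetic(self):
        # 9 pairs - 3 present - 1 marked = 5; floor(0.5 * 5) = 2
        negs = select_negatives(
            self._net(), {("a", "y")}, NSSParams(alpha=1, rho=0.5, sample_rate=0.5, seed=0)
        )
        assert len(negs) == 2
        assert not negs & {("a", "x"), ("b", "y"), ("c", "z"), ("a", "y")}

    def test_rate_one_whole_pool(self):
        negs = select_negatives(
            self._net(), set(), NSSParams(sample_rate=1.0, seed=0)
        )
        assert len(negs) == 6

    def test_rate_zero_empty(self):
        assert select_negatives(self._net(), set(), NSSParams(sample_rate=0.0, seed=0)) == set()

    def test_marked_present_edges_ignored(self):
        # a marked pair that is also present must not shrink the pool twice
        negs = select_negatives(
            self._net(), {("a", "x")}, NSSParams(sample_rate=1.0, seed=0)
        )
        assert len(negs) == 6

    def test_deterministic(self):
        p = NSSParams(sample_rate=0.5, seed=11)
        assert select_negatives(self._net(), set(), p) == select_negatives(
            self._net(), set(), p
        )

    def test_random_selection_equals_empty_marked(self):
        p = NSSParams(sample_rate=0.5, seed=3)
        assert select_negatives_random(self._net(), p) == select_negatives(
            self._net(), set(), p
        )

    def test_random_on_2x2(self):
        net = BipartiteNetwork(["a", "b"], ["x", "y"], {("a", "x")})
        negs = select_negatives_random(net, NSSParams(sample_rate=1.0, seed=0))
        assert negs == {("a", "y"), ("b", "x"), ("b", "y")}

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match="sample_rate"):
            NSSParams(sample_rate=1.5)


class TestChainDeductions:
    """Lattice deductions checked on sampled small lattices."""

    def _chains(self, ctx):
        concepts = list(enumerate_concepts_bruteforce(ctx))
        for c1 in concepts:
            for c2 in concepts:
                if c1 == c2 or not c1.leq(c2):
                    continue
                for c3 in concepts:
                    if c2 == c3 or not c2.leq(c3):
                        continue
                    yield c1, c2, c3

    def test_size_monotonicity(self):
        for seed in range(15):
            ctx = random_context(seed, max_side=6)
            for c1, c2, c3 in self._chains(ctx):
                assert len(c1.extent) > len(c2.extent) > len(c3.extent)
                assert len(c1.intent) < len(c2.intent) < len(c3.intent)

    def test_sigma_multiplicativity(self):
        from fractions import Fraction

        for seed in range(15):
            ctx = random_context(seed, max_side=6)
            for c1, c2, c3 in self._chains(ctx):
                a1, a2, a3 = (len(c.extent) for c in (c1, c2, c3))
                b1, b2, b3 = (len(c.intent) for c in (c1, c2, c3))
                assert Fraction(a3, a1) == Fraction(a2, a1) * Fraction(a3, a2)
                if b1 and b2 and b3:
                    assert Fraction(b1, b3) == Fraction(b2, b3) * Fraction(b1, b2)
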