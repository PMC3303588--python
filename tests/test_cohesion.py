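import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gcpnet.cohesion import (
    ProfileSet,
    cohesion_score,
    gene_contributions,
    matching_score,
    permutation_pvalue,
    similarity_matrix,
)
from gcpnet.profiles import ConceptProfile

from conftest import make_profile, random_profile_set


def brute_force_cohesion(profile_set, ids):
    """Explicit double loop over pairs and genes (the independent oracle)."""
    rows = [profile_set.matrix[profile_set.index_of(c)] for c in ids]
    pairs = list(itertools.combinations(range(len(rows)), 2))
    total = sum(float(rows[i] @ rows[j]) for i, j in pairs)
    return total / len(pairs)


def brute_force_contributions(profile_set, ids):
    rows = [profile_set.matrix[profile_set.index_of(c)] for c in ids]
    pairs = list(itertools.combinations(range(len(rows)), 2))
    genes = profile_set.gene_ids
    score = brute_force_cohesion(profile_set, ids)
    out = {}
    for gi, gene in enumerate(genes):
        contrib = sum(rows[i][gi] * rows[j][gi] for i, j in pairs) / len(pairs)
        pct = 100.0 * contrib / score
        if pct > 0:
            out[gene] = pct
    return out


def exhaustive_pvalue(profile_set, group):
    """Exact permutation probability: enumerate every same-size subset."""
    observed = brute_force_cohesion(profile_set, group)
    subsets = list(itertools.combinations(profile_set.concept_ids, len(group)))
    hits = sum(
        brute_force_cohesion(profile_set, s) >= observed - 1e-12 for s in subsets
    )
    return hits / len(subsets)


class TestMatchingScore:
    def test_identical_profiles_score_one(self):
        p = make_profile("a", {"g1": 0.3, "g2": 0.4})
        q = make_profile("b", {"g1": 0.3, "g2": 0.4})
        assert matching_score(p, q) == pytest.approx(1.0)

    def test_disjoint_support_scores_zero(self):
        p = make_profile("a", {"g1": 1.0})
        q = make_profile("b", {"g2": 1.0})
        assert matching_score(p, q) == 0.0

    def test_arithmetic_example(self):
        p = ConceptProfile("a", {"g1": 0.6, "g2": 0.8}, normalized=True)
        q = ConceptProfile("b", {"g1": 0.8, "g2": 0.6}, normalized=True)
        assert matching_score(p, q) == pytest.approx(0.96)

    def test_unnormalised_profile_rejected(self):
        p = ConceptProfile("a", {"g1": 2.0})
        q = make_profile("b", {"g1": 1.0})
        with pytest.raises(ValueError):
            matching_score(p, q)

    def test_degenerate_profile_rejected(self):
        p = ConceptProfile("a", {}, normalized=True)
        q = make_profile("b", {"g1": 1.0})
        with pytest.raises(ValueError):
            matching_score(p, q)


class TestCohesionScore:
    def test_identical_pair_scores_one(self):
        ps = ProfileSet(
            [make_profile("a", {"g1": 1.0}), make_profile("b", {"g1": 2.0})]
        )
        assert cohesion_score(ps) == pytest.approx(1.0)

    def test_pairwise_orthogonal_scores_zero(self):
        ps = ProfileSet(
            [make_profile(c, {f"g{i}": 1.0}) for i, c in enumerate("abc")]
        )
        assert cohesion_score(ps) == pytest.approx(0.0, abs=1e-12)

    def test_mean_of_pairwise_scores(self, rng):
        ps = random_profile_set(3, 20, rng)
        pairwise = [
            float(ps.matrix[i] @ ps.matrix[j])
            for i, j in itertools.combinations(range(3), 2)
        ]
        assert cohesion_score(ps) == pytest.approx(np.mean(pairwise), abs=1e-12)

    def test_reorder_invariance(self, rng):
        ps = random_profile_set(5, 15, rng)
        a = brute_force_cohesion(ps, ["c0", "c1", "c2", "c3"])
        b = brute_force_cohesion(ps, ["c3", "c1", "c0", "c2"])
        assert a == pytest.approx(b, abs=1e-12)
        M = ps.subset(["c0", "c1", "c2", "c3"])
        assert cohesion_score(M) == pytest.approx(a, abs=1e-12)

    def test_single_profile_rejected(self):
        ps = ProfileSet([make_profile("a", {"g": 1}), make_profile("b", {"g": 1})])
        with pytest.raises(ValueError):
            cohesion_score(ps.matrix[:1])


class TestGeneContributions:
    def test_two_identical_profiles_split_by_squared_weight(self):
        ps = ProfileSet(
            [
                ConceptProfile("a", {"g1": 0.6, "g2": 0.8}, normalized=True),
                ConceptProfile("b", {"g1": 0.6, "g2": 0.8}, normalized=True),
            ]
        )
        contrib = gene_contributions(ps)
        assert contrib["g1"] == pytest.approx(36.0)
        assert contrib["g2"] == pytest.approx(64.0)

    def test_gene_absent_from_group_contributes_nothing(self, rng):
        ps = random_profile_set(3, 10, rng)
        contrib = gene_contributions(ps)
        for gi, gene in enumerate(ps.gene_ids):
            if not ps.matrix[:, gi].any():
                assert gene not in contrib

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        ps = random_profile_set(5, 30, rng)
        contrib = gene_contributions(ps)
        oracle = brute_force_contributions(ps, ps.concept_ids)
        assert set(contrib) == set(oracle)
        for gene in oracle:
            assert contrib[gene] == pytest.approx(oracle[gene], abs=1e-9)

    def test_contributions_sum_to_hundred(self, rng):
        ps = random_profile_set(6, 25, rng)
        assert sum(gene_contributions(ps).values()) == pytest.approx(100.0, abs=1e-6)

    def test_zero_cohesion_rejected(self):
        ps = ProfileSet(
            [make_profile("a", {"g1": 1.0}), make_profile("b", {"g2": 1.0})]
        )
        with pytest.raises(ValueError):
            gene_contributions(ps)


class TestPermutationPvalue:
    def test_identical_pair_beaten_only_by_itself(self):
        """A pair of identical profiles in an otherwise orthogonal universe:
        only a draw re-selecting the pair itself reaches cohesion 1, so the
        exact P is 1/C(8,2) and the Monte-Carlo estimate sits nearby."""
        profiles = [
            make_profile("a1", {"shared": 1.0}),
            make_profile("a2", {"shared": 1.0}),
        ] + [make_profile(f"o{i}", {f"g{i}": 1.0}) for i in range(6)]
        ps = ProfileSet(profiles)
        exact = exhaustive_pvalue(ps, ("a1", "a2"))
        assert exact == pytest.approx(1 / 28)
        result = permutation_pvalue(["a1", "a2"], ps, iterations=500, rng_seed=3)
        assert result.score == pytest.approx(1.0)
        se = math.sqrt(exact * (1 - exact) / 500)
        assert abs(result.p_value - exact) <= 3 * se

    def test_exhaustive_enumeration_on_four_profiles(self, rng):
        """With 4 profiles and a strictly best pair, the exact P over all
        C(4,2)=6 subsets is 1/6; the Monte-Carlo estimate at 10,000
        iterations must land within 3 standard errors."""
        ps = best_pair_universe(rng)
        exact = exhaustive_pvalue(ps, ("a1", "a2"))
        assert exact == pytest.approx(1 / 6)
        result = permutation_pvalue(["a1", "a2"], ps, iterations=10_000, rng_seed=99)
        se = math.sqrt(exact * (1 - exact) / 10_000)
        assert abs(result.p_value - exact) <= 3 * se

    @pytest.mark.parametrize("m", [2, 3])
    def test_converges_to_exhaustive_value_on_small_universes(self, m, rng):
        ps = random_profile_set(7, 12, rng)
        group = ps.concept_ids[:m]
        exact = exhaustive_pvalue(ps, group)
        result = permutation_pvalue(group, ps, iterations=20_000, rng_seed=7)
        se = math.sqrt(max(exact * (1 - exact), 1e-6) / 20_000)
        assert abs(result.p_value - exact) <= 4 * se

    def test_deterministic_for_fixed_seed(self, rng):
        ps = random_profile_set(6, 10, rng)
        r1 = permutation_pvalue(["c0", "c1"], ps, iterations=200, rng_seed=42)
        r2 = permutation_pvalue(["c0", "c1"], ps, iterations=200, rng_seed=42)
        assert r1.p_value == r2.p_value
        assert r1.score == r2.score

    def test_p_value_granularity(self, rng):
        ps = random_profile_set(6, 10, rng)
        r = permutation_pvalue(["c0", "c1"], ps, iterations=200, rng_seed=1)
        assert (r.p_value * 200) == pytest.approx(round(r.p_value * 200))

    def test_universe_not_larger_than_group_rejected(self):
        ps = ProfileSet([make_profile("a", {"g": 1}), make_profile("b", {"g": 1})])
        with pytest.raises(ValueError):
            permutation_pvalue(["a", "b"], ps, iterations=10)

    def test_result_contributions_match_standalone(self, rng):
        ps = random_profile_set(6, 15, rng)
        result = permutation_pvalue(["c0", "c1", "c2"], ps, iterations=50, rng_seed=0)
        oracle = brute_force_contributions(ps, ["c0", "c1", "c2"])
        assert result.contributions == pytest.approx(oracle, abs=1e-9)


def best_pair_universe(rng):
    """Four profiles where (a1, a2) is the strictly most cohesive pair."""
    return ProfileSet(
        [
            make_profile("a1", {"g1": 1.0, "g2": 0.1}),
            make_profile("a2", {"g1": 1.0, "g2": 0.2}),
            make_profile("b1", {"g3": 1.0, "g1": 0.1}),
            make_profile("b2", {"g4": 1.0, "g2": 0.1}),
        ]
    )


class TestSimilarityMatrix:
    def test_symmetric_unit_diagonal(self, rng):
        ps = random_profile_set(5, 20, rng)
        sim = similarity_matrix(ps)
        assert np.allclose(sim.values, sim.values.T)
        assert np.allclose(np.diag(sim.values), 1.0)
        off = sim.values[~np.eye(5, dtype=bool)]
        assert ((off >= 0) & (off <= 1)).all()
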