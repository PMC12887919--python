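"""Hypergeometric tail math, background inference and profiling."""

import math

import numpy as np
import pytest
from scipy import stats

from toothprot.enrichment import (
    enrich,
    hypergeom_upper_tail,
    infer_background,
    profile_categories,
    randomized_tail_pvalue,
)
from toothprot.io_formats import PathwaySet, ValidationError
from toothprot.reference import (
    DEFAULT_BACKGROUND,
    REFERENCE_ENRICHMENT,
    REFERENCE_QUERY_SIZE,
    fit_reference_background,
)
from toothprot.synthetic import SyntheticTruth, generate_pathway_sets


class TestUpperTail:
    def test_zero_successes_give_probability_one(self):
        assert hypergeom_upper_tail(0, 5, 10, 100) == 1.0

    def test_small_case_matches_enumeration(self):
        # N=5, K=3, n=2: C(5,2)=10 draws; both from K: C(3,2)=3 -> P(X>=2)=0.3
        assert hypergeom_upper_tail(2, 3, 2, 5) == pytest.approx(0.3, abs=1e-12)

    def test_agrees_with_scipy_on_grid(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            N = int(rng.integers(2, 5000))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            x = int(rng.integers(0, min(K, n) + 1))
            ours = hypergeom_upper_tail(x, K, n, N)
            ref = stats.hypergeom.sf(x - 1, N, K, n)
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-13)

    def test_large_background_is_finite_and_sane(self):
        p = hypergeom_upper_tail(3, 500, 1000, 10**7)
        assert 0.0 < p < 1e-4

    def test_monotone_in_x_and_background(self):
        ps = [hypergeom_upper_tail(x, 50, 100, 2000) for x in range(0, 20)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        # growing the background dilutes the pathway: x hits become
        # rarer by chance and the tail probability shrinks
        pNs = [hypergeom_upper_tail(3, 50, 100, N) for N in (500, 1000, 5000, 20000)]
        assert all(a >= b for a, b in zip(pNs, pNs[1:]))

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_upper_tail(4, 3, 10, 20)
        with pytest.raises(ValidationError):
            hypergeom_upper_tail(1, 30, 10, 20)

    def test_randomized_pvalue_interpolates_the_tail(self):
        x, K, n, N = 3, 40, 60, 500
        lo = hypergeom_upper_tail(x + 1, K, n, N)
        hi = hypergeom_upper_tail(x, K, n, N)
        assert randomized_tail_pvalue(x, K, n, N, 0.0) == pytest.approx(lo)
        assert randomized_tail_pvalue(x, K, n, N, 1.0) == pytest.approx(hi)


class TestEnrich:
    def _pathways(self):
        return [
            PathwaySet("PW1", "whole background", frozenset(f"P{i}" for i in range(10))),
            PathwaySet("PW2", "half", frozenset(f"P{i}" for i in range(5))),
            PathwaySet("PW3", "untouched", frozenset({"Q1", "Q2"})),
        ]

    def test_whole_background_pathway_is_uninformative(self):
        query = {f"P{i}" for i in range(4)}
        results = enrich(query, self._pathways()[:1], N=10)
        assert results[0].entities_ratio == 1.0
        assert results[0].p_value == pytest.approx(1.0)

    def test_unhit_pathways_are_dropped(self):
        results = enrich({"P0", "P1"}, self._pathways(), N=10)
        assert {r.pathway_id for r in results} == {"PW1", "PW2"}

    def test_reference_entity_ratio(self):
        results = enrich(
            {"P0"},
            [PathwaySet("PW", "big", frozenset(f"P{i}" for i in range(573)))],
            N=DEFAULT_BACKGROUND,
        )
        assert round(results[0].entities_ratio, 4) == 0.0520

    def test_ranking_by_entity_ratio_among_significant(self):
        rng = np.random.default_rng(0)
        universe = [f"P{i}" for i in range(400)]
        query = universe[:30]
        pathways = [
            PathwaySet(f"PW{k}", "x", frozenset(universe[: 20 + 30 * k]))
            for k in range(4)
        ]
        results = enrich(query, pathways, N=400)
        sig = [r for r in results if r.significant]
        assert [r.rank for r in sig] == list(range(1, len(sig) + 1))
        ratios = [r.entities_ratio for r in sig]
        assert ratios == sorted(ratios, reverse=True)
        for r in results:
            if not r.significant:
                assert r.rank is None

    def test_oversized_pathway_rejected(self):
        with pytest.raises(ValidationError):
            enrich({"P0"}, [PathwaySet("PW", "x", frozenset(f"P{i}" for i in range(11)))], N=10)

    def test_planted_pathway_attains_smallest_p(self):
        # one pathway drawing 80% of its members from the "hit" set must
        # dominate 99 null pathways in nearly every replicate
        universe = [f"SYN{i:05d}" for i in range(1, 2001)]
        planted = {a: 1.0 for a in universe[:100]}
        wins = 0
        for seed in range(100):
            truth = SyntheticTruth(planted=dict(planted))
            pathways = generate_pathway_sets(
                universe, truth, n_pathways=100, sizes=(30, 60),
                seed=seed, n_enriched=1, enriched_fraction=0.8,
            )
            results = enrich(set(planted), pathways, N=2000)
            by_p = min(results, key=lambda r: (r.p_value, r.pathway_id))
            wins += by_p.pathway_id in truth.enriched_pathways
        assert wins >= 95


class TestInferBackground:
    def test_single_pair_interval_contains_fit(self):
        fit = infer_background([(573, 0.0520)])
        lo, hi = fit.feasible_interval
        assert (lo, hi) == (11009, 11029)
        assert lo <= fit.n_background <= hi

    def test_exact_pair(self):
        assert infer_background([(10, 0.5)]).n_background == 20

    def test_reference_pairs_recover_background(self):
        fit = fit_reference_background()
        assert fit.consistent
        assert abs(fit.n_background - 11017) <= 10
        lo, hi = fit.feasible_interval
        assert lo <= DEFAULT_BACKGROUND <= hi
        # the fitted N reproduces every printed ratio at 4 decimals
        for _, _, _, K, ratio, _ in REFERENCE_ENRICHMENT:
            assert round(K / fit.n_background, 4) == ratio

    def test_five_large_pathways_suffice(self):
        pairs = [(K, r) for _, _, _, K, r, _ in REFERENCE_ENRICHMENT
                 if K in (573, 532, 191, 180, 151)]
        fit = infer_background(pairs)
        assert abs(fit.n_background - 11017) <= 10

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValidationError):
            infer_background([(5, 0.0)])


class TestProfileCategories:
    CATS = {
        "P1": [("function", "Binding")],
        "P2": [("function", "Binding"), ("process", "Metabolism")],
        "P3": [("function", "Transport")],
    }

    def test_counts_reflect_query_membership(self):
        profile = profile_categories({"P1", "P2"}, self.CATS)
        assert profile["function"]["counts"] == {"Binding": 2}
        assert profile["process"]["counts"] == {"Metabolism": 1}
        assert profile["_unannotated"]["count"] == 0

    def test_empty_query_gives_empty_profile(self):
        assert profile_categories(set(), self.CATS) == {}

    def test_matches_brute_force_tally_on_random_fixture(self):
        rng = np.random.default_rng(50)
        terms = ["Binding", "Transport", "Catalysis", "Structure"]
        cats = {
            f"P{i}": [("function", terms[int(rng.integers(len(terms)))])]
            for i in range(50)
        }
        query = {f"P{i}" for i in range(50) if rng.random() < 0.5} | {"X1"}
        profile = profile_categories(query, cats)
        for term in terms:
            expected = sum(
                1 for acc in query
                if acc in cats and cats[acc][0][1] == term
            )
            assert profile["function"]["counts"].get(term, 0) == expected
        assert profile["_unannotated"]["count"] == 1
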