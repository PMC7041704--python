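"""Matched-null resampling: pools, sampler, oracle, and the full test."""

import math
from collections import Counter
from itertools import permutations

import numpy as np
import pytest

from matchloci import (
    AnalysisConfig,
    GeneUniverse,
    LocusCatalog,
    ValidationError,
    build_matching_pools,
    count_overlapping_loci,
    enrichment_test,
    exact_null_oracle,
    oracle_mean,
    sample_null_set,
)
from matchloci.enrich import MatchingPools


def _uniform_universe(gene_ids, expr=None, length=None):
    n = len(gene_ids)
    return GeneUniverse.from_values(
        gene_ids,
        expr if expr is not None else [1.0] * n,
        length if length is not None else [100] * n,
    )


def _manual_pools(universe, query, pools_by_gene, window=5.0):
    index = universe.frame.index
    query = sorted(query)
    positions = index.get_indexer(query)
    pools = [
        np.asarray(index.get_indexer(pools_by_gene[g]), dtype=np.int64)
        for g in query
    ]
    return MatchingPools(
        universe=universe,
        query=query,
        query_positions=positions,
        pools=pools,
        effective_window=np.full(len(query), window),
        base_window=window,
        widen_step=1.0,
    )


def test_locus_level_overlap_counting():
    catalog = LocusCatalog({"L1": {"g1", "g2"}, "L2": {"g3"}, "L3": {"g4"}})
    assert count_overlapping_loci({"g1", "g3", "g5"}, catalog) == 2
    assert count_overlapping_loci(set(), catalog) == 0
    # both hits in L1 count the locus once
    assert count_overlapping_loci({"g1", "g2"}, catalog) == 1


def test_identical_covariates_pool_is_universe_minus_query():
    universe = _uniform_universe([f"g{i}" for i in range(6)])
    pools = build_matching_pools(["g0", "g1"], universe, AnalysisConfig())
    for g in ("g0", "g1"):
        assert set(pools.pool_genes(g)) == {"g2", "g3", "g4", "g5"}
    assert pools.n_widened == 0


def test_isolated_gene_pool_widens_until_populated():
    universe = _uniform_universe(["a", "b", "c"], expr=[1.0, 2.0, 3.0])
    pools = build_matching_pools(["b"], universe, AnalysisConfig())
    assert pools.n_widened == 1
    assert pools.effective_window[0] > 5.0
    assert set(pools.pool_genes("b")) >= {"a"} or set(pools.pool_genes("b")) >= {"c"}


def test_pools_respect_window_on_generated_universe(small_dataset):
    universe = small_dataset.universe
    flags = small_dataset.labels.flags
    query = sorted(flags.index[flags["il10_regulated"]])
    pools = build_matching_pools(query, universe, AnalysisConfig())
    assert pools.n_widened == 0
    expr = universe.frame["expr_pct"]
    lens = universe.frame["len_pct"]
    qset = set(query)
    for i, g in enumerate(pools.query):
        members = pools.pool_genes(g)
        assert not qset & set(members)
        w = pools.effective_window[i]
        assert (abs(expr[members] - expr[g]) <= w).all()
        assert (abs(lens[members] - lens[g]) <= w).all()


def test_query_gene_missing_from_universe_is_an_error(small_dataset):
    with pytest.raises(ValidationError, match="not_a_gene"):
        build_matching_pools(["not_a_gene"], small_dataset.universe,
                             AnalysisConfig())


def test_single_candidate_pool_is_deterministic():
    universe = _uniform_universe(["q", "x"])
    pools = build_matching_pools(["q"], universe, AnalysisConfig())
    rng = np.random.default_rng(0)
    for _ in range(10):
        assert sample_null_set(pools, rng) == ["x"]


def test_null_sets_are_unique_and_disjoint_from_query(small_dataset):
    flags = small_dataset.labels.flags
    query = sorted(flags.index[flags["il10_repressed"]])
    pools = build_matching_pools(query, small_dataset.universe, AnalysisConfig())
    rng = np.random.default_rng(1)
    qset = set(query)
    for _ in range(50):
        null = sample_null_set(pools, rng)
        assert len(null) == len(query)
        assert len(set(null)) == len(null)
        assert not set(null) & qset


def test_exhausted_pool_widens_transiently():
    # q1 and q2 share the single matched candidate x; the second pick must
    # widen its window to reach the distant gene y
    universe = _uniform_universe(["q1", "q2", "x", "y"],
                                 expr=[1.0, 1.0, 1.0, 100.0])
    pools = build_matching_pools(["q1", "q2"], universe, AnalysisConfig())
    assert {frozenset(pools.pool_genes(g)) for g in ("q1", "q2")} == {frozenset({"x"})}
    rng = np.random.default_rng(2)
    assert set(sample_null_set(pools, rng)) == {"x", "y"}


def _enumerate_set_probabilities(pools: MatchingPools):
    """Brute-force pmf over null sets: uniform over orders, uniform picks."""
    k = len(pools.query)
    probs: Counter = Counter()
    pool_lists = [list(map(int, p)) for p in pools.pools]
    for order in permutations(range(k)):
        def recurse(depth, chosen, weight):
            if depth == k:
                probs[frozenset(chosen)] += weight
                return
            avail = [x for x in pool_lists[order[depth]] if x not in chosen]
            for pick in avail:
                recurse(depth + 1, chosen | {pick}, weight / len(avail))
        recurse(0, frozenset(), 1.0 / math.factorial(k))
    return probs


def test_sampler_frequencies_match_enumeration():
    """Empirical null-set frequencies on a tiny instance match exhaustive
    enumeration over processing orders and uniform picks (3 SE)."""
    universe = _uniform_universe(["q1", "q2", "a", "b", "c", "d"])
    pools = _manual_pools(
        universe, ["q1", "q2"],
        {"q1": ["a", "b", "c"], "q2": ["a", "b"]},
    )
    expected = _enumerate_set_probabilities(pools)
    index = universe.frame.index
    rng = np.random.default_rng(3)
    draws = 50_000
    observed: Counter = Counter()
    for _ in range(draws):
        null = sample_null_set(pools, rng)
        observed[frozenset(index.get_indexer(null))] += 1
    assert set(observed) == set(expected)
    for key, p in expected.items():
        se = math.sqrt(p * (1 - p) / draws)
        assert abs(observed[key] / draws - p) <= 3 * se


def test_oracle_pmf_on_one_gene_query():
    universe = _uniform_universe(["q", "a", "b"])
    pools = _manual_pools(universe, ["q"], {"q": ["a", "b"]})
    catalog = LocusCatalog({"L1": {"a"}})
    assert exact_null_oracle(pools, catalog) == {0: 0.5, 1: 0.5}


def test_oracle_pmf_when_pools_miss_all_loci():
    universe = _uniform_universe(["q", "a", "b"])
    pools = _manual_pools(universe, ["q"], {"q": ["a", "b"]})
    catalog = LocusCatalog({"L1": {"zzz"}})
    assert exact_null_oracle(pools, catalog) == {0: 1.0}


def test_oracle_rejects_oversized_instances(small_dataset):
    flags = small_dataset.labels.flags
    query = sorted(flags.index[flags["il10_repressed"]])
    pools = build_matching_pools(query, small_dataset.universe, AnalysisConfig())
    with pytest.raises(ValueError, match="too large"):
        exact_null_oracle(pools, small_dataset.catalog)


def test_monte_carlo_null_mean_matches_oracle():
    """MC null mean on a 12-gene universe agrees with the exact oracle."""
    gene_ids = [f"g{i:02d}" for i in range(12)]
    universe = _uniform_universe(gene_ids)
    query = gene_ids[:3]
    catalog = LocusCatalog({
        "L1": {"g03", "g04"}, "L2": {"g05"}, "L3": {"g06", "g07"},
        "L4": {"g00"},  # a locus on a query gene: nulls can never hit it
    })
    config = AnalysisConfig(n_null=5000, seed=4)
    pools = build_matching_pools(query, universe, config)
    pmf = exact_null_oracle(pools, catalog)
    expected = oracle_mean(pmf)
    var = sum(k**2 * v for k, v in pmf.items()) - expected**2
    result = enrichment_test(query, catalog, universe, config, pools=pools)
    se = math.sqrt(var / config.n_null)
    assert abs(result.null_mean - expected) <= 3 * se


def test_enrichment_result_is_bit_reproducible(small_dataset):
    flags = small_dataset.labels.flags
    query = sorted(flags.index[flags["il10_repressed"]])
    config = AnalysisConfig(n_null=300, seed=5)
    a = enrichment_test(query, small_dataset.catalog, small_dataset.universe, config)
    b = enrichment_test(query, small_dataset.catalog, small_dataset.universe, config)
    assert np.array_equal(a.null_overlaps, b.null_overlaps)
    assert a.as_dict() == b.as_dict()


def test_enrichment_rejects_empty_inputs(small_dataset):
    config = AnalysisConfig(n_null=10)
    with pytest.raises(ValidationError, match="query"):
        enrichment_test([], small_dataset.catalog, small_dataset.universe, config)


def test_unreachable_observed_overlap_reports_bounded_p():
    # loci sit exclusively on query genes, so every null overlap is 0:
    # the ratio is undefined and the P value is reported as a bound
    gene_ids = [f"g{i}" for i in range(20)]
    universe = _uniform_universe(gene_ids)
    query = gene_ids[:3]
    catalog = LocusCatalog({f"L{i}": {g} for i, g in enumerate(query)})
    config = AnalysisConfig(n_null=100, seed=6)
    result = enrichment_test(query, catalog, universe, config)
    assert result.observed_overlap == 3
    assert result.null_mean == 0.0
    assert math.isnan(result.enrichment_ratio)
    assert result.empirical_p == 0.0
    assert result.p_display == "< 0.01"
    conservative = enrichment_test(
        query, catalog, universe,
        AnalysisConfig(n_null=100, seed=6, conservative_p=True),
    )
    assert conservative.empirical_p == pytest.approx(1 / 101)
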