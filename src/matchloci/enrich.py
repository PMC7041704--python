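"""Locus-overlap enrichment against expression/length-matched null gene sets.

The statistic asks whether a query gene list hits more GWAS risk loci than
expected for a random list of comparable genes.  Overlap is counted at the
locus level: a locus counts once if at least one of its member genes is in
the list, so the count is usually smaller than the number of overlapping
genes.  The null distribution comes from resampled gene sets in which each
query gene is replaced by a gene drawn uniformly from the universe members
lying within a joint percentile window (default +/-5 points on both the
expression and the gene-length percentile), excluding the query genes
themselves and genes already chosen for the same null set.  Fold enrichment
is the observed overlap divided by the mean null overlap, and the one-tailed
empirical P value is the proportion of null sets with at least the observed
overlap.

Genes are processed in a freshly randomised order for every null set:
sequential without-replacement sampling is order-dependent, and
randomisation removes any systematic bias toward early query genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .datamodel import AnalysisConfig, GeneUniverse, LocusCatalog, ValidationError

log = logging.getLogger("matchloci")


@dataclass
class MatchingPools:
    """Per-query-gene candidate pools for matched null sampling.

    ``pools[i]`` holds universe positions within ``effective_window[i]``
    percentile points of query gene ``query[i]`` on both covariates, never
    including any query gene.  Windows wider than the configured default
    record pool widening (counted by ``n_widened``).
    """

    universe: GeneUniverse
    query: list
    query_positions: np.ndarray
    pools: list
    effective_window: np.ndarray
    base_window: float
    widen_step: float

    @property
    def n_widened(self) -> int:
        return int(np.sum(self.effective_window > self.base_window))

    def pool_genes(self, gene_id: str) -> list:
        i = self.query.index(gene_id)
        return list(np.asarray(self.universe.gene_ids)[self.pools[i]])


def count_overlapping_loci(genes, catalog: LocusCatalog) -> int:
    """Number of loci containing at least one gene of ``genes``."""
    hit: set = set()
    reverse = catalog.gene_to_loci
    for g in genes:
        loci = reverse.get(g)
        if loci:
            hit.update(loci)
    return len(hit)


def _eligible(expr_pct, len_pct, e0, l0, window, excluded_mask):
    return np.flatnonzero(
        (np.abs(expr_pct - e0) <= window)
        & (np.abs(len_pct - l0) <= window)
        & ~excluded_mask
    )


def build_matching_pools(
    query, universe: GeneUniverse, config: AnalysisConfig
) -> MatchingPools:
    """Build the matched candidate pool for every query gene.

    Any gene whose pool is empty at ``match_window_pct`` has its window
    widened by ``widen_step_pct`` until a candidate qualifies; the widened
    window is recorded and logged.
    """
    qset = sorted(set(query))
    missing = [g for g in qset if g not in universe]
    if missing:
        raise ValidationError(f"query gene(s) absent from universe: {missing}")
    if len(universe) < len(qset) + 1:
        raise ValidationError(
            f"universe of {len(universe)} genes cannot supply null genes for a "
            f"{len(qset)}-gene query"
        )
    index = universe.frame.index
    expr_pct = universe.frame["expr_pct"].to_numpy()
    len_pct = universe.frame["len_pct"].to_numpy()
    positions = index.get_indexer(qset)
    qmask = np.zeros(len(universe), dtype=bool)
    qmask[positions] = True

    pools, windows = [], np.empty(len(qset))
    for i, pos in enumerate(positions):
        window = config.match_window_pct
        while True:
            elig = _eligible(expr_pct, len_pct, expr_pct[pos], len_pct[pos],
                             window, qmask)
            if elig.size:
                break
            window += config.widen_step_pct
        if window > config.match_window_pct:
            log.warning(
                "matching pool for %s required widening to +/-%.1f percentile points",
                qset[i], window,
            )
        pools.append(elig)
        windows[i] = window
    mp = MatchingPools(
        universe=universe,
        query=qset,
        query_positions=positions,
        pools=pools,
        effective_window=windows,
        base_window=config.match_window_pct,
        widen_step=config.widen_step_pct,
    )
    if mp.n_widened:
        log.warning("%d of %d query genes required pool widening",
                    mp.n_widened, len(qset))
    return mp


def _sample_positions(mp: MatchingPools, rng: np.random.Generator) -> list:
    """One null set as universe positions (order randomised per draw)."""
    order = rng.permutation(len(mp.query))
    chosen: set = set()
    expr_pct = mp.universe.frame["expr_pct"].to_numpy()
    len_pct = mp.universe.frame["len_pct"].to_numpy()
    qmask = np.zeros(len(mp.universe), dtype=bool)
    qmask[mp.query_positions] = True
    out = []
    for j in order:
        pool = mp.pools[j]
        m = pool.size
        pick = -1
        for _ in range(8):  # rejection sampling; collisions are rare
            cand = int(pool[rng.integers(m)])
            if cand not in chosen:
                pick = cand
                break
        if pick < 0:
            avail = [int(x) for x in pool if int(x) not in chosen]
            if avail:
                pick = avail[rng.integers(len(avail))]
            else:
                # pool exhausted by earlier picks: widen transiently
                window = mp.effective_window[j]
                pos = mp.query_positions[j]
                while True:
                    window += mp.widen_step
                    elig = _eligible(expr_pct, len_pct, expr_pct[pos],
                                     len_pct[pos], window, qmask)
                    avail = [int(x) for x in elig if int(x) not in chosen]
                    if avail:
                        log.warning(
                            "transient widening to +/-%.1f for %s during null draw",
                            window, mp.query[j],
                        )
                        break
                    if window > 100.0:
                        raise ValidationError(
                            "universe exhausted while sampling a null set "
                            "(pathological instance)"
                        )
                pick = avail[rng.integers(len(avail))]
        chosen.add(pick)
        out.append(pick)
    return out


def sample_null_set(mp: MatchingPools, rng: np.random.Generator) -> list:
    """Draw one matched null gene set (unique genes, disjoint from the query)."""
    gene_ids = np.asarray(mp.universe.gene_ids)
    return [str(g) for g in gene_ids[_sample_positions(mp, rng)]]


@dataclass
class EnrichmentResult:
    """Observed locus overlap, its matched-null distribution, and summaries."""

    observed_overlap: int
    null_overlaps: np.ndarray
    null_mean: float
    enrichment_ratio: float
    empirical_p: float
    p_display: str
    n_widened: int
    n_query: int
    n_null: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "observed_overlap": self.observed_overlap,
            "null_mean": self.null_mean,
            "enrichment_ratio": self.enrichment_ratio,
            "empirical_p": self.empirical_p,
            "p_display": self.p_display,
            "n_widened": self.n_widened,
            "n_query": self.n_query,
            "n_null": self.n_null,
            "seed": self.seed,
        }


def enrichment_test(
    query,
    catalog: LocusCatalog,
    universe: GeneUniverse,
    config: AnalysisConfig,
    pools: MatchingPools | None = None,
) -> EnrichmentResult:
    """Run the matched-null locus-overlap enrichment test.

    Draws ``config.n_null`` independent null sets seeded by ``config.seed``;
    the full null overlap vector is returned so results are auditable and
    bit-reproducible.  ``empirical_p`` is r/B (or (r+1)/(B+1) with
    ``conservative_p``); when no null set reaches the observed overlap the
    display string reports "< 1/B".
    """
    qset = sorted(set(query))
    if not qset:
        raise ValidationError("enrichment_test requires a non-empty query gene set")
    if catalog.n_loci == 0:
        raise ValidationError("enrichment_test requires a non-empty locus catalog")
    observed = count_overlapping_loci(qset, catalog)
    if pools is None:
        pools = build_matching_pools(qset, universe, config)

    # locus ids -> ints per universe position, for fast null overlap counting
    locus_index = {locus_id: k for k, locus_id in enumerate(sorted(catalog.loci))}
    gene_ids = universe.gene_ids
    loci_of: list = [()] * len(universe)
    for pos, g in enumerate(gene_ids):
        hits = catalog.gene_to_loci.get(g)
        if hits:
            loci_of[pos] = tuple(locus_index[l] for l in hits)

    rng = np.random.default_rng(config.seed)
    B = config.n_null
    null_overlaps = np.empty(B, dtype=np.int64)
    for b in range(B):
        positions = _sample_positions(pools, rng)
        hit: set = set()
        for pos in positions:
            loci = loci_of[pos]
            if loci:
                hit.update(loci)
        null_overlaps[b] = len(hit)

    null_mean = float(null_overlaps.mean())
    ratio = observed / null_mean if null_mean > 0 else math.nan
    if math.isnan(ratio):
        log.warning("null mean overlap is 0; enrichment ratio undefined")
    r = int(np.sum(null_overlaps >= observed))
    if config.conservative_p:
        empirical_p = (r + 1) / (B + 1)
    else:
        empirical_p = r / B
    p_display = f"< {1.0 / B:g}" if r == 0 else f"{empirical_p:g}"
    return EnrichmentResult(
        observed_overlap=observed,
        null_overlaps=null_overlaps,
        null_mean=null_mean,
        enrichment_ratio=ratio,
        empirical_p=empirical_p,
        p_display=p_display,
        n_widened=pools.n_widened,
        n_query=len(qset),
        n_null=B,
        seed=config.seed,
    )


def exact_null_oracle(mp: MatchingPools, catalog: LocusCatalog,
                      max_states: int = 2_000_000) -> dict:
    """Exact pmf of the null overlap count by exhaustive enumeration.

    Averages uniformly over query processing orders and, within an order,
    over uniform without-replacement picks from each pool.  Only feasible for
    tiny instances (orders x pool-size product bounded by ``max_states``);
    intended as an independent test oracle for the Monte-Carlo sampler.
    """
    k = len(mp.query)
    bound = math.factorial(k)
    for pool in mp.pools:
        bound *= max(pool.size, 1)
    if bound > max_states:
        raise ValueError(f"instance too large for enumeration ({bound} states)")

    gene_ids = np.asarray(mp.universe.gene_ids)
    pool_sets = [list(map(int, pool)) for pool in mp.pools]
    pmf: dict = {}
    order_weight = 1.0 / math.factorial(k)

    def recurse(order, depth, chosen, weight):
        if depth == len(order):
            genes = [str(g) for g in gene_ids[list(chosen)]]
            overlap = count_overlapping_loci(genes, catalog)
            pmf[overlap] = pmf.get(overlap, 0.0) + weight
            return
        j = order[depth]
        avail = [x for x in pool_sets[j] if x not in chosen]
        if not avail:
            raise ValueError(
                "oracle does not model pool exhaustion; use a larger instance"
            )
        w = weight / len(avail)
        for pick in avail:
            chosen.append(pick)
            recurse(order, depth + 1, chosen, w)
            chosen.pop()

    for order in permutations(range(k)):
        recurse(order, 0, [], order_weight)
    total = sum(pmf.values())
    return {k_: v / total for k_, v in sorted(pmf.items())}


def oracle_mean(pmf: dict) -> float:
    """Expectation of an overlap pmf from :func:`exact_null_oracle`."""
    return sum(k * v for k, v in pmf.items())
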