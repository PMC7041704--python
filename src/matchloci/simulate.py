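"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the study design this pipeline analyses: a background
of ~10,000 expressed macrophage genes with log-normal expression and gene
length, a catalog of GWAS risk loci (mostly 1–3 candidate genes each), and
eight differential-expression contrast tables (wild-type and receptor-mutant
genotypes under LPS, IL-10, and combined stimulation, plus two interaction
terms).  Genes receive planted response-category labels — LPS-induced/
-suppressed in both genotypes, IL-10-repressed or -rescued subsets thereof,
and a small IL-10-alone set — and the emitted summary statistics are drawn so
that, at zero label noise, the downstream classifier recovers the labels
exactly.  Locus membership can be enriched for a target category by a
configurable fold, which is what the enrichment statistic must then recover.

DE tables are simulated at the summary level (log2 fold change and FDR): the
upstream count model fit is not part of this pipeline, and the classifier
consumes summaries only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .datamodel import CONTRASTS, DETable, GeneUniverse, LocusCatalog

#: Planted/derived category flags, in emission order.
FLAG_COLUMNS = (
    "lps_up_shared",
    "lps_down_shared",
    "il10_alone_up",
    "il10_alone_down",
    "il10_repressed",
    "il10_rescued",
    "il10_regulated",
)


@dataclass
class SimulationConfig:
    """Generator parameters.

    Category-size defaults mirror the study's reported response structure:
    ~10.5% of genes LPS-up and ~9.5% LPS-down in both genotypes, 29% of the
    LPS-up genes repressed by IL-10 co-treatment, 8% of the LPS-down genes
    rescued, and 25 genes responding to IL-10 alone.  The locus catalog
    defaults to 165 loci averaging ~2.2 candidate genes.  ``planted_fold``
    scales the probability that a locus member gene is drawn from
    ``target_category`` relative to that category's share of the universe
    (1.0 = no enrichment, the null).
    """

    n_genes: int = 10_000
    n_loci: int = 165
    locus_size_mean: float = 1.2  # extra genes per locus (Poisson mean)
    frac_lps_up: float = 0.105
    frac_lps_down: float = 0.095
    frac_repressed_of_up: float = 0.29
    frac_rescued_of_down: float = 0.08
    n_il10_alone: int = 25
    planted_fold: float = 1.0
    target_category: str = "il10_repressed"
    label_noise: float = 0.0
    alpha: float = 0.05
    expr_logmean: float = 1.0
    expr_logsd: float = 1.5
    len_logmean: float = math.log(3000.0)
    len_logsd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_lps_up", "frac_lps_down", "frac_repressed_of_up",
                     "frac_rescued_of_down"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_lps_up + self.frac_lps_down > 1.0:
            raise ValueError("frac_lps_up + frac_lps_down must be <= 1")
        if self.planted_fold < 0:
            raise ValueError("planted_fold must be >= 0")
        if not (0.0 <= self.label_noise < 1.0):
            raise ValueError("label_noise must lie in [0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.target_category not in FLAG_COLUMNS:
            raise ValueError(
                f"target_category must be one of {FLAG_COLUMNS}"
            )
        if self.n_loci < 1 or self.locus_size_mean < 0 or self.n_il10_alone < 0:
            raise ValueError("n_loci >= 1, locus_size_mean >= 0, n_il10_alone >= 0 required")

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.field_names()}


@dataclass
class TruthLabels:
    """Planted per-gene category flags plus per-locus target-draw records."""

    flags: pd.DataFrame
    locus_target_members: dict = field(default_factory=dict)

    def genes_in(self, category: str) -> list:
        return list(self.flags.index[self.flags[category]])


def _gene_ids(n_genes: int) -> list:
    width = max(4, len(str(n_genes)))
    return [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]


def generate_universe(config: SimulationConfig, rng: np.random.Generator) -> GeneUniverse:
    """Draw a log-normal expression/length background of ``n_genes`` genes."""
    if config.n_genes < 10:
        raise ValueError("n_genes must be >= 10 (percentile matching is meaningless below)")
    expression = rng.lognormal(config.expr_logmean, config.expr_logsd, config.n_genes)
    length = np.ceil(
        rng.lognormal(config.len_logmean, config.len_logsd, config.n_genes)
    ).astype(np.int64)
    length = np.maximum(length, 1)
    return GeneUniverse.from_values(_gene_ids(config.n_genes), expression, length)


def assign_categories(
    universe: GeneUniverse, config: SimulationConfig, rng: np.random.Generator
) -> TruthLabels:
    """Plant response-category labels with exact (round-half-even) counts.

    LPS-up and LPS-down base sets are disjoint; IL-10-repressed genes sit
    inside LPS-up, IL-10-rescued inside LPS-down, and IL-10-alone genes are
    drawn from outside both base sets (split into up/down at random).
    """
    n = len(universe)
    n_up = round(config.frac_lps_up * n)
    n_down = round(config.frac_lps_down * n)
    n_rep = round(config.frac_repressed_of_up * n_up)
    n_res = round(config.frac_rescued_of_down * n_down)
    n_alone = config.n_il10_alone
    if n_up + n_down > n:
        raise ValueError(
            f"infeasible: {n_up} LPS-up + {n_down} LPS-down exceeds {n} genes"
        )
    if n_alone > n - n_up - n_down:
        raise ValueError(
            f"infeasible: {n_alone} IL-10-alone genes requested but only "
            f"{n - n_up - n_down} genes lie outside the LPS base sets"
        )

    perm = rng.permutation(n)
    up = perm[:n_up]
    down = perm[n_up:n_up + n_down]
    alone = perm[n_up + n_down:n_up + n_down + n_alone]
    rep = up[:n_rep]
    res = down[:n_res]
    alone_up_mask = rng.random(n_alone) < 0.5

    flags = pd.DataFrame(
        False, index=pd.Index(universe.gene_ids, name="gene_id"),
        columns=list(FLAG_COLUMNS),
    )
    cols = flags.columns
    arr = flags.to_numpy()
    arr[up, cols.get_loc("lps_up_shared")] = True
    arr[down, cols.get_loc("lps_down_shared")] = True
    arr[rep, cols.get_loc("il10_repressed")] = True
    arr[res, cols.get_loc("il10_rescued")] = True
    arr[alone[alone_up_mask], cols.get_loc("il10_alone_up")] = True
    arr[alone[~alone_up_mask], cols.get_loc("il10_alone_down")] = True
    flags.iloc[:, :] = arr
    flags["il10_regulated"] = (
        flags["il10_alone_up"] | flags["il10_alone_down"]
        | flags["il10_repressed"] | flags["il10_rescued"]
    )
    return TruthLabels(flags=flags)


def generate_loci(
    universe: GeneUniverse,
    labels: TruthLabels,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> LocusCatalog:
    """Draw the locus catalog, optionally enriched for the target category.

    Each locus has ``1 + Poisson(locus_size_mean)`` member genes.  Every
    member is drawn from the target category with probability
    ``planted_fold x baseline`` (baseline = category share of the universe),
    otherwise uniformly from non-target genes; duplicates within a locus are
    redrawn.  The labels record which members came from the target draw.
    """
    n = len(universe)
    target_mask = labels.flags[config.target_category].to_numpy()
    target = np.flatnonzero(target_mask)
    nontarget = np.flatnonzero(~target_mask)
    baseline = len(target) / n
    p_star = config.planted_fold * baseline
    if p_star > 1.0:
        raise ValueError(
            f"infeasible enrichment: planted_fold x baseline = {p_star:.3f} > 1"
        )
    if config.planted_fold != 1.0 and len(target) == 0 and config.planted_fold != 0.0:
        raise ValueError("target category is empty; cannot plant enrichment")

    gene_ids = np.asarray(universe.gene_ids)
    sizes = 1 + rng.poisson(config.locus_size_mean, config.n_loci)
    width = max(3, len(str(config.n_loci)))
    loci: dict = {}
    target_members: dict = {}
    for k, size in enumerate(sizes, start=1):
        locus_id = f"L{k:0{width}d}"
        members: set = set()
        from_target: set = set()
        while len(members) < size:
            if len(target) and rng.random() < p_star:
                idx = int(target[rng.integers(len(target))])
                is_target_draw = True
            else:
                idx = int(nontarget[rng.integers(len(nontarget))])
                is_target_draw = False
            if idx in members:
                continue
            members.add(idx)
            if is_target_draw:
                from_target.add(idx)
        loci[locus_id] = frozenset(gene_ids[list(members)])
        target_members[locus_id] = frozenset(gene_ids[list(from_target)])
    labels.locus_target_members = target_members
    return LocusCatalog(loci)


def _emit_table(
    contrast_id: str,
    gene_ids,
    planted_sig: np.ndarray,
    planted_sign: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> DETable:
    n = len(gene_ids)
    # fixed draw order keeps tables reproducible regardless of noise level
    flip = rng.random(n) < config.label_noise
    rand_sign = rng.integers(0, 2, n) * 2 - 1
    mag_sig = 1.0 + np.abs(rng.normal(0.8, 0.4, n))
    fc_nonsig = rng.normal(0.0, 0.3, n)
    fdr_sig = rng.uniform(0.0, config.alpha, n)
    fdr_nonsig = rng.uniform(config.alpha, 1.0, n)

    emitted = planted_sig ^ flip
    sign = np.where(planted_sign != 0, planted_sign, rand_sign)
    log2fc = np.where(emitted, sign * mag_sig, fc_nonsig)
    fdr = np.where(emitted, fdr_sig, fdr_nonsig)
    frame = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": fdr * 0.5, "fdr": fdr},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return DETable(contrast_id, frame)


def generate_contrast_tables(
    universe: GeneUniverse,
    labels: TruthLabels,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict:
    """Emit all eight DE tables consistent with the planted labels.

    Significant genes get |log2fc| = 1 + |N(0.8, 0.4)| (linear FC > 2) with
    the planted sign and FDR ~ U(0, alpha); non-significant genes get
    log2fc ~ N(0, 0.3) and FDR ~ U(alpha, 1).  Interaction tables are
    significant exactly for genes whose WT and KO planted states differ.
    ``label_noise`` flips each emitted significance call independently
    (planted truth is unchanged).  The raw p-value column is a placeholder
    (fdr/2); downstream logic reads only log2fc and fdr.
    """
    f = labels.flags
    up = f["lps_up_shared"].to_numpy()
    down = f["lps_down_shared"].to_numpy()
    alone_up = f["il10_alone_up"].to_numpy()
    alone_down = f["il10_alone_down"].to_numpy()
    rep = f["il10_repressed"].to_numpy()
    res = f["il10_rescued"].to_numpy()
    zeros = np.zeros(len(f), dtype=np.int64)

    lps_sig = up | down
    lps_sign = np.where(up, 1, np.where(down, -1, 0))
    alone_sig = alone_up | alone_down
    alone_sign = np.where(alone_up, 1, np.where(alone_down, -1, 0))
    mod_sig = rep | res
    mod_sign = np.where(rep, -1, np.where(res, 1, 0))

    plan = {
        "WT_LPS_vs_unstim": (lps_sig, lps_sign),
        "KO_LPS_vs_unstim": (lps_sig, lps_sign),
        "WT_IL10_vs_unstim": (alone_sig, alone_sign),
        "KO_IL10_vs_unstim": (np.zeros(len(f), dtype=bool), zeros),
        "WT_IL10LPS_vs_LPS": (mod_sig, mod_sign),
        "KO_IL10LPS_vs_LPS": (np.zeros(len(f), dtype=bool), zeros),
        "INTERACTION_IL10": (alone_sig, alone_sign),
        "INTERACTION_IL10LPS": (mod_sig, mod_sign),
    }
    gene_ids = list(f.index)
    return {
        cid: _emit_table(cid, gene_ids, sig, sign, config, rng)
        for cid, (sig, sign) in ((c, plan[c]) for c in CONTRASTS)
    }


@dataclass
class SimulatedDataset:
    """A complete synthetic run: background, truth, loci, and DE tables."""

    config: SimulationConfig
    universe: GeneUniverse
    labels: TruthLabels
    catalog: LocusCatalog
    tables: dict


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset; all randomness flows from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    universe = generate_universe(config, rng)
    labels = assign_categories(universe, config, rng)
    catalog = generate_loci(universe, labels, config, rng)
    tables = generate_contrast_tables(universe, labels, config, rng)
    return SimulatedDataset(config, universe, labels, catalog, tables)


def synthetic_published_overlap_lists(
    n_regulated: int = 369, n_candidates: int = 361, n_shared: int = 21
) -> tuple:
    """Synthetic stand-in for the published gene-list overlap analysis.

    The study data underlying the real lists (IL-10-regulated genes and
    prioritized GWAS candidates) are under restricted access, so this builds
    a synthetic pair of identifier lists at the published cardinalities: a
    369-gene regulated list and a 361-gene candidate list sharing exactly 21
    genes.  Intended for worked examples and tests of the overlap stage.
    """
    if n_shared > min(n_regulated, n_candidates):
        raise ValueError("shared genes cannot exceed either list size")
    shared = [f"SHARED{i:03d}" for i in range(1, n_shared + 1)]
    reg_only = [f"REG{i:04d}" for i in range(1, n_regulated - n_shared + 1)]
    cand_only = [f"CAND{i:04d}" for i in range(1, n_candidates - n_shared + 1)]
    return shared + reg_only, shared + cand_only
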