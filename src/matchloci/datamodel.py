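"""Core domain types shared by every pipeline stage.

The pipeline operates on four containers: a gene universe (the expressed-gene
background with expression and gene-length covariates and their percentiles),
per-contrast differential-expression summary tables, a catalog of GWAS risk
loci (each a named set of candidate genes), and an analysis configuration that
holds the significance and matching parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.stats import rankdata

#: Controlled vocabulary of differential-expression contrasts.  WT is the
#: IL-10-responsive genotype; KO the IL-10-receptor-deficient genotype.
CONTRASTS = (
    "WT_LPS_vs_unstim",
    "KO_LPS_vs_unstim",
    "WT_IL10_vs_unstim",
    "KO_IL10_vs_unstim",
    "WT_IL10LPS_vs_LPS",
    "KO_IL10LPS_vs_LPS",
    "INTERACTION_IL10",
    "INTERACTION_IL10LPS",
)

#: Contrasts the classifier always needs (the genotype-by-treatment
#: interaction tables are optional unless ``require_interaction`` is set).
REQUIRED_CONTRASTS = CONTRASTS[:6]
INTERACTION_CONTRASTS = CONTRASTS[6:]


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(ValueError):
    """A file parses but its contents violate a domain invariant."""


def compute_percentiles(values) -> np.ndarray:
    """Average-rank percentiles on a 0–100 scale.

    The percentile of value ``v`` is ``100 * rank(v) / N`` where tied values
    receive the average of the ranks they span.  Output order matches input
    order; distinct values map to strictly increasing percentiles.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute percentiles of an empty sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError("percentile input contains non-finite values")
    return 100.0 * rankdata(arr, method="average") / arr.size


@dataclass(frozen=True)
class GeneUniverse:
    """All expressed genes with covariates and matching percentiles.

    ``frame`` is indexed by gene_id with columns ``expression``, ``length_bp``,
    ``expr_pct`` and ``len_pct``; the percentile columns are the coordinates
    used for covariate-matched null sampling.
    """

    frame: pd.DataFrame

    @classmethod
    def from_values(cls, gene_ids, expression, length_bp) -> "GeneUniverse":
        gene_ids = list(gene_ids)
        if len(set(gene_ids)) != len(gene_ids):
            seen, dups = set(), []
            for g in gene_ids:
                if g in seen:
                    dups.append(g)
                seen.add(g)
            raise ValidationError(f"duplicate gene_id(s) in universe: {sorted(set(dups))}")
        if any(not isinstance(g, str) or not g for g in gene_ids):
            raise ValidationError("gene_id must be a non-empty string")
        expr = np.asarray(expression, dtype=float)
        length = np.asarray(length_bp)
        if expr.size != len(gene_ids) or length.size != len(gene_ids):
            raise ValidationError("gene_ids, expression and length_bp must align")
        if expr.size and (not np.all(np.isfinite(expr)) or np.any(expr < 0)):
            raise ValidationError("expression must be finite and non-negative")
        if length.size and (np.any(length < 1) or np.any(length != np.floor(length))):
            raise ValidationError("length_bp must be integers >= 1")
        frame = pd.DataFrame(
            {"expression": expr, "length_bp": length.astype(np.int64)},
            index=pd.Index(gene_ids, name="gene_id"),
        )
        if len(frame):
            frame["expr_pct"] = compute_percentiles(frame["expression"].to_numpy())
            frame["len_pct"] = compute_percentiles(frame["length_bp"].to_numpy())
        else:
            frame["expr_pct"] = np.empty(0)
            frame["len_pct"] = np.empty(0)
        return cls(frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.frame.index

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)


@dataclass(frozen=True)
class DETable:
    """One contrast's differential-expression summary, keyed by gene.

    ``frame`` is indexed by gene_id with columns ``log2fc``, ``pvalue`` and
    ``fdr``.  Genes absent from a table are treated downstream as
    non-significant in that contrast.
    """

    contrast_id: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.contrast_id not in CONTRASTS:
            raise ValidationError(
                f"unknown contrast_id {self.contrast_id!r}; expected one of {CONTRASTS}"
            )
        if self.frame.index.has_duplicates:
            dups = sorted(self.frame.index[self.frame.index.duplicated()].unique())
            raise ValidationError(f"duplicate gene_id(s) in DE table: {dups}")
        for col in ("pvalue", "fdr"):
            vals = self.frame[col].to_numpy(dtype=float)
            if vals.size and (np.any(vals < 0) or np.any(vals > 1) or not np.all(np.isfinite(vals))):
                raise ValidationError(f"{col} values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class LocusCatalog:
    """GWAS risk loci as named gene sets, with a gene-to-loci reverse index.

    A gene may belong to several loci; overlap with a gene list is always
    counted at the locus level (a locus counts once no matter how many of its
    members hit the list).
    """

    loci: dict
    gene_to_loci: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        loci = {k: frozenset(v) for k, v in self.loci.items()}
        for locus_id, members in loci.items():
            if not members:
                raise ValidationError(f"locus {locus_id!r} has no member genes")
        object.__setattr__(self, "loci", loci)
        reverse: dict = {}
        for locus_id, members in loci.items():
            for g in members:
                reverse.setdefault(g, set()).add(locus_id)
        object.__setattr__(
            self, "gene_to_loci", {g: frozenset(s) for g, s in reverse.items()}
        )

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def genes(self) -> frozenset:
        return frozenset(self.gene_to_loci)

    @property
    def n_genes(self) -> int:
        return len(self.gene_to_loci)


@dataclass
class AnalysisConfig:
    """Thresholds and matching parameters for classification and enrichment.

    alpha
        FDR significance threshold (default 0.05).
    fold_change_min
        Linear fold-change threshold; a call requires |log2fc| > log2(this).
    require_interaction
        Additionally require the genotype-by-treatment interaction term to be
        significant for the IL-10-modulated categories.
    match_window_pct
        Half-width, in percentile points, of the joint expression/length
        matching window for null genes (default 5).
    n_null
        Number of matched null gene sets (default 10,000).
    widen_step_pct
        Increment by which an empty matching pool's window is widened.
    conservative_p
        Use (r+1)/(B+1) instead of r/B for the empirical P value.
    subnet_fold_change_gate
        Apply the fold-change threshold (not just FDR) when retaining
        subnetwork nodes.
    """

    alpha: float = 0.05
    fold_change_min: float = 2.0
    require_interaction: bool = False
    match_window_pct: float = 5.0
    n_null: int = 10_000
    widen_step_pct: float = 1.0
    seed: int = 0
    conservative_p: bool = False
    subnet_fold_change_gate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.fold_change_min < 1.0:
            raise ValidationError("fold_change_min must be >= 1")
        if self.match_window_pct <= 0:
            raise ValidationError("match_window_pct must be > 0")
        if self.n_null < 1:
            raise ValidationError("n_null must be >= 1")
        if self.widen_step_pct <= 0:
            raise ValidationError("widen_step_pct must be > 0")

    @property
    def log2fc_min(self) -> float:
        return math.log2(self.fold_change_min)

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))
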