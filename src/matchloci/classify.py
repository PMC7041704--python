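"""IL-10 response categories by set algebra over significance calls.

A gene is called significant in a contrast when FDR < alpha and
|log2fc| > log2(fold_change_min), with the sign matching the requested
direction.  Categories (non-exclusive):

* ``lps_up_shared`` / ``lps_down_shared`` — induced/suppressed by LPS in both
  the wild-type and the receptor-deficient genotype.
* ``il10_alone_up`` / ``il10_alone_down`` — regulated by IL-10 alone in
  wild-type cells with no call in the mutant.
* ``il10_repressed`` — LPS-induced in both genotypes, with the induction
  significantly reduced by IL-10 co-treatment in wild-type but not mutant.
* ``il10_rescued`` — the symmetric rescue of LPS-suppressed genes.
* ``il10_regulated`` — the union of the IL-10-dependent flags.

Optionally (``require_interaction``), the IL-10-dependent categories also
require the genotype-by-treatment interaction term to be significant.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .datamodel import (
    AnalysisConfig,
    DETable,
    INTERACTION_CONTRASTS,
    REQUIRED_CONTRASTS,
)
from .simulate import FLAG_COLUMNS

log = logging.getLogger("matchloci")


def is_significant(log2fc: float, fdr: float, config: AnalysisConfig,
                   direction: str = "any") -> bool:
    """Joint FDR + fold-change significance call for a single DE row."""
    if direction not in ("up", "down", "any"):
        raise ValueError("direction must be 'up', 'down' or 'any'")
    if not (fdr < config.alpha and abs(log2fc) > config.log2fc_min):
        return False
    if direction == "up":
        return log2fc > 0
    if direction == "down":
        return log2fc < 0
    return True


def significance_mask(table: DETable, genes: pd.Index, config: AnalysisConfig,
                      direction: str = "any") -> np.ndarray:
    """Vectorised :func:`is_significant` aligned to ``genes``.

    Genes absent from the table are non-significant.
    """
    aligned = table.frame.reindex(genes)
    log2fc = aligned["log2fc"].to_numpy(dtype=float)
    fdr = aligned["fdr"].to_numpy(dtype=float)
    present = ~np.isnan(fdr)
    log2fc = np.nan_to_num(log2fc)
    fdr = np.where(present, fdr, 1.0)
    sig = present & (fdr < config.alpha) & (np.abs(log2fc) > config.log2fc_min)
    if direction == "up":
        sig &= log2fc > 0
    elif direction == "down":
        sig &= log2fc < 0
    elif direction != "any":
        raise ValueError("direction must be 'up', 'down' or 'any'")
    n_absent = int((~present).sum())
    if n_absent:
        log.info(
            "%s: %d of %d genes absent from table, treated as non-significant",
            table.contrast_id, n_absent, len(genes),
        )
    return sig


def classify_genes(tables: dict, config: AnalysisConfig,
                   genes=None) -> pd.DataFrame:
    """Compute per-gene category flags from the eight contrast tables.

    ``tables`` maps contrast_id to :class:`DETable`; the six genotype
    contrasts are required, the two interaction tables only when
    ``config.require_interaction``.  ``genes`` fixes the output index
    (default: the sorted union of genes across the supplied tables).
    Returns a boolean frame with one column per flag.
    """
    needed = list(REQUIRED_CONTRASTS)
    if config.require_interaction:
        needed += list(INTERACTION_CONTRASTS)
    for cid in needed:
        if cid not in tables:
            raise KeyError(f"missing required contrast table: {cid}")

    if genes is None:
        all_genes: set = set()
        for cid in needed:
            all_genes.update(tables[cid].frame.index)
        genes = pd.Index(sorted(all_genes), name="gene_id")
    else:
        genes = pd.Index(genes, name="gene_id")

    def sig(cid: str, direction: str) -> np.ndarray:
        return significance_mask(tables[cid], genes, config, direction)

    lps_up = sig("WT_LPS_vs_unstim", "up") & sig("KO_LPS_vs_unstim", "up")
    lps_down = sig("WT_LPS_vs_unstim", "down") & sig("KO_LPS_vs_unstim", "down")
    alone_up = sig("WT_IL10_vs_unstim", "up") & ~sig("KO_IL10_vs_unstim", "any")
    alone_down = sig("WT_IL10_vs_unstim", "down") & ~sig("KO_IL10_vs_unstim", "any")
    repressed = (
        lps_up
        & sig("WT_IL10LPS_vs_LPS", "down")
        & ~sig("KO_IL10LPS_vs_LPS", "down")
    )
    rescued = (
        lps_down
        & sig("WT_IL10LPS_vs_LPS", "up")
        & ~sig("KO_IL10LPS_vs_LPS", "up")
    )
    if config.require_interaction:
        inter_il10 = sig("INTERACTION_IL10", "any")
        inter_il10lps = sig("INTERACTION_IL10LPS", "any")
        alone_up &= inter_il10
        alone_down &= inter_il10
        repressed &= inter_il10lps
        rescued &= inter_il10lps

    flags = pd.DataFrame(
        {
            "lps_up_shared": lps_up,
            "lps_down_shared": lps_down,
            "il10_alone_up": alone_up,
            "il10_alone_down": alone_down,
            "il10_repressed": repressed,
            "il10_rescued": rescued,
        },
        index=genes,
    )
    flags["il10_regulated"] = (
        flags["il10_alone_up"] | flags["il10_alone_down"]
        | flags["il10_repressed"] | flags["il10_rescued"]
    )
    return flags[list(FLAG_COLUMNS)]


def category_fractions(flags: pd.DataFrame) -> dict:
    """Per-flag counts plus the repressed-of-up and rescued-of-down fractions.

    Fractions are NaN (with a warning) when their denominator is empty.
    """
    counts = {col: int(flags[col].sum()) for col in flags.columns}
    n_up = counts["lps_up_shared"]
    n_down = counts["lps_down_shared"]
    if n_up == 0:
        log.warning("no LPS-up-shared genes; repressed_fraction undefined")
        repressed_fraction = math.nan
    else:
        repressed_fraction = counts["il10_repressed"] / n_up
    if n_down == 0:
        log.warning("no LPS-down-shared genes; rescued_fraction undefined")
        rescued_fraction = math.nan
    else:
        rescued_fraction = counts["il10_rescued"] / n_down
    return {
        "counts": counts,
        "repressed_fraction": repressed_fraction,
        "rescued_fraction": rescued_fraction,
    }
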