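"""Readers and writers for the pipeline's tab-separated file formats.

All files are tab-delimited UTF-8 with a required header row; lines starting
with ``#`` are comments.  Formats:

* ``universe.tsv``   — gene_id, expression, length_bp
* ``loci.tsv``       — locus_id, gene_id (long format, one membership per row)
* ``de_<contrast>.tsv`` — gene_id, log2fc, pvalue, fdr
* ``edges.tsv``      — gene_a, gene_b (undirected interaction edges)
* gene lists         — one gene_id per line
* ``config.yaml``    — keys mirroring :class:`~matchloci.datamodel.AnalysisConfig`
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .datamodel import (
    AnalysisConfig,
    DETable,
    FormatError,
    GeneUniverse,
    LocusCatalog,
    ValidationError,
)

log = logging.getLogger("matchloci")


def _read_tsv(path, required: tuple) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty (header row required)") from None
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    return frame


def read_universe(path) -> GeneUniverse:
    """Read a gene universe and compute matching percentiles."""
    frame = _read_tsv(path, ("gene_id", "expression", "length_bp"))
    try:
        universe = GeneUniverse.from_values(
            frame["gene_id"], frame["expression"], frame["length_bp"]
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None
    log.info("read_universe %s: %d genes", path, len(universe))
    return universe


def write_universe(universe: GeneUniverse, path) -> None:
    universe.frame[["expression", "length_bp"]].to_csv(path, sep="\t")


def read_de_table(path, contrast_id: str) -> DETable:
    """Read one contrast's DE summary table."""
    frame = _read_tsv(path, ("gene_id", "log2fc", "pvalue", "fdr"))
    frame = frame.set_index("gene_id")
    try:
        table = DETable(contrast_id, frame[["log2fc", "pvalue", "fdr"]])
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None
    log.info("read_de_table %s (%s): %d rows", path, contrast_id, len(table))
    return table


def write_de_table(table: DETable, path) -> None:
    table.frame.to_csv(path, sep="\t")


def read_loci(path) -> LocusCatalog:
    """Read a locus catalog in long format (locus_id, gene_id per row).

    Parsed line by line so malformed rows can be reported with their line
    number.
    """
    path = Path(path)
    loci: dict = {}
    header_seen = False
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if not header_seen:
                if parts[:2] != ["locus_id", "gene_id"]:
                    raise FormatError(
                        f"{path}: line {lineno}: expected header 'locus_id\\tgene_id'"
                    )
                header_seen = True
                continue
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise FormatError(f"{path}: line {lineno}: empty or missing field")
            locus_id, gene_id = parts[0].strip(), parts[1].strip()
            loci.setdefault(locus_id, set()).add(gene_id)
    if not header_seen:
        raise FormatError(f"{path}: file is empty (header row required)")
    catalog = LocusCatalog(loci)
    log.info(
        "read_loci %s: %d loci, %d distinct genes",
        path, catalog.n_loci, catalog.n_genes,
    )
    return catalog


def write_loci(catalog: LocusCatalog, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("locus_id\tgene_id\n")
        for locus_id in sorted(catalog.loci):
            for gene_id in sorted(catalog.loci[locus_id]):
                handle.write(f"{locus_id}\t{gene_id}\n")


def read_gene_list(path) -> list:
    """Read a plain gene list, one id per line, '#' comments allowed."""
    genes = []
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for g in genes:
            handle.write(f"{g}\n")


def read_edges(path) -> list:
    """Read an undirected edge list (gene_a, gene_b)."""
    frame = _read_tsv(path, ("gene_a", "gene_b"))
    if frame[["gene_a", "gene_b"]].isna().any().any():
        raise FormatError(f"{path}: edge row with empty field")
    return list(zip(frame["gene_a"].astype(str), frame["gene_b"].astype(str)))


def load_config(path) -> AnalysisConfig:
    """Load an analysis configuration from YAML; unknown keys are rejected."""
    with open(path, encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    unknown = set(data) - set(AnalysisConfig.field_names())
    if unknown:
        raise ValidationError(f"{path}: unknown config key(s): {sorted(unknown)}")
    return AnalysisConfig(**data)


def dump_config(config: AnalysisConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(
            {name: getattr(config, name) for name in AnalysisConfig.field_names()},
            handle,
            sort_keys=True,
        )
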