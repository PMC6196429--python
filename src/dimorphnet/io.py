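"""Readers and writers for the tabular formats used throughout the pipeline.

All tables are plain TSV with a header row.  Gene sets travel as GMT
(name, description, then tab-separated gene ids).  Genomic coordinates are
1-based inclusive in every table that carries them.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

GWAS_COLUMNS = ["snp", "chrom", "pos", "pvalue"]
EQTL_COLUMNS = ["snp", "gene", "pvalue", "snp_pos", "gene_start", "gene_end"]


# ---------------------------------------------------------------- expression

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    First column holds gene ids, remaining columns one sample each.
    Zero-variance genes are dropped with a warning (they carry no
    correlation information and would produce NaN adjacencies).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise DataError(f"{path}: duplicate gene or sample ids")
    variances = df.var(axis=1)
    flat = variances[variances == 0].index
    if len(flat):
        logger.warning("dropping %d zero-variance genes from %s", len(flat), path)
        df = df.drop(index=flat)
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_trait(path: str | Path) -> pd.Series:
    """Read a per-sample trait vector (columns: sample, value)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise DataError(f"{path}: expected two columns (sample, value)")
    s = pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str))
    s.index.name = "sample"
    return s


def write_trait(trait: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample": trait.index, "value": trait.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


# ------------------------------------------------------------------ genetics

def read_gwas(path: str | Path) -> pd.DataFrame:
    """Read GWAS summary statistics (snp, chrom, pos, pvalue).

    P-value bounds (0, 1] and snp uniqueness are enforced on read.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str})
    missing = set(GWAS_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    if df["snp"].duplicated().any():
        raise DataError(f"{path}: duplicate snp ids")
    p = df["pvalue"].to_numpy(float)
    if ((p <= 0) | (p > 1)).any():
        raise DataError(f"{path}: pvalue outside (0, 1]")
    return df[GWAS_COLUMNS]


def write_gwas(gwas: pd.DataFrame, path: str | Path) -> None:
    gwas[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_eqtl(path: str | Path, p_cut: float | None = None) -> pd.DataFrame:
    """Read a cis-eQTL table (snp, gene, pvalue, snp_pos, gene_start, gene_end).

    With ``p_cut`` set (strict mode) rows at or above the threshold are
    rejected at load time.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "gene": str})
    missing = set(EQTL_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    if p_cut is not None and (df["pvalue"] >= p_cut).any():
        raise DataError(f"{path}: eQTL pvalue >= {p_cut} in strict mode")
    return df[EQTL_COLUMNS]


def write_eqtl(eqtl: pd.DataFrame, path: str | Path) -> None:
    eqtl[EQTL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ld(path: str | Path) -> dict[str, str]:
    """Read SNP -> LD block assignments (snp, block_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected columns (snp, block_id)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_ld(blocks: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"snp": list(blocks.keys()), "block_id": list(blocks.values())}
    ).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- gene sets

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into an ordered mapping name -> gene set.

    Duplicate genes within a record are collapsed with a warning; an empty
    file yields an empty collection.  Lines with fewer than 3 fields are an
    error (reported with the line number).
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, genes = fields[0], fields[2:]
            genes = [g for g in genes if g]
            unique = set(genes)
            if len(unique) < len(genes):
                logger.warning(
                    "%s:%d: %d duplicate genes collapsed in set %s",
                    path, lineno, len(genes) - len(unique), name,
                )
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = unique
    return sets


def write_gmt(sets: Mapping[str, set[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ------------------------------------------------------------------ networks

def read_network_edges(path: str | Path) -> list[tuple[str, str]]:
    """Read an edge-list TSV (node_a, node_b); header optional."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataError(f"{path}:{lineno}: edge line has fewer than 2 fields")
            a, b = fields[0], fields[1]
            if lineno == 1 and (a.lower(), b.lower()) == ("node_a", "node_b"):
                continue
            edges.append((a, b))
    return edges


def write_network_edges(edges, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-column gene list (header optional, first column used)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df.iloc[:, 0].dropna().tolist()
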