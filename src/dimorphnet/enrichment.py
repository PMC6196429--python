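"""Fisher's exact test utilities: module annotation, overlap tables, lookups.

All tests are one-sided (enrichment) hypergeometric tails on a 2x2 table of
joint membership over an explicit gene universe — the universe is always a
required input because enrichment values are meaningless without it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError


def normalize_gene_id(gene: str) -> str:
    """Canonical gene-symbol form: upper case, stripped (ortholog display)."""
    return gene.strip().upper()


@dataclass
class ContingencyResult:
    query_id: str
    reference_id: str
    overlap: int
    query_size: int
    reference_size: int
    universe_size: int
    fold_change: float
    pvalue: float
    adjusted_p: float = float("nan")
    method: str = ""


def fisher_overlap(
    query: set[str],
    reference: set[str],
    universe: set[str],
    query_id: str = "query",
    reference_id: str = "reference",
) -> ContingencyResult:
    """One-sided Fisher's exact (hypergeometric) test of set overlap.

    fold_change = (overlap/|query|) / (|reference|/|universe|).
    """
    if not universe or not query:
        raise DataError("empty universe or query set")
    if not query <= universe or not reference <= universe:
        raise DataError("query and reference must be subsets of the universe")
    n, kq, kr = len(universe), len(query), len(reference)
    k = len(query & reference)
    p = float(stats.hypergeom.sf(k - 1, n, kr, kq))
    fold = (k / kq) / (kr / n) if kr else float("nan")
    return ContingencyResult(query_id, reference_id, k, kq, kr, n, fold, p)


@dataclass
class AnnotationResult:
    module_id: str
    pathway_id: str
    overlap: int
    pvalue: float
    adjusted_p: float
    tier: str  # "significant" | "suggestive"


def annotate_modules(
    modules: Mapping[str, set[str]],
    pathways: Mapping[str, set[str]],
    universe: set[str],
    min_overlap: int = 5,
    alpha: float = 0.05,
    suggestive_p: float = 5e-3,
    top_n: int = 5,
) -> list[AnnotationResult]:
    """Annotate each module with its top enriched pathways.

    Bonferroni correction over the pathways tested per module; significant
    terms need adjusted P < alpha and >= ``min_overlap`` shared genes, at
    most ``top_n`` reported per module.  Modules without significant terms
    fall back to suggestive annotations (uncorrected P < ``suggestive_p``,
    same overlap floor), also capped at ``top_n``.
    """
    if not pathways:
        raise DataError("empty pathway collection")
    n_tests = len(pathways)
    results: list[AnnotationResult] = []
    for mod_id, mod_genes in modules.items():
        mod = mod_genes & universe
        if not mod:
            continue
        hits = []
        for pw_id, pw_genes in pathways.items():
            pw = pw_genes & universe
            if not pw:
                continue
            res = fisher_overlap(mod, pw, universe, mod_id, pw_id)
            adj = min(res.pvalue * n_tests, 1.0)
            hits.append((pw_id, res.overlap, res.pvalue, adj))
        significant = sorted(
            (h for h in hits if h[3] < alpha and h[1] >= min_overlap),
            key=lambda h: (h[3], h[2], h[0]))[:top_n]
        if significant:
            results.extend(
                AnnotationResult(mod_id, pw, k, p, adj, "significant")
                for pw, k, p, adj in significant)
        else:
            suggestive = sorted(
                (h for h in hits if h[2] < suggestive_p and h[1] >= min_overlap),
                key=lambda h: (h[2], h[0]))[:top_n]
            results.extend(
                AnnotationResult(mod_id, pw, k, p, adj, "suggestive")
                for pw, k, p, adj in suggestive)
    return results


def annotation_table(results: list[AnnotationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.module_id, r.pathway_id, r.overlap, r.pvalue, r.adjusted_p, r.tier)
         for r in results],
        columns=["module_id", "pathway_id", "overlap", "pvalue",
                 "adjusted_p", "tier"])


def deg_overlap_table(
    networks: Mapping[str, set[str]],
    deg_lists: Mapping[str, set[str]],
    universe: set[str],
    key_drivers: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Condition-matched overlap between subnetwork genes and DEG lists.

    Keys of ``networks`` and ``deg_lists`` are condition labels (for example
    ``liver_M``) and must match pairwise; each matched pair yields one row
    with the overlap gene list, the overlapping key drivers for that
    condition (if given), the fold change, and the one-sided Fisher P.
    """
    unmatched = set(networks) - set(deg_lists)
    if unmatched:
        raise DataError(f"no DEG list for conditions: {sorted(unmatched)}")
    rows = []
    for label in networks:
        res = fisher_overlap(networks[label], deg_lists[label], universe,
                             label, f"DEG_{label}")
        shared = sorted(networks[label] & deg_lists[label])
        kd = sorted(set(shared) & set((key_drivers or {}).get(label, set())))
        rows.append((label, res.query_size, res.reference_size, res.overlap,
                     len(kd), ",".join(kd), ",".join(shared),
                     res.fold_change, res.pvalue))
    return pd.DataFrame(rows, columns=[
        "condition", "network_size", "deg_size", "overlap", "overlap_kd_size",
        "overlap_kd_list", "overlap_genes", "fold_change", "pvalue"])


def known_gene_lookup(
    key_drivers: Iterable[str],
    known_list: Iterable[str],
) -> pd.DataFrame:
    """Intersection of key drivers with a curated disease-gene list.

    Ids are matched after symbol normalization; the report keeps the
    original spellings as provenance.
    """
    drivers = list(key_drivers)
    known = list(known_list)
    if not drivers or not known:
        raise DataError("both gene lists must be non-empty")
    known_map: dict[str, str] = {}
    for g in known:
        known_map.setdefault(normalize_gene_id(g), g)
    rows = [
        (d, known_map[normalize_gene_id(d)], normalize_gene_id(d))
        for d in drivers if normalize_gene_id(d) in known_map
    ]
    return pd.DataFrame(rows, columns=["key_driver", "known_as", "symbol"])
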