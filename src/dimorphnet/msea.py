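"""Marker set enrichment analysis (MSEA).

Genes of each query set are mapped to their cis-eSNPs (eQTL P below a
cutoff, SNP within a window of the gene body), trimmed to one eSNP per LD
block, and the GWAS P-values of the surviving markers are scored with a
quantile-based modified chi-square statistic

    chi = sum_i (O_i - E_i) / (sqrt(E_i) + kappa)

over quantile thresholds spanning the top 50% to the top 99.9% of GWAS
ranks (10 points, kappa = 1).  Significance comes from the chi values of
size-matched random gene sets mapped and pruned identically; a one-sided
Gaussian tail P is primary, with the empirical P reported alongside.
Benjamini-Hochberg FDR < 0.05 defines the significant sets.

The statistic is rank-based: it is invariant under any strictly monotone
transform applied jointly to all GWAS P-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

DEFAULT_TOP_RANGE = (0.50, 0.999)


@dataclass
class ChiComputation:
    """One evaluation of the quantile-count modified chi-square statistic."""

    chi: float
    observed: np.ndarray  # O_i per quantile point
    expected: np.ndarray  # E_i per quantile point
    thresholds: np.ndarray  # P-value threshold q_i per quantile point
    n_markers: int
    kappa: float = 1.0


def chi_statistic(
    set_pvalues: Sequence[float],
    all_pvalues: Sequence[float],
    n_quantiles: int = 10,
    top_range: tuple[float, float] = DEFAULT_TOP_RANGE,
    kappa: float = 1.0,
) -> ChiComputation:
    """Quantile-count chi statistic of a marker P-value set vs background.

    Thresholds q_i are background order statistics at the (1 - f_i) rank
    quantiles with f_i evenly spaced over ``top_range``; O_i counts set
    markers with P <= q_i; E_i = m * (empirical background fraction <= q_i)
    so ties in P-values cannot bias O - E.
    """
    set_p = np.sort(np.asarray(set_pvalues, dtype=float))
    if set_p.size == 0:
        raise DataError("empty marker set")
    bg = np.sort(np.asarray(all_pvalues, dtype=float))
    f = np.linspace(top_range[0], top_range[1], n_quantiles)
    ranks = np.maximum((np.ceil((1.0 - f) * bg.size)).astype(int), 1)
    q = bg[ranks - 1]
    frac = np.searchsorted(bg, q, side="right") / bg.size
    observed = np.searchsorted(set_p, q, side="right").astype(float)
    expected = set_p.size * frac
    chi = float(np.sum((observed - expected) / (np.sqrt(expected) + kappa)))
    return ChiComputation(chi, observed, expected, q, int(set_p.size), kappa)


def map_genes_to_esnps(
    genes: Iterable[str],
    eqtl: pd.DataFrame,
    cis_window: int = 1_000_000,
    p_cut: float = 1e-6,
) -> set[str]:
    """SNPs with an eQTL (P < p_cut) to any query gene, within the cis window."""
    genes = set(genes)
    sub = eqtl[eqtl["gene"].isin(genes) & (eqtl["pvalue"] < p_cut)]
    in_window = (
        (sub["snp_pos"] >= sub["gene_start"] - cis_window)
        & (sub["snp_pos"] <= sub["gene_end"] + cis_window)
    )
    return set(sub.loc[in_window, "snp"])


def prune_ld(
    esnps: Iterable[str],
    ld: Mapping[str, str],
    eqtl: pd.DataFrame,
    gwas: pd.DataFrame,
) -> set[str]:
    """Keep one eSNP per LD block: the best (smallest) eQTL P, ties by snp id.

    SNPs absent from the LD map are treated as singleton blocks.
    """
    esnps = set(esnps)
    known = set(gwas["snp"])
    missing = esnps - known
    if missing:
        raise DataError(f"{len(missing)} eSNPs absent from the GWAS table")
    best_p = eqtl[eqtl["snp"].isin(esnps)].groupby("snp")["pvalue"].min()
    chosen: dict[str, tuple[float, str]] = {}
    for snp in sorted(esnps):
        block = ld.get(snp, f"__singleton__{snp}")
        cand = (float(best_p.get(snp, 1.0)), snp)
        if block not in chosen or cand < chosen[block]:
            chosen[block] = cand
    return {snp for _, snp in chosen.values()}


class MseaIndex:
    """Pre-indexed GWAS + eQTL + LD data for fast repeated map/prune/score.

    Rows of the filtered eQTL table are sorted by (LD block, eQTL P, snp id)
    so that LD pruning of any gene set reduces to a first-occurrence scan
    over blocks; chi thresholds over the GWAS background are precomputed.
    """

    def __init__(
        self,
        gwas: pd.DataFrame,
        eqtl: pd.DataFrame,
        ld: Mapping[str, str],
        cis_window: int = 1_000_000,
        p_cut: float = 1e-6,
        n_quantiles: int = 10,
        top_range: tuple[float, float] = DEFAULT_TOP_RANGE,
        kappa: float = 1.0,
    ) -> None:
        self.kappa = kappa
        snp_ids = gwas["snp"].to_numpy(str)
        if len(set(snp_ids)) != len(snp_ids):
            raise DataError("duplicate snp ids in GWAS table")
        self._gwas_p = dict(zip(snp_ids, gwas["pvalue"].to_numpy(float)))

        sub = eqtl[eqtl["pvalue"] < p_cut].copy()
        sub = sub[
            (sub["snp_pos"] >= sub["gene_start"] - cis_window)
            & (sub["snp_pos"] <= sub["gene_end"] + cis_window)
        ]
        sub = sub[sub["snp"].isin(self._gwas_p)]
        blocks = [ld.get(s, f"__singleton__{s}") for s in sub["snp"]]
        sub = sub.assign(block=blocks).sort_values(
            ["block", "pvalue", "snp"], kind="stable").reset_index(drop=True)

        self._row_gene = sub["gene"].to_numpy(str)
        self._row_block = pd.factorize(sub["block"])[0]
        self._row_p = np.array([self._gwas_p[s] for s in sub["snp"]])
        self._row_snp = sub["snp"].to_numpy(str)

        order = np.argsort(self._row_gene, kind="stable")
        sorted_genes = self._row_gene[order]
        uniq, starts = np.unique(sorted_genes, return_index=True)
        ends = np.append(starts[1:], len(sorted_genes))
        self._gene_rows = {
            g: order[s:e] for g, s, e in zip(uniq, starts, ends)
        }
        self.mapped_genes = set(uniq.tolist())

        bg = np.sort(gwas["pvalue"].to_numpy(float))
        f = np.linspace(top_range[0], top_range[1], n_quantiles)
        ranks = np.maximum((np.ceil((1.0 - f) * bg.size)).astype(int), 1)
        self._q = bg[ranks - 1]
        self._frac = np.searchsorted(bg, self._q, side="right") / bg.size
        self._null_cache: dict[tuple[int, int, int], np.ndarray] = {}

    # -- mapping ---------------------------------------------------------

    def marker_rows(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices of the pruned marker set for a gene set."""
        parts = [self._gene_rows[g] for g in genes if g in self._gene_rows]
        if not parts:
            return np.array([], dtype=int)
        rows = np.sort(np.concatenate(parts))
        blocks = self._row_block[rows]
        _, first = np.unique(blocks, return_index=True)
        return rows[first]

    def markers(self, genes: Iterable[str]) -> set[str]:
        return set(self._row_snp[self.marker_rows(genes)].tolist())

    # -- scoring ---------------------------------------------------------

    def chi_from_rows(self, rows: np.ndarray) -> float:
        p = np.sort(self._row_p[rows])
        observed = np.searchsorted(p, self._q, side="right")
        expected = p.size * self._frac
        return float(np.sum((observed - expected) / (np.sqrt(expected) + self.kappa)))

    def chi(self, genes: Iterable[str]) -> tuple[float, int]:
        rows = self.marker_rows(genes)
        if rows.size == 0:
            return np.nan, 0
        return self.chi_from_rows(rows), int(rows.size)

    def null_chis(
        self,
        gene_count: int,
        universe: Sequence[str],
        n_null: int = 1000,
        seed: int = 0,
    ) -> np.ndarray:
        """Chi values of ``n_null`` random gene sets of ``gene_count`` genes.

        Cached by (gene_count, n_null, seed); the universe is assumed fixed
        for the lifetime of the index.
        """
        key = (gene_count, n_null, seed)
        if key not in self._null_cache:
            rng = np.random.default_rng([seed, gene_count])
            uni = np.asarray(universe)
            chis = []
            for _ in range(n_null):
                genes = uni[rng.choice(len(uni), size=gene_count, replace=False)]
                rows = self.marker_rows(genes)
                if rows.size:
                    chis.append(self.chi_from_rows(rows))
            if len(chis) < 10:
                raise DataError(
                    "fewer than 10 non-degenerate null sets; universe too sparse")
            self._null_cache[key] = np.array(chis)
        return self._null_cache[key]


def msea_pvalue(
    chi_observed: float,
    gene_count: int,
    index: MseaIndex,
    universe: Sequence[str],
    n_null: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float, float]:
    """One-sided P of an observed chi against size-matched random gene sets.

    Returns (gaussian_p, empirical_p, null_mean, null_sd).  The empirical P
    is floored at 1/(n_null + 1) so it is never exactly zero.
    """
    if n_null < 100:
        raise DataError("n_null must be >= 100")
    null = index.null_chis(gene_count, universe, n_null=n_null, seed=seed)
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    gauss = float(stats.norm.sf((chi_observed - mean) / sd)) if sd > 0 else \
        (0.5 if chi_observed == mean else float(chi_observed < mean))
    empirical = max((1 + int(np.sum(null >= chi_observed))) / (null.size + 1),
                    1.0 / (n_null + 1))
    return gauss, empirical, mean, sd


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted P-values (monotone step-up)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def run_msea(
    gene_sets: Mapping[str, set[str]],
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    ld: Mapping[str, str],
    cis_window: int = 1_000_000,
    p_cut: float = 1e-6,
    n_quantiles: int = 10,
    top_range: tuple[float, float] = DEFAULT_TOP_RANGE,
    kappa: float = 1.0,
    n_null: int = 1000,
    fdr_cut: float = 0.05,
    seed: int = 0,
    universe: Sequence[str] | None = None,
    index: MseaIndex | None = None,
) -> pd.DataFrame:
    """Score every gene set for GWAS enrichment through its pruned eSNPs.

    Returns one row per set (set_id, n_genes, n_markers, chi, pvalue,
    p_empirical, fdr, significant, status).  Sets mapping to zero markers get
    status 'unmapped' and are excluded from the BH correction.
    """
    if not gene_sets:
        raise DataError("empty gene set collection")
    if index is None:
        index = MseaIndex(gwas, eqtl, ld, cis_window=cis_window, p_cut=p_cut,
                          n_quantiles=n_quantiles, top_range=top_range,
                          kappa=kappa)
    if universe is None:
        uni = set(index.mapped_genes)
        for members in gene_sets.values():
            uni |= set(members)
        universe = sorted(uni)

    rows = []
    for name, members in gene_sets.items():
        chi, n_markers = index.chi(members)
        if n_markers == 0:
            rows.append((name, len(members), 0, np.nan, np.nan, np.nan, "unmapped"))
            continue
        gauss, emp, _, _ = msea_pvalue(
            chi, len(members), index, universe, n_null=n_null, seed=seed)
        rows.append((name, len(members), n_markers, chi, gauss, emp, "tested"))
    table = pd.DataFrame(
        rows, columns=["set_id", "n_genes", "n_markers", "chi", "pvalue",
                       "p_empirical", "status"])
    table["fdr"] = np.nan
    tested = table["status"] == "tested"
    if tested.any():
        table.loc[tested, "fdr"] = multipletests(
            table.loc[tested, "pvalue"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = tested & (table["fdr"] < fdr_cut)
    return table
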